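"""Synthetic structure/sequence/metadata generation.

Builds families of sequence variants with idealized backbone geometry so
that every other module can be exercised without downloading anything:
helices and strands from ideal torsion angles, hinge-motion pairs for
open/closed conformational comparisons, geometric ligand placements for
contact detection, unmodeled gaps, and pLDDT profiles for computed models.

All randomness flows from a single seeded :class:`numpy.random.Generator`
per :class:`FixtureSpec`, so a fixed seed yields byte-identical output
files.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .model_io import (
    Atom,
    DomainAnnotation,
    DomainSource,
    LigandInstance,
    PolymerEntity,
    PolymerInstance,
    Provenance,
    ResidueRecord,
    Sidecar,
    StructureModel,
    write_fasta,
    write_structure,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# ideal backbone parameters (lengths in Angstrom, angles in degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA = 180.0

#: ideal torsions per secondary-structure element
TORSIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
}


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position atom d given three predecessors and internal coordinates
    (natural extension reference frame)."""
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(chi),
        bond * math.sin(theta) * math.sin(chi),
    ])
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def build_ideal_chain(
    ss_layout: Sequence[tuple[str, int]],
    sequence: str,
    entry_id: str = "FIX1",
    chain_id: str = "A",
    rng: np.random.Generator | None = None,
) -> StructureModel:
    """Build an N/CA/C/O backbone from ideal torsions.

    Helix: phi=-57, psi=-47; strand: phi=-139, psi=+135; coil: seeded
    random torsions.  Layout lengths must sum to the sequence length.
    """
    total = sum(n for _, n in ss_layout)
    if total != len(sequence) or total == 0:
        raise ValueError(
            f"layout length {total} != sequence length {len(sequence)}"
        )
    rng = rng if rng is not None else np.random.default_rng(0)
    phis: list[float] = []
    psis: list[float] = []
    for element, n in ss_layout:
        for _ in range(n):
            if element in TORSIONS:
                phi, psi = TORSIONS[element]
            elif element == "coil":
                phi = float(rng.uniform(-180, 0))
                psi = float(rng.uniform(-90, 180))
            else:
                raise ValueError(f"unknown element {element!r}")
            phis.append(phi)
            psis.append(psi)

    L = len(sequence)
    N = np.zeros((L, 3))
    CA = np.zeros((L, 3))
    C = np.zeros((L, 3))
    theta = math.radians(ANGLE_N_CA_C)
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    C[0] = CA[0] + BOND_CA_C * np.array([-math.cos(theta), math.sin(theta), 0.0])
    for i in range(L - 1):
        N[i + 1] = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psis[i])
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C,
                              phis[i + 1])
    residues = []
    for i, aa in enumerate(sequence):
        psi_o = psis[i] - 180.0
        O = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi_o)
        atoms = [
            Atom("N", "N", *np.round(N[i], 4)),
            Atom("CA", "C", *np.round(CA[i], 4)),
            Atom("C", "C", *np.round(C[i], 4)),
            Atom("O", "O", *np.round(O, 4)),
        ]
        residues.append(ResidueRecord(i + 1, aa, modeled=True, atoms=atoms))
    inst = PolymerInstance(chain_id, f"{entry_id}_1", residues)
    return StructureModel(entry_id, [inst])


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = math.radians(angle_deg)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)


def make_hinge_pair(base: StructureModel, pivot_seq_pos: int,
                    rotation_deg: float) -> StructureModel:
    """Rigidly rotate all residues at or beyond the pivot about an axis
    through the pivot CA, leaving the N-terminal side untouched.

    The axis is built from the *fixed* side of the chain (the incoming
    chain direction at the pivot crossed with a lab axis), so repeated
    application composes exactly: two 30 deg hinges equal one 60 deg hinge.
    """
    chain = base.chains[0]
    positions = {r.seq_pos for r in chain.residues if r.modeled}
    if pivot_seq_pos <= min(positions) or pivot_seq_pos >= max(positions):
        raise ValueError("pivot must be strictly inside the chain")
    pivot_res = next(r for r in chain.residues if r.seq_pos == pivot_seq_pos)
    prev_res = next(r for r in chain.residues if r.seq_pos == pivot_seq_pos - 1)
    pivot_ca = np.array(pivot_res.atom("CA")[2:])
    prev_ca = np.array(prev_res.atom("CA")[2:])
    v_fixed = pivot_ca - prev_ca
    e = np.array([1.0, 0.0, 0.0])
    if np.linalg.norm(np.cross(v_fixed, e)) < 1e-6:
        e = np.array([0.0, 1.0, 0.0])
    axis = np.cross(v_fixed, e)
    R = rotation_about_axis(axis, rotation_deg)

    out = copy.deepcopy(base)
    for inst in out.chains:
        for rec in inst.residues:
            if rec.seq_pos < pivot_seq_pos or not rec.modeled:
                continue
            rec.atoms = [
                Atom(a.name, a.element,
                     *(R @ (np.array([a.x, a.y, a.z]) - pivot_ca) + pivot_ca))
                for a in rec.atoms
            ]
    return out


# ---------------------------------------------------------------------------
# group fixture


class PlddtRegion(BaseModel):
    """Mean/sd of the pLDDT profile over one equal slice of the chain."""

    mean: float = Field(ge=0, le=100)
    sd: float = Field(ge=0)


class LigandSite(BaseModel):
    comp_id: str
    anchor_seq_pos: int
    offset: float = Field(gt=0, description="placement distance from the anchor CA, Angstrom")


class FixtureSpec(BaseModel):
    """Parameters of a synthetic group of sequence variants.

    The defaults emulate the archival situation the group tools target: a
    family of nine near-identical protein variants -- five experimental
    entries and four computed models -- of a two-domain, ~100-residue
    protein with a sugar-like single-ligand binding site, sparse point
    mutations, occasional unmodeled loops in the experimental entries, and
    a high-confidence-core pLDDT profile on the computed models.
    """

    seed: int = 0
    n_entities: int = Field(default=9, ge=1)
    n_computed: int = Field(default=4, ge=0)
    length_range: tuple[int, int] = (100, 100)
    mutation_rate: float = Field(default=0.05, ge=0, le=1)
    unmodeled_gap_prob: float = Field(default=0.3, ge=0, le=1)
    coordinate_noise_sd: float = Field(
        default=0.3, ge=0,
        description="per-member Gaussian coordinate jitter, Angstrom; "
                    "emulates independent determinations of one fold")
    ss_layout: list[tuple[str, int]] | None = None
    hinge: tuple[int, float] | None = None
    ligand_sites: list[LigandSite] = Field(
        default_factory=lambda: [LigandSite(comp_id="GLC", anchor_seq_pos=48, offset=3.5)]
    )
    plddt_profile: list[PlddtRegion] = Field(
        default_factory=lambda: [
            PlddtRegion(mean=62, sd=8),
            PlddtRegion(mean=92, sd=3),
            PlddtRegion(mean=68, sd=8),
        ]
    )
    organism: str = "Escherichia coli"
    accession: str = "P0AEE5"

    @model_validator(mode="after")
    def _check(self) -> "FixtureSpec":
        if self.n_computed > self.n_entities:
            raise ValueError("n_computed exceeds n_entities")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 10:
            raise ValueError("bad length_range")
        return self


@dataclass
class GroupFixture:
    """In-memory result of :func:`build_group_fixture`."""

    entities: list[PolymerEntity]
    structures: dict[str, StructureModel]
    sidecar: Sidecar


def default_layout(length: int) -> list[tuple[str, int]]:
    """Alternating helix/coil/strand/coil layout covering ``length``."""
    layout: list[tuple[str, int]] = []
    pattern = [("helix", 12), ("coil", 4), ("strand", 8), ("coil", 4)]
    remaining = length
    i = 0
    while remaining > 0:
        element, n = pattern[i % len(pattern)]
        n = min(n, remaining)
        layout.append((element, n))
        remaining -= n
        i += 1
    return layout


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Point-mutate each position with probability ``rate``, drawing the
    replacement uniformly from all 20 residues (so the expected identity to
    the input is 1 - rate * 19/20)."""
    out = []
    for c in seq:
        if rng.random() < rate:
            out.append(AA20[int(rng.integers(20))])
        else:
            out.append(c)
    return "".join(out)


def build_group_fixture(spec: FixtureSpec) -> GroupFixture:
    """Generate the entities, structures and sidecar tables of one group."""
    rng = np.random.default_rng(spec.seed)
    length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    ancestral = "".join(AA20[int(i)] for i in rng.integers(0, 20, size=length))
    layout = spec.ss_layout or default_layout(length)

    entities: list[PolymerEntity] = []
    structures: dict[str, StructureModel] = {}
    ent_rows = []
    dom_rows = []
    mid = length // 2
    for k in range(spec.n_entities):
        computed = k >= spec.n_entities - spec.n_computed
        if computed:
            entry_id = f"CSM_{k + 1:03d}"
            uid = entry_id
        else:
            entry_id = f"{k + 1:04d}"
            uid = f"{entry_id}_1"
        seq = ancestral if k == 0 else mutate_sequence(ancestral, spec.mutation_rate, rng)
        # one shared backbone per group: members are conformers of one fold,
        # so coil torsions come from a generator re-seeded per fixture
        sm = build_ideal_chain(layout, seq, entry_id=entry_id,
                               rng=np.random.default_rng(spec.seed))
        sm.chains[0].entity_uid = uid
        if spec.hinge is not None and k % 2 == 1:
            sm = make_hinge_pair(sm, spec.hinge[0], spec.hinge[1])
        if spec.coordinate_noise_sd > 0:
            _jitter(sm, spec.coordinate_noise_sd, rng)
        sm.provenance = Provenance.COMPUTED if computed else Provenance.EXPERIMENTAL
        if computed:
            _apply_plddt(sm, spec.plddt_profile, rng)
        else:
            _apply_gaps(sm, spec.unmodeled_gap_prob, rng)
            _place_ligands(sm, spec.ligand_sites)
        ent = PolymerEntity(
            entity_uid=uid,
            entry_id=entry_id,
            sequence=seq,
            provenance=sm.provenance,
            accession=spec.accession,
            organism=spec.organism,
            release_date=f"{2015 + (k % 9)}-06-01",
            deposition_group_id=None if computed else "G_0001",
            domain_annotations=[
                DomainAnnotation(DomainSource.PFAM, "PF00001", 1, mid),
                DomainAnnotation(DomainSource.PFAM, "PF00002", mid + 1, length),
            ],
        )
        entities.append(ent)
        structures[uid] = sm
        ent_rows.append({
            "entity_uid": uid,
            "accession": ent.accession,
            "organism": ent.organism,
            "release_date": ent.release_date,
            "deposition_group_id": ent.deposition_group_id or "",
            "provenance": ent.provenance.value,
        })
        for d in ent.domain_annotations:
            dom_rows.append({
                "entity_uid": uid, "source": d.source.value,
                "domain_id": d.domain_id, "begin": d.begin, "end": d.end,
            })
    import pandas as pd

    sidecar = Sidecar(pd.DataFrame(ent_rows), pd.DataFrame(dom_rows))
    return GroupFixture(entities, structures, sidecar)


def _jitter(sm: StructureModel, sd: float, rng: np.random.Generator) -> None:
    for inst in sm.chains:
        for rec in inst.residues:
            rec.atoms = [
                Atom(a.name, a.element,
                     *np.round(np.array([a.x, a.y, a.z])
                               + rng.normal(scale=sd, size=3), 4))
                for a in rec.atoms
            ]


def _apply_plddt(sm: StructureModel, profile: list[PlddtRegion],
                 rng: np.random.Generator) -> None:
    for inst in sm.chains:
        n = len(inst.residues)
        bounds = np.linspace(0, n, len(profile) + 1).astype(int)
        for ri, rec in enumerate(inst.residues):
            region = int(np.searchsorted(bounds[1:], ri, side="right"))
            region = min(region, len(profile) - 1)
            val = rng.normal(profile[region].mean, profile[region].sd)
            rec.confidence = float(np.clip(round(val, 2), 0.0, 100.0))


def _apply_gaps(sm: StructureModel, gap_prob: float,
                rng: np.random.Generator) -> None:
    """With probability ``gap_prob`` (twice), blank out an interior loop of
    4-12 residues, emulating unmodeled density."""
    for inst in sm.chains:
        n = len(inst.residues)
        for _ in range(2):
            if rng.random() >= gap_prob:
                continue
            glen = int(rng.integers(4, 13))
            start = int(rng.integers(5, max(6, n - glen - 5)))
            for rec in inst.residues[start:start + glen]:
                rec.modeled = False
                rec.atoms = []
                rec.confidence = None


def _place_ligands(sm: StructureModel, sites: list[LigandSite]) -> None:
    """Place each ligand's single heavy atom at ``offset`` Angstrom from the
    anchor CA, pointing away from the chain centroid (out of the backbone)."""
    chain = sm.chains[0]
    cas = {r.seq_pos: np.array(r.atom("CA")[2:])
           for r in chain.residues if r.modeled and r.atom("CA")}
    if not cas:
        return
    centroid = np.mean(list(cas.values()), axis=0)
    for site in sites:
        ca = cas.get(site.anchor_seq_pos)
        if ca is None:
            continue
        direction = ca - centroid
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 1e-6 else np.array([0.0, 0.0, 1.0])
        pos = ca + site.offset * direction
        sm.ligands.append(LigandInstance(
            site.comp_id, chain.chain_id,
            [Atom("C1", "C", *np.round(pos, 4))],
        ))


def make_group_fixture(spec: FixtureSpec, out_dir: str | Path) -> GroupFixture:
    """Generate a fixture set and write it to ``out_dir``: one mmCIF per
    entry, ``sequences.fasta``, ``entities.tsv`` and ``domains.tsv``."""
    fx = build_group_fixture(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for uid, sm in fx.structures.items():
        ent = next(e for e in fx.entities if e.entity_uid == uid)
        write_structure(sm, out / f"{sm.entry_id}.cif",
                        sequences={uid: ent.sequence})
    write_fasta(fx.entities, out / "sequences.fasta")
    fx.sidecar.write(out / "entities.tsv", out / "domains.tsv")
    return fx
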