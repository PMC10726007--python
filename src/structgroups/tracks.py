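"""Positional tracks: per-alignment-column structural information.

Maps member-level structural observations (modeled regions, pLDDT,
secondary structure, domain families, ligand contacts, point mutations)
onto the column system of a group alignment.  Three kinds of denominator
are used deliberately:

* structural-feature frequencies divide by members with a *modeled* residue
  at the column,
* per-ligand binding frequencies divide by members contacting that ligand
  *anywhere* (so a ligand seen in one member still shows frequency 1.0 at
  its site, instead of being diluted by the group size),
* the global binding histogram is a raw count of (member, ligand) contact
  events per column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import StrEnum
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .model_io import PolymerEntity, Provenance, StructureModel

if TYPE_CHECKING:  # pragma: no cover
    from .alignment import GroupAlignment
    from .groups import Group

logger = logging.getLogger(__name__)

#: heavy-atom distance defining a protein-ligand contact, Angstrom
CONTACT_CUTOFF = 4.5

#: pLDDT confidence bins (lower edges, half-open on the lower side)
PLDDT_BINS = (("very-high", 90.0), ("confident", 70.0), ("low", 50.0),
              ("very-low", float("-inf")))


class TrackKind(StrEnum):
    SYMBOL = "symbol"
    FRACTION = "fraction"
    COUNT = "count"
    REGION = "region"
    SCORE = "score"


@dataclass
class PositionalTrack:
    """Per-column values (or column-region list) for one group track."""

    track_id: str
    group_id: str
    kind: TrackKind
    values: list
    provenance_note: str = ""

    def __post_init__(self) -> None:
        if self.kind is TrackKind.FRACTION:
            for v in self.values:
                if v is not None and not (0.0 <= v <= 1.0):
                    raise ValueError(f"fraction value {v} outside [0,1]")
        if self.kind is TrackKind.COUNT:
            for v in self.values:
                if v is not None and (v < 0 or int(v) != v):
                    raise ValueError(f"count value {v} invalid")


@dataclass
class ContactRecord:
    """One residue-ligand contact (minimum heavy-atom distance <= cutoff)."""

    member_uid: str
    seq_pos: int
    comp_id: str
    min_distance: float


# ---------------------------------------------------------------------------
# per-member coordinate-derived tracks


def _member_chain(structure: StructureModel, member_uid: str):
    chains = structure.chains_of_entity(member_uid)
    if not chains:
        raise KeyError(f"{member_uid} not present in entry {structure.entry_id}")
    return chains[0]


def modeled_track(member_uid: str, structure: StructureModel,
                  ga: "GroupAlignment") -> PositionalTrack:
    """Modeled/unmodeled regions of one member, in alignment columns.

    The two region lists partition the member's aligned columns.
    """
    if member_uid not in ga.members:
        raise KeyError(f"{member_uid} not in group alignment")
    chain = _member_chain(structure, member_uid)
    modeled_by_pos = {r.seq_pos: r.modeled for r in chain.residues}
    modeled_cols: list[int] = []
    unmodeled_cols: list[int] = []
    for reg in ga.members[member_uid]:
        for c in range(reg.column_begin, reg.column_end + 1):
            pos = reg.member_begin + (c - reg.column_begin)
            (modeled_cols if modeled_by_pos.get(pos, False)
             else unmodeled_cols).append(c)
    return PositionalTrack(
        track_id=f"modeled:{member_uid}", group_id=ga.group_id,
        kind=TrackKind.REGION,
        values=[("modeled", _runs(modeled_cols)),
                ("unmodeled", _runs(unmodeled_cols))],
        provenance_note="columns with experimentally defined coordinates",
    )


def _runs(cols: Sequence[int]) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    for c in cols:
        if runs and c == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], c)
        else:
            runs.append((c, c))
    return runs


def plddt_track(member_uid: str, structure: StructureModel,
                ga: "GroupAlignment") -> tuple[PositionalTrack, PositionalTrack]:
    """Per-column pLDDT of a computed model plus its categorical binning
    (very-high >= 90, confident [70, 90), low [50, 70), very-low < 50)."""
    if structure.provenance is not Provenance.COMPUTED:
        raise ValueError("pLDDT tracks exist only for computed models")
    chain = _member_chain(structure, member_uid)
    conf_by_pos = {r.seq_pos: r.confidence for r in chain.residues if r.modeled}
    scores: list[float | None] = [None] * ga.n_columns
    cats: list[str | None] = [None] * ga.n_columns
    for reg in ga.members[member_uid]:
        for c in range(reg.column_begin, reg.column_end + 1):
            pos = reg.member_begin + (c - reg.column_begin)
            conf = conf_by_pos.get(pos)
            if conf is None:
                continue
            scores[c - 1] = conf
            cats[c - 1] = plddt_bin(conf)
    return (
        PositionalTrack(f"plddt:{member_uid}", ga.group_id, TrackKind.SCORE,
                        scores, "per-residue prediction confidence"),
        PositionalTrack(f"plddt_bin:{member_uid}", ga.group_id,
                        TrackKind.SYMBOL, cats, "pLDDT confidence category"),
    )


def plddt_bin(conf: float) -> str:
    for label, lo in PLDDT_BINS:
        if conf >= lo:
            return label
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# secondary structure (CA-geometry assignment)


def assign_secondary_structure(structure: StructureModel
                               ) -> dict[str, dict[int, str]]:
    """Per-residue H/E/C labels from CA geometry (P-SEA-style criteria).

    Works from CA coordinates alone, so it applies equally to experimental
    entries and computed models.  Stretches shorter than 5 modeled residues
    cannot support a helix/strand assignment and come back all-C.
    """
    import biotite.structure as struc

    out: dict[str, dict[int, str]] = {}
    for chain in structure.chains:
        recs = [r for r in chain.residues if r.modeled and r.atom("CA")]
        labels: dict[int, str] = {}
        # split into contiguous modeled segments; assign each independently
        segments: list[list] = []
        for r in recs:
            if segments and r.seq_pos == segments[-1][-1].seq_pos + 1:
                segments[-1].append(r)
            else:
                segments.append([r])
        for seg in segments:
            if len(seg) < 5:
                for r in seg:
                    labels[r.seq_pos] = "C"
                continue
            arr = struc.AtomArray(len(seg))
            for i, r in enumerate(seg):
                a = r.atom("CA")
                arr.coord[i] = (a.x, a.y, a.z)
                arr.chain_id[i] = chain.chain_id
                arr.res_id[i] = r.seq_pos
                arr.res_name[i] = "ALA"
                arr.atom_name[i] = "CA"
                arr.element[i] = "C"
            sse = struc.annotate_sse(arr)
            mapped = {"a": "H", "b": "E", "c": "C"}
            for r, s in zip(seg, sse):
                labels[r.seq_pos] = mapped.get(str(s), "C")
        out[chain.chain_id] = labels
    return out


def feature_frequency_track(
    group: "Group",
    ga: "GroupAlignment",
    feature: str | tuple[str, str, str],
    structures: Mapping[str, StructureModel] | None = None,
    entities: Iterable[PolymerEntity] | None = None,
) -> PositionalTrack:
    """Fraction of members carrying a feature at each column.

    ``feature`` is ``"helix"``, ``"strand"``, or ``("domain", source, id)``.
    The denominator is the number of members with a modeled residue at the
    column (``None`` where it is zero).
    """
    if isinstance(feature, str):
        if feature not in ("helix", "strand"):
            raise ValueError(f"unknown feature {feature!r}")
        target = {"helix": "H", "strand": "E"}[feature]
        if structures is None:
            raise ValueError("structural features require structures")
        has_feature, is_modeled = _structure_feature_maps(ga, structures, target)
        track_id = feature
    else:
        kind, source, domain_id = feature
        if kind != "domain":
            raise ValueError(f"unknown feature {feature!r}")
        if entities is None or structures is None:
            raise ValueError("domain features require entities and structures")
        from .model_io import DomainSource

        DomainSource(source)  # validates the source name
        _, is_modeled = _structure_feature_maps(ga, structures, target=None)
        has_feature = {}
        by_uid = {e.entity_uid: e for e in entities}
        for uid in ga.members:
            ent = by_uid.get(uid)
            if ent is None:
                continue
            positions = set()
            for d in ent.domain_annotations:
                if d.source.value == source and d.domain_id == domain_id:
                    positions.update(range(d.begin, d.end + 1))
            has_feature[uid] = positions
        track_id = f"domain:{source}:{domain_id}"

    values: list[float | None] = []
    for col in range(1, ga.n_columns + 1):
        denom = 0
        num = 0
        for uid in ga.members:
            pos = ga.member_pos_at(uid, col)
            if pos is None or pos not in is_modeled.get(uid, set()):
                continue
            denom += 1
            if pos in has_feature.get(uid, set()):
                num += 1
        values.append(None if denom == 0 else num / denom)
    return PositionalTrack(track_id, ga.group_id, TrackKind.FRACTION, values,
                           "fraction of members with the feature, over "
                           "members modeled at the column")


def _structure_feature_maps(ga: "GroupAlignment",
                            structures: Mapping[str, StructureModel],
                            target: str | None):
    has_feature: dict[str, set[int]] = {}
    is_modeled: dict[str, set[int]] = {}
    for uid in ga.members:
        sm = structures.get(uid)
        if sm is None:
            continue
        chain = _member_chain(sm, uid)
        is_modeled[uid] = {r.seq_pos for r in chain.residues if r.modeled}
        if target is not None:
            sse = assign_secondary_structure(sm)[chain.chain_id]
            has_feature[uid] = {p for p, s in sse.items() if s == target}
    return has_feature, is_modeled


# ---------------------------------------------------------------------------
# ligand contacts and binding tracks


def detect_contacts(structure: StructureModel, member_uid: str,
                    cutoff: float = CONTACT_CUTOFF) -> list[ContactRecord]:
    """All (residue, ligand component) pairs with any heavy-atom pair within
    ``cutoff`` Angstrom.  Hydrogens are ignored; waters never appear as
    ligands.  Plain all-pairs distances (desk-scale structures)."""
    records: list[ContactRecord] = []
    chains = structure.chains_of_entity(member_uid)
    if not chains or not structure.ligands:
        return records
    for lig in structure.ligands:
        lig_xyz = np.array([(a.x, a.y, a.z) for a in lig.atoms
                            if a.element.upper() != "H"])
        if lig_xyz.size == 0:
            continue
        best: dict[int, float] = {}
        for chain in chains:
            for rec in chain.residues:
                if not rec.modeled:
                    continue
                res_xyz = np.array([(a.x, a.y, a.z) for a in rec.atoms
                                    if a.element.upper() != "H"])
                if res_xyz.size == 0:
                    continue
                d = float(cdist(res_xyz, lig_xyz).min())
                if d <= cutoff:
                    best[rec.seq_pos] = min(d, best.get(rec.seq_pos, np.inf))
        for pos in sorted(best):
            records.append(ContactRecord(member_uid, pos, lig.comp_id, best[pos]))
    return records


def binding_tracks(
    group: "Group",
    ga: "GroupAlignment",
    contacts: Iterable[ContactRecord],
) -> tuple[PositionalTrack, dict[str, PositionalTrack]]:
    """Global binding histogram and per-ligand relative frequencies.

    global[c] counts (member, ligand) contact events at column c.
    per_ligand[L][c] = members contacting L at column c / members contacting
    L anywhere -- the relative normalization that keeps rarely-present
    ligands from showing near-zero frequencies.
    """
    contacts = list(contacts)
    global_counts = [0] * ga.n_columns
    by_ligand: dict[str, dict[str, set[int]]] = {}
    for rec in contacts:
        if rec.member_uid not in ga.members:
            continue
        col = ga.column_of(rec.member_uid, rec.seq_pos)
        if col is None:
            continue
        global_counts[col - 1] += 1
        by_ligand.setdefault(rec.comp_id, {}).setdefault(
            rec.member_uid, set()).add(col)
    global_track = PositionalTrack(
        "global_binding", ga.group_id, TrackKind.COUNT, global_counts,
        "(member, ligand) contact events per column")
    per_ligand: dict[str, PositionalTrack] = {}
    for comp_id, member_cols in sorted(by_ligand.items()):
        n_binders = len(member_cols)
        if n_binders == 0:
            continue
        vals: list[float] = []
        for col in range(1, ga.n_columns + 1):
            n = sum(1 for cols in member_cols.values() if col in cols)
            vals.append(n / n_binders)
        per_ligand[comp_id] = PositionalTrack(
            f"binding:{comp_id}", ga.group_id, TrackKind.FRACTION, vals,
            f"fraction of the {n_binders} members contacting {comp_id}")
    return global_track, per_ligand


# ---------------------------------------------------------------------------
# mutation markers


def mutation_markers(member_uid: str, ga: "GroupAlignment",
                     sequences: Mapping[str, str]) -> set[int]:
    """Columns where the member residue differs from the reference residue
    (substitutions only; gaps are not markers)."""
    ref = ga.reference_sequence
    out: set[int] = set()
    seq = sequences[member_uid]
    for reg in ga.members[member_uid]:
        for c in range(reg.column_begin, reg.column_end + 1):
            pos = reg.member_begin + (c - reg.column_begin)
            if seq[pos - 1] != ref[c - 1]:
                out.add(c)
    return out


# ---------------------------------------------------------------------------
# TSV export (BED-like)


def tracks_to_tsv(tracks: Iterable[PositionalTrack], path) -> None:
    """Write value tracks as (group_id, track_id, column_begin, column_end,
    value) rows, collapsing runs of equal values."""
    with open(path, "w") as fh:
        fh.write("group_id\ttrack_id\tcolumn_begin\tcolumn_end\tvalue\n")
        for tr in tracks:
            if tr.kind is TrackKind.REGION:
                for label, runs in tr.values:
                    for b, e in runs:
                        fh.write(f"{tr.group_id}\t{tr.track_id}\t{b}\t{e}\t{label}\n")
                continue
            run_start = None
            run_val = object()
            for i, v in enumerate(list(tr.values) + [object()], start=1):
                if v != run_val:
                    if run_start is not None and run_val is not None:
                        fh.write(f"{tr.group_id}\t{tr.track_id}\t{run_start}"
                                 f"\t{i - 1}\t{run_val}\n")
                    run_start, run_val = i, v
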