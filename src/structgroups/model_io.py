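"""Structure, sequence and metadata I/O.

Projects mmCIF (PDBx) and legacy PDB files onto the archival hierarchy used
throughout the package:

* entry  -- one deposited structure (or one computed model),
* entity -- a unique polymer sequence within an entry,
* instance -- one occurrence (chain) of an entity.

Experimental entries and computed structure models (CSMs) share the same
in-memory representation; a CSM carries its per-residue prediction
confidence (pLDDT, 0-100) copied from the isotropic B-factor column.
Residues that belong to the entity sequence but have no atomic coordinates
are kept as explicit ``modeled=False`` records so that downstream alignment
tracks can distinguish unmodeled stretches from deletions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import StrEnum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import gemmi
import pandas as pd

logger = logging.getLogger(__name__)

#: the 20 standard one-letter codes plus 'X' for anything non-standard
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}
_THREE_TO_ONE = {v: k for k, v in _ONE_TO_THREE.items() if k != "X"}


class Provenance(StrEnum):
    """Origin of a structure: experimentally determined or computed."""

    EXPERIMENTAL = "experimental"
    COMPUTED = "computed"


class DomainSource(StrEnum):
    SCOP = "SCOP"
    CATH = "CATH"
    PFAM = "PFAM"
    ECOD = "ECOD"


class Atom(NamedTuple):
    name: str
    element: str
    x: float
    y: float
    z: float


@dataclass
class DomainAnnotation:
    """A domain-family assignment over a 1-based inclusive sequence range."""

    source: DomainSource
    domain_id: str
    begin: int
    end: int


@dataclass
class PolymerEntity:
    """One polymer sequence with provenance and optional metadata.

    The unit of grouping: reference-accession and sequence-identity groups
    collect entities, never chains.  ``entity_uid`` is globally unique --
    ``"<entry_id>_<entity_id>"`` for experimental entries, the model id for
    computed models.
    """

    entity_uid: str
    entry_id: str
    sequence: str
    provenance: Provenance = Provenance.EXPERIMENTAL
    accession: str | None = None
    description: str | None = None
    organism: str | None = None
    release_date: str | None = None
    deposition_group_id: str | None = None
    domain_annotations: list[DomainAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"entity {self.entity_uid}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"entity {self.entity_uid}: invalid residue codes {sorted(bad)}"
            )
        for d in self.domain_annotations:
            if not (1 <= d.begin <= d.end <= len(self.sequence)):
                raise ValueError(
                    f"entity {self.entity_uid}: domain {d.domain_id} range "
                    f"({d.begin},{d.end}) outside sequence of length "
                    f"{len(self.sequence)}"
                )


@dataclass
class ResidueRecord:
    """One position of an entity sequence within a chain.

    ``seq_pos`` is the 1-based position in the entity sequence (mmCIF
    label_seq_id convention).  Unmodeled residues carry no atoms.
    """

    seq_pos: int
    aa: str
    modeled: bool
    atoms: list[Atom] = field(default_factory=list)
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not self.modeled and self.atoms:
            raise ValueError(f"residue {self.seq_pos}: unmodeled but has atoms")
        if self.confidence is not None and not (0.0 <= self.confidence <= 100.0):
            raise ValueError(
                f"residue {self.seq_pos}: confidence {self.confidence} not in [0,100]"
            )

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class PolymerInstance:
    """One chain: an occurrence of an entity within an entry."""

    chain_id: str
    entity_uid: str
    residues: list[ResidueRecord]

    def __post_init__(self) -> None:
        pos = [r.seq_pos for r in self.residues]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(
                f"chain {self.chain_id}: residue positions not strictly increasing"
            )

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass
class LigandInstance:
    """A non-polymer chemical component (never water, never a standard
    amino acid) with its atoms."""

    comp_id: str
    chain_id: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if self.comp_id == "HOH" or self.comp_id in STANDARD_AA3:
            raise ValueError(f"{self.comp_id} is not a ligand component")


@dataclass
class StructureModel:
    """Parsed 3D coordinates of one entry: chains, ligands, provenance."""

    entry_id: str
    chains: list[PolymerInstance]
    ligands: list[LigandInstance] = field(default_factory=list)
    provenance: Provenance = Provenance.EXPERIMENTAL

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError(f"entry {self.entry_id}: no polymer chains")

    def chain(self, chain_id: str) -> PolymerInstance:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def chains_of_entity(self, entity_uid: str) -> list[PolymerInstance]:
        return [c for c in self.chains if c.entity_uid == entity_uid]


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


def three_to_one(name: str) -> str:
    """Map a chemical component id to a one-letter code; unknowns become X."""
    if name in _THREE_TO_ONE:
        return _THREE_TO_ONE[name]
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        one = info.one_letter_code.upper()
        if one in AA_ALPHABET and one != "X":
            return one
    logger.warning("unknown residue name %r mapped to 'X'", name)
    return "X"


def one_to_three(code: str) -> str:
    return _ONE_TO_THREE[code]


# ---------------------------------------------------------------------------
# reading


def read_structure(
    path: str | Path,
    format: str = "auto",
    provenance: Provenance | str = Provenance.EXPERIMENTAL,
) -> StructureModel:
    """Parse an mmCIF or legacy PDB file into a :class:`StructureModel`.

    Residues listed in the entity sequence but absent from the coordinates
    appear with ``modeled=False``.  For computed models (``provenance=
    "computed"``) the B-factor column is copied into per-residue confidence.
    Provenance is always declared by the caller (sidecar metadata or CLI
    flag); it is never inferred from the coordinate content.
    """
    path = Path(path)
    provenance = Provenance(provenance)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "pdb": gemmi.CoorFormat.Pdb,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models")
    st.setup_entities()
    _renumber_insertion_codes(st)
    st.assign_label_seq_id()
    model = st[0]

    chains: list[PolymerInstance] = []
    ligands: list[LigandInstance] = []
    for ch in model:
        poly = ch.get_polymer()
        poly_subchain = poly.subchain_id() if len(poly) else None
        # non-polymer residues -> ligands (waters dropped)
        for res in ch:
            if poly_subchain is not None and res.subchain == poly_subchain:
                continue
            if res.name == "HOH" or res.name in STANDARD_AA3:
                continue
            atoms = [
                Atom(a.name, a.element.name, a.pos.x, a.pos.y, a.pos.z)
                for a in res
            ]
            if atoms:
                ligands.append(LigandInstance(res.name, ch.name, atoms))
        if len(poly) == 0:
            continue
        ent = st.get_entity_of(poly)
        entity_id = ent.name if ent is not None else ch.name
        full_seq = _full_sequence(ent)
        observed: dict[int, gemmi.Residue] = {}
        for res in poly:
            if res.label_seq is not None:
                observed[res.label_seq] = res
        if not observed:
            # no label_seq assignment (e.g. legacy PDB without SEQRES):
            # number observed residues sequentially
            observed = {i + 1: res for i, res in enumerate(poly)}
        if not full_seq:
            # no SEQRES/entity_poly_seq: sequence is whatever was observed
            full_seq = [three_to_one(observed[k].name) for k in sorted(observed)]
            observed = {
                i + 1: observed[k] for i, k in enumerate(sorted(observed))
            }
        records: list[ResidueRecord] = []
        for pos, aa in enumerate(full_seq, start=1):
            res = observed.get(pos)
            if res is None or len(res) == 0:
                records.append(ResidueRecord(pos, aa, modeled=False))
                continue
            atoms = [
                Atom(a.name, a.element.name, a.pos.x, a.pos.y, a.pos.z)
                for a in res
            ]
            conf = None
            if provenance is Provenance.COMPUTED:
                ca = res.find_atom("CA", "*")
                conf = float(ca.b_iso if ca is not None else res[0].b_iso)
                conf = min(max(conf, 0.0), 100.0)
            records.append(ResidueRecord(pos, aa, modeled=True, atoms=atoms,
                                         confidence=conf))
        entity_uid = (
            st.name if provenance is Provenance.COMPUTED
            else f"{st.name}_{entity_id}"
        )
        chains.append(PolymerInstance(ch.name, entity_uid, records))
    if not chains:
        raise StructureParseError(f"{path}: no polymer chains found")
    return StructureModel(st.name, chains, ligands, provenance)


def _full_sequence(ent: gemmi.Entity | None) -> list[str]:
    if ent is None or not ent.full_sequence:
        return []
    return [three_to_one(gemmi.Entity.first_mon(m)) for m in ent.full_sequence]


def _renumber_insertion_codes(st: gemmi.Structure) -> None:
    """Replace author numbering containing insertion codes with a plain
    sequential numbering (downstream coordinates are single-integer)."""
    for model in st:
        for ch in model:
            if not any(r.seqid.icode.strip() for r in ch):
                continue
            mapping = []
            for i, res in enumerate(ch, start=1):
                mapping.append((f"{res.seqid.num}{res.seqid.icode.strip()}", i))
                res.seqid = gemmi.SeqId(i, " ")
            logger.warning(
                "chain %s: insertion codes renumbered sequentially: %s",
                ch.name, mapping,
            )


# ---------------------------------------------------------------------------
# writing


def structure_to_gemmi(sm: StructureModel, sequences: Mapping[str, str] | None = None) -> gemmi.Structure:
    """Build a gemmi Structure (with full entity sequences) from a model."""
    st = gemmi.Structure()
    st.name = sm.entry_id
    model = gemmi.Model("1")
    entity_ids: dict[str, str] = {}
    entities: dict[str, gemmi.Entity] = {}
    for idx, inst in enumerate(sm.chains, start=1):
        ch = gemmi.Chain(inst.chain_id)
        if inst.entity_uid not in entity_ids:
            eid = str(len(entity_ids) + 1)
            entity_ids[inst.entity_uid] = eid
            ent = gemmi.Entity(eid)
            ent.entity_type = gemmi.EntityType.Polymer
            ent.polymer_type = gemmi.PolymerType.PeptideL
            seq = (sequences or {}).get(inst.entity_uid, inst.sequence)
            ent.full_sequence = [one_to_three(c) for c in seq]
            entities[eid] = ent
        eid = entity_ids[inst.entity_uid]
        subchain = f"{inst.chain_id}p"
        for rec in inst.residues:
            if not rec.modeled:
                continue
            res = gemmi.Residue()
            res.name = one_to_three(rec.aa)
            res.seqid = gemmi.SeqId(rec.seq_pos, " ")
            res.label_seq = rec.seq_pos
            res.subchain = subchain
            res.entity_type = gemmi.EntityType.Polymer
            for a in rec.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(a.x, a.y, a.z)
                if rec.confidence is not None:
                    atom.b_iso = rec.confidence
                res.add_atom(atom)
            ch.add_residue(res)
        entities[eid].subchains = list(entities[eid].subchains) + [subchain]
        model.add_chain(ch)
    lig_ent = None
    for li_idx, lig in enumerate(sm.ligands, start=1):
        ch = None
        for existing in model:
            if existing.name == lig.chain_id:
                ch = existing
                break
        if ch is None:
            ch = gemmi.Chain(lig.chain_id)
            model.add_chain(ch)
        res = gemmi.Residue()
        res.name = lig.comp_id
        res.seqid = gemmi.SeqId(900 + li_idx, " ")
        res.subchain = f"L{li_idx}"
        res.entity_type = gemmi.EntityType.NonPolymer
        res.het_flag = "H"
        for a in lig.atoms:
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(a.x, a.y, a.z)
            res.add_atom(atom)
        ch.add_residue(res)
        if lig_ent is None:
            lig_ent = gemmi.Entity(str(len(entities) + 1))
            lig_ent.entity_type = gemmi.EntityType.NonPolymer
        lig_ent.subchains = list(lig_ent.subchains) + [f"L{li_idx}"]
    st.add_model(model)
    for ent in entities.values():
        st.entities.append(ent)
    if lig_ent is not None:
        st.entities.append(lig_ent)
    return st


def write_structure(sm: StructureModel, path: str | Path,
                    sequences: Mapping[str, str] | None = None) -> None:
    """Write a model as mmCIF (the only coordinate output format)."""
    st = structure_to_gemmi(sm, sequences)
    st.make_mmcif_document().write_file(str(Path(path)))


# ---------------------------------------------------------------------------
# entity extraction and sidecar metadata


@dataclass
class Sidecar:
    """Tabular per-entity metadata: one row per entity_uid plus an optional
    domain-annotation table (entity_uid, source, domain_id, begin, end)."""

    entities: pd.DataFrame
    domains: pd.DataFrame | None = None

    ENTITY_COLUMNS = (
        "entity_uid", "accession", "organism", "release_date",
        "deposition_group_id", "provenance",
    )
    DOMAIN_COLUMNS = ("entity_uid", "source", "domain_id", "begin", "end")

    @classmethod
    def read(cls, entities_path: str | Path,
             domains_path: str | Path | None = None) -> "Sidecar":
        ent = pd.read_csv(entities_path, sep="\t", dtype=str).fillna("")
        dom = None
        if domains_path is not None:
            dom = pd.read_csv(domains_path, sep="\t", dtype=str).fillna("")
        return cls(ent, dom)

    def write(self, entities_path: str | Path,
              domains_path: str | Path | None = None) -> None:
        self.entities.to_csv(entities_path, sep="\t", index=False)
        if domains_path is not None and self.domains is not None:
            self.domains.to_csv(domains_path, sep="\t", index=False)


def extract_entities(
    structure: StructureModel,
    sidecar: Sidecar | None = None,
) -> list[PolymerEntity]:
    """One entity per distinct entity identifier in the structure, with
    sidecar metadata merged by entity_uid.  Idempotent; chains sharing an
    entity contribute a single record."""
    out: list[PolymerEntity] = []
    seen: dict[str, PolymerEntity] = {}
    for inst in structure.chains:
        if inst.entity_uid in seen:
            if seen[inst.entity_uid].sequence != inst.sequence:
                raise ValueError(
                    f"{inst.entity_uid}: chains disagree on sequence"
                )
            continue
        ent = PolymerEntity(
            entity_uid=inst.entity_uid,
            entry_id=structure.entry_id,
            sequence=inst.sequence,
            provenance=structure.provenance,
        )
        seen[inst.entity_uid] = ent
        out.append(ent)
    if sidecar is not None:
        merge_sidecar(out, sidecar)
    return out


def merge_sidecar(entities: Iterable[PolymerEntity], sidecar: Sidecar) -> None:
    """Fill optional entity fields from the sidecar tables, in place.
    Rows referring to unknown entity_uids are ignored with a warning."""
    by_uid = {e.entity_uid: e for e in entities}
    for row in sidecar.entities.itertuples(index=False):
        uid = row.entity_uid
        ent = by_uid.get(uid)
        if ent is None:
            logger.warning("sidecar row for unknown entity %r ignored", uid)
            continue
        for col in ("accession", "organism", "release_date",
                    "deposition_group_id"):
            val = getattr(row, col, "")
            if val:
                setattr(ent, col, val)
        prov = getattr(row, "provenance", "")
        if prov:
            ent.provenance = Provenance(prov)
    if sidecar.domains is not None:
        for row in sidecar.domains.itertuples(index=False):
            ent = by_uid.get(row.entity_uid)
            if ent is None:
                logger.warning(
                    "domain row for unknown entity %r ignored", row.entity_uid
                )
                continue
            ann = DomainAnnotation(
                DomainSource(row.source), row.domain_id,
                int(row.begin), int(row.end),
            )
            if not (1 <= ann.begin <= ann.end <= len(ent.sequence)):
                raise ValueError(
                    f"{row.entity_uid}: domain range out of bounds"
                )
            ent.domain_annotations.append(ann)


def load_structure_dir(
    structure_dir: str | Path,
    sidecar: Sidecar | None = None,
) -> tuple[list[PolymerEntity], dict[str, StructureModel]]:
    """Read every ``*.cif`` in a directory, honouring sidecar provenance.

    Computed models are identified through the sidecar (a computed entity's
    uid is its entry id) and re-read so that B-factors become confidences.
    Returns the extracted entities (sidecar merged) and a map
    entity_uid -> StructureModel.
    """
    computed_entries: set[str] = set()
    if sidecar is not None and "provenance" in sidecar.entities.columns:
        computed_entries = set(
            sidecar.entities.loc[
                sidecar.entities["provenance"] == Provenance.COMPUTED.value,
                "entity_uid",
            ]
        )
    entities: list[PolymerEntity] = []
    structures: dict[str, StructureModel] = {}
    for path in sorted(Path(structure_dir).glob("*.cif")):
        sm = read_structure(path)
        if sm.entry_id in computed_entries:
            sm = read_structure(path, provenance=Provenance.COMPUTED)
        entities.extend(extract_entities(sm))
        structures.update({c.entity_uid: sm for c in sm.chains})
    if sidecar is not None:
        merge_sidecar(entities, sidecar)
    return entities, structures


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(entities: Iterable[PolymerEntity], path: str | Path) -> None:
    """Write entity sequences as FASTA, one record per entity_uid."""
    entities = list(entities)
    if not entities:
        raise ValueError("no entities to write")
    with open(path, "w") as fh:
        for e in entities:
            fh.write(f">{e.entity_uid}\n")
            for i in range(0, len(e.sequence), 60):
                fh.write(e.sequence[i:i + 60] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
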