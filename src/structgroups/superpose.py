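"""Alignment-guided rigid-body superposition.

Residue correspondences come from the group alignment (two members
correspond where they share an alignment column and both are modeled), the
fit is a least-squares Kabsch/SVD rotation over CA atoms, and the
resulting rigid transformation is applied to the member's *entire* entry --
all chains and ligands -- so ligand placements can be compared across
conformations.  An optional column range restricts the fit to a subset of
the alignment (e.g. one domain), which is how open/closed conformational
differences are isolated; RMSD can additionally be evaluated over any
other column range after fitting.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

from .model_io import Atom, StructureModel

if TYPE_CHECKING:  # pragma: no cover
    from .alignment import GroupAlignment
    from .groups import Group

logger = logging.getLogger(__name__)


@dataclass
class SuperpositionResult:
    """Rigid transformation ``x -> R x + t`` of the target onto the
    reference, with the CA RMSD over the matched pairs."""

    rotation: np.ndarray
    translation: np.ndarray
    n_pairs: int
    rmsd: float
    column_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation is not proper (det != +1)")
        if self.rmsd < 0 or self.n_pairs < 3:
            raise ValueError("invalid rmsd or pair count")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


class DegenerateGeometryError(ValueError):
    """Raised when the point sets cannot determine a rotation."""


def correspondence(
    ga: "GroupAlignment",
    ref_member: str,
    target_member: str,
    column_range: tuple[int, int] | None = None,
    structures: Mapping[str, StructureModel] | None = None,
) -> list[tuple[int, int]]:
    """(ref_seq_pos, target_seq_pos) pairs sharing an alignment column,
    restricted to ``column_range`` and to residues modeled (with a CA atom)
    in both structures when these are supplied."""
    for uid in (ref_member, target_member):
        if uid not in ga.members:
            raise KeyError(f"{uid} not in group alignment")
    lo, hi = column_range if column_range else (1, ga.n_columns)

    def modeled_positions(uid: str) -> set[int] | None:
        if structures is None or uid not in structures:
            return None
        chains = structures[uid].chains_of_entity(uid)
        out: set[int] = set()
        for ch in chains:
            out.update(r.seq_pos for r in ch.residues
                       if r.modeled and r.atom("CA"))
        return out

    ref_ok = modeled_positions(ref_member)
    tgt_ok = modeled_positions(target_member)
    pairs: list[tuple[int, int]] = []
    for col in range(lo, hi + 1):
        p = ga.member_pos_at(ref_member, col)
        q = ga.member_pos_at(target_member, col)
        if p is None or q is None:
            continue
        if ref_ok is not None and p not in ref_ok:
            continue
        if tgt_ok is not None and q not in tgt_ok:
            continue
        pairs.append((p, q))
    if len(pairs) < 3:
        raise DegenerateGeometryError(
            f"only {len(pairs)} residue correspondences between "
            f"{ref_member} and {target_member}; need >= 3"
        )
    return pairs


def kabsch(ref_coords: np.ndarray, target_coords: np.ndarray,
           column_range: tuple[int, int] | None = None) -> SuperpositionResult:
    """Least-squares optimal rigid fit of target points onto reference
    points (Kabsch/SVD), reflection-corrected, RMSD evaluated after the
    transformation."""
    P = np.asarray(ref_coords, dtype=float)
    Q = np.asarray(target_coords, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate arrays must be matching (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    P0 = P - cp
    Q0 = Q - cq
    # collinear targets cannot fix the rotation about their own axis
    if np.linalg.matrix_rank(np.vstack([P0, Q0]), tol=1e-8) < 2:
        raise DegenerateGeometryError("degenerate (collinear) geometry")
    H = Q0.T @ P0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    rmsd = float(np.sqrt(np.mean(np.sum((Q @ R.T + t - P) ** 2, axis=1))))
    return SuperpositionResult(R, t, n, rmsd, column_range)


def _ca_coords(structure: StructureModel, member_uid: str,
               positions: Sequence[int]) -> np.ndarray:
    chain = structure.chains_of_entity(member_uid)[0]
    by_pos = {r.seq_pos: r for r in chain.residues}
    out = []
    for p in positions:
        a = by_pos[p].atom("CA")
        out.append((a.x, a.y, a.z))
    return np.array(out)


def transform_structure(sm: StructureModel,
                        result: SuperpositionResult) -> StructureModel:
    """Apply a rigid transformation to every atom of an entry, ligands
    included."""
    out = copy.deepcopy(sm)
    R, t = result.rotation, result.translation
    for chain in out.chains:
        for rec in chain.residues:
            rec.atoms = [
                Atom(a.name, a.element, *(R @ np.array([a.x, a.y, a.z]) + t))
                for a in rec.atoms
            ]
    for lig in out.ligands:
        lig.atoms = [
            Atom(a.name, a.element, *(R @ np.array([a.x, a.y, a.z]) + t))
            for a in lig.atoms
        ]
    return out


def superpose_pair(
    ga: "GroupAlignment",
    structures: Mapping[str, StructureModel],
    ref_member: str,
    target_member: str,
    column_range: tuple[int, int] | None = None,
) -> SuperpositionResult:
    """Fit one target member onto the reference member over CA atoms of
    alignment-matched, mutually modeled residues."""
    pairs = correspondence(ga, ref_member, target_member, column_range,
                           structures)
    P = _ca_coords(structures[ref_member], ref_member, [p for p, _ in pairs])
    Q = _ca_coords(structures[target_member], target_member,
                   [q for _, q in pairs])
    return kabsch(P, Q, column_range)


def rmsd_over_columns(
    ga: "GroupAlignment",
    structures: Mapping[str, StructureModel],
    ref_member: str,
    target_member: str,
    column_range: tuple[int, int] | None = None,
) -> float:
    """CA RMSD between two members over a column range, *without* refitting
    (structures are compared as given, e.g. after transformation)."""
    pairs = correspondence(ga, ref_member, target_member, column_range,
                           structures)
    P = _ca_coords(structures[ref_member], ref_member, [p for p, _ in pairs])
    Q = _ca_coords(structures[target_member], target_member,
                   [q for _, q in pairs])
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


def superpose_members(
    group: "Group",
    ga: "GroupAlignment",
    structures: Mapping[str, StructureModel],
    ref_member: str | None = None,
    targets: Sequence[str] | None = None,
    column_range: tuple[int, int] | None = None,
    eval_range: tuple[int, int] | None = None,
) -> dict[str, tuple[SuperpositionResult, StructureModel, float | None]]:
    """Superpose group members onto a reference member.

    Returns, per target, the fit result, the fully transformed entry, and
    (when ``eval_range`` is given) the post-fit RMSD over that range.
    Members whose correspondence fails are skipped with a logged reason.
    The reference defaults to the group's first-ranked member.
    """
    ref = ref_member or group.member_uids[0]
    if ref not in structures:
        raise KeyError(f"reference member {ref} has no structure")
    target_list = list(targets) if targets is not None else [
        u for u in group.member_uids if u != ref and u in structures
    ]
    out: dict[str, tuple[SuperpositionResult, StructureModel, float | None]] = {}
    for uid in target_list:
        try:
            result = superpose_pair(ga, structures, ref, uid, column_range)
        except (KeyError, DegenerateGeometryError) as exc:
            logger.warning("skipping %s: %s", uid, exc)
            continue
        moved = transform_structure(structures[uid], result)
        eval_rmsd = None
        if eval_range is not None:
            eval_rmsd = rmsd_over_columns(
                ga, {**structures, uid: moved}, ref, uid, eval_range
            )
        out[uid] = (result, moved, eval_rmsd)
    return out
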