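"""Pairwise global alignment and reference-anchored group alignments.

The group alignment is a *star* alignment: one member (the reference
accession sequence for accession groups, the cluster representative for
identity groups) defines the column system -- column c is reference
position c -- and every member is aligned to it pairwise with an optimal
global (Needleman-Wunsch/Gotoh, affine gaps) alignment.  Member residues
aligned to a reference position occupy that column; insertions relative to
the reference are kept in the data model but receive no column, since they
cannot be displayed against reference coordinates.

Scoring model: substitution matrix (BLOSUM62 by default) with an affine
gap penalty; a gap run of length k costs ``gap_open + k * gap_extend``.
Traceback ties are broken deterministically: diagonal, then up (gap in the
second sequence), then left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import TYPE_CHECKING, Mapping, Sequence

from .tracks import PositionalTrack, TrackKind

if TYPE_CHECKING:  # pragma: no cover
    from .clustering import ClusteringConfig
    from .groups import Group

NEG_INF = float("-inf")


@lru_cache(maxsize=4)
def load_substitution_matrix(name: str = "BLOSUM62") -> dict[tuple[str, str], float]:
    """Load a substitution matrix (via Biopython) as a symbol-pair dict."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(name)
    alphabet = mat.alphabet
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            out[(a, b)] = float(mat[i, j])
    return out


@dataclass
class PairwiseAlignment:
    """Optimal global alignment as matched 1-based position pairs."""

    aligned_pairs: list[tuple[int, int]]
    score: float

    def __post_init__(self) -> None:
        pa = [p for p, _ in self.aligned_pairs]
        pb = [q for _, q in self.aligned_pairs]
        if any(b <= a for a, b in zip(pa, pa[1:])) or any(
            b <= a for a, b in zip(pb, pb[1:])
        ):
            raise ValueError("aligned pairs must be strictly increasing")


def align_pair_global(
    seq_a: str,
    seq_b: str,
    config: "ClusteringConfig | None" = None,
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences (Gotoh three-state DP).

    Returns the matched (pos_a, pos_b) pairs and the alignment score in
    substitution-matrix units.  Deterministic: at score ties the traceback
    prefers the diagonal move, then up, then left.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if config is None:
        from .clustering import ClusteringConfig

        config = ClusteringConfig()
    sub = load_substitution_matrix(config.substitution_matrix)
    go, ge = float(config.gap_open), float(config.gap_extend)
    n, m = len(seq_a), len(seq_b)

    # state 0 = M (diagonal), 1 = X (gap in b, "up"), 2 = Y (gap in a, "left")
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    ptr: list[list[list[int]]] = [
        [[0, 0, 0] for _ in range(m + 1)] for _ in range(n + 1)
    ]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(go + ge * i)
        ptr[i][0][1] = 1
    for j in range(1, m + 1):
        Y[0][j] = -(go + ge * j)
        ptr[0][j][2] = 2

    for i in range(1, n + 1):
        ai = seq_a[i - 1]
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        ptri = ptr[i]
        for j in range(1, m + 1):
            s = sub[(ai, seq_b[j - 1])]
            # M: predecessors at (i-1, j-1), preference M > X > Y
            best, state = Mi1[j - 1], 0
            if Xi1[j - 1] > best:
                best, state = Xi1[j - 1], 1
            if Yi1[j - 1] > best:
                best, state = Yi1[j - 1], 2
            Mi[j] = best + s
            ptri[j][0] = state
            # X (gap in b): from (i-1, j)
            best, state = Mi1[j] - go - ge, 0
            if Xi1[j] - ge > best:
                best, state = Xi1[j] - ge, 1
            if Yi1[j] - go - ge > best:
                best, state = Yi1[j] - go - ge, 2
            Xi[j] = best
            ptri[j][1] = state
            # Y (gap in a): from (i, j-1)
            best, state = Mi[j - 1] - go - ge, 0
            if Xi[j - 1] - go - ge > best:
                best, state = Xi[j - 1] - go - ge, 1
            if Yi[j - 1] - ge > best:
                best, state = Yi[j - 1] - ge, 2
            Yi[j] = best
            ptri[j][2] = state

    ends = (M[n][m], X[n][m], Y[n][m])
    score = max(ends)
    state = ends.index(score)  # index() returns first max: M > X > Y preference
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        prev = ptr[i][j][state]
        if state == 0:
            pairs.append((i, j))
            i, j = i - 1, j - 1
        elif state == 1:
            i -= 1
        else:
            j -= 1
        state = prev
    pairs.reverse()
    return PairwiseAlignment(pairs, score)


# ---------------------------------------------------------------------------
# group (star) alignment


@dataclass
class AlignedRegion:
    """A contiguous aligned block: member positions ``member_begin..end``
    occupy alignment columns ``column_begin..end`` (1-based, inclusive)."""

    member_begin: int
    member_end: int
    column_begin: int
    column_end: int

    def __post_init__(self) -> None:
        if self.member_end - self.member_begin != self.column_end - self.column_begin:
            raise ValueError("region lengths differ between member and columns")
        if self.member_begin < 1 or self.column_begin < 1:
            raise ValueError("positions are 1-based")

    def __len__(self) -> int:
        return self.member_end - self.member_begin + 1


@dataclass
class GroupAlignment:
    """Reference-anchored alignment of a group.

    ``members`` maps member_uid to its sorted, non-overlapping aligned
    regions; ``insertions`` records member segments that have no column
    (insertions relative to the reference).
    """

    group_id: str
    n_columns: int
    reference_uid: str
    reference_sequence: str
    members: dict[str, list[AlignedRegion]]
    insertions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def member_order(self) -> list[str]:
        return list(self.members)

    def column_of(self, member_uid: str, member_pos: int) -> int | None:
        for r in self.members[member_uid]:
            if r.member_begin <= member_pos <= r.member_end:
                return r.column_begin + (member_pos - r.member_begin)
        return None

    def member_pos_at(self, member_uid: str, column: int) -> int | None:
        for r in self.members[member_uid]:
            if r.column_begin <= column <= r.column_end:
                return r.member_begin + (column - r.column_begin)
        return None

    def span(self, member_uid: str) -> tuple[int, int] | None:
        """First and last aligned column of a member (None if unaligned)."""
        regs = self.members[member_uid]
        if not regs:
            return None
        return regs[0].column_begin, regs[-1].column_end

    def depth(self) -> list[int]:
        """Per-column count of members with a residue in that column."""
        d = [0] * self.n_columns
        for regs in self.members.values():
            for r in regs:
                for c in range(r.column_begin, r.column_end + 1):
                    d[c - 1] += 1
        return d

    def symbol_at(self, member_uid: str, column: int,
                  sequences: Mapping[str, str]) -> str | None:
        """Residue letter at a column, '-' for a gap inside the member's
        aligned span, None outside the span (terminal truncation)."""
        span = self.span(member_uid)
        if span is None or not (span[0] <= column <= span[1]):
            return None
        pos = self.member_pos_at(member_uid, column)
        if pos is None:
            return "-"
        return sequences[member_uid][pos - 1]


def pairs_to_regions(pairs: Sequence[tuple[int, int]]) -> list[AlignedRegion]:
    """Collapse matched (ref_pos, member_pos) pairs into contiguous blocks.

    Note the reference position is the *column*; the member position is the
    member coordinate.
    """
    regions: list[AlignedRegion] = []
    for ref, mem in pairs:
        if (
            regions
            and ref == regions[-1].column_end + 1
            and mem == regions[-1].member_end + 1
        ):
            regions[-1].column_end += 1
            regions[-1].member_end += 1
        else:
            regions.append(AlignedRegion(mem, mem, ref, ref))
    return regions


def build_group_alignment(
    group: "Group",
    sequences: Mapping[str, str],
    config: "ClusteringConfig | None" = None,
) -> GroupAlignment:
    """Align every group member to the group's reference sequence.

    The reference is the group's ``reference_sequence`` (accession groups)
    or the first-ranked member, i.e. the cluster representative, for
    identity groups.  Columns are reference positions 1..len(reference).
    """
    from .groups import GroupProvenance

    if group.provenance is GroupProvenance.REFERENCE_ACCESSION:
        if not group.reference_sequence:
            raise ValueError("accession group lacks a reference sequence")
        ref_seq = group.reference_sequence
        ref_uid = group.group_id.split("_", 1)[-1]
    else:
        ref_uid = group.member_uids[0]
        ref_seq = sequences[ref_uid]

    members: dict[str, list[AlignedRegion]] = {}
    insertions: dict[str, list[tuple[int, int]]] = {}
    for uid in group.member_uids:
        seq = sequences.get(uid)
        if seq is None:
            import logging

            logging.getLogger(__name__).warning(
                "member %s has no sequence; skipped from alignment", uid
            )
            continue
        aln = align_pair_global(ref_seq, seq, config)
        members[uid] = pairs_to_regions(aln.aligned_pairs)
        ins = _insertion_runs(aln.aligned_pairs, len(seq))
        if ins:
            insertions[uid] = ins
    return GroupAlignment(
        group_id=group.group_id,
        n_columns=len(ref_seq),
        reference_uid=ref_uid,
        reference_sequence=ref_seq,
        members=members,
        insertions=insertions,
    )


def _insertion_runs(pairs: Sequence[tuple[int, int]], member_len: int
                    ) -> list[tuple[int, int]]:
    aligned = {mem for _, mem in pairs}
    runs: list[tuple[int, int]] = []
    start = None
    for pos in range(1, member_len + 1):
        if pos not in aligned:
            if start is None:
                start = pos
        elif start is not None:
            runs.append((start, pos - 1))
            start = None
    if start is not None:
        runs.append((start, member_len))
    return runs


# ---------------------------------------------------------------------------
# summary tracks


def consensus_track(ga: GroupAlignment,
                    sequences: Mapping[str, str]) -> PositionalTrack:
    """Most frequent symbol (residue or gap) at each column.

    A member counts as a gap at columns inside its aligned span where it has
    no residue (deletion); members whose span does not reach the column are
    excluded from that column's tally.  Ties are broken residue-over-gap,
    then alphabetically.
    """
    if not ga.members:
        raise ValueError("empty group alignment")
    values: list[str] = []
    for col in range(1, ga.n_columns + 1):
        counts: dict[str, int] = {}
        for uid in ga.members:
            sym = ga.symbol_at(uid, col, sequences)
            if sym is not None:
                counts[sym] = counts.get(sym, 0) + 1
        if not counts:
            values.append("-")
            continue
        # sort: count desc, residue before gap, then alphabetical
        best = min(counts.items(),
                   key=lambda kv: (-kv[1], kv[0] == "-", kv[0]))
        values.append(best[0])
    return PositionalTrack(
        track_id="consensus", group_id=ga.group_id, kind=TrackKind.SYMBOL,
        values=values,
        provenance_note="modal residue-or-gap per column over members "
                        "whose aligned span covers the column",
    )


def variation_track(ga: GroupAlignment,
                    sequences: Mapping[str, str]) -> PositionalTrack:
    """Per-column amino-acid variation: 1 - modal-residue fraction among
    members with a residue at the column.  Columns with no residues carry
    ``None`` (undefined)."""
    if not ga.members:
        raise ValueError("empty group alignment")
    values: list[float | None] = []
    for col in range(1, ga.n_columns + 1):
        counts: dict[str, int] = {}
        depth = 0
        for uid in ga.members:
            pos = ga.member_pos_at(uid, col)
            if pos is None:
                continue
            aa = sequences[uid][pos - 1]
            counts[aa] = counts.get(aa, 0) + 1
            depth += 1
        if depth == 0:
            values.append(None)
        else:
            values.append(1.0 - max(counts.values()) / depth)
    return PositionalTrack(
        track_id="sequence_variation", group_id=ga.group_id,
        kind=TrackKind.FRACTION, values=values,
        provenance_note="1 - modal residue fraction over members with a "
                        "residue at the column",
    )


def to_a2m(ga: GroupAlignment, sequences: Mapping[str, str]) -> str:
    """Render the group alignment as A2M-style FASTA.

    Match columns are reference positions: uppercase residue, or ``-`` for
    a deletion, or ``.`` outside the member's aligned span.  Insertions
    relative to the reference are emitted lowercase after the column they
    follow.
    """
    lines = [f">{ga.reference_uid}", ga.reference_sequence]
    for uid in ga.member_order():
        seq = sequences[uid]
        ins_after: dict[int, str] = {}
        for begin, end in ga.insertions.get(uid, []):
            # anchor the run to the column of the preceding aligned residue
            col = ga.column_of(uid, begin - 1) if begin > 1 else 0
            ins_after[col or 0] = seq[begin - 1:end].lower()
        span = ga.span(uid)
        out = [ins_after.get(0, "")]
        for col in range(1, ga.n_columns + 1):
            if span is None or not (span[0] <= col <= span[1]):
                out.append(".")
            else:
                pos = ga.member_pos_at(uid, col)
                out.append("-" if pos is None else seq[pos - 1])
            out.append(ins_after.get(col, ""))
        lines.append(f">{uid}")
        lines.append("".join(out))
    return "\n".join(lines) + "\n"


def paginate(ga: GroupAlignment, page: int, page_size: int = 50,
             order: Sequence[str] | None = None) -> list[str]:
    """Member uids on one page (1-based) of ``page_size`` alignment tracks;
    pages beyond the member list are empty."""
    if page < 1:
        raise ValueError("page numbering is 1-based")
    members = list(order) if order is not None else ga.member_order()
    start = (page - 1) * page_size
    return members[start:start + page_size]
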