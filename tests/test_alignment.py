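import numpy as np
import pytest

from oracles import nw_score_oracle
from structgroups.alignment import (
    AlignedRegion,
    GroupAlignment,
    align_pair_global,
    build_group_alignment,
    consensus_track,
    load_substitution_matrix,
    paginate,
    pairs_to_regions,
    variation_track,
)
from structgroups.clustering import ClusteringConfig
from structgroups.groups import Group, GroupProvenance

AA = "ACDEFGHIKLMNPQRSTVWY"
SUB = load_substitution_matrix("BLOSUM62")


class TestPairwiseGlobal:
    def test_identical_sequences_score_is_diagonal_sum(self):
        seq = "MKVLAWGHEE"
        aln = align_pair_global(seq, seq)
        assert aln.aligned_pairs == [(i, i) for i in range(1, len(seq) + 1)]
        assert aln.score == sum(SUB[(c, c)] for c in seq)

    def test_textbook_pair_matches_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        assert align_pair_global(a, b).score == nw_score_oracle(
            a, b, SUB, 11.0, 1.0)

    @pytest.mark.parametrize("a,b", [("A", "A"), ("A", "W"), ("AC", "A"),
                                     ("W", "ACD"), ("ACD", "DCA")])
    def test_tiny_sequences_match_oracle(self, a, b):
        aln = align_pair_global(a, b)
        assert aln.score == nw_score_oracle(a, b, SUB, 11.0, 1.0)
        assert len(aln.aligned_pairs) <= min(len(a), len(b))

    def test_seeded_random_pairs_match_oracle_exactly(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            a = "".join(rng.choice(list(AA), size=rng.integers(1, 41)))
            b = "".join(rng.choice(list(AA), size=rng.integers(1, 41)))
            assert align_pair_global(a, b).score == nw_score_oracle(
                a, b, SUB, 11.0, 1.0)

    def test_gap_penalty_config_respected(self):
        cfg = ClusteringConfig(gap_open=2.0, gap_extend=0.5)
        a, b = "ACDEFGHIK", "ACDIK"
        assert align_pair_global(a, b, cfg).score == nw_score_oracle(
            a, b, SUB, 2.0, 0.5)

    def test_pairs_strictly_increasing_and_order_preserving(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = "".join(rng.choice(list(AA), size=30))
            b = "".join(rng.choice(list(AA), size=25))
            pairs = align_pair_global(a, b).aligned_pairs
            assert all(p2 > p1 and q2 > q1 for (p1, q1), (p2, q2)
                       in zip(pairs, pairs[1:]))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair_global("", "ACD")


class TestStarAlignment:
    REF = ("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVK"
           "ALPDAQFEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPDEDRLSPLHSVY")

    def _group(self, members):
        return Group(group_id="seqid100_0001",
                     provenance=GroupProvenance.SEQUENCE_IDENTITY,
                     member_uids=list(members), threshold=1.0)

    def test_identical_member_single_full_region(self):
        seqs = {"r_1": self.REF, "m_1": self.REF}
        ga = build_group_alignment(self._group(seqs), seqs)
        L = len(self.REF)
        assert ga.n_columns == L
        assert ga.members["m_1"] == [AlignedRegion(1, L, 1, L)]

    def test_internal_deletion_splits_into_two_regions(self):
        member = self.REF[:39] + self.REF[60:]
        seqs = {"r_1": self.REF, "m_1": member}
        ga = build_group_alignment(self._group(seqs), seqs)
        L = len(self.REF)
        regions = ga.members["m_1"]
        assert [(r.column_begin, r.column_end) for r in regions] == [
            (1, 39), (61, L)]
        assert [(r.member_begin, r.member_end) for r in regions] == [
            (1, 39), (40, len(member))]

    def test_insertion_recorded_without_column(self):
        member = self.REF[:50] + "WWWWW" + self.REF[50:]
        seqs = {"r_1": self.REF, "m_1": member}
        ga = build_group_alignment(self._group(seqs), seqs)
        assert ga.insertions["m_1"] == [(51, 55)]
        for run in ga.insertions["m_1"]:
            for pos in range(run[0], run[1] + 1):
                assert ga.column_of("m_1", pos) is None

    def test_column_map_injective_and_order_preserving(self):
        member = self.REF[:39] + self.REF[60:]
        seqs = {"r_1": self.REF, "m_1": member}
        ga = build_group_alignment(self._group(seqs), seqs)
        cols = [ga.column_of("m_1", p) for p in range(1, len(member) + 1)]
        cols = [c for c in cols if c is not None]
        assert len(set(cols)) == len(cols)
        assert cols == sorted(cols)

    def test_consensus_of_identical_members_is_the_sequence(self):
        seqs = {f"m{i}_1": self.REF for i in range(4)}
        ga = build_group_alignment(self._group(seqs), seqs)
        track = consensus_track(ga, seqs)
        assert "".join(track.values) == self.REF


def _manual_ga(members):
    """GroupAlignment over 4 columns with hand-chosen regions."""
    return GroupAlignment(group_id="g", n_columns=4, reference_uid="ref",
                          reference_sequence="AAAA", members=members)


class TestConsensusAndVariation:
    def test_modal_residue(self):
        # column 1: A, A, C -> 'A'
        members = {
            "a": [AlignedRegion(1, 4, 1, 4)],
            "b": [AlignedRegion(1, 4, 1, 4)],
            "c": [AlignedRegion(1, 4, 1, 4)],
        }
        seqs = {"a": "AAAA", "b": "AAAA", "c": "CAAA"}
        assert consensus_track(_manual_ga(members), seqs).values[0] == "A"

    def test_majority_gap_wins(self):
        # column 2 deleted in b and c but within their spans -> gap majority
        members = {
            "a": [AlignedRegion(1, 4, 1, 4)],
            "b": [AlignedRegion(1, 1, 1, 1), AlignedRegion(2, 3, 3, 4)],
            "c": [AlignedRegion(1, 1, 1, 1), AlignedRegion(2, 3, 3, 4)],
        }
        seqs = {"a": "AAAA", "b": "AAA", "c": "AAA"}
        assert consensus_track(_manual_ga(members), seqs).values[1] == "-"

    def test_tie_breaks_residue_over_gap_then_alphabetical(self):
        members = {
            "a": [AlignedRegion(1, 4, 1, 4)],
            "b": [AlignedRegion(1, 4, 1, 4)],
        }
        seqs = {"a": "CAAA", "b": "AAAA"}
        assert consensus_track(_manual_ga(members), seqs).values[0] == "A"
        # residue vs gap tie -> residue
        members2 = {
            "a": [AlignedRegion(1, 4, 1, 4)],
            "b": [AlignedRegion(1, 1, 1, 1), AlignedRegion(2, 3, 3, 4)],
        }
        seqs2 = {"a": "AAAA", "b": "AAA"}
        assert consensus_track(_manual_ga(members2), seqs2).values[1] == "A"

    @pytest.mark.parametrize("residues,expected", [
        ("AAAA", 0.0),
        ("AAAAACCCCC", 0.5),
        ("ACDE", 0.75),
    ])
    def test_variation_values(self, residues, expected):
        members = {f"m{i}": [AlignedRegion(1, 1, 1, 1)]
                   for i in range(len(residues))}
        seqs = {f"m{i}": residues[i] for i in range(len(residues))}
        ga = GroupAlignment(group_id="g", n_columns=1, reference_uid="ref",
                            reference_sequence="A", members=members)
        assert variation_track(ga, seqs).values[0] == pytest.approx(expected)

    def test_variation_invariant_under_member_reordering(self):
        seqs = {"a": "ACDE", "b": "ACDA", "c": "AADE"}
        regions = lambda: [AlignedRegion(1, 4, 1, 4)]
        fwd = _manual_ga({k: regions() for k in ("a", "b", "c")})
        rev = _manual_ga({k: regions() for k in ("c", "b", "a")})
        assert variation_track(fwd, seqs).values == \
            variation_track(rev, seqs).values

    def test_depth_zero_column_undefined(self):
        members = {"a": [AlignedRegion(1, 1, 1, 1)]}
        ga = GroupAlignment(group_id="g", n_columns=2, reference_uid="ref",
                            reference_sequence="AA", members=members)
        assert variation_track(ga, {"a": "A"}).values[1] is None


class TestPaginate:
    def _ga(self, n):
        members = {f"m{i:03d}": [AlignedRegion(1, 1, 1, 1)] for i in range(n)}
        return GroupAlignment(group_id="g", n_columns=1, reference_uid="r",
                              reference_sequence="A", members=members)

    def test_blocks_of_fifty(self):
        ga = self._ga(120)
        sizes = [len(paginate(ga, p)) for p in (1, 2, 3)]
        assert sizes == [50, 50, 20]

    def test_small_group_single_page(self):
        assert len(paginate(self._ga(10), 1)) == 10

    def test_pages_partition_members(self):
        ga = self._ga(120)
        seen = []
        for p in range(1, 4):
            seen.extend(paginate(ga, p))
        assert sorted(seen) == sorted(ga.member_order())
        assert len(set(seen)) == len(seen)

    def test_page_beyond_range_empty(self):
        assert paginate(self._ga(10), 5) == []

    def test_page_zero_rejected(self):
        with pytest.raises(ValueError):
            paginate(self._ga(10), 0)


class TestA2M:
    REF = TestStarAlignment.REF

    def _ga(self, member):
        from structgroups.alignment import to_a2m

        seqs = {"r_1": self.REF, "m_1": member}
        g = Group(group_id="seqid100_0001",
                  provenance=GroupProvenance.SEQUENCE_IDENTITY,
                  member_uids=list(seqs), threshold=1.0)
        return to_a2m(build_group_alignment(g, seqs), seqs)

    def test_deletion_shown_as_dashes(self):
        member = self.REF[:39] + self.REF[60:]
        block = self._ga(member).splitlines()
        m_line = block[block.index(">m_1") + 1]
        assert m_line[39:60] == "-" * 21
        assert m_line.replace("-", "") == member

    def test_insertion_lowercase(self):
        member = self.REF[:50] + "WWWWW" + self.REF[50:]
        block = self._ga(member).splitlines()
        m_line = block[block.index(">m_1") + 1]
        assert "wwwww" in m_line
        assert m_line.replace("wwwww", "")[:len(self.REF)] == self.REF


def test_pairs_to_regions_merges_contiguous_runs():
    pairs = [(1, 1), (2, 2), (5, 3), (6, 4), (8, 9)]
    regs = pairs_to_regions(pairs)
    assert [(r.column_begin, r.column_end, r.member_begin, r.member_end)
            for r in regs] == [(1, 2, 1, 2), (5, 6, 3, 4), (8, 8, 9, 9)]
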