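import numpy as np
import pytest

from oracles import brute_force_contacts
from structgroups.alignment import AlignedRegion, GroupAlignment, build_group_alignment
from structgroups.fixtures import build_ideal_chain
from structgroups.groups import Group, GroupProvenance
from structgroups.model_io import Atom, LigandInstance, Provenance
from structgroups.tracks import (
    ContactRecord,
    binding_tracks,
    detect_contacts,
    feature_frequency_track,
    modeled_track,
    mutation_markers,
    plddt_bin,
    plddt_track,
    assign_secondary_structure,
)


def identity_ga(seqs, group_id="seqid100_0001"):
    members = {uid: [AlignedRegion(1, len(s), 1, len(s))]
               for uid, s in seqs.items()}
    first = next(iter(seqs.values()))
    return GroupAlignment(group_id=group_id, n_columns=len(first),
                          reference_uid=next(iter(seqs)),
                          reference_sequence=first, members=members)


def chain_structure(uid, seq, unmodeled=()):
    sm = build_ideal_chain([("helix", len(seq))], seq,
                           entry_id=uid.split("_")[0],
                           rng=np.random.default_rng(0))
    sm.chains[0].entity_uid = uid
    for rec in sm.chains[0].residues:
        if rec.seq_pos in unmodeled:
            rec.modeled = False
            rec.atoms = []
    return sm


class TestModeledTrack:
    def test_fully_modeled_single_region(self):
        seq = "A" * 20
        ga = identity_ga({"m_1": seq})
        sm = chain_structure("m_1", seq)
        tr = modeled_track("m_1", sm, ga)
        regions = dict(tr.values)
        assert regions["modeled"] == [(1, 20)]
        assert regions["unmodeled"] == []

    def test_gap_bookkeeping(self):
        seq = "A" * 100
        ga = identity_ga({"m_1": seq})
        sm = chain_structure("m_1", seq,
                             unmodeled=set(range(1, 10)) | set(range(91, 101)))
        regions = dict(modeled_track("m_1", sm, ga).values)
        assert regions["unmodeled"] == [(1, 9), (91, 100)]
        assert regions["modeled"] == [(10, 90)]

    def test_partition_of_aligned_columns(self):
        seq = "A" * 30
        ga = identity_ga({"m_1": seq})
        sm = chain_structure("m_1", seq, unmodeled={5, 6, 17})
        regions = dict(modeled_track("m_1", sm, ga).values)
        cols = set()
        for _, runs in regions.items():
            for b, e in runs:
                for c in range(b, e + 1):
                    assert c not in cols
                    cols.add(c)
        assert cols == set(range(1, 31))

    def test_member_absent_from_alignment(self):
        sm = chain_structure("m_1", "A" * 10)
        ga = identity_ga({"other_1": "A" * 10})
        with pytest.raises(KeyError):
            modeled_track("m_1", sm, ga)


class TestPlddtTrack:
    def _computed(self, seq, confs):
        sm = chain_structure("c1", seq)
        sm.provenance = Provenance.COMPUTED
        for rec, c in zip(sm.chains[0].residues, confs):
            rec.confidence = c
        sm.chains[0].entity_uid = "c1"
        return sm

    def test_uniform_high_confidence(self):
        seq = "A" * 10
        sm = self._computed(seq, [95.0] * 10)
        ga = identity_ga({"c1": seq})
        scores, cats = plddt_track("c1", sm, ga)
        assert all(v == 95.0 for v in scores.values)
        assert all(v == "very-high" for v in cats.values)

    def test_bin_edges_half_open(self):
        assert plddt_bin(69.9) == "low"
        assert plddt_bin(70.0) == "confident"
        assert plddt_bin(90.0) == "very-high"
        assert plddt_bin(49.999) == "very-low"

    def test_columns_equal_confidences_under_identity_alignment(self):
        seq = "A" * 8
        confs = [10.0 * i for i in range(8)]
        sm = self._computed(seq, confs)
        scores, _ = plddt_track("c1", sm, identity_ga({"c1": seq}))
        assert scores.values == confs

    def test_experimental_member_rejected(self):
        seq = "A" * 8
        sm = chain_structure("m_1", seq)
        with pytest.raises(ValueError):
            plddt_track("m_1", sm, identity_ga({"m_1": seq}))


class TestSecondaryStructure:
    def test_ideal_helix_mostly_H(self):
        sm = build_ideal_chain([("helix", 20)], "A" * 20)
        labels = assign_secondary_structure(sm)["A"]
        interior = [labels[p] for p in range(3, 19)]
        assert sum(l == "H" for l in interior) >= 0.8 * len(interior)

    def test_ideal_strand_mostly_E(self):
        sm = build_ideal_chain([("strand", 20)], "A" * 20)
        labels = assign_secondary_structure(sm)["A"]
        values = list(labels.values())
        assert sum(l == "E" for l in values) >= len(values) - 4

    def test_short_chain_all_coil(self):
        sm = build_ideal_chain([("helix", 4)], "A" * 4)
        labels = assign_secondary_structure(sm)["A"]
        assert set(labels.values()) == {"C"}


class TestFeatureFrequency:
    def test_all_members_helical(self):
        seqs = {f"m{i}_1": "A" * 20 for i in range(3)}
        structures = {u: chain_structure(u, s) for u, s in seqs.items()}
        g = Group(group_id="seqid100_0001",
                  provenance=GroupProvenance.SEQUENCE_IDENTITY,
                  member_uids=list(seqs), threshold=1.0)
        ga = identity_ga(seqs)
        tr = feature_frequency_track(g, ga, "helix", structures=structures)
        # interior columns where the annotation fires must be unanimous
        assert all(v in (0.0, 1.0) for v in tr.values)
        assert any(v == 1.0 for v in tr.values)

    def test_domain_fraction(self, worked_entities, worked_structures,
                             worked_group, worked_alignment):
        tr = feature_frequency_track(
            worked_group, worked_alignment, ("domain", "PFAM", "PF9999"),
            structures=worked_structures, entities=worked_entities)
        # PF9999 spans positions 1-6 on 2 of the 4 members
        assert tr.values[:6] == [0.5] * 6
        assert tr.values[6:] == [0.0] * 6

    def test_quarter_fraction_with_unmodeled(self):
        seqs = {f"m{i}_1": "A" * 10 for i in range(4)}
        structures = {u: chain_structure(u, s) for u, s in seqs.items()}
        # member m0 annotated at position 5; m3 unmodeled there
        entities = []
        from structgroups.model_io import DomainAnnotation, DomainSource, PolymerEntity

        for i, (u, s) in enumerate(seqs.items()):
            dom = [DomainAnnotation(DomainSource.SCOP, "d1", 5, 5)] if i == 0 else []
            entities.append(PolymerEntity(entity_uid=u, entry_id=u, sequence=s,
                                          domain_annotations=dom))
        g = Group(group_id="seqid100_0001",
                  provenance=GroupProvenance.SEQUENCE_IDENTITY,
                  member_uids=list(seqs), threshold=1.0)
        ga = identity_ga(seqs)
        tr = feature_frequency_track(g, ga, ("domain", "SCOP", "d1"),
                                     structures=structures, entities=entities)
        assert tr.values[4] == 0.25
        structures["m3_1"] = chain_structure("m3_1", "A" * 10, unmodeled={5})
        tr = feature_frequency_track(g, ga, ("domain", "SCOP", "d1"),
                                     structures=structures, entities=entities)
        assert tr.values[4] == pytest.approx(1 / 3)

    def test_unknown_source_rejected(self, worked_group, worked_alignment,
                                     worked_structures, worked_entities):
        with pytest.raises(ValueError):
            feature_frequency_track(
                worked_group, worked_alignment, ("domain", "NOPE", "x"),
                structures=worked_structures, entities=worked_entities)


class TestDetectContacts:
    def _with_ligand(self, offset_from_ca_of=11, dist=3.0):
        seq = "A" * 20
        sm = chain_structure("m_1", seq)
        ca = next(r for r in sm.chains[0].residues
                  if r.seq_pos == offset_from_ca_of).atom("CA")
        # place perpendicular to the local helix axis, away from the chain
        chain_ca = np.array([r.atom("CA")[2:] for r in sm.chains[0].residues])
        center = chain_ca.mean(axis=0)
        direction = np.array([ca.x, ca.y, ca.z]) - center
        direction /= np.linalg.norm(direction)
        pos = np.array([ca.x, ca.y, ca.z]) + dist * direction
        sm.ligands.append(LigandInstance("GLC", "A",
                                         [Atom("C1", "C", *pos)]))
        return sm

    def test_anchor_residue_in_contact(self):
        sm = self._with_ligand()
        contacts = detect_contacts(sm, "m_1")
        assert 11 in {c.seq_pos for c in contacts}

    def test_distant_ligand_no_contacts(self):
        sm = self._with_ligand(dist=50.0)
        assert detect_contacts(sm, "m_1") == []

    def test_translation_invariance(self):
        sm = self._with_ligand()
        before = [(c.seq_pos, c.comp_id, round(c.min_distance, 9))
                  for c in detect_contacts(sm, "m_1")]
        shift = np.array([10.0, -5.0, 2.0])
        for rec in sm.chains[0].residues:
            rec.atoms = [Atom(a.name, a.element, a.x + shift[0],
                              a.y + shift[1], a.z + shift[2])
                         for a in rec.atoms]
        for lig in sm.ligands:
            lig.atoms = [Atom(a.name, a.element, a.x + shift[0],
                              a.y + shift[1], a.z + shift[2])
                         for a in lig.atoms]
        after = [(c.seq_pos, c.comp_id, round(c.min_distance, 9))
                 for c in detect_contacts(sm, "m_1")]
        assert before == after

    def test_agrees_with_brute_force_scan(self):
        sm = self._with_ligand()
        got = sorted((c.seq_pos, c.comp_id, c.min_distance)
                     for c in detect_contacts(sm, "m_1"))
        expected = brute_force_contacts(sm, "m_1", 4.5)
        assert [(p, c) for p, c, _ in got] == [(p, c) for p, c, _ in expected]
        for (_, _, d1), (_, _, d2) in zip(got, expected):
            assert d1 == pytest.approx(d2, abs=1e-9)


class TestBindingTracks:
    def _group_ga(self, n=4, length=12):
        seqs = {f"m{i}_1": "A" * length for i in range(n)}
        g = Group(group_id="seqid100_0001",
                  provenance=GroupProvenance.SEQUENCE_IDENTITY,
                  member_uids=list(seqs), threshold=1.0)
        return g, identity_ga(seqs)

    def test_single_binder_full_frequency(self):
        g, ga = self._group_ga()
        contacts = [ContactRecord("m0_1", p, "GLC", 3.0) for p in (10, 11, 12)]
        _, per_ligand = binding_tracks(g, ga, contacts)
        tr = per_ligand["GLC"]
        assert tr.values[9:12] == [1.0, 1.0, 1.0]
        assert all(v == 0.0 for v in tr.values[:9])

    def test_two_binders_denominator(self):
        g, ga = self._group_ga()
        contacts = [
            ContactRecord("m0_1", 10, "GTP", 3.0),
            ContactRecord("m1_1", 10, "GTP", 3.0),
            ContactRecord("m0_1", 11, "GTP", 3.0),
        ]
        _, per_ligand = binding_tracks(g, ga, contacts)
        assert per_ligand["GTP"].values[9] == 1.0
        assert per_ligand["GTP"].values[10] == 0.5

    def test_global_track_conserves_events(self):
        g, ga = self._group_ga()
        contacts = [
            ContactRecord("m0_1", 5, "GLC", 3.0),
            ContactRecord("m1_1", 5, "GTP", 3.0),
            ContactRecord("m2_1", 7, "GLC", 3.0),
        ]
        global_track, _ = binding_tracks(g, ga, contacts)
        assert sum(global_track.values) == len(contacts)

    def test_no_contacts_no_per_ligand_tracks(self):
        g, ga = self._group_ga()
        global_track, per_ligand = binding_tracks(g, ga, [])
        assert per_ligand == {}
        assert sum(global_track.values) == 0


class TestMutationMarkers:
    def test_identical_member_no_markers(self, worked_alignment):
        from conftest import WORKED_SEQS

        assert mutation_markers("m2_1", worked_alignment, WORKED_SEQS) == set()

    def test_single_substitution_marks_its_column(self):
        ref = "A" * 100
        member = ref[:75] + "G" + ref[76:]
        seqs = {"r_1": ref, "m_1": member}
        ga = identity_ga(seqs)
        assert mutation_markers("m_1", ga, seqs) == {76}

    def test_marker_count_equals_hamming_distance(self, worked_alignment):
        from conftest import WORKED_SEQS

        ref = worked_alignment.reference_sequence
        for uid, seq in WORKED_SEQS.items():
            ham = sum(a != b for a, b in zip(ref, seq))
            assert len(mutation_markers(uid, worked_alignment,
                                        WORKED_SEQS)) == ham


class TestWorkedConsensusVariation:
    """Hand-computed values on the 4-member worked fixture."""

    def test_consensus_is_majority_sequence(self, worked_alignment):
        from conftest import WORKED_SEQS
        from structgroups.alignment import consensus_track

        track = consensus_track(worked_alignment, WORKED_SEQS)
        assert "".join(track.values) == "ACDEFGHIKLMN"

    def test_variation_quarter_at_mutated_columns(self, worked_alignment):
        from conftest import WORKED_SEQS
        from structgroups.alignment import variation_track

        values = variation_track(worked_alignment, WORKED_SEQS).values
        assert values[3] == pytest.approx(0.25)   # E4A in one of four
        assert values[6] == pytest.approx(0.25)   # H7A in one of four
        for i, v in enumerate(values):
            if i not in (3, 6):
                assert v == 0.0
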