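import numpy as np
import pytest

from structgroups.alignment import build_group_alignment
from structgroups.fixtures import FixtureSpec, build_group_fixture, build_ideal_chain
from structgroups.groups import Group, GroupProvenance
from structgroups.model_io import (
    DomainAnnotation,
    DomainSource,
    PolymerEntity,
    Provenance,
)


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic group: 5 experimental + 4 computed variants."""
    return build_group_fixture(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def default_group(default_fixture):
    fx = default_fixture
    return Group(
        group_id="seqid100_0001",
        provenance=GroupProvenance.SEQUENCE_IDENTITY,
        member_uids=[e.entity_uid for e in fx.entities],
        threshold=1.0,
        title="default fixture group",
    )


@pytest.fixture(scope="session")
def default_alignment(default_fixture, default_group):
    sequences = {e.entity_uid: e.sequence for e in default_fixture.entities}
    return build_group_alignment(default_group, sequences)


# ---------------------------------------------------------------------------
# worked 4-member fixture: small enough that every track value is known by
# hand.  Sequences are identical up to two point substitutions, so the star
# alignment is gapless and columns equal sequence positions.

WORKED_SEQS = {
    "m1_1": "ACDEFGHIKLMN",
    "m2_1": "ACDEFGHIKLMN",
    "m3_1": "ACDEFGAIKLMN",  # H7A
    "m4_1": "ACDAFGHIKLMN",  # E4A
}


@pytest.fixture(scope="session")
def worked_entities():
    ents = []
    for uid, seq in WORKED_SEQS.items():
        domains = []
        if uid in ("m1_1", "m2_1"):
            domains = [DomainAnnotation(DomainSource.PFAM, "PF9999", 1, 6)]
        ents.append(PolymerEntity(
            entity_uid=uid, entry_id=uid.split("_")[0], sequence=seq,
            provenance=Provenance.EXPERIMENTAL, organism="Escherichia coli",
            release_date="2020-01-01", domain_annotations=domains,
        ))
    return ents


@pytest.fixture(scope="session")
def worked_structures():
    out = {}
    for uid, seq in WORKED_SEQS.items():
        sm = build_ideal_chain([("helix", len(seq))], seq,
                               entry_id=uid.split("_")[0],
                               rng=np.random.default_rng(0))
        sm.chains[0].entity_uid = uid
        out[uid] = sm
    return out


@pytest.fixture(scope="session")
def worked_group():
    return Group(
        group_id="seqid100_0001",
        provenance=GroupProvenance.SEQUENCE_IDENTITY,
        member_uids=list(WORKED_SEQS),
        threshold=1.0,
    )


@pytest.fixture(scope="session")
def worked_alignment(worked_group):
    return build_group_alignment(worked_group, WORKED_SEQS)
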