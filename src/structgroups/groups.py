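"""Group assembly, member ranking, and summary histograms.

Three grouping methods are supported, at two granularities:

* deposition groups collect *entries* deposited together (keyed on the
  deposition-group id),
* reference-accession groups collect *entities* sharing a reference
  database accession (UniProt-style),
* sequence-identity groups re-label the clusters of one identity threshold.

Group summaries are attribute histograms over members; selecting a bin
splits every histogram into stacked matching/non-matching counts, which
always sum to the unfiltered counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import StrEnum
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from .model_io import PolymerEntity
from .clustering import Cluster, threshold_pct

if TYPE_CHECKING:  # pragma: no cover
    from .alignment import GroupAlignment

logger = logging.getLogger(__name__)


class GroupProvenance(StrEnum):
    DEPOSITION = "deposition"
    REFERENCE_ACCESSION = "reference_accession"
    SEQUENCE_IDENTITY = "sequence_identity"


#: histogram attributes understood by :func:`summarize`
SUPPORTED_ATTRIBUTES = (
    "organism",
    "release_year",
    "determination_methodology",
    "domain_source",
)


@dataclass
class Group:
    """A provenance-tagged ordered member set."""

    group_id: str
    provenance: GroupProvenance
    member_uids: list[str]
    threshold: float | None = None
    reference_sequence: str | None = None
    title: str = ""

    def __post_init__(self) -> None:
        self.provenance = GroupProvenance(self.provenance)
        if not self.member_uids:
            raise ValueError(f"group {self.group_id}: no members")
        if (self.threshold is not None) != (
            self.provenance is GroupProvenance.SEQUENCE_IDENTITY
        ):
            raise ValueError(
                f"group {self.group_id}: threshold present iff identity group"
            )
        if (self.reference_sequence is not None) != (
            self.provenance is GroupProvenance.REFERENCE_ACCESSION
        ):
            raise ValueError(
                f"group {self.group_id}: reference sequence present iff "
                "accession group"
            )


@dataclass
class HistogramSummary:
    """Ordered (label, matching, nonmatching) bins for one attribute.
    Without a subgroup filter every nonmatching count is zero."""

    attribute: str
    bins: list[tuple[str, int, int]] = field(default_factory=list)

    def total(self) -> int:
        return sum(m + n for _, m, n in self.bins)


def build_groups(
    entities: Sequence[PolymerEntity],
    method: GroupProvenance | str,
    clusters: Sequence[Cluster] | None = None,
    reference_sequences: Mapping[str, str] | None = None,
) -> list[Group]:
    """Assemble groups under one provenance method.

    Deposition groups key on ``deposition_group_id`` over *entries*;
    accession groups key on ``accession`` over entities (entities without
    an accession belong to no group); identity groups are the supplied
    clusters re-labelled.  For accession groups the reference sequence is
    taken from ``reference_sequences`` (accession -> sequence) when given,
    else from the longest member sequence (ties by entity_uid).
    """
    method = GroupProvenance(method)
    if method is GroupProvenance.DEPOSITION:
        by_key: dict[str, list[str]] = {}
        seen_entries: dict[str, set[str]] = {}
        for e in entities:
            if not e.deposition_group_id:
                continue
            seen = seen_entries.setdefault(e.deposition_group_id, set())
            if e.entry_id not in seen:
                seen.add(e.entry_id)
                by_key.setdefault(e.deposition_group_id, []).append(e.entry_id)
        return [
            Group(f"dep_{key}", method, members,
                  title=f"Deposition group {key}")
            for key, members in sorted(by_key.items())
        ]
    if method is GroupProvenance.REFERENCE_ACCESSION:
        by_acc: dict[str, list[PolymerEntity]] = {}
        for e in entities:
            if e.accession:
                by_acc.setdefault(e.accession, []).append(e)
        groups = []
        for acc, members in sorted(by_acc.items()):
            if reference_sequences and acc in reference_sequences:
                ref = reference_sequences[acc]
            else:
                ref = min(members,
                          key=lambda e: (-len(e.sequence), e.entity_uid)
                          ).sequence
            groups.append(Group(
                f"uni_{acc}", method, [m.entity_uid for m in members],
                reference_sequence=ref,
                title=f"Accession group {acc}",
            ))
        return groups
    # sequence identity
    if clusters is None:
        raise ValueError("identity grouping requires clusters")
    thresholds = {c.threshold for c in clusters}
    if len(thresholds) != 1:
        raise ValueError(f"clusters from mixed thresholds: {thresholds}")
    thr = thresholds.pop()
    pct = threshold_pct(thr)
    return [
        Group(
            f"seqid{pct}_{i:04d}", method, list(c.member_uids), threshold=thr,
            title=f"Sequence identity {pct}% cluster {i}",
        )
        for i, c in enumerate(clusters, start=1)
    ]


def rank_members(
    group: Group,
    entities: Sequence[PolymerEntity],
    ga: "GroupAlignment | None" = None,
) -> list[str]:
    """Member order for display and pagination.

    Accession groups rank by reference coverage (aligned reference
    positions / reference length, from the group alignment) descending,
    ties by release date ascending then entity_uid; other provenances keep
    input order.
    """
    if group.provenance is not GroupProvenance.REFERENCE_ACCESSION:
        return list(group.member_uids)
    if ga is None:
        raise ValueError(
            "ranking an accession group needs its alignment; call "
            "build_group_alignment first"
        )
    by_uid = {e.entity_uid: e for e in entities}
    ref_len = len(group.reference_sequence or "")

    def coverage(uid: str) -> float:
        regs = ga.members.get(uid, [])
        covered = sum(r.column_end - r.column_begin + 1 for r in regs)
        return covered / ref_len if ref_len else 0.0

    def sort_key(uid: str):
        e = by_uid.get(uid)
        date = e.release_date if e is not None and e.release_date else "9999-12-31"
        return (-coverage(uid), date, uid)

    return sorted(group.member_uids, key=sort_key)


# ---------------------------------------------------------------------------
# summaries


def _attribute_values(entity: PolymerEntity, attribute: str) -> list[str]:
    if attribute == "organism":
        return [entity.organism or "unknown"]
    if attribute == "release_year":
        return [entity.release_date[:4] if entity.release_date else "unknown"]
    if attribute == "determination_methodology":
        return [entity.provenance.value]
    if attribute == "domain_source":
        sources = sorted({d.source.value for d in entity.domain_annotations})
        return sources or ["unknown"]
    raise ValueError(
        f"unknown attribute {attribute!r}; supported: {SUPPORTED_ATTRIBUTES}"
    )


def _group_entities(group: Group,
                    entities: Sequence[PolymerEntity]) -> list[PolymerEntity]:
    if group.provenance is GroupProvenance.DEPOSITION:
        # entry granularity: one synthetic record per entry via its first entity
        by_entry: dict[str, PolymerEntity] = {}
        for e in entities:
            by_entry.setdefault(e.entry_id, e)
        return [by_entry[m] for m in group.member_uids if m in by_entry]
    by_uid = {e.entity_uid: e for e in entities}
    return [by_uid[m] for m in group.member_uids if m in by_uid]


def summarize(group: Group, entities: Sequence[PolymerEntity],
              attribute: str) -> HistogramSummary:
    """Histogram of one attribute over group members (multi-valued
    attributes, e.g. domain sources, contribute one count per value).
    Bins are ordered by count descending, then label."""
    members = _group_entities(group, entities)
    counts: dict[str, int] = {}
    for e in members:
        for v in _attribute_values(e, attribute):
            counts[v] = counts.get(v, 0) + 1
    bins = [(label, n, 0) for label, n in
            sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return HistogramSummary(attribute, bins)


def filter_subgroup(
    group: Group,
    entities: Sequence[PolymerEntity],
    predicate: tuple[str, str],
    attributes: Iterable[str] = SUPPORTED_ATTRIBUTES,
) -> tuple[list[str], dict[str, HistogramSummary]]:
    """Select members matching ``(attribute, bin label)`` and recompute all
    histograms as stacked matching/non-matching counts.

    matching + nonmatching always equals the unfiltered bin count.  An
    absent bin label yields an empty subset (with a warning), not an error.
    """
    attr, label = predicate
    members = _group_entities(group, entities)
    all_labels = {v for e in members for v in _attribute_values(e, attr)}
    if label not in all_labels:
        logger.warning("bin %r not present in attribute %r", label, attr)
    matching_ids = [
        e.entity_uid if group.provenance is not GroupProvenance.DEPOSITION
        else e.entry_id
        for e in members if label in _attribute_values(e, attr)
    ]
    matching_set = set(matching_ids)
    summaries: dict[str, HistogramSummary] = {}
    for attribute in attributes:
        counts: dict[str, list[int]] = {}
        for e in members:
            uid = (e.entity_uid
                   if group.provenance is not GroupProvenance.DEPOSITION
                   else e.entry_id)
            is_match = uid in matching_set
            for v in _attribute_values(e, attribute):
                slot = counts.setdefault(v, [0, 0])
                slot[0 if is_match else 1] += 1
        bins = [(lbl, m, nm) for lbl, (m, nm) in
                sorted(counts.items(), key=lambda kv: (-sum(kv[1]), kv[0]))]
        summaries[attribute] = HistogramSummary(attribute, bins)
    return matching_ids, summaries


def subgroup(group: Group, member_subset: Sequence[str]) -> Group:
    """A group restricted to a member subset (e.g. after filtering), for
    passing to downstream track and superposition computations."""
    ordered = [u for u in group.member_uids if u in set(member_subset)]
    return Group(
        group_id=group.group_id,
        provenance=group.provenance,
        member_uids=ordered,
        threshold=group.threshold,
        reference_sequence=group.reference_sequence,
        title=group.title,
    )
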