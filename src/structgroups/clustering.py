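"""Multi-threshold sequence-identity clustering with incremental updates.

A transparent greedy centroid algorithm (CD-HIT style): entities are
visited longest-first and either join the first existing cluster whose
representative they match at or above the identity threshold, or found a
new cluster.  Identity is computed from an optimal global alignment and
normalized by the *shorter* sequence length, so a full-length chain and an
exact fragment of it share a cluster at 100%.

Weekly-update semantics are reproduced by :func:`update_clusters`: new
entities are assigned against the existing representatives (scanned in
cluster-id order) without ever disturbing existing memberships.

Cluster files use the one-line-per-cluster whitespace-separated layout of
the public ``clusters-by-entity-<threshold>.txt`` archives, representative
first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from pydantic import BaseModel, Field, field_validator

from .alignment import align_pair_global
from .model_io import PolymerEntity

DEFAULT_THRESHOLDS = (0.30, 0.50, 0.70, 0.90, 0.95, 1.00)


class ClusteringConfig(BaseModel):
    """Alignment and threshold parameters for identity clustering."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = Field(default=11.0, ge=0)
    gap_extend: float = Field(default=1.0, ge=0)

    @field_validator("thresholds")
    @classmethod
    def _thresholds_in_range(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        for t in v:
            if not (0.0 < t <= 1.0):
                raise ValueError(f"threshold {t} outside (0, 1]")
        return tuple(sorted(v))


@dataclass
class Cluster:
    """One sequence-identity cluster at a single threshold."""

    cluster_id: str
    threshold: float
    representative_uid: str
    member_uids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.representative_uid not in self.member_uids:
            raise ValueError(
                f"{self.cluster_id}: representative not among members"
            )


def threshold_pct(threshold: float) -> int:
    pct = round(threshold * 100)
    if abs(pct - threshold * 100) > 1e-9:
        raise ValueError(f"threshold {threshold} is not a whole percentage")
    return pct


def make_cluster_id(threshold: float, ordinal: int) -> str:
    """Cluster ids are ``<threshold-pct>_<ordinal>``, zero-padded so that
    lexicographic order equals founding order."""
    return f"{threshold_pct(threshold)}_{ordinal:04d}"


def pairwise_identity(seq_a: str, seq_b: str,
                      config: ClusteringConfig | None = None) -> float:
    """Sequence identity under an optimal global alignment:
    identical aligned columns / min(len_a, len_b).  Symmetric."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    config = config or ClusteringConfig()
    aln = align_pair_global(seq_a, seq_b, config)
    matches = sum(
        1 for i, j in aln.aligned_pairs if seq_a[i - 1] == seq_b[j - 1]
    )
    return matches / min(len(seq_a), len(seq_b))


def cluster_sequences(entities: Sequence[PolymerEntity], threshold: float,
                      config: ClusteringConfig | None = None) -> list[Cluster]:
    """Greedy centroid clustering at one identity threshold.

    Entities are sorted by (length desc, entity_uid asc); each joins the
    first representative it matches at >= threshold, else founds a new
    cluster.  Deterministic.
    """
    if not entities:
        raise ValueError("no entities to cluster")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    config = config or ClusteringConfig()
    order = sorted(entities, key=lambda e: (-len(e.sequence), e.entity_uid))
    clusters: list[Cluster] = []
    reps: list[PolymerEntity] = []
    for ent in order:
        placed = False
        for cl, rep in zip(clusters, reps):
            if pairwise_identity(rep.sequence, ent.sequence, config) >= threshold:
                cl.member_uids.append(ent.entity_uid)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(
                make_cluster_id(threshold, len(clusters) + 1), threshold,
                ent.entity_uid, [ent.entity_uid],
            ))
            reps.append(ent)
    return clusters


def cluster_all_thresholds(
    entities: Sequence[PolymerEntity],
    config: ClusteringConfig | None = None,
) -> dict[float, list[Cluster]]:
    """Independent clustering solutions for every configured threshold."""
    config = config or ClusteringConfig()
    return {t: cluster_sequences(entities, t, config)
            for t in config.thresholds}


def update_clusters(
    existing: Sequence[Cluster],
    new_entities: Sequence[PolymerEntity],
    config: ClusteringConfig | None = None,
    threshold: float | None = None,
    representatives: dict[str, str] | None = None,
) -> list[Cluster]:
    """Incremental update: assign new entities against existing clusters.

    Each new entity joins the first existing representative (clusters
    scanned in cluster-id order) meeting the threshold, else founds a new
    cluster with the next ordinal.  Existing memberships never change.

    ``representatives`` maps representative uid -> sequence for clusters
    whose representative is not among ``new_entities``; it defaults to the
    sequences found in ``new_entities``.
    """
    config = config or ClusteringConfig()
    thresholds = {c.threshold for c in existing}
    if len(thresholds) > 1:
        raise ValueError(f"mixed thresholds in existing clusters: {thresholds}")
    if not existing:
        if threshold is None:
            raise ValueError("threshold required when no existing clusters")
        return cluster_sequences(new_entities, threshold, config)
    thr = thresholds.pop()
    rep_seqs = dict(representatives or {})
    for e in new_entities:
        rep_seqs.setdefault(e.entity_uid, e.sequence)

    clusters = [Cluster(c.cluster_id, c.threshold, c.representative_uid,
                        list(c.member_uids)) for c in existing]
    clusters.sort(key=lambda c: c.cluster_id)
    next_ordinal = len(clusters) + 1
    order = sorted(new_entities, key=lambda e: (-len(e.sequence), e.entity_uid))
    for ent in order:
        placed = False
        for cl in clusters:
            rep_seq = rep_seqs.get(cl.representative_uid)
            if rep_seq is None:
                raise ValueError(
                    f"no sequence for representative {cl.representative_uid}"
                )
            if pairwise_identity(rep_seq, ent.sequence, config) >= thr:
                cl.member_uids.append(ent.entity_uid)
                placed = True
                break
        if not placed:
            cl = Cluster(make_cluster_id(thr, next_ordinal), thr,
                         ent.entity_uid, [ent.entity_uid])
            clusters.append(cl)
            rep_seqs[ent.entity_uid] = ent.sequence
            next_ordinal += 1
    return clusters


def check_partition(clusters: Sequence[Cluster],
                    entity_uids: Iterable[str]) -> None:
    """Assert the clusters partition the entity set (disjoint + covering)."""
    seen: set[str] = set()
    for c in clusters:
        for uid in c.member_uids:
            if uid in seen:
                raise AssertionError(f"{uid} appears in more than one cluster")
            seen.add(uid)
    expected = set(entity_uids)
    if seen != expected:
        raise AssertionError(
            f"cluster membership does not cover the entity set: "
            f"missing={expected - seen}, extra={seen - expected}"
        )


# ---------------------------------------------------------------------------
# cluster file format


def cluster_file_name(threshold: float) -> str:
    return f"clusters-by-entity-{threshold_pct(threshold)}.txt"


def write_cluster_file(clusters: Sequence[Cluster], path: str | Path) -> None:
    """One cluster per line, members whitespace-separated, representative
    first.  All clusters must share one threshold."""
    thresholds = {c.threshold for c in clusters}
    if len(thresholds) != 1:
        raise ValueError("cluster file holds a single threshold")
    with open(path, "w") as fh:
        for c in clusters:
            members = [c.representative_uid] + [
                u for u in c.member_uids if u != c.representative_uid
            ]
            fh.write(" ".join(members) + "\n")


def read_cluster_file(path: str | Path, threshold: float) -> list[Cluster]:
    """Inverse of :func:`write_cluster_file` (cluster ids are regenerated
    in line order)."""
    clusters: list[Cluster] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            members = line.split()
            if not line.strip():
                continue
            if not members:
                raise ValueError(f"{path}:{lineno}: malformed cluster line")
            clusters.append(Cluster(
                make_cluster_id(threshold, len(clusters) + 1), threshold,
                members[0], members,
            ))
    return clusters
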