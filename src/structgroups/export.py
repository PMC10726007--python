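"""JSON serialization of group documents and the end-to-end pipeline.

Document shapes follow the group API vocabulary (group provenance records,
aligned regions per member, alignment documents with optional consensus /
variation summaries, annotation documents with a histogram flag).  They
are pydantic models; the JSON Schemas shipped under
``structgroups/schemas/`` are generated from these models and versioned
in-repo.  No wire compatibility with any remote service is claimed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Sequence

from pydantic import BaseModel, Field, model_validator

from . import __version__
from .alignment import (
    AlignedRegion,
    GroupAlignment,
    build_group_alignment,
    consensus_track,
    variation_track,
)
from .groups import Group, GroupProvenance
from .tracks import PositionalTrack

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"


class GroupProvenanceRecord(BaseModel):
    """Metadata describing a grouping methodology."""

    method: Literal["deposition", "reference_accession", "sequence_identity"]
    granularity: Literal["entry", "entity"]
    software_name: str = "structgroups"
    description: str = ""
    version: str = __version__

    @model_validator(mode="after")
    def _granularity_matches(self) -> "GroupProvenanceRecord":
        if (self.granularity == "entry") != (self.method == "deposition"):
            raise ValueError("entry granularity iff deposition grouping")
        return self


def provenance_record(group: Group) -> GroupProvenanceRecord:
    descriptions = {
        GroupProvenance.DEPOSITION:
            "structures deposited together as one batch",
        GroupProvenance.REFERENCE_ACCESSION:
            "polymer entities sharing a reference database accession",
        GroupProvenance.SEQUENCE_IDENTITY:
            "polymer entities clustered by pairwise sequence identity",
    }
    return GroupProvenanceRecord(
        method=group.provenance.value,
        granularity="entry" if group.provenance is GroupProvenance.DEPOSITION
        else "entity",
        description=descriptions[group.provenance],
    )


class AlignedRegionModel(BaseModel):
    member_begin: int = Field(ge=1)
    member_end: int = Field(ge=1)
    column_begin: int = Field(ge=1)
    column_end: int = Field(ge=1)


class MemberAlignmentModel(BaseModel):
    member_uid: str
    aligned_regions: list[AlignedRegionModel]


class TrackModel(BaseModel):
    track_id: str
    kind: str
    values: list


class GroupAlignmentDocument(BaseModel):
    """The group MSA as aligned regions per member, with optional summary
    tracks recomputed over the emitted member set."""

    schema_version: str = SCHEMA_VERSION
    group_id: str
    reference: str
    n_columns: int
    members: list[MemberAlignmentModel]
    consensus: TrackModel | None = None
    variation: TrackModel | None = None

    @model_validator(mode="after")
    def _lengths(self) -> "GroupAlignmentDocument":
        for tr in (self.consensus, self.variation):
            if tr is not None and len(tr.values) != self.n_columns:
                raise ValueError("summary track length != n_columns")
        return self


class GroupAnnotationsDocument(BaseModel):
    """Positional annotations, either aggregated over the MSA (histogram
    mode) or as per-member feature lists with their column mappings."""

    schema_version: str = SCHEMA_VERSION
    group_id: str
    mode: Literal["per_member", "histogram"]
    tracks: list[TrackModel] = Field(default_factory=list)
    per_member: dict[str, list[dict]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _mode_content(self) -> "GroupAnnotationsDocument":
        if self.mode == "histogram" and self.per_member:
            raise ValueError("histogram mode carries only aggregated tracks")
        return self


def _track_model(tr: PositionalTrack) -> TrackModel:
    return TrackModel(track_id=tr.track_id, kind=tr.kind.value,
                      values=list(tr.values))


def export_group_alignment(
    group: Group,
    ga: GroupAlignment,
    sequences: Mapping[str, str],
    include_summary: bool = True,
    member_filter: Sequence[str] | None = None,
) -> GroupAlignmentDocument:
    """Serialize a group alignment; a member filter restricts the emitted
    members and recomputes consensus/variation over the subset."""
    members = ga.member_order()
    if member_filter is not None:
        unknown = sorted(set(member_filter) - set(members))
        if unknown:
            raise KeyError(f"filter names unknown members: {unknown}")
        members = [u for u in members if u in set(member_filter)]
    sub = GroupAlignment(
        group_id=ga.group_id, n_columns=ga.n_columns,
        reference_uid=ga.reference_uid,
        reference_sequence=ga.reference_sequence,
        members={u: ga.members[u] for u in members},
        insertions={u: v for u, v in ga.insertions.items() if u in set(members)},
    )
    doc = GroupAlignmentDocument(
        group_id=ga.group_id,
        reference=ga.reference_uid,
        n_columns=ga.n_columns,
        members=[
            MemberAlignmentModel(
                member_uid=u,
                aligned_regions=[
                    AlignedRegionModel(**vars(r)) for r in sub.members[u]
                ],
            )
            for u in members
        ],
    )
    if include_summary:
        doc.consensus = _track_model(consensus_track(sub, sequences))
        doc.variation = _track_model(variation_track(sub, sequences))
    return doc


def import_group_alignment(doc: GroupAlignmentDocument | dict
                           ) -> GroupAlignmentDocument:
    """Validate a document (round-trip entry point)."""
    if isinstance(doc, dict):
        return GroupAlignmentDocument.model_validate(doc)
    return GroupAlignmentDocument.model_validate(doc.model_dump())


def alignment_document_to_group_alignment(
    doc: GroupAlignmentDocument,
    reference_sequence: str,
) -> GroupAlignment:
    return GroupAlignment(
        group_id=doc.group_id,
        n_columns=doc.n_columns,
        reference_uid=doc.reference,
        reference_sequence=reference_sequence,
        members={
            m.member_uid: [AlignedRegion(**r.model_dump())
                           for r in m.aligned_regions]
            for m in doc.members
        },
    )


def export_group_annotations(
    group: Group,
    tracks: Sequence[PositionalTrack] | None = None,
    per_member: Mapping[str, Sequence[dict]] | None = None,
    histogram_flag: bool = True,
) -> GroupAnnotationsDocument:
    """Serialize annotations: aggregated positional tracks when
    ``histogram_flag`` is set, per-member feature lists otherwise."""
    if histogram_flag:
        return GroupAnnotationsDocument(
            group_id=group.group_id, mode="histogram",
            tracks=[_track_model(t) for t in (tracks or [])],
        )
    return GroupAnnotationsDocument(
        group_id=group.group_id, mode="per_member",
        per_member={k: list(v) for k, v in (per_member or {}).items()},
    )


def dump_json(doc: BaseModel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(doc.model_dump(), indent=2, sort_keys=True) + "\n"
    )


# ---------------------------------------------------------------------------
# shipped JSON schemas

DOCUMENT_MODELS = {
    "group_provenance": GroupProvenanceRecord,
    "group_alignment": GroupAlignmentDocument,
    "group_annotations": GroupAnnotationsDocument,
}


def shipped_schema(name: str) -> dict:
    """Load one of the JSON Schemas versioned under structgroups/schemas."""
    text = (resources.files("structgroups") / "schemas" /
            f"{name}.schema.json").read_text()
    return json.loads(text)


def validate_document(payload: dict, name: str) -> BaseModel:
    """Validate a JSON payload against a shipped document type."""
    model = DOCUMENT_MODELS[name]
    return model.model_validate(payload)


def write_schemas(out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, model in DOCUMENT_MODELS.items():
        schema = model.model_json_schema()
        (out / f"{name}.schema.json").write_text(
            json.dumps(schema, indent=2, sort_keys=True) + "\n"
        )


# ---------------------------------------------------------------------------
# pipeline


class PipelineConfig(BaseModel):
    """Configuration of one end-to-end run.

    Stages execute in dependency order: cluster -> group -> align ->
    tracks -> superpose -> export.  Structure-dependent stages are skipped
    (with a note in the run summary) when no coordinate files are given.
    """

    structure_dir: str | None = None
    fasta: str | None = None
    sidecar_entities: str | None = None
    sidecar_domains: str | None = None
    import_clusters: str | None = None
    stages: list[str] = Field(default_factory=lambda: [
        "cluster", "group", "align", "tracks", "superpose", "export",
    ])
    method: Literal["deposition", "reference_accession", "sequence_identity"] = (
        "sequence_identity"
    )
    threshold: float = 1.0
    thresholds: tuple[float, ...] | None = None
    reference_member: str | None = None
    column_range: tuple[int, int] | None = None
    eval_range: tuple[int, int] | None = None
    seed: int = 0
    out_dir: str = "structgroups_out"


def _config_hash(config: PipelineConfig) -> str:
    # hash the scientific configuration, not the output location
    payload = config.model_dump()
    payload.pop("out_dir", None)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig | str | Path) -> Path:
    """Execute the configured stages; every stage is logged with its
    parameters and all outputs are deterministic for a fixed config."""
    from . import clustering as cl
    from . import model_io, tracks as tr
    from .groups import build_groups
    from .superpose import superpose_members
    from .model_io import write_structure

    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.model_validate(
            json.loads(Path(config).read_text())
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "software": "structgroups",
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    # ---- inputs
    sidecar = None
    if config.sidecar_entities:
        sidecar = model_io.Sidecar.read(config.sidecar_entities,
                                        config.sidecar_domains)
    if config.structure_dir:
        entities, structures = model_io.load_structure_dir(
            config.structure_dir, sidecar)
    elif config.fasta:
        structures = {}
        entities = [
            model_io.PolymerEntity(entity_uid=uid, entry_id=uid.split("_")[0],
                                   sequence=seq)
            for uid, seq in model_io.read_fasta(config.fasta)
        ]
        if sidecar is not None:
            model_io.merge_sidecar(entities, sidecar)
    else:
        raise ValueError("config must name structure_dir or fasta")
    sequences = {e.entity_uid: e.sequence for e in entities}

    def stage_enabled(name: str) -> bool:
        return name in config.stages

    try:
        clusters = None
        if stage_enabled("cluster"):
            logger.info("stage cluster: thresholds=%s",
                        config.thresholds or (config.threshold,))
            cfg = cl.ClusteringConfig(
                thresholds=config.thresholds or (config.threshold,))
            if config.import_clusters:
                clusters = cl.read_cluster_file(config.import_clusters,
                                                config.threshold)
            else:
                for t in cfg.thresholds:
                    sols = cl.cluster_sequences(entities, t, cfg)
                    cl.check_partition(sols, [e.entity_uid for e in entities])
                    cl.write_cluster_file(sols, out / cl.cluster_file_name(t))
                    if abs(t - config.threshold) < 1e-9:
                        clusters = sols
            summary["stages"]["cluster"] = {
                "n_clusters": len(clusters) if clusters else 0}

        groups = None
        if stage_enabled("group"):
            logger.info("stage group: method=%s", config.method)
            groups = build_groups(entities, config.method, clusters=clusters)
            (out / "groups.json").write_text(json.dumps(
                [
                    {
                        "group_id": g.group_id,
                        "provenance": g.provenance.value,
                        "threshold": g.threshold,
                        "members": g.member_uids,
                        "title": g.title,
                    }
                    for g in groups
                ], indent=2) + "\n")
            summary["stages"]["group"] = {"n_groups": len(groups)}

        alignments: dict[str, GroupAlignment] = {}
        if stage_enabled("align") and groups:
            for g in groups:
                alignments[g.group_id] = build_group_alignment(g, sequences)
            summary["stages"]["align"] = {"n_alignments": len(alignments)}

        all_tracks: dict[str, list[PositionalTrack]] = {}
        if stage_enabled("tracks") and alignments:
            if not structures:
                summary["stages"]["tracks"] = {"skipped": "no coordinates"}
            else:
                for g in groups:
                    ga = alignments[g.group_id]
                    ts = [consensus_track(ga, sequences),
                          variation_track(ga, sequences)]
                    for feat in ("helix", "strand"):
                        ts.append(tr.feature_frequency_track(
                            g, ga, feat, structures=structures,
                            entities=entities))
                    contacts = []
                    for uid in g.member_uids:
                        if uid in structures:
                            contacts.extend(
                                tr.detect_contacts(structures[uid], uid))
                    gl, per_ligand = tr.binding_tracks(g, ga, contacts)
                    ts.append(gl)
                    ts.extend(per_ligand.values())
                    all_tracks[g.group_id] = ts
                tr.tracks_to_tsv(
                    [t for ts in all_tracks.values() for t in ts],
                    out / "tracks.tsv")
                summary["stages"]["tracks"] = {
                    "n_tracks": sum(map(len, all_tracks.values()))}

        if stage_enabled("superpose") and alignments:
            if not structures:
                summary["stages"]["superpose"] = {"skipped": "no coordinates"}
            else:
                sup_dir = out / "superposed"
                sup_dir.mkdir(exist_ok=True)
                rows = ["member\tn_pairs\trmsd\tcolumn_range"]
                n_done = 0
                for g in groups:
                    ga = alignments[g.group_id]
                    with_structs = [u for u in g.member_uids
                                    if u in structures]
                    if len(with_structs) < 2:
                        continue
                    ref = config.reference_member or with_structs[0]
                    results = superpose_members(
                        g, ga, structures, ref_member=ref,
                        column_range=config.column_range,
                        eval_range=config.eval_range)
                    for uid, (res, moved, _) in results.items():
                        cr = (f"{res.column_range[0]}:{res.column_range[1]}"
                              if res.column_range else "full")
                        rows.append(
                            f"{uid}\t{res.n_pairs}\t{res.rmsd:.4f}\t{cr}")
                        write_structure(
                            moved, sup_dir / f"{moved.entry_id}_on_{ref}.cif",
                            sequences={uid: sequences.get(uid, "")} if
                            sequences.get(uid) else None)
                        n_done += 1
                (out / "rmsd.tsv").write_text("\n".join(rows) + "\n")
                summary["stages"]["superpose"] = {"n_superposed": n_done}

        if stage_enabled("export") and alignments:
            for g in groups:
                ga = alignments[g.group_id]
                dump_json(export_group_alignment(g, ga, sequences),
                          out / f"{g.group_id}.alignment.json")
                dump_json(
                    export_group_annotations(
                        g, tracks=all_tracks.get(g.group_id, []),
                        histogram_flag=True),
                    out / f"{g.group_id}.annotations.json")
                dump_json(provenance_record(g),
                          out / f"{g.group_id}.provenance.json")
            summary["stages"]["export"] = {"n_groups": len(groups)}
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    (out / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return out
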