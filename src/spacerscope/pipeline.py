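"""End-to-end orchestration: matching -> filtering -> clustering -> PAM/
orientation -> strand bias.

This is thin glue over the analysis modules; every step is usable on its
own.  External (database-supplied) orientations are keyed per spacer and
reduced to a per-cluster majority for type III/unassigned clusters.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._seq import revcomp
from .config_io import OrfAnnotation, PipelineConfig, SpacerRecord, SubjectSequence
from .match_filter import (
    Hit,
    apply_two_step_filter,
    extract_flanks,
    find_all_hits,
    is_array_hit,
)
from .pam_orient import (
    FlankProfile,
    OrientationCall,
    PamCall,
    build_profile,
    call_pam,
    consensus_flanks,
    pam_side_for_subtype,
    predict_orientation,
    reorient_consensus_pairs,
)
from .repeat_cluster import RepeatCluster, SubtypeReference, cluster_repeats
from .strand_bias import (
    StrandBiasSummary,
    StrandCall,
    classify_strand,
    find_orfs,
    group_strand_bias,
    select_primary_target,
)

logger = logging.getLogger("spacerscope")


@dataclass
class PipelineResult:
    hits: list[Hit]
    kept_hits: list[Hit]
    clusters: list[RepeatCluster]
    profiles: dict[str, tuple[FlankProfile, FlankProfile]]
    orientations: dict[str, OrientationCall]
    pam_calls: dict[str, PamCall | None]
    strand_calls: list[StrandCall]
    strand_summaries: list[StrandBiasSummary] = field(default_factory=list)

    def cluster_of(self, spacer_id: str) -> RepeatCluster | None:
        for cluster in self.clusters:
            if spacer_id in cluster.member_repeats:
                return cluster
        return None


def run_pipeline(
    records: Sequence[SpacerRecord],
    subjects: Sequence[SubjectSequence],
    config: PipelineConfig | None = None,
    orf_annotations: Sequence[OrfAnnotation] | None = None,
    references: Sequence[SubtypeReference] | None = None,
    external_orientations: Mapping[str, str] | None = None,
    group_by: str = "subtype",
) -> PipelineResult:
    """Run the full analysis on in-memory records and subjects.

    ``external_orientations`` maps spacer_id -> 'forward'/'reverse' for
    clusters whose orientation cannot be inferred from the PAM side
    (type III and unassigned); ``orf_annotations`` override the internal
    ORF scanner when given.
    """
    config = config or PipelineConfig()
    by_id = {r.spacer_id: r for r in records}
    subjects_by_id = {s.subject_id: s for s in subjects}

    hits = find_all_hits(records, subjects, config)
    for hit in hits:
        extract_flanks(hit, subjects_by_id[hit.subject_id], config)
        is_array_hit(hit, by_id[hit.spacer_id].repeat, config)
    kept = apply_two_step_filter(hits, records, config)

    clusters = cluster_repeats(records, config, references)

    hits_by_spacer: dict[str, list[Hit]] = defaultdict(list)
    for hit in kept:
        hits_by_spacer[hit.spacer_id].append(hit)
    consensus = {sid: consensus_flanks(hs) for sid, hs in hits_by_spacer.items()}

    profiles: dict[str, tuple[FlankProfile, FlankProfile]] = {}
    orientations: dict[str, OrientationCall] = {}
    pam_calls: dict[str, PamCall | None] = {}
    for cluster in clusters:
        pairs = {sid: consensus[sid] for sid in cluster.member_spacer_ids if sid in consensus}
        if not pairs:
            cluster.n_unique_protospacers = 0
            orientations[cluster.cluster_id] = OrientationCall(cluster.cluster_id, "undetermined")
            pam_calls[cluster.cluster_id] = None
            continue
        prof = build_profile(cluster, pairs, config)
        external = _majority_external(cluster, external_orientations)
        call = predict_orientation(cluster, prof, config, external_orientation=external)
        if call.orientation == "reverse":
            # flip the cluster into its transcribed orientation and rebuild
            pairs = reorient_consensus_pairs(pairs)
            cluster.representative_repeat = revcomp(cluster.representative_repeat)
            cluster.member_repeats = {s: revcomp(r) for s, r in cluster.member_repeats.items()}
            prof = build_profile(cluster, pairs, config)
        profiles[cluster.cluster_id] = prof
        orientations[cluster.cluster_id] = call
        side = pam_side_for_subtype(cluster.subtype) or "upstream"
        if call.orientation == "undetermined" and call.source == "external":
            pam_calls[cluster.cluster_id] = None
        else:
            pam_calls[cluster.cluster_id] = call_pam(cluster, prof, config, side=side)

    strand_calls = _strand_calls(
        records, kept, subjects_by_id, clusters, orientations, orf_annotations, config
    )
    summaries = group_strand_bias(strand_calls, records, group_by, config)
    return PipelineResult(
        hits=hits,
        kept_hits=kept,
        clusters=clusters,
        profiles=profiles,
        orientations=orientations,
        pam_calls=pam_calls,
        strand_calls=strand_calls,
        strand_summaries=summaries,
    )


_ORIENTATION_CODE = {"forward": 1, "reverse": 0, "undetermined": -1}
_STRAND_CODE = {"coding": 1, "template": 0, "undetermined": -1}


def spacer_annotation_rows(
    records: Sequence[SpacerRecord], result: PipelineResult
) -> list[dict]:
    """Per-spacer annotation table rows.

    Orientation and strand calls use the {1, 0, -1} encoding (1 coding
    strand / forward, 0 template strand / reverse, -1 undetermined); the
    separate reason column distinguishes intergenic hits from unresolved
    orientations.
    """
    kept_ids = {h.spacer_id for h in result.kept_hits}
    strand_by_id = {c.spacer_id: c for c in result.strand_calls}
    rows = []
    for record in records:
        cluster = result.cluster_of(record.spacer_id)
        orientation = (
            result.orientations[cluster.cluster_id].orientation if cluster else "undetermined"
        )
        pam = result.pam_calls.get(cluster.cluster_id) if cluster else None
        strand = strand_by_id.get(record.spacer_id)
        rows.append(
            {
                "spacer": record.sequence,
                "repeat": record.repeat,
                "accession": record.host_accession,
                "subtype": record.subtype or "",
                "hit": int(record.spacer_id in kept_ids),
                "repeat_cluster": cluster.cluster_id if cluster else "",
                "orientation_PAMbased": _ORIENTATION_CODE[orientation],
                "strand_call": _STRAND_CODE[strand.call] if strand else -1,
                "PAM": pam.motif if pam else "",
                "undetermined_reason": strand.reason if strand else "no_kept_hit",
            }
        )
    return rows


def _majority_external(
    cluster: RepeatCluster, external: Mapping[str, str] | None
) -> str | None:
    if not external:
        return None
    votes = [external[s] for s in cluster.member_spacer_ids if s in external]
    if not votes:
        return None
    return max(("forward", "reverse"), key=votes.count)


def _strand_calls(
    records: Sequence[SpacerRecord],
    kept: Sequence[Hit],
    subjects_by_id: Mapping[str, SubjectSequence],
    clusters: Sequence[RepeatCluster],
    orientations: Mapping[str, OrientationCall],
    orf_annotations: Sequence[OrfAnnotation] | None,
    config: PipelineConfig,
) -> list[StrandCall]:
    cluster_of: dict[str, RepeatCluster] = {}
    for cluster in clusters:
        for sid in cluster.member_spacer_ids:
            cluster_of[sid] = cluster

    orfs_by_subject: dict[str, list[OrfAnnotation]] = defaultdict(list)
    if orf_annotations is not None:
        for orf in orf_annotations:
            orfs_by_subject[orf.subject_id].append(orf)
    scanned: set[str] = set()

    hits_by_spacer: dict[str, list[Hit]] = defaultdict(list)
    for hit in kept:
        hits_by_spacer[hit.spacer_id].append(hit)

    calls: list[StrandCall] = []
    for record in records:
        hits = hits_by_spacer.get(record.spacer_id)
        if not hits:
            continue
        target = select_primary_target(hits, subjects_by_id)
        best = max(
            (h for h in hits if h.subject_id == target),
            key=lambda h: (h.matched_fraction, -h.s_start),
        )
        cluster = cluster_of.get(record.spacer_id)
        call = orientations.get(cluster.cluster_id) if cluster else None
        orientation = call.orientation if call else "undetermined"
        source = call.source if call else "pam_based"
        if orf_annotations is None and target not in scanned:
            orfs_by_subject[target] = find_orfs(subjects_by_id[target], config)
            scanned.add(target)
        calls.append(
            classify_strand(best, orfs_by_subject[target], orientation, source)
        )
    return calls
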