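"""Self-contained recovery benchmarks on planted synthetic data.

Each routine generates its inputs from a seed, runs the relevant pipeline
stage, and measures recovery against the planted truth.  They back both
the acceptance checks and the reproduction script; all rates are returned
on a 0-100 percent scale unless noted.
"""

from __future__ import annotations

import dataclasses
import math
from collections import defaultdict
from typing import Mapping

import numpy as np

from .config_io import PipelineConfig
from .cooccurrence import categorize_compatibility
from .match_filter import apply_two_step_filter, extract_flanks, find_all_hits, is_array_hit
from .pam_orient import (
    FlankProfile,
    build_profile,
    call_pam,
    gc_background,
    information_content,
    predict_orientation,
    reorient_consensus_pairs,
)
from .pipeline import run_pipeline
from .repeat_cluster import RepeatCluster
from .strand_bias import binomial_strand_test
from .synthetic_data import (
    GeneratorParams,
    generate_compatibility_cohort,
    generate_flank_cluster,
    generate_universe,
)


def _stub_cluster(i: int, subtype: str = "I-E", gc: float = 0.5) -> RepeatCluster:
    cluster = RepeatCluster(f"bench{i:04d}", "ACGTTGCAACGTTGCAACGTTGCAACGTT", subtype=subtype)
    cluster.mean_spacer_gc = gc
    return cluster


def worked_example_strand_bias(n_total: int = 977, n_template: int = 611) -> dict:
    """Template-strand percentage and exact binomial p for printed counts."""
    pct = round(100 * n_template / n_total)
    p = binomial_strand_test(n_total - n_template, n_template)
    return {"template_pct": pct, "p_value": p}


def pam_recovery(seed: int, n_clusters: int = 200, n_protospacers: int = 30,
                 motif: str = "AAG", adherence: float = 0.9) -> float:
    """Percent of clusters whose planted 3-nt PAM is called verbatim at the
    planted positions."""
    rng = np.random.default_rng(seed)
    config = PipelineConfig()
    n_ok = 0
    want = frozenset(range(-len(motif), 0))
    for i in range(n_clusters):
        cluster = _stub_cluster(i)
        pairs = generate_flank_cluster(rng, n_protospacers, (motif, "upstream"), adherence)
        call = call_pam(cluster, build_profile(cluster, pairs, config), config)
        if call is not None and call.motif == motif and call.flagged_positions == want:
            n_ok += 1
    return 100 * n_ok / n_clusters


def pam_false_call_rate(seed: int, n_clusters: int = 200,
                        gcs: tuple[float, ...] = (0.3, 0.5, 0.7)) -> float:
    """Worst-case percent of PAM calls on PAM-free clusters across GC levels."""
    config = PipelineConfig()
    worst = 0.0
    for j, gc in enumerate(gcs):
        rng = np.random.default_rng(seed + 1000 * (j + 1))
        n_false = 0
        for i in range(n_clusters):
            cluster = _stub_cluster(i, gc=gc)
            pairs = generate_flank_cluster(rng, 30, pam=None, gc=gc)
            if call_pam(cluster, build_profile(cluster, pairs, config), config) is not None:
                n_false += 1
        worst = max(worst, 100 * n_false / n_clusters)
    return worst


def orientation_accuracy(seed: int, n_clusters: int = 100) -> dict:
    """Orientation calls on planted forward/reverse clusters.

    Returns the percent of determined calls that are correct, the percent
    of clusters determined, and the percent of under-sized clusters
    (8 protospacers) called undetermined (should be 100)."""
    rng = np.random.default_rng(seed)
    config = PipelineConfig()
    n_det, n_ok = 0, 0
    for i in range(n_clusters):
        planted = "forward" if i % 2 == 0 else "reverse"
        cluster = _stub_cluster(i)
        pairs = generate_flank_cluster(rng, 30, ("AAG", "upstream"), 0.9)
        if planted == "reverse":
            pairs = reorient_consensus_pairs(pairs)
        call = predict_orientation(cluster, build_profile(cluster, pairs, config), config)
        if call.orientation != "undetermined":
            n_det += 1
            n_ok += call.orientation == planted
    n_small_undet = 0
    n_small = 50
    for i in range(n_small):
        cluster = _stub_cluster(i)
        pairs = generate_flank_cluster(rng, 8, ("AAG", "upstream"), 0.9)
        call = predict_orientation(cluster, build_profile(cluster, pairs, config), config)
        n_small_undet += call.orientation == "undetermined"
    return {
        "determined_accuracy_pct": 100 * n_ok / n_det if n_det else float("nan"),
        "determined_pct": 100 * n_det / n_clusters,
        "small_cluster_undetermined_pct": 100 * n_small_undet / n_small,
    }


def filtering_properties(seed: int) -> dict:
    """No-new-contigs, array-hit removal sensitivity and threshold
    monotonicity on a default synthetic universe."""
    import dataclasses as dc

    universe = generate_universe(GeneratorParams(rng_seed=seed % 2**31))
    records, subjects = universe.records, universe.subjects
    by_id = {r.spacer_id: r for r in records}
    subs = {s.subject_id: s for s in subjects}
    config = PipelineConfig()
    hits = find_all_hits(records, subjects, config)
    for h in hits:
        extract_flanks(h, subs[h.subject_id], config)
        is_array_hit(h, by_id[h.spacer_id].repeat, config)
    kept = apply_two_step_filter(hits, records, config)

    step1_subjects = {h.subject_id for h in kept if h.kept_step == "step1"}
    new_subjects = {h.subject_id for h in kept} - step1_subjects

    planted = {
        (h["spacer_id"], h["subject_id"])
        for h in universe.truth.hits
        if h["provenance"] == "array_embedded"
    }
    kept_keys = {(h.spacer_id, h.subject_id) for h in kept}
    removed = len(planted - kept_keys)

    strict_hits = [dc.replace(h) for h in hits]
    strict = apply_two_step_filter(
        strict_hits, records, PipelineConfig(step1_frac=0.95, step2_frac=0.80)
    )
    loose_keys = {(h.spacer_id, h.subject_id, h.s_start, h.strand) for h in kept}
    strict_keys = {(h.spacer_id, h.subject_id, h.s_start, h.strand) for h in strict}
    return {
        "new_subjects_after_step2": len(new_subjects),
        "array_removal_sensitivity_pct": 100 * removed / len(planted),
        "monotonicity_violations": len(strict_keys - loose_keys),
    }


def binomial_oracle(max_n: int = 25) -> dict:
    """Exact test vs exhaustive outcome enumeration for all n <= max_n."""
    worst = 0.0
    for n in range(1, max_n + 1):
        for k in range(n + 1):
            pmf_k = math.comb(n, k)
            expected = sum(
                math.comb(n, i) for i in range(n + 1) if math.comb(n, i) <= pmf_k
            ) / 2 ** n
            worst = max(worst, abs(binomial_strand_test(k, n - k) - expected))
    return {"max_abs_diff": worst, "p_15_vs_5": binomial_strand_test(15, 5)}


STRAND_BIAS_PLAN: Mapping[str, float] = {
    "III-B": 0.65, "I-B": 0.55, "II-A": 0.50, "I-E": 0.43,
}


def strand_bias_recovery(seed: int, n_per_group: int = 400) -> dict:
    """End-to-end recovery of planted per-subtype coding fractions."""
    params = GeneratorParams(
        n_clusters=len(STRAND_BIAS_PLAN),
        spacers_per_cluster=n_per_group,
        subtypes=list(STRAND_BIAS_PLAN),
        coding_fraction=dict(STRAND_BIAS_PLAN),
        hits_per_spacer=(1, 1),
        n_decoy_spacers=0,
        n_array_embedded_hits=0,
        rng_seed=seed % 2**31,
    )
    universe = generate_universe(params)
    external = {
        sid: universe.truth.clusters[t["cluster"]]["orientation"]
        for sid, t in universe.truth.spacers.items()
    }
    result = run_pipeline(universe.records, universe.subjects,
                          orf_annotations=universe.orfs,
                          external_orientations=external)
    groups = {}
    for summary in result.strand_summaries:
        planted = STRAND_BIAS_PLAN[summary.group]
        groups[summary.group] = {
            "planted": planted,
            "measured": summary.fraction_coding,
            "n": summary.n_coding + summary.n_template,
            "significant": summary.significant,
            "p_value": summary.p_value,
        }
    max_err = max(abs(g["measured"] - g["planted"]) for g in groups.values())
    return {"groups": groups, "max_abs_error": max_err}


def compatibility_precision_recall(seed: int, n_per_category: int = 5,
                                   n_negative: int = 5) -> dict:
    contexts, catalog, labels = generate_compatibility_cohort(
        n_per_category, n_negative, rng_seed=seed % 2**31
    )
    tp = fp = fn = 0
    for ctx in contexts:
        want = labels[ctx.host_accession]
        got = categorize_compatibility(ctx, catalog).category
        if want == "none":
            fp += got != "none"
        elif got == want:
            tp += 1
        else:
            fn += 1
            fp += got != "none"
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return {"precision": precision, "recall": recall}


def information_content_closed_forms() -> float:
    """Max abs error of the information content against closed-form values."""
    cases = [
        (np.array([[8, 0, 0, 0]]), 0.5, 2.0),
        (np.array([[3, 7, 7, 3]]), 0.7, 0.0),
        (np.array([[0, 0, 10, 0]]), 0.7, math.log2(1 / 0.35)),
    ]
    worst = 0.0
    for counts, gc, expected in cases:
        profile = FlankProfile("bench", "upstream", counts, gc_background(gc), int(counts.sum()))
        worst = max(worst, abs(information_content(profile)[0] - expected))
    return worst
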