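"""Array-to-cas-cluster linkage and multi-effector compatibility categories.

Genomes carrying several CRISPR-Cas systems are classified into three
organizations of multi-effector compatible arrays:

* **category 1** — two DNA-targeting systems with their own repeat
  clusters (and adaptation machinery) sharing the same PAM;
* **category 2** — a DNA-targeting and an RNA-targeting system with
  distinct repeat clusters sharing the same PAM;
* **category 3** — cas gene clusters of different subtypes within the
  proximity window of a single repeat cluster, with no other arrays
  linked to those cas clusters (shared repeats and shared machinery).

A genome can satisfy several; the most-shared category (3 > 2 > 1) is
reported with all evidence listed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config_io import PipelineConfig
from .pam_orient import PamCall
from .repeat_cluster import RepeatCluster

DNA_TARGETING_TYPES = frozenset({"I", "II", "IV", "V"})
RNA_TARGETING_TYPES = frozenset({"III", "VI"})


def targeting_mode(subtype: str) -> str:
    base = subtype.split("-")[0]
    if base in DNA_TARGETING_TYPES:
        return "DNA"
    if base in RNA_TARGETING_TYPES:
        return "RNA"
    raise ValueError(f"unknown subtype {subtype!r}")


@dataclass(frozen=True)
class CasCluster:
    subtype: str
    has_cas1_cas2: bool
    start: int
    end: int

    @property
    def targeting_mode(self) -> str:
        return targeting_mode(self.subtype)


@dataclass(frozen=True)
class ArrayInfo:
    array_id: str
    repeat_cluster_id: str
    start: int
    end: int


@dataclass
class CasContext:
    """CRISPR arrays and cas gene clusters of one genome."""

    host_accession: str
    cas_clusters: list[CasCluster] = field(default_factory=list)
    arrays: list[ArrayInfo] = field(default_factory=list)


@dataclass
class CompatibilityCall:
    host_accession: str
    category: int | str  # 1, 2, 3 or 'none'
    subtype_pair: tuple[str, ...] = ()
    shared_pam: str | None = None
    evidence: list[str] = field(default_factory=list)


def _interval_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Edge-to-edge distance of two half-open intervals (0 when overlapping)."""
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


def link_arrays_to_systems(
    context: CasContext, config: PipelineConfig | None = None
) -> dict[str, list[CasCluster]]:
    """Link each array to every cas cluster within the proximity window."""
    config = config or PipelineConfig()
    links: dict[str, list[CasCluster]] = {}
    for array in context.arrays:
        links[array.array_id] = [
            cc
            for cc in context.cas_clusters
            if _interval_distance((array.start, array.end), (cc.start, cc.end))
            < config.proximity_bp
        ]
    return links


def _normalize_pam(motif: str) -> str:
    """Exact-match form of a motif: strip uninformative N at either edge."""
    return motif.strip("N")


def _catalog_entry(entry) -> tuple[str, str | None]:
    """(motif, subtype) from a PamCall or (motif, subtype) tuple."""
    if isinstance(entry, PamCall):
        return entry.motif, entry.subtype
    motif, subtype = entry
    return motif, subtype


def categorize_compatibility(
    context: CasContext,
    pam_catalog: Mapping[str, object],
    strand_summaries: Mapping[str, float] | None = None,
    config: PipelineConfig | None = None,
) -> CompatibilityCall:
    """Classify one genome into compatibility categories 1/2/3 or none.

    ``pam_catalog`` maps repeat_cluster_id to a :class:`PamCall` (or a
    ``(motif, subtype)`` tuple) for clusters with a called PAM.  "Same
    PAM" means exact motif-string equality after stripping edge N;
    near-matches via degenerate codes never drive a category.
    ``strand_summaries`` (repeat_cluster_id -> coding fraction), when
    given, is recorded as evidence for RNA-compatible calls.
    """
    config = config or PipelineConfig()
    links = link_arrays_to_systems(context, config)

    # PAM + subtype per repeat cluster present in this genome
    cluster_info: dict[str, tuple[str, str]] = {}
    for array in context.arrays:
        rc = array.repeat_cluster_id
        if rc in cluster_info or rc not in pam_catalog:
            continue
        motif, subtype = _catalog_entry(pam_catalog[rc])
        if motif and subtype:
            cluster_info[rc] = (_normalize_pam(motif), subtype)

    satisfied: list[tuple[int, tuple[str, ...], str | None, str]] = []

    rcs = sorted(cluster_info)
    for i, rc_a in enumerate(rcs):
        for rc_b in rcs[i + 1 :]:
            pam_a, st_a = cluster_info[rc_a]
            pam_b, st_b = cluster_info[rc_b]
            if pam_a != pam_b or st_a == st_b:
                continue
            modes = {targeting_mode(st_a), targeting_mode(st_b)}
            pair = tuple(sorted((st_a, st_b)))
            if modes == {"DNA"}:
                satisfied.append((1, pair, pam_a, f"shared PAM {pam_a}: {rc_a}+{rc_b}"))
            elif modes == {"DNA", "RNA"}:
                note = f"shared PAM {pam_a}: {rc_a}+{rc_b}"
                if strand_summaries:
                    rna_rc = rc_a if targeting_mode(st_a) == "RNA" else rc_b
                    frac = strand_summaries.get(rna_rc)
                    if frac is not None:
                        note += f" (coding fraction {frac:.2f})"
                satisfied.append((2, pair, pam_a, note))

    # category 3: one repeat cluster serving cas clusters of different subtypes
    arrays_by_rc: dict[str, list[ArrayInfo]] = {}
    for array in context.arrays:
        arrays_by_rc.setdefault(array.repeat_cluster_id, []).append(array)
    for rc, arrays in sorted(arrays_by_rc.items()):
        linked = {cc for a in arrays for cc in links[a.array_id]}
        subtypes = sorted({cc.subtype for cc in linked})
        if len(subtypes) < 2:
            continue
        other_arrays = [a for a in context.arrays if a.repeat_cluster_id != rc]
        if any(set(links[a.array_id]) & linked for a in other_arrays):
            continue
        pam = cluster_info.get(rc, (None,))[0]
        satisfied.append((3, tuple(subtypes), pam, f"repeat cluster {rc} linked to {'+'.join(subtypes)}"))

    if not satisfied:
        return CompatibilityCall(context.host_accession, "none")
    satisfied.sort(key=lambda s: -s[0])
    category, pair, pam, _ = satisfied[0]
    return CompatibilityCall(
        host_accession=context.host_accession,
        category=category,
        subtype_pair=pair,
        shared_pam=pam,
        evidence=[f"category {c}: {note}" for c, _, _, note in satisfied],
    )


def pam_frequency_by_acquisition(
    clusters: Sequence[RepeatCluster],
    pam_calls: Mapping[str, PamCall | None],
    contexts: Iterable[CasContext] | None = None,
    min_hits: int = 25,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Fraction of eligible repeat clusters with a PAM call, per subtype.

    Clusters need >= ``min_hits`` unique protospacers to be eligible.
    Type III clusters are split by whether any linked cas cluster of
    their subtype carries its own cas1-cas2 acquisition module (derived
    from ``contexts`` when provided).
    """
    config = config or PipelineConfig()
    cas12_by_rc: dict[str, bool] = {}
    if contexts is not None:
        for context in contexts:
            links = link_arrays_to_systems(context, config)
            for array in context.arrays:
                for cc in links[array.array_id]:
                    if cc.targeting_mode == "RNA":
                        rc = array.repeat_cluster_id
                        cas12_by_rc[rc] = cas12_by_rc.get(rc, False) or cc.has_cas1_cas2

    rows: dict[str, list[int]] = {}
    for cluster in clusters:
        if cluster.n_unique_protospacers < min_hits or cluster.subtype is None:
            continue
        group = cluster.subtype
        if cluster.subtype.split("-")[0] == "III" and cluster.cluster_id in cas12_by_rc:
            suffix = "cas1-2" if cas12_by_rc[cluster.cluster_id] else "no-cas1-2"
            group = f"{cluster.subtype}|{suffix}"
        n_total, n_pam = rows.setdefault(group, [0, 0])
        rows[group][0] = n_total + 1
        rows[group][1] = n_pam + (1 if pam_calls.get(cluster.cluster_id) else 0)

    return pd.DataFrame(
        [
            {"group": g, "n_clusters": n, "n_with_pam": p, "fraction": p / n}
            for g, (n, p) in sorted(rows.items())
        ],
        columns=["group", "n_clusters", "n_with_pam", "fraction"],
    )
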