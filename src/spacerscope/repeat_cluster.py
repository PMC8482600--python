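"""Repeat clustering, subtype assignment and per-cluster spacer GC.

Repeats are clustered greedily at >= 90% global identity with equal length
(deterministic: repeats sorted by descending abundance, then
lexicographically, each joining the first compatible cluster).  Subtypes
are inferred by the closest reference repeat over both orientations at a
74% identity floor.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._align import alignment_identities
from ._seq import gc_fraction, revcomp
from .config_io import PipelineConfig, SpacerRecord, SUBTYPE_VOCABULARY


@dataclass
class SubtypeReference:
    repeat: str
    subtype: str

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPE_VOCABULARY:
            raise ValueError(f"unknown subtype label {self.subtype!r}")


@dataclass
class RepeatCluster:
    """Spacers sharing >= 90%-identical, equal-length repeats."""

    cluster_id: str
    representative_repeat: str
    member_spacer_ids: list[str] = field(default_factory=list)
    member_repeats: dict[str, str] = field(default_factory=dict)  # spacer_id -> repeat
    subtype: str | None = None
    mean_spacer_gc: float = 0.0
    n_unique_protospacers: int = 0


def global_identity(a: str, b: str) -> float:
    """Identities of the best global alignment divided by alignment length.

    Orientation-aware callers pass the reverse complement explicitly.
    """
    if not a or not b:
        raise ValueError("global_identity requires non-empty sequences")
    ident, length = alignment_identities(a, b)
    return ident / length


def cluster_repeats(
    records: Sequence[SpacerRecord],
    config: PipelineConfig | None = None,
    references: Sequence[SubtypeReference] | None = None,
) -> list[RepeatCluster]:
    """Greedy incremental clustering of repeats at the identity threshold.

    Cluster subtype comes from ``references`` when given, else from the
    majority subtype label of the member records.
    """
    config = config or PipelineConfig()
    by_repeat: dict[str, list[SpacerRecord]] = defaultdict(list)
    for r in records:
        by_repeat[r.repeat].append(r)
    # canonical order: most abundant repeats first, ties lexicographic
    ordered = sorted(by_repeat, key=lambda rep: (-len(by_repeat[rep]), rep))

    clusters: list[RepeatCluster] = []
    for rep in ordered:
        home = None
        for cluster in clusters:
            if len(cluster.representative_repeat) != len(rep):
                continue
            if global_identity(cluster.representative_repeat, rep) >= config.repeat_cluster_identity:
                home = cluster
                break
        if home is None:
            home = RepeatCluster(cluster_id=f"rc{len(clusters):04d}", representative_repeat=rep)
            clusters.append(home)
        for record in by_repeat[rep]:
            home.member_spacer_ids.append(record.spacer_id)
            home.member_repeats[record.spacer_id] = rep

    spacer_seq = {r.spacer_id: r.sequence for r in records}
    subtype_of = {r.spacer_id: r.subtype for r in records}
    for cluster in clusters:
        seqs = [spacer_seq[s] for s in cluster.member_spacer_ids]
        cluster.mean_spacer_gc = sum(gc_fraction(s) for s in seqs) / len(seqs)
        if references:
            cluster.subtype = assign_subtype(cluster.representative_repeat, references, config)
        else:
            labels = [subtype_of[s] for s in cluster.member_spacer_ids if subtype_of[s]]
            if labels:
                counts = Counter(labels)
                top = max(counts.values())
                cluster.subtype = min(l for l, c in counts.items() if c == top)
    return clusters


def assign_subtype(
    repeat: str,
    references: Sequence[SubtypeReference],
    config: PipelineConfig | None = None,
) -> str | None:
    """Best-identity reference subtype over both orientations, or None.

    A label is returned only when the best identity reaches the subtype
    threshold; ties break by higher identity then lexicographic label.
    """
    config = config or PipelineConfig()
    if not references:
        raise ValueError("assign_subtype requires at least one reference repeat")
    best: tuple[float, str] | None = None
    for ref in references:
        ident = max(
            global_identity(repeat, ref.repeat),
            global_identity(revcomp(repeat), ref.repeat),
        )
        candidate = (ident, ref.subtype)
        if best is None or ident > best[0] or (ident == best[0] and ref.subtype < best[1]):
            best = candidate
    identity, label = best
    return label if identity >= config.subtype_identity else None
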