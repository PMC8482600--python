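"""Flank profiles, GC-corrected information content, orientation and PAM calls.

Per repeat cluster, every spacer contributes one observation per flank
position: its *consensus flank*, the per-position plurality base over all
of that spacer's kept hits.  Identical consensus-flank pairs within a
cluster collapse to a single "unique protospacer" before counting.

Conservation is measured as relative entropy (bits) of the observed base
frequencies against a background derived from the cluster's mean spacer
GC content (p_A = p_T = (1-GC)/2, p_C = p_G = GC/2), which suppresses the
spurious conservation that uncorrected logos show in GC-extreme taxa.

Orientation is predicted from the side of the conserved flank: the PAM
sits 5' of the protospacer in type I/IV/V systems and 3' in type II, so a
cluster whose conserved flank falls on the subtype's known PAM side is
``forward``, on the opposite side ``reverse``.  Type III and unassigned
clusters keep their externally supplied orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import BASES, IUPAC_CODE, IUPAC_SET, revcomp
from .config_io import PipelineConfig
from .match_filter import Hit
from .repeat_cluster import RepeatCluster

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

FlankPair = tuple[str, str]


@dataclass
class FlankProfile:
    """Per-position base counts and information content for one flank side."""

    cluster_id: str
    side: str  # 'upstream' | 'downstream'
    counts: np.ndarray  # (flank_len, 4) over A,C,G,T
    background: np.ndarray  # (4,) probabilities
    n_protospacers: int
    ic: np.ndarray = field(default=None)  # (flank_len,) bits
    median_ic: float = 0.0  # pooled over both sides, set by build_profile

    def positions(self) -> list[int]:
        """Signed positions: -L..-1 (upstream) or +1..+L (downstream)."""
        length = self.counts.shape[0]
        if self.side == "upstream":
            return list(range(-length, 0))
        return list(range(1, length + 1))

    def frequencies(self, position: int) -> dict[str, float]:
        """Observed base frequencies at a signed position (N excluded)."""
        row = self.counts[self._row(position)]
        total = row.sum()
        if total == 0:
            return {b: 0.0 for b in BASES}
        return {b: row[_BASE_INDEX[b]] / total for b in BASES}

    def ic_at(self, position: int) -> float:
        return float(self.ic[self._row(position)])

    def _row(self, position: int) -> int:
        length = self.counts.shape[0]
        if self.side == "upstream":
            if not -length <= position <= -1:
                raise IndexError(f"position {position} outside upstream flank")
            return position + length
        if not 1 <= position <= length:
            raise IndexError(f"position {position} outside downstream flank")
        return position - 1


@dataclass
class OrientationCall:
    cluster_id: str
    orientation: str  # 'forward' | 'reverse' | 'undetermined'
    qualifying_positions_per_side: dict[str, int] = field(default_factory=dict)
    conservation_score_per_side: dict[str, float] = field(default_factory=dict)
    source: str = "pam_based"  # 'pam_based' | 'external'


@dataclass
class PamCall:
    cluster_id: str
    side: str
    flagged_positions: frozenset[int]
    motif: str
    frequencies: dict[int, dict[str, float]] = field(default_factory=dict)
    representative_repeat: str = ""
    subtype: str | None = None


def pam_side_for_subtype(subtype: str | None) -> str | None:
    """Known PAM side: upstream for type I/IV/V, downstream for type II.

    Returns None for type III/VI and unassigned clusters, whose
    orientation must be supplied externally.
    """
    if subtype is None:
        return None
    base = subtype.split("-")[0]
    if base in ("I", "IV", "V"):
        return "upstream"
    if base == "II":
        return "downstream"
    return None


def consensus_flanks(hits: Sequence[Hit]) -> FlankPair:
    """Per-position plurality base over one spacer's hits; ties and all-N -> N."""
    if not hits:
        raise ValueError("consensus_flanks requires at least one hit")

    def consensus(strings: list[str]) -> str:
        length = max(len(s) for s in strings)
        out = []
        for i in range(length):
            counts = {b: 0 for b in BASES}
            for s in strings:
                if i < len(s) and s[i] in counts:
                    counts[s[i]] += 1
            top = max(counts.values())
            if top == 0:
                out.append("N")
                continue
            winners = [b for b, c in counts.items() if c == top]
            out.append(winners[0] if len(winners) == 1 else "N")
        return "".join(out)

    return (
        consensus([h.upstream_flank for h in hits]),
        consensus([h.downstream_flank for h in hits]),
    )


def gc_background(gc: float) -> np.ndarray:
    """Expected base probabilities (A,C,G,T) at a given GC content."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("GC content must be in [0,1]")
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def information_content(profile: FlankProfile) -> np.ndarray:
    """Per-position relative entropy vs the GC background, in bits.

    ic_i = sum_b f_b log2(f_b / p_b) with 0 log 0 == 0; positions with no
    ACGT observation score 0.  Fills ``profile.ic`` and returns it.
    """
    counts = profile.counts.astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = np.where(totals > 0, counts / np.where(totals == 0, 1, totals), 0.0)
        terms = np.where(freqs > 0, freqs * np.log2(freqs / profile.background), 0.0)
    profile.ic = terms.sum(axis=1)
    return profile.ic


def build_profile(
    cluster: RepeatCluster,
    consensus_pairs: Mapping[str, FlankPair],
    config: PipelineConfig | None = None,
) -> tuple[FlankProfile, FlankProfile]:
    """Accumulate one observation per unique protospacer per position.

    ``consensus_pairs`` maps spacer_id -> (upstream, downstream) consensus
    flanks.  Duplicate identical pairs collapse to one protospacer.  Both
    profiles get their information content and the pooled median over all
    2 x flank_len positions.
    """
    config = config or PipelineConfig()
    length = config.flank_len
    unique_pairs = sorted(set(consensus_pairs.values()))
    background = gc_background(cluster.mean_spacer_gc)
    profiles = {}
    for side, idx in (("upstream", 0), ("downstream", 1)):
        counts = np.zeros((length, 4), dtype=np.int64)
        for pair in unique_pairs:
            flank = pair[idx]
            for i in range(min(length, len(flank))):
                j = _BASE_INDEX.get(flank[i])
                if j is not None:
                    counts[i, j] += 1
        profiles[side] = FlankProfile(
            cluster_id=cluster.cluster_id,
            side=side,
            counts=counts,
            background=background,
            n_protospacers=len(unique_pairs),
        )
    up, down = profiles["upstream"], profiles["downstream"]
    pooled = np.concatenate([information_content(up), information_content(down)])
    up.median_ic = down.median_ic = float(np.median(pooled))
    cluster.n_unique_protospacers = len(unique_pairs)
    return up, down


def reorient_consensus_pairs(pairs: Mapping[str, FlankPair]) -> dict[str, FlankPair]:
    """Flip every consensus pair to the opposite array orientation."""
    return {sid: (revcomp(d), revcomp(u)) for sid, (u, d) in pairs.items()}


def _qualifying_positions(
    profile: FlankProfile, bits_min: float, median_factor: float
) -> list[int]:
    return [
        p
        for p in profile.positions()
        if profile.ic_at(p) > bits_min and profile.ic_at(p) > median_factor * profile.median_ic
    ]


def predict_orientation(
    cluster: RepeatCluster,
    profiles: tuple[FlankProfile, FlankProfile],
    config: PipelineConfig | None = None,
    external_orientation: str | None = None,
) -> OrientationCall:
    """Orientation of the array from the side of the conserved flank.

    A side qualifies when >= 2 positions exceed both the absolute bit
    threshold and the median-ratio threshold.  Clusters with fewer than
    ``min_protospacers`` unique protospacers, or with no qualifying side,
    are undetermined.  Type III/unassigned clusters return the external
    orientation unchanged.
    """
    config = config or PipelineConfig()
    pam_side = pam_side_for_subtype(cluster.subtype)
    if pam_side is None:
        return OrientationCall(
            cluster_id=cluster.cluster_id,
            orientation=external_orientation or "undetermined",
            source="external",
        )
    up, down = profiles
    if up.n_protospacers < config.min_protospacers:
        return OrientationCall(cluster.cluster_id, "undetermined")

    qual = {
        p.side: _qualifying_positions(p, config.orient_bits_min, config.orient_median_factor)
        for p in (up, down)
    }
    scores = {
        side: sum((up if side == "upstream" else down).ic_at(pos) for pos in positions)
        for side, positions in qual.items()
    }
    qualifying_sides = [s for s, positions in qual.items() if len(positions) >= 2]
    if not qualifying_sides:
        return OrientationCall(
            cluster.cluster_id,
            "undetermined",
            {s: len(p) for s, p in qual.items()},
            scores,
        )
    chosen = max(qualifying_sides, key=lambda s: scores[s])
    orientation = "forward" if chosen == pam_side else "reverse"
    return OrientationCall(
        cluster.cluster_id,
        orientation,
        {s: len(p) for s, p in qual.items()},
        scores,
    )


def motif_to_iupac(freqs: Mapping[str, float]) -> str:
    """Smallest base set with cumulative frequency >= 0.8, as an IUPAC code.

    Bases enter the set in descending frequency (alphabetical tie-break).
    """
    ordered = sorted(freqs, key=lambda b: (-freqs[b], b))
    total, chosen = 0.0, []
    for base in ordered:
        chosen.append(base)
        total += freqs[base]
        if total >= 0.8 - 1e-12:
            break
    return IUPAC_CODE[frozenset(chosen)]


def call_pam(
    cluster: RepeatCluster,
    profiles: tuple[FlankProfile, FlankProfile],
    config: PipelineConfig | None = None,
    side: str | None = None,
) -> PamCall | None:
    """Call the PAM on the subtype's PAM side of oriented profiles.

    Positions are flagged when their information content exceeds both the
    absolute PAM bit threshold and the median-ratio threshold.  A call
    requires >= ``min_protospacers`` unique protospacers and
    >= ``pam_min_size`` flagged positions.  The motif spans from the most
    distal flagged position through the protospacer edge, with unflagged
    interior positions rendered N.
    """
    config = config or PipelineConfig()
    if side is None:
        # type III clusters take their (trans-acquired) PAM upstream
        side = pam_side_for_subtype(cluster.subtype) or "upstream"
    profile = profiles[0] if side == "upstream" else profiles[1]
    if profile.n_protospacers < config.min_protospacers:
        return None
    flagged = _qualifying_positions(profile, config.pam_bits_min, config.pam_median_factor)
    if len(flagged) < config.pam_min_size:
        return None
    if side == "upstream":
        span = range(min(flagged), 0)
    else:
        span = range(1, max(flagged) + 1)
    motif, freqs = [], {}
    for pos in span:
        freqs[pos] = profile.frequencies(pos)
        motif.append(motif_to_iupac(freqs[pos]) if pos in flagged else "N")
    return PamCall(
        cluster_id=cluster.cluster_id,
        side=side,
        flagged_positions=frozenset(flagged),
        motif="".join(motif),
        frequencies=freqs,
        representative_repeat=cluster.representative_repeat,
        subtype=cluster.subtype,
    )


def compare_repeat_pam(
    cluster: RepeatCluster, pam_call: PamCall
) -> list[tuple[int, str, str, bool]]:
    """Position-wise comparison of the PAM with the adjacent repeat bases.

    Upstream PAMs (-k..-1) align with the *last* k repeat bases (the
    repeat occupying the same positions relative to the spacer in the
    array); downstream PAMs (+1..+k) align with the *first* k repeat
    bases of the repeat on the other side.  A position matches when the
    repeat base lies in the IUPAC set of the PAM character.
    """
    repeat = cluster.representative_repeat
    k = len(pam_call.motif)
    if k > len(repeat):
        raise ValueError("PAM longer than repeat")
    rows = []
    if pam_call.side == "upstream":
        repeat_slice = repeat[-k:]
        positions = range(-k, 0)
    else:
        repeat_slice = repeat[:k]
        positions = range(1, k + 1)
    for pos, repeat_base, pam_char in zip(positions, repeat_slice, pam_call.motif):
        rows.append((pos, repeat_base, pam_char, repeat_base in IUPAC_SET[pam_char]))
    return rows


def aggregate_repeat_pam(
    comparisons: Iterable[Sequence[tuple[int, str, str, bool]]]
) -> dict[int, float]:
    """Per-position match frequency over many cluster comparisons."""
    hits: dict[int, list[bool]] = {}
    for rows in comparisons:
        for pos, _, _, match in rows:
            hits.setdefault(pos, []).append(match)
    return {pos: sum(v) / len(v) for pos, v in sorted(hits.items())}


CRRNA_HANDLE = "ATTGAAAC"


def detect_crRNA_handle_motif(
    repeat: str, max_mismatch: int = 1, window: int = 10
) -> tuple[bool, int | None]:
    """Look for the crRNA 5'-handle motif ATTGAAAC near the repeat 3' end.

    Returns (found, offset) where offset counts bases between the motif
    end and the repeat 3' end (0 = motif flush with the end).  At most
    ``max_mismatch`` substitutions are allowed within the last ``window``
    nucleotides.
    """
    m = len(CRRNA_HANDLE)
    for offset in range(0, max(0, min(window, len(repeat)) - m) + 1):
        end = len(repeat) - offset
        start = end - m
        if start < 0:
            break
        window_seq = repeat[start:end]
        mismatches = sum(1 for a, b in zip(window_seq, CRRNA_HANDLE) if a != b)
        if mismatches <= max_mismatch:
            return True, offset
    return False, None
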