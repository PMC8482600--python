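"""Spacer-to-subject matching and the two-step matched-fraction filter.

The internal matcher is a seed-and-extend nucleotide search: exact
``seed_word``-mer seeding (default 10, both strands) followed by a gapped
extension (edlib, infix mode) over a banded window around the seed
diagonal.  It reproduces the permissive >=80%-matched-fraction regime the
filter operates in without reimplementing BLAST statistics; pre-computed
tabular hits can be ingested instead via :mod:`spacerscope.config_io`.

The filter removes (i) spacers shorter than the minimum length, (ii) hits
inside CRISPR arrays (repeat aligning to a hit flank with more than 13
identities), then keeps hits with matched fraction > 90% (step 1) and
additionally > 80% when another spacer of the same genus hit the same
subject in step 1 (step 2).  Step 2 can never introduce a new subject.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from ._align import overlap_identity_score
from ._seq import revcomp
from .config_io import PipelineConfig, SpacerRecord, SubjectSequence

logger = logging.getLogger("spacerscope")

_EXTENSION_BAND = 3  # extra bases allowed on each side of the seed diagonal


@dataclass
class Hit:
    """One spacer-to-subject match.

    Coordinates are 0-based half-open on the subject plus strand; flanks
    are reported 5'->3' on the strand whose sequence matches the spacer as
    given (minus-strand hits therefore carry reverse-complemented subject
    sequence), padded with N at contig edges.
    """

    spacer_id: str
    subject_id: str
    s_start: int
    s_end: int
    strand: str
    n_ident: int
    q_len: int
    upstream_flank: str = ""
    downstream_flank: str = ""
    in_array: bool = False
    kept_step: str = "dropped"  # step1 | step2 | dropped

    @property
    def matched_fraction(self) -> float:
        return self.n_ident / self.q_len


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def _extend_candidates(
    query: str, subject: str, anchors: Iterable[int]
) -> list[tuple[int, int, int]]:
    """Align query around each anchor diagonal; return (start, end, n_ident)."""
    qlen = len(query)
    out: dict[tuple[int, int], int] = {}
    seen_windows: set[tuple[int, int]] = set()
    for anchor in anchors:
        w_start = max(0, anchor - _EXTENSION_BAND)
        w_end = min(len(subject), anchor + qlen + _EXTENSION_BAND)
        if (w_start, w_end) in seen_windows:
            continue
        seen_windows.add((w_start, w_end))
        window = subject[w_start:w_end]
        result = edlib.align(query, window, mode="HW", task="path")
        if result["editDistance"] < 0 or not result["locations"]:
            continue
        loc = result["locations"][0]
        nice = edlib.getNiceAlignment(result, query, window)
        n_ident = nice["matched_aligned"].count("|")
        s0, s1 = w_start + loc[0], w_start + loc[1] + 1
        key = (s0, s1)
        if n_ident > out.get(key, -1):
            out[key] = n_ident
    return [(s0, s1, n) for (s0, s1), n in out.items()]


def _collapse_overlaps(hits: list[Hit]) -> list[Hit]:
    """Per (spacer, subject), drop hits overlapping >=50% with a better one."""
    by_key: dict[tuple[str, str], list[Hit]] = defaultdict(list)
    for h in hits:
        by_key[(h.spacer_id, h.subject_id)].append(h)
    kept: list[Hit] = []
    for group in by_key.values():
        group.sort(key=lambda h: (-h.n_ident, h.s_start, h.strand))
        chosen: list[Hit] = []
        for h in group:
            span = h.s_end - h.s_start
            clash = any(
                max(0, min(h.s_end, c.s_end) - max(h.s_start, c.s_start))
                >= 0.5 * min(span, c.s_end - c.s_start)
                for c in chosen
            )
            if not clash:
                chosen.append(h)
        kept.extend(chosen)
    kept.sort(key=lambda h: (h.spacer_id, h.subject_id, h.s_start, h.strand))
    return kept


def find_hits(
    spacer: SpacerRecord | str,
    subject: SubjectSequence,
    config: PipelineConfig | None = None,
    _index: Mapping[str, list[int]] | None = None,
) -> list[Hit]:
    """Seed-and-extend search of one spacer against one subject, both strands."""
    config = config or PipelineConfig()
    if isinstance(spacer, SpacerRecord):
        spacer_id, seq = spacer.spacer_id, spacer.sequence
    else:
        spacer_id, seq = "query", spacer
    k = config.seed_word
    if len(seq) < k:
        return []
    index = _index if _index is not None else _kmer_index(subject.sequence, k)
    hits: list[Hit] = []
    for strand in "+-":
        oriented = seq if strand == "+" else revcomp(seq)
        anchors: set[int] = set()
        for j in range(len(oriented) - k + 1):
            for i in index.get(oriented[j : j + k], ()):
                anchors.add(i - j)
        for s0, s1, n_ident in _extend_candidates(oriented, subject.sequence, sorted(anchors)):
            hits.append(
                Hit(
                    spacer_id=spacer_id,
                    subject_id=subject.subject_id,
                    s_start=s0,
                    s_end=s1,
                    strand=strand,
                    n_ident=n_ident,
                    q_len=len(seq),
                )
            )
    return _collapse_overlaps(hits)


def find_all_hits(
    records: Sequence[SpacerRecord],
    subjects: Sequence[SubjectSequence],
    config: PipelineConfig | None = None,
) -> list[Hit]:
    """Search every spacer against every subject.

    The spacers' ``seed_word``-mers are indexed once (both strands); each
    subject is scanned a single time, so the cost scales with total
    subject length rather than with spacers x subjects.
    """
    config = config or PipelineConfig()
    k = config.seed_word
    # kmer -> list of (record index, query offset, strand)
    seed_index: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    for ri, record in enumerate(records):
        for strand in "+-":
            oriented = record.sequence if strand == "+" else revcomp(record.sequence)
            for j in range(len(oriented) - k + 1):
                seed_index[oriented[j : j + k]].append((ri, j, strand))

    hits: list[Hit] = []
    for subject in subjects:
        seq = subject.sequence
        # (record, strand) -> anchor diagonals
        anchors: dict[tuple[int, str], set[int]] = defaultdict(set)
        for i in range(len(seq) - k + 1):
            for ri, j, strand in seed_index.get(seq[i : i + k], ()):
                anchors[(ri, strand)].add(i - j)
        subject_hits: list[Hit] = []
        for (ri, strand), diag in sorted(anchors.items()):
            record = records[ri]
            oriented = record.sequence if strand == "+" else revcomp(record.sequence)
            for s0, s1, n_ident in _extend_candidates(oriented, seq, sorted(diag)):
                subject_hits.append(
                    Hit(
                        spacer_id=record.spacer_id,
                        subject_id=subject.subject_id,
                        s_start=s0,
                        s_end=s1,
                        strand=strand,
                        n_ident=n_ident,
                        q_len=len(record.sequence),
                    )
                )
        hits.extend(_collapse_overlaps(subject_hits))
    return hits


def hits_from_table(df) -> list[Hit]:
    """Convert a parsed extended tabular hit table (see
    :func:`spacerscope.config_io.read_hit_table`) into Hit objects."""
    return [
        Hit(
            spacer_id=str(row.qseqid),
            subject_id=str(row.sseqid),
            s_start=int(row.s_start),
            s_end=int(row.s_end),
            strand=str(row.strand),
            n_ident=int(row.nident),
            q_len=int(row.qlen),
        )
        for row in df.itertuples(index=False)
    ]


def extract_flanks(
    hit: Hit, subject: SubjectSequence, config: PipelineConfig | None = None
) -> tuple[str, str]:
    """Flanking sequence on both sides of the protospacer, spacer orientation.

    Upstream is the ``flank_len`` bases 5' of the protospacer on the strand
    matching the spacer; positions beyond the contig are N.  Sets the
    flanks on ``hit`` and returns them.
    """
    config = config or PipelineConfig()
    n = config.flank_len
    seq = subject.sequence
    left = seq[max(0, hit.s_start - n) : hit.s_start].rjust(n, "N")
    right = seq[hit.s_end : hit.s_end + n].ljust(n, "N")
    if hit.strand == "+":
        up, down = left, right
    else:
        up, down = revcomp(right), revcomp(left)
    hit.upstream_flank, hit.downstream_flank = up, down
    return up, down


def is_array_hit(
    hit: Hit, repeat: str, config: PipelineConfig | None = None
) -> bool:
    """True when the spacer's repeat aligns to either flank with > 13 identities.

    The alignment is global with free end gaps (the repeat is longer than
    the flank window) and the identity statistic is net of interior gap
    costs, so chance alignments cannot inflate it by gapping.  Both the
    repeat and its reverse complement are tested (arrays occur on either
    strand).  Sets ``hit.in_array`` as a side effect.
    """
    config = config or PipelineConfig()
    flanks = [f for f in (hit.upstream_flank, hit.downstream_flank) if f]
    best = 0
    for flank in flanks:
        for rep in (repeat, revcomp(repeat)):
            score = overlap_identity_score(
                rep, flank, config.array_gap_open, config.array_gap_extend
            )
            best = max(best, score)
    hit.in_array = best > config.array_identity_min
    return hit.in_array


def apply_two_step_filter(
    hits: Sequence[Hit],
    records: Sequence[SpacerRecord],
    config: PipelineConfig | None = None,
) -> list[Hit]:
    """Apply the two-step matched-fraction filter; returns kept hits.

    Step 1 keeps matched fraction > ``step1_frac``; step 2 additionally
    keeps fraction > ``step2_frac`` on subjects that already received a
    step-1 hit from a *different* spacer of the same genus.  Spacers
    shorter than ``min_spacer_len`` and in-array hits are removed first.
    Every hit's ``kept_step`` is labeled.
    """
    config = config or PipelineConfig()
    genus_of = {r.spacer_id: r.genus for r in records}

    eligible: list[Hit] = []
    for h in hits:
        h.kept_step = "dropped"
        if h.q_len < config.min_spacer_len or h.in_array:
            continue
        eligible.append(h)

    step1 = [h for h in eligible if h.matched_fraction > config.step1_frac]
    for h in step1:
        h.kept_step = "step1"

    # subject -> genus -> spacer ids with a step-1 hit
    anchors: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for h in step1:
        genus = genus_of.get(h.spacer_id)
        if genus:
            anchors[h.subject_id][genus].add(h.spacer_id)

    kept = list(step1)
    for h in eligible:
        if h.kept_step == "step1" or h.matched_fraction <= config.step2_frac:
            continue
        genus = genus_of.get(h.spacer_id)
        if not genus:
            logger.info("spacer %s has no genus; step-1 only", h.spacer_id)
            continue
        anchor_ids = anchors[h.subject_id].get(genus, set())
        if anchor_ids - {h.spacer_id}:
            h.kept_step = "step2"
            kept.append(h)
    return kept
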