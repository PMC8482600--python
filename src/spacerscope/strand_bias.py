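"""Coding- vs template-strand targeting of spacers inside ORFs.

Strand semantics follow the base-pairing picture: a crRNA in its
transcribed orientation hybridizes ("targets") the subject strand
complementary to the one its sequence matches.  When that targeted strand
is the ORF's coding strand, the same crRNA can also base-pair the mRNA, so
coding-strand targeting is synonymous with RNA-targeting capability;
template-strand targeting is DNA-only.  Bias per group is tested with an
exact two-sided binomial test at p0 = 0.5.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import binomtest

from ._seq import revcomp
from .config_io import OrfAnnotation, PipelineConfig, SpacerRecord, SubjectSequence
from .match_filter import Hit

_SOURCE_PRIORITY = {"nucleotide_db": 0, "synthetic": 1, "metagenome": 2}

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
MIN_ORF_NT = 90


@dataclass
class StrandCall:
    spacer_id: str
    subject_id: str | None
    call: str  # 'coding' | 'template' | 'undetermined'
    orf: OrfAnnotation | None = None
    spacer_orientation_source: str = "pam_based"  # 'pam_based' | 'external'
    reason: str = ""  # why undetermined, when it is


@dataclass
class StrandBiasSummary:
    group: str
    n_coding: int
    n_template: int
    fraction_coding: float
    p_value: float
    significant: bool


def select_primary_target(
    hits: Sequence[Hit], subjects: Mapping[str, SubjectSequence]
) -> str:
    """One target subject per spacer: prefer nucleotide-database subjects
    over metagenomic ones, then the longest subject, then lexicographic id."""
    if not hits:
        raise ValueError("select_primary_target requires at least one hit")
    ids = sorted({h.subject_id for h in hits})
    return min(
        ids,
        key=lambda sid: (
            _SOURCE_PRIORITY.get(subjects[sid].source_class, 3),
            -subjects[sid].length,
            sid,
        ),
    )


def find_orfs(
    subject: SubjectSequence, config: PipelineConfig | None = None
) -> list[OrfAnnotation]:
    """Simple six-frame ORF scan (bacterial code).

    One ORF per stop codon: the longest open frame starting at ATG/GTG/TTG,
    minimum 90 nt including the stop.  GFF annotations, when available,
    take precedence over this scanner.
    """
    orfs: list[OrfAnnotation] = []
    n = len(subject.sequence)
    for strand, seq in (("+", subject.sequence), ("-", revcomp(subject.sequence))):
        for frame in range(3):
            start_candidate: int | None = None
            for i in range(frame, len(seq) - 2, 3):
                codon = seq[i : i + 3]
                if codon in STOP_CODONS:
                    if start_candidate is not None and i + 3 - start_candidate >= MIN_ORF_NT:
                        lo, hi = start_candidate, i + 3
                        if strand == "-":
                            lo, hi = n - hi, n - lo
                        orfs.append(OrfAnnotation(subject.subject_id, lo, hi, strand))
                    start_candidate = None
                elif start_candidate is None and codon in START_CODONS:
                    start_candidate = i
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def classify_strand(
    hit: Hit,
    orfs: Sequence[OrfAnnotation],
    orientation: str,
    orientation_source: str = "pam_based",
) -> StrandCall:
    """Classify one hit as coding- or template-strand targeting.

    ``orientation`` is the array-orientation call for the spacer's cluster
    ('forward': the stored spacer is the transcribed crRNA sequence;
    'reverse': the transcribed sequence is its reverse complement;
    'undetermined' propagates).  Requires the protospacer to lie fully
    inside exactly one ORF.
    """
    if orientation == "undetermined":
        return StrandCall(hit.spacer_id, hit.subject_id, "undetermined",
                          spacer_orientation_source=orientation_source,
                          reason="orientation_undetermined")
    # subject strand matched by the crRNA in its transcribed orientation
    s = hit.strand if orientation == "forward" else ("-" if hit.strand == "+" else "+")
    containing = [
        o for o in orfs
        if o.subject_id == hit.subject_id and o.start <= hit.s_start and hit.s_end <= o.end
    ]
    if len(containing) != 1:
        reason = "intergenic_or_partial" if not containing else "overlapping_orfs"
        return StrandCall(hit.spacer_id, hit.subject_id, "undetermined",
                          spacer_orientation_source=orientation_source, reason=reason)
    orf = containing[0]
    # the crRNA hybridizes the complement of s; that is the coding strand
    # exactly when s is the ORF's template strand
    call = "coding" if s != orf.strand else "template"
    return StrandCall(hit.spacer_id, hit.subject_id, call, orf, orientation_source)


def binomial_strand_test(n_coding: int, n_template: int) -> float:
    """Exact two-sided binomial p-value at p0 = 0.5.

    Two-sided: the sum of probabilities of all outcomes no more likely
    than the observed one.
    """
    n = n_coding + n_template
    if n < 1:
        raise ValueError("binomial_strand_test requires at least one call")
    return binomtest(n_coding, n, 0.5, alternative="two-sided").pvalue


def _cas_context(record: SpacerRecord) -> str:
    """Which Cas effector *types* co-occur in the host genome."""
    types = sorted({g.split("-")[0] for g in record.cas_genes})
    return "+".join(types) if types else "none"


def group_strand_bias(
    strand_calls: Sequence[StrandCall],
    records: Sequence[SpacerRecord],
    group_by: str = "subtype",
    config: PipelineConfig | None = None,
) -> list[StrandBiasSummary]:
    """Per-group coding/template counts with exact binomial p-values.

    ``group_by`` is one of ``'subtype'``, ``'genus_subtype'`` or
    ``'subtype_cas_context'``.  Undetermined calls are excluded; groups
    with no determined calls are omitted.
    """
    config = config or PipelineConfig()
    if group_by not in ("subtype", "genus_subtype", "subtype_cas_context"):
        raise KeyError(f"unknown group key {group_by!r}")
    by_id = {r.spacer_id: r for r in records}

    def key(r: SpacerRecord) -> str:
        if group_by == "subtype":
            return r.subtype or "unassigned"
        if group_by == "genus_subtype":
            return f"{r.genus or 'unknown'}|{r.subtype or 'unassigned'}"
        if group_by == "subtype_cas_context":
            return f"{r.subtype or 'unassigned'}|{_cas_context(r)}"
        raise KeyError(f"unknown group key {group_by!r}")

    counts: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for call in strand_calls:
        if call.call == "undetermined":
            continue
        record = by_id.get(call.spacer_id)
        if record is None:
            raise KeyError(f"strand call for unknown spacer {call.spacer_id!r}")
        counts[key(record)][0 if call.call == "coding" else 1] += 1

    summaries = []
    for group in sorted(counts):
        n_coding, n_template = counts[group]
        p = binomial_strand_test(n_coding, n_template)
        summaries.append(
            StrandBiasSummary(
                group=group,
                n_coding=n_coding,
                n_template=n_template,
                fraction_coding=n_coding / (n_coding + n_template),
                p_value=p,
                significant=p < config.alpha,
            )
        )
    return summaries
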