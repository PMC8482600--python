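"""Primary-target selection, ORF scanning, strand classification and the
exact binomial bias test."""

import math

import numpy as np
import pytest

from spacerscope._seq import revcomp
from spacerscope.config_io import OrfAnnotation, SpacerRecord, SubjectSequence
from spacerscope.match_filter import Hit
from spacerscope.strand_bias import (
    StrandCall,
    binomial_strand_test,
    classify_strand,
    find_orfs,
    group_strand_bias,
    select_primary_target,
)
from spacerscope.synthetic_data import _random_codons, _random_seq


def _hit(spacer_id="sp", subject_id="s1", start=100, end=132, strand="+"):
    return Hit(spacer_id, subject_id, start, end, strand, 32, 32)


class TestPrimaryTarget:
    def _subjects(self, *specs):
        return {
            sid: SubjectSequence(sid, "A" * length, source)
            for sid, length, source in specs
        }

    def test_single_hit(self):
        subjects = self._subjects(("s1", 1000, "nucleotide_db"))
        assert select_primary_target([_hit()], subjects) == "s1"

    def test_database_priority_beats_length(self):
        subjects = self._subjects(
            ("meta", 5000, "metagenome"), ("nt", 3000, "nucleotide_db")
        )
        hits = [_hit(subject_id="meta"), _hit(subject_id="nt")]
        assert select_primary_target(hits, subjects) == "nt"

    def test_longest_within_class(self):
        subjects = self._subjects(
            ("a", 4000, "nucleotide_db"), ("b", 6000, "nucleotide_db")
        )
        hits = [_hit(subject_id="a"), _hit(subject_id="b")]
        assert select_primary_target(hits, subjects) == "b"


class TestFindOrfs:
    def test_planted_plus_strand_orf(self, rng):
        orf = "ATG" + _random_codons(rng, 98, 0.5) + "TAA"  # 300 nt
        # in-frame stop right before the start codon pins the ORF start
        prefix = _random_seq(rng, 97, 0.5) + "TAA"
        subject = SubjectSequence("s1", prefix + orf + _random_seq(rng, 100, 0.5))
        orfs = find_orfs(subject)
        assert OrfAnnotation("s1", 100, 400, "+") in orfs

    def test_planted_minus_strand_orf(self, rng):
        orf = "ATG" + _random_codons(rng, 60, 0.5) + "TAA"
        subject = SubjectSequence("s1", _random_seq(rng, 50, 0.5) + revcomp(orf) + _random_seq(rng, 50, 0.5))
        orfs = find_orfs(subject)
        match = [o for o in orfs if o.strand == "-" and o.start == 50]
        assert match and match[0].end == 50 + len(orf)

    def test_short_orf_not_reported(self, rng):
        orf = "ATG" + _random_codons(rng, 18, 0.5) + "TAA"  # 60 nt
        subject = SubjectSequence("s1", "C" * 50 + orf + "C" * 50)
        assert all(o.end - o.start >= 90 for o in find_orfs(subject))


class TestClassifyStrand:
    ORF = OrfAnnotation("s1", 50, 350, "+")

    def test_minus_strand_hit_in_plus_orf_is_coding(self):
        """The crRNA matches the template strand, so it base-pairs the mRNA."""
        call = classify_strand(_hit(strand="-"), [self.ORF], "forward")
        assert call.call == "coding"

    def test_plus_strand_hit_in_plus_orf_is_template(self):
        call = classify_strand(_hit(strand="+"), [self.ORF], "forward")
        assert call.call == "template"

    def test_reverse_array_orientation_flips_call(self):
        call = classify_strand(_hit(strand="+"), [self.ORF], "reverse")
        assert call.call == "coding"

    def test_undetermined_orientation_propagates(self):
        call = classify_strand(_hit(), [self.ORF], "undetermined")
        assert call.call == "undetermined"
        assert call.reason == "orientation_undetermined"

    def test_partial_overlap_undetermined(self):
        call = classify_strand(_hit(start=40, end=72), [self.ORF], "forward")
        assert call.call == "undetermined"
        assert call.reason == "intergenic_or_partial"

    def test_overlapping_orfs_undetermined(self):
        orfs = [self.ORF, OrfAnnotation("s1", 60, 360, "-")]
        assert classify_strand(_hit(), orfs, "forward").call == "undetermined"

    def test_revcomp_subject_invariance(self):
        """Flipping the subject flips ORF and hit strand together: same call."""
        n = 500
        fwd = classify_strand(_hit(strand="-"), [self.ORF], "forward")
        flipped_orf = OrfAnnotation("s1", n - 350, n - 50, "-")
        rev = classify_strand(_hit(start=n - 132, end=n - 100, strand="+"),
                              [flipped_orf], "forward")
        assert fwd.call == rev.call == "coding"


class TestBinomialTest:
    def test_symmetric_counts_give_one(self):
        assert binomial_strand_test(5, 5) == pytest.approx(1.0)

    def test_fifteen_vs_five(self):
        # exact enumeration: 2 * P(X <= 5 | n=20, p=0.5) = 43400/2^20
        assert binomial_strand_test(15, 5) == pytest.approx(0.0413894653, abs=1e-9)

    def test_symmetry(self):
        for a, b in [(3, 9), (0, 7), (12, 12)]:
            assert binomial_strand_test(a, b) == pytest.approx(binomial_strand_test(b, a))

    def test_matches_enumeration_for_small_n(self):
        """Exact two-sided p equals the sum of outcome probabilities <= observed."""
        for n in range(1, 26):
            for k in range(n + 1):
                pmf_k = math.comb(n, k)
                expected = sum(
                    math.comb(n, i) for i in range(n + 1) if math.comb(n, i) <= pmf_k
                ) / 2 ** n
                assert binomial_strand_test(k, n - k) == pytest.approx(expected, abs=1e-12)


class TestGroupStrandBias:
    def _calls_and_records(self, spec, rng):
        """spec: {subtype: (n, coding_fraction)} -> synthetic calls/records."""
        calls, records = [], []
        i = 0
        for subtype, (n, frac) in spec.items():
            for _ in range(n):
                sid = f"sp{i}"
                i += 1
                records.append(SpacerRecord(sid, "A" * 32, "G" * 29, "N1",
                                            genus="Escherichia", subtype=subtype))
                call = "coding" if rng.random() < frac else "template"
                calls.append(StrandCall(sid, "s1", call))
        return calls, records

    def test_planted_bias_recovered_and_significant(self):
        rng = np.random.default_rng(10)
        calls, records = self._calls_and_records({"III-B": (500, 0.65)}, rng)
        (summary,) = group_strand_bias(calls, records)
        assert summary.fraction_coding == pytest.approx(0.65, abs=0.05)
        assert summary.significant

    def test_no_bias_rarely_significant(self):
        """Type-I error control: planted 50% at n=100 is non-significant at
        alpha 0.01 in >= 95% of seeds."""
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            calls, records = self._calls_and_records({"I-E": (100, 0.5)}, rng)
            (summary,) = group_strand_bias(calls, records)
            hits += summary.significant
        assert hits <= 2

    def test_undetermined_only_group_omitted(self):
        records = [SpacerRecord("a", "A" * 32, "G" * 29, "N1", subtype="I-E")]
        calls = [StrandCall("a", "s1", "undetermined")]
        assert group_strand_bias(calls, records) == []

    def test_unknown_group_key(self):
        with pytest.raises(KeyError):
            group_strand_bias([], [], group_by="habitat")

    def test_cas_context_grouping(self):
        records = [
            SpacerRecord("a", "A" * 32, "G" * 29, "N1", subtype="I-E",
                         cas_genes=frozenset({"I-E", "III-A"})),
            SpacerRecord("b", "A" * 32, "G" * 29, "N2", subtype="I-E",
                         cas_genes=frozenset({"I-E"})),
        ]
        calls = [StrandCall("a", "s1", "coding"), StrandCall("b", "s1", "template")]
        groups = {s.group for s in group_strand_bias(calls, records, "subtype_cas_context")}
        assert groups == {"I-E|I+III", "I-E|I"}
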