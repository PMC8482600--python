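"""Seed-and-extend matcher, flank extraction, array-hit test, two-step filter."""

import dataclasses

import numpy as np
import pytest

from spacerscope._seq import revcomp
from spacerscope.config_io import PipelineConfig, SpacerRecord, SubjectSequence
from spacerscope.match_filter import (
    Hit,
    apply_two_step_filter,
    extract_flanks,
    find_hits,
    is_array_hit,
)


def _rand(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _mutate(rng, seq, n_sub):
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_sub, replace=False):
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


class TestFindHits:
    def test_exact_substring_is_perfect_hit(self, rng):
        spacer = _rand(rng, 32)
        subject = SubjectSequence("s1", _rand(rng, 100) + spacer + _rand(rng, 100))
        hits = find_hits(spacer, subject)
        assert len(hits) == 1
        h = hits[0]
        assert (h.s_start, h.s_end, h.strand) == (100, 132, "+")
        assert h.matched_fraction == 1.0

    def test_two_substitutions_counted(self, rng):
        spacer = _rand(rng, 32)
        proto = _mutate(rng, spacer, 2)
        subject = SubjectSequence("s1", _rand(rng, 80) + proto + _rand(rng, 80))
        hits = find_hits(spacer, subject)
        best = max(hits, key=lambda h: h.n_ident)
        assert best.n_ident == 30
        assert best.matched_fraction == pytest.approx(0.9375)

    def test_no_shared_seed_word_no_hits(self):
        spacer = "A" * 32
        subject = SubjectSequence("s1", "CG" * 200)
        assert find_hits(spacer, subject) == []

    def test_minus_strand_hit(self, rng):
        spacer = _rand(rng, 32)
        subject = SubjectSequence("s1", _rand(rng, 50) + revcomp(spacer) + _rand(rng, 50))
        hits = find_hits(spacer, subject)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].s_start, hits[0].s_end) == (50, 82)

    def test_matches_exhaustive_oracle(self, rng):
        """Every location with <= 3 substitutions found by sliding-window scan
        is reported by the matcher (subjects <= 2 kb)."""
        spacer = _rand(rng, 32)
        parts = [_rand(rng, 300)]
        for n_sub in (0, 1, 3):
            parts.append(_mutate(rng, spacer, n_sub))
            parts.append(_rand(rng, 200))
        parts.append(revcomp(_mutate(rng, spacer, 2)))
        parts.append(_rand(rng, 200))
        subject = SubjectSequence("s1", "".join(parts))

        oracle = set()
        for strand, seq in (("+", subject.sequence), ("-", revcomp(subject.sequence))):
            for i in range(len(seq) - 32 + 1):
                window = seq[i : i + 32]
                if sum(1 for a, b in zip(window, spacer) if a != b) <= 3:
                    lo = i if strand == "+" else len(seq) - i - 32
                    oracle.add((lo, lo + 32, strand))
        found = {(h.s_start, h.s_end, h.strand) for h in find_hits(spacer, subject)}
        assert oracle <= found


class TestExtractFlanks:
    def test_plus_strand_convention(self, rng):
        seq = _rand(rng, 300)
        subject = SubjectSequence("s1", seq)
        hit = Hit("sp", "s1", 100, 132, "+", 32, 32)
        up, down = extract_flanks(hit, subject)
        assert up == seq[77:100]
        assert down == seq[132:155]

    def test_minus_strand_matches_revcomp_recompute(self, rng):
        """Minus-strand flanks equal plus-strand flanks on the revcomp subject."""
        seq = _rand(rng, 300)
        subject = SubjectSequence("s1", seq)
        hit = Hit("sp", "s1", 100, 132, "-", 32, 32)
        up, down = extract_flanks(hit, subject)

        flipped = SubjectSequence("s1", revcomp(seq))
        mirror = Hit("sp", "s1", len(seq) - 132, len(seq) - 100, "+", 32, 32)
        up2, down2 = extract_flanks(mirror, flipped)
        assert (up, down) == (up2, down2)

    def test_contig_edge_padded_with_n(self, rng):
        subject = SubjectSequence("s1", _rand(rng, 50))
        hit = Hit("sp", "s1", 5, 37, "+", 32, 32)
        up, down = extract_flanks(hit, subject)
        assert up == "N" * 18 + subject.sequence[0:5]
        assert down == subject.sequence[37:50] + "N" * 10


class TestArrayHit:
    def _hit_with_flanks(self, up, down):
        hit = Hit("sp", "s1", 0, 32, "+", 32, 32)
        hit.upstream_flank, hit.downstream_flank = up, down
        return hit

    def test_repeat_prefix_in_flank_flagged(self, rng):
        repeat = _rand(rng, 29)
        hit = self._hit_with_flanks(repeat[:23], _rand(rng, 23))
        assert is_array_hit(hit, repeat) is True

    def test_identity_boundary_14_vs_13(self):
        """Exactly 14 identical positions flags the hit; exactly 13 does not."""
        repeat = "A" * 23
        hit14 = self._hit_with_flanks("A" * 14 + "G" * 9, "G" * 23)
        hit13 = self._hit_with_flanks("A" * 13 + "G" * 10, "G" * 23)
        assert is_array_hit(hit14, repeat) is True
        assert is_array_hit(hit13, repeat) is False

    def test_reverse_complement_repeat_tested(self, rng):
        repeat = _rand(rng, 29)
        hit = self._hit_with_flanks(revcomp(repeat)[:23], _rand(rng, 23))
        assert is_array_hit(hit, repeat) is True

    def test_random_pairs_rarely_flagged(self):
        """Monte-Carlo null: unrelated repeat/flank pairs stay below threshold
        in >= 99% of 1000 simulated pairs."""
        rng = np.random.default_rng(5)
        false_flags = 0
        for _ in range(1000):
            hit = self._hit_with_flanks(_rand(rng, 23), "")
            if is_array_hit(hit, _rand(rng, 29)):
                false_flags += 1
        assert false_flags <= 10


class TestTwoStepFilter:
    def _records(self):
        return [
            SpacerRecord("a", "A" * 32, "G" * 29, "N1", genus="Escherichia"),
            SpacerRecord("b", "C" * 32, "G" * 29, "N2", genus="Escherichia"),
            SpacerRecord("c", "G" * 32, "G" * 29, "N3", genus="Moraxella"),
            SpacerRecord("short", "A" * 20, "G" * 29, "N4", genus="Escherichia"),
        ]

    def _hit(self, spacer_id, subject_id, n_ident, q_len=32, in_array=False):
        hit = Hit(spacer_id, subject_id, 0, q_len, "+", n_ident, q_len)
        hit.in_array = in_array
        return hit

    def test_step1_threshold(self):
        hits = [self._hit("a", "s1", 30)]  # 0.9375 > 0.90
        kept = apply_two_step_filter(hits, self._records())
        assert [h.kept_step for h in kept] == ["step1"]

    def test_step2_requires_same_genus_co_hit(self):
        hits = [
            self._hit("a", "s1", 32),      # step-1 anchor, Escherichia
            self._hit("b", "s1", 26),      # 0.8125, same genus, same subject
            self._hit("c", "s2", 26),      # 0.8125, no anchor on s2
        ]
        kept = apply_two_step_filter(hits, self._records())
        steps = {h.spacer_id: h.kept_step for h in kept}
        assert steps == {"a": "step1", "b": "step2"}

    def test_short_spacers_and_array_hits_removed(self):
        hits = [
            self._hit("short", "s1", 20, q_len=20),
            self._hit("a", "s2", 32, in_array=True),
        ]
        assert apply_two_step_filter(hits, self._records()) == []

    def test_step2_adds_no_new_subjects(self, default_universe, default_result):
        step1_subjects = {h.subject_id for h in default_result.kept_hits if h.kept_step == "step1"}
        all_subjects = {h.subject_id for h in default_result.kept_hits}
        assert all_subjects == step1_subjects

    def test_filter_monotonic_in_step1_threshold(self, default_universe, default_result):
        """The kept set at step1_frac=0.95 is a subset of the set at 0.90."""
        hits = [dataclasses.replace(h) for h in default_result.hits]
        strict = apply_two_step_filter(
            hits, default_universe.records, PipelineConfig(step1_frac=0.95, step2_frac=0.80)
        )
        loose_keys = {
            (h.spacer_id, h.subject_id, h.s_start, h.strand) for h in default_result.kept_hits
        }
        strict_keys = {(h.spacer_id, h.subject_id, h.s_start, h.strand) for h in strict}
        assert strict_keys <= loose_keys

    def test_strand_symmetry(self, rng):
        """Reverse-complementing a subject swaps hit strands and preserves flanks."""
        spacer = _rand(rng, 32)
        seq = _rand(rng, 150) + spacer + _rand(rng, 150)
        fwd = SubjectSequence("s1", seq)
        rev = SubjectSequence("s1", revcomp(seq))
        h1 = find_hits(spacer, fwd)[0]
        h2 = find_hits(spacer, rev)[0]
        assert {h1.strand, h2.strand} == {"+", "-"}
        assert extract_flanks(h1, fwd) == extract_flanks(h2, rev)
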