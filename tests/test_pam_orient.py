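"""Flank profiles, information content, orientation and PAM calling."""

import math

import numpy as np
import pytest

from spacerscope._seq import revcomp
from spacerscope.config_io import PipelineConfig
from spacerscope.match_filter import Hit
from spacerscope.pam_orient import (
    FlankProfile,
    build_profile,
    call_pam,
    compare_repeat_pam,
    consensus_flanks,
    detect_crRNA_handle_motif,
    gc_background,
    information_content,
    motif_to_iupac,
    predict_orientation,
    reorient_consensus_pairs,
)
from spacerscope.repeat_cluster import RepeatCluster
from spacerscope.synthetic_data import generate_flank_cluster


def _hit(up, down):
    h = Hit("sp", "s", 0, 32, "+", 32, 32)
    h.upstream_flank, h.downstream_flank = up, down
    return h


def _cluster(subtype="I-E", gc=0.5, repeat="ACGTTGCAACGTTGCAACGTTGCAACGTT"):
    c = RepeatCluster("rc0", repeat, subtype=subtype)
    c.mean_spacer_gc = gc
    return c


class TestConsensusFlanks:
    def test_majority_base(self):
        hits = [_hit(u + "A" * 20, "C" * 23) for u in ("AAG", "AAG", "AAC")]
        up, _ = consensus_flanks(hits)
        assert up.startswith("AAG")

    def test_tie_becomes_n(self):
        hits = [_hit("A" + "G" * 22, "C" * 23), _hit("C" + "G" * 22, "C" * 23)]
        up, _ = consensus_flanks(hits)
        assert up[0] == "N"

    def test_single_hit_identity(self):
        h = _hit("A" * 23, "T" * 23)
        assert consensus_flanks([h]) == ("A" * 23, "T" * 23)


class TestBuildProfile:
    def test_duplicate_pairs_collapse(self):
        cluster = _cluster()
        pairs = {"a": ("A" * 23, "C" * 23), "b": ("A" * 23, "C" * 23),
                 "c": ("G" * 23, "C" * 23)}
        up, down = build_profile(cluster, pairs)
        assert up.n_protospacers == 2
        assert cluster.n_unique_protospacers == 2
        assert up.counts.sum(axis=1).max() == 2  # one observation per protospacer

    def test_gc_background_formula(self):
        assert gc_background(0.7) == pytest.approx([0.15, 0.35, 0.35, 0.15])

    def test_position_sums(self):
        cluster = _cluster()
        pairs = generate_flank_cluster(np.random.default_rng(0), n_protospacers=10)
        up, down = build_profile(cluster, pairs)
        assert (up.counts.sum(axis=1) <= 10).all()


class TestInformationContent:
    def test_all_a_uniform_is_two_bits(self):
        profile = FlankProfile("rc", "upstream", np.array([[8, 0, 0, 0]]),
                               gc_background(0.5), 8)
        assert information_content(profile)[0] == pytest.approx(2.0, abs=1e-12)

    def test_background_matching_is_zero(self):
        profile = FlankProfile("rc", "upstream", np.array([[3, 7, 7, 3]]),
                               gc_background(0.7), 20)
        assert information_content(profile)[0] == pytest.approx(0.0, abs=1e-12)

    def test_all_g_at_gc_70(self):
        profile = FlankProfile("rc", "upstream", np.array([[0, 0, 10, 0]]),
                               gc_background(0.7), 10)
        assert information_content(profile)[0] == pytest.approx(
            math.log2(1 / 0.35), abs=1e-12
        )

    def test_matches_brute_force_sum(self, rng):
        """Closed form equals the explicit per-base relative-entropy sum."""
        counts = rng.integers(0, 30, size=(23, 4))
        profile = FlankProfile("rc", "upstream", counts, gc_background(0.6), 30)
        ic = information_content(profile)
        for i in range(23):
            total = counts[i].sum()
            expected = 0.0
            for j, p in enumerate(profile.background):
                if total and counts[i, j]:
                    f = counts[i, j] / total
                    expected += f * math.log2(f / p)
            assert ic[i] == pytest.approx(expected, abs=1e-12)


class TestOrientation:
    def _profiles(self, cluster, pairs):
        return build_profile(cluster, pairs)

    def test_planted_upstream_motif_forward(self):
        cluster = _cluster("I-E")
        pairs = generate_flank_cluster(np.random.default_rng(1), n_protospacers=50)
        call = predict_orientation(cluster, self._profiles(cluster, pairs))
        assert call.orientation == "forward"

    def test_reverse_cluster_detected_and_flip_restores(self):
        cluster = _cluster("I-E")
        pairs = generate_flank_cluster(np.random.default_rng(1), n_protospacers=50)
        flipped = reorient_consensus_pairs(pairs)
        call = predict_orientation(cluster, self._profiles(cluster, flipped))
        assert call.orientation == "reverse"
        # flipping back restores the forward profile exactly
        restored = reorient_consensus_pairs(flipped)
        up1, _ = self._profiles(cluster, pairs)
        up2, _ = self._profiles(cluster, restored)
        assert (up1.counts == up2.counts).all()

    def test_small_cluster_undetermined(self):
        cluster = _cluster("I-E")
        pairs = generate_flank_cluster(np.random.default_rng(2), n_protospacers=8)
        call = predict_orientation(cluster, self._profiles(cluster, pairs))
        assert call.orientation == "undetermined"

    def test_type_iii_uses_external(self):
        cluster = _cluster("III-B")
        pairs = generate_flank_cluster(np.random.default_rng(3), pam=None)
        call = predict_orientation(cluster, self._profiles(cluster, pairs),
                                   external_orientation="reverse")
        assert (call.orientation, call.source) == ("reverse", "external")


class TestPamCall:
    def test_planted_pam_recovered(self):
        cluster = _cluster("I-E")
        pairs = generate_flank_cluster(np.random.default_rng(4), n_protospacers=50)
        call = call_pam(cluster, build_profile(cluster, pairs))
        assert call is not None
        assert call.flagged_positions == frozenset({-3, -2, -1})
        assert call.motif == "AAG"

    def test_no_signal_no_call(self):
        cluster = _cluster("I-E")
        pairs = generate_flank_cluster(np.random.default_rng(5), pam=None, n_protospacers=50)
        assert call_pam(cluster, build_profile(cluster, pairs)) is None

    def test_single_position_no_call(self):
        """A lone conserved position does not reach the 2-nt minimum PAM size."""
        cluster = _cluster("I-E")
        pairs = generate_flank_cluster(
            np.random.default_rng(6), pam=("G", "upstream"), adherence=1.0,
            n_protospacers=50,
        )
        assert call_pam(cluster, build_profile(cluster, pairs)) is None

    def test_downstream_motif_coordinates(self):
        cluster = _cluster("II-A")
        pairs = generate_flank_cluster(
            np.random.default_rng(7), pam=("TGG", "downstream"), n_protospacers=50
        )
        call = call_pam(cluster, build_profile(cluster, pairs))
        assert call is not None
        assert call.side == "downstream"
        assert call.flagged_positions == frozenset({1, 2, 3})
        assert call.motif == "TGG"

    def test_reverse_complement_equivariance(self):
        """Flipping a stored cluster leaves the called motif invariant."""
        cluster = _cluster("I-E")
        pairs = generate_flank_cluster(np.random.default_rng(8), n_protospacers=40)
        forward_call = call_pam(cluster, build_profile(cluster, pairs))
        flipped = reorient_consensus_pairs(pairs)
        # orientation logic would flip the cluster back before calling
        restored = reorient_consensus_pairs(flipped)
        flipped_call = call_pam(cluster, build_profile(cluster, restored))
        assert forward_call.motif == flipped_call.motif


class TestIupac:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ({"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0}, "A"),
            ({"A": 0.50, "T": 0.45, "G": 0.05, "C": 0.0}, "W"),
            ({"A": 0.3, "C": 0.3, "G": 0.3, "T": 0.1}, "V"),
            ({"A": 0.85, "C": 0.05, "G": 0.05, "T": 0.05}, "A"),
        ],
    )
    def test_cumulative_rule(self, freqs, expected):
        assert motif_to_iupac(freqs) == expected


class TestRepeatPamComparison:
    def _call(self, motif, side="upstream"):
        from spacerscope.pam_orient import PamCall

        positions = (
            frozenset(range(-len(motif), 0)) if side == "upstream"
            else frozenset(range(1, len(motif) + 1))
        )
        return PamCall("rc0", side, positions, motif)

    def test_mismatch_pattern(self):
        cluster = _cluster(repeat="G" * 26 + "CAT")  # repeat -3 is C
        rows = compare_repeat_pam(cluster, self._call("AAT"))
        assert rows[0] == (-3, "C", "A", False)

    def test_pam_equal_to_repeat_end_matches_everywhere(self):
        cluster = _cluster(repeat="G" * 26 + "AAG")
        rows = compare_repeat_pam(cluster, self._call("AAG"))
        assert all(match for _, _, _, match in rows)

    def test_ie_style_g_match_at_minus_one(self):
        cluster = _cluster(repeat="C" * 26 + "TCG")  # ...G end, AAG PAM
        rows = compare_repeat_pam(cluster, self._call("AAG"))
        assert rows[-1] == (-1, "G", "G", True)
        assert not rows[0][3] and not rows[1][3]

    def test_downstream_uses_repeat_start(self):
        cluster = _cluster(repeat="TGG" + "C" * 26)
        rows = compare_repeat_pam(cluster, self._call("TGG", side="downstream"))
        assert [pos for pos, *_ in rows] == [1, 2, 3]
        assert all(match for *_, match in rows)


class TestRepeatPamAggregation:
    def test_per_position_match_frequency(self):
        from spacerscope.pam_orient import aggregate_repeat_pam

        comparisons = [
            [(-3, "C", "A", False), (-2, "A", "T", False), (-1, "G", "G", True)],
            [(-3, "T", "A", False), (-2, "C", "A", False), (-1, "C", "G", False)],
        ]
        freqs = aggregate_repeat_pam(comparisons)
        assert freqs == {-3: 0.0, -2: 0.0, -1: 0.5}


class TestHandleMotif:
    def test_exact_at_end(self):
        found, offset = detect_crRNA_handle_motif("G" * 21 + "ATTGAAAC")
        assert (found, offset) == (True, 0)

    def test_one_mismatch_allowed(self):
        found, _ = detect_crRNA_handle_motif("G" * 21 + "ATTGAAAT")
        assert found is True
        found_strict, _ = detect_crRNA_handle_motif("G" * 21 + "ATTGAAAT", max_mismatch=0)
        assert found_strict is False

    def test_absent_motif(self):
        found, offset = detect_crRNA_handle_motif("ACGT" * 7)
        assert (found, offset) == (False, None)

    def test_planted_repeats_carry_handle(self, default_universe):
        """Type I/III cluster repeats in the universe end with the handle."""
        for info in default_universe.truth.clusters.values():
            if info["subtype"].split("-")[0] in ("I", "III"):
                found, offset = detect_crRNA_handle_motif(info["repeat"])
                assert found and offset == 0
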