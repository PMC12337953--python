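"""PS-IDR sliding-window detection, cumulative length curves, recall AUC."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from idpome.llps import (
    DEFAULT_CONFIG,
    LLPSConfig,
    PSProfile,
    PSRegion,
    SequenceLengthError,
    analyze_protein,
    classify_windows,
    cumulative_ps_curve,
    find_ps_idrs,
    ps_score,
    recall_auc,
    window_features,
)

W = DEFAULT_CONFIG.window


class TestWindowFeatures:
    def test_hydrophobic_window(self):
        disorder, contact = window_features("I" * W)
        assert disorder < 0 and contact == 0.0

    def test_sticker_repeat_window(self):
        disorder, contact = window_features(("RG" * W)[:W])
        assert disorder > 0 and contact == 1.0

    def test_poly_alanine_has_no_stickers(self):
        _, contact = window_features("A" * W)
        assert contact == 0.0

    def test_wrong_window_length(self):
        with pytest.raises(ValueError):
            window_features("A" * (W - 1))


class TestClassifyWindows:
    def test_length_filter(self):
        with pytest.raises(SequenceLengthError):
            classify_windows("A" * 24)
        with pytest.raises(SequenceLengthError):
            classify_windows("A" * 10_001)

    def test_archetypal_label_patterns(self):
        assert set(classify_windows(("RG" * 60)[:100])) == {"P"}
        assert set(classify_windows("ILVA" * 25)) == {"F"}
        # charged but sticker-poor: disordered, not PS-prone
        assert set(classify_windows("EK" * 50)) == {"D"}


class TestFindPsIdrs:
    def test_single_window_expands_to_window_coverage(self):
        labels = np.array(["F"] * 76)
        labels[10] = "P"
        regions = find_ps_idrs(labels, 100)
        assert regions == [PSRegion(11, 35)]
        assert regions[0].length == W

    def test_short_coverage_dropped(self):
        cfg = LLPSConfig(window=5, min_region=20)
        labels = np.array(["F"] * 96)
        labels[10] = "P"  # covers 5 residues < min_region
        assert find_ps_idrs(labels, 100, cfg) == []

    def test_separated_runs_stay_separate(self):
        cfg = LLPSConfig(window=5, min_region=5)
        labels = np.array(["F"] * 96)
        labels[0:3] = "P"    # residues 1..7
        labels[50:53] = "P"  # residues 51..57
        regions = find_ps_idrs(labels, 100, cfg)
        assert [(r.start, r.end) for r in regions] == [(1, 7), (51, 57)]

    def test_label_count_must_match(self):
        with pytest.raises(ValueError):
            find_ps_idrs(np.array(["F"] * 10), 100)


class TestPsScore:
    def test_coverage_ratios(self):
        assert ps_score([], 200) == 0.0
        assert ps_score([PSRegion(1, 200)], 200) == 1.0
        assert ps_score([PSRegion(51, 100)], 200) == 0.25

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            ps_score([], 0)

    def test_raising_contact_threshold_never_raises_score(self):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("RGYSQPEKAILV"), size=300))
        scores = [
            analyze_protein("x", seq, LLPSConfig(contact_threshold=t)).ps_score
            for t in (0.2, 0.3, 0.4, 0.5, 0.6)
        ]
        assert all(a >= b for a, b in zip(scores, scores[1:]))


class TestCumulativeCurve:
    def _profiles(self, max_lengths):
        return [
            PSProfile(f"P{i}", (PSRegion(1, m),) if m else (), 500, m / 500)
            for i, m in enumerate(max_lengths)
        ]

    def test_worked_example_point(self):
        # 15 of 100 proteins with a PS-IDR of at least 50 residues -> (50, 15%)
        profiles = self._profiles([60] * 15 + [30] * 35 + [0] * 50)
        curve = cumulative_ps_curve(profiles, lengths=[0, 50])
        assert curve.loc[curve["length"] == 50, "percent"].item() == 15.0
        assert curve.loc[curve["length"] == 0, "percent"].item() == 100.0

    def test_no_regions_flatlines_at_zero(self):
        curve = cumulative_ps_curve(self._profiles([0] * 10), lengths=[20, 50, 100])
        assert (curve["percent"] == 0.0).all()

    @given(st.lists(st.integers(0, 400), min_size=1, max_size=50))
    def test_monotone_non_increasing_and_bounded(self, max_lengths):
        curve = cumulative_ps_curve(self._profiles(max_lengths))
        percent = curve["percent"].to_numpy()
        assert (np.diff(percent) <= 1e-12).all()
        assert percent.min() >= 0.0 and percent.max() <= 100.0
        assert percent[0] == 100.0


def brute_force_auc(test, ref):
    """Pairwise Mann-Whitney oracle: P(t > r) + 0.5 P(t = r)."""
    wins = sum((t > r) + 0.5 * (t == r) for t in test for r in ref)
    return wins / (len(test) * len(ref))


class TestRecallAuc:
    def test_perfect_separation(self):
        assert recall_auc([0.9, 0.8], [0.1, 0.2]) == pytest.approx(1.0)

    def test_tied_reference_hand_case(self):
        assert recall_auc([0.9, 0.1], [0.5, 0.5]) == pytest.approx(0.5)

    def test_identical_samples_are_null(self):
        assert recall_auc([0.3, 0.7, 0.5], [0.3, 0.7, 0.5]) == pytest.approx(0.5)

    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=12),
        st.lists(st.integers(0, 5), min_size=1, max_size=12),
    )
    def test_matches_pairwise_oracle(self, test, ref):
        t = [x / 5 for x in test]
        r = [x / 5 for x in ref]
        assert recall_auc(t, r) == pytest.approx(brute_force_auc(t, r), abs=1e-12)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            recall_auc([], [0.5])
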