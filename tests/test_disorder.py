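"""Per-residue disorder profiles: hydropathy/charge windows, the two
built-in predictors, and the consensus combiner."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from idpome.disorder import (
    DisorderProfile,
    consensus_profile,
    foldindex_profile,
    get_predictor,
    normalized_hydropathy,
    propensity_profile,
    table_predictor,
    window_net_charge,
)
from idpome.io import AMINO_ACIDS

sequences = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=120)


class TestHydropathyAndCharge:
    def test_normalized_scale_endpoints(self):
        np.testing.assert_allclose(normalized_hydropathy("I" * 30), 1.0)
        np.testing.assert_allclose(normalized_hydropathy("R" * 30), 0.0)

    def test_truncated_window_hand_mean(self):
        # "IR", window 3: both windows cover both residues -> mean of {1, 0}
        np.testing.assert_allclose(normalized_hydropathy("IR", 3), [0.5, 0.5])

    def test_charge_extremes_and_cancellation(self):
        np.testing.assert_allclose(window_net_charge("E" * 20), 1.0)
        np.testing.assert_allclose(window_net_charge("G" * 20), 0.0)
        np.testing.assert_allclose(window_net_charge("KE", 3), [0.0, 0.0])

    @pytest.mark.parametrize("window", [2, 1, 0, 4])
    def test_invalid_window_rejected(self, window):
        with pytest.raises(ValueError):
            normalized_hydropathy("MKVMKV", window)


class TestFoldindexProfile:
    def test_charged_homopolymer_saturates_disordered(self):
        # poly-K: <H> = 0.6/9, |<R>| = 1 -> FI ~ -1.965 -> clamped to 1
        np.testing.assert_allclose(foldindex_profile("K" * 40).scores, 1.0)

    def test_hydrophobic_homopolymer_saturates_ordered(self):
        # poly-I: FI = 2.785 - 1.151 = 1.634 -> clamped to 0
        np.testing.assert_allclose(foldindex_profile("I" * 40).scores, 0.0)

    def test_unclamped_hand_value(self):
        # poly-G: FI = 2.785 * (4.1/9) - 1.151 -> s = 0.5 - FI/2
        fi = 2.785 * ((-0.4 + 4.5) / 9) - 1.151
        np.testing.assert_allclose(
            foldindex_profile("G" * 30).scores, 0.5 - fi / 2, rtol=1e-12
        )


class TestPropensityProfile:
    def test_scale_endpoints(self):
        np.testing.assert_allclose(propensity_profile("P" * 30).scores, 1.0)
        np.testing.assert_allclose(propensity_profile("W" * 30).scores, 0.0)

    def test_two_residue_mean(self):
        prof = propensity_profile("PW", window=3)
        np.testing.assert_allclose(prof.scores, [0.5, 0.5])

    def test_unknown_residue_under_custom_scale(self):
        with pytest.raises(ValueError, match="not covered"):
            propensity_profile("MK", scale={"M": 0.1, "V": 0.9})


class TestConsensus:
    def _profile(self, scores, pid="P1"):
        return DisorderProfile(pid, np.asarray(scores, float), "x")

    def test_single_profile_identity(self):
        p = self._profile([0.1, 0.9])
        np.testing.assert_array_equal(consensus_profile([p]).scores, p.scores)

    def test_equal_weight_midpoint_and_hand_weighted_mean(self):
        lo, hi = self._profile([0.0, 0.0]), self._profile([1.0, 1.0])
        np.testing.assert_allclose(consensus_profile([lo, hi]).scores, 0.5)
        a, b = self._profile([0.2, 0.8]), self._profile([0.6, 0.4])
        np.testing.assert_allclose(
            consensus_profile([a, b], weights=(1, 3)).scores, [0.5, 0.5]
        )

    def test_permutation_invariance(self):
        ps = [self._profile([0.1, 0.5]), self._profile([0.9, 0.3]), self._profile([0.4, 0.4])]
        fwd = consensus_profile(ps, weights=(1, 2, 3)).scores
        rev = consensus_profile(ps[::-1], weights=(3, 2, 1)).scores
        np.testing.assert_allclose(fwd, rev)

    def test_length_mismatch_and_bad_weights(self):
        with pytest.raises(ValueError, match="length"):
            consensus_profile([self._profile([0.1]), self._profile([0.1, 0.2])])
        with pytest.raises(ValueError, match="weights"):
            consensus_profile([self._profile([0.1])], weights=[0.0])


class TestProfileInvariants:
    @given(sequences, st.sampled_from([3, 5, 9, 21]))
    def test_profiles_bounded_for_random_sequences(self, seq, window):
        for predict in (foldindex_profile, propensity_profile):
            scores = predict(seq, window=window).scores
            assert len(scores) == len(seq)
            assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_predictors_agree_on_archetype_rank_direction(self):
        charged = "PESKQGDE" * 8   # charged, low hydropathy
        hydrophobic = "MKVLIVFA" * 8
        for name in ("foldindex", "topidp"):
            predict = get_predictor(name)
            assert predict(charged).scores.mean() > predict(hydrophobic).scores.mean()


class TestTablePredictor:
    def test_lookup_and_length_check(self):
        predict = table_predictor({"P1": np.array([0.9, 0.1, 0.5])}, "ext")
        prof = predict("MKV", "P1")
        assert prof.predictor == "ext"
        np.testing.assert_allclose(prof.scores, [0.9, 0.1, 0.5])
        with pytest.raises(ValueError, match="3 scores"):
            predict("MKVA", "P1")
        with pytest.raises(KeyError):
            predict("MKV", "P2")
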