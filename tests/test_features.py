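"""DTW, fixed-weight LSTM embeddings, statistical descriptors, 36-D assembly."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from copreserve import (
    CHANNELS,
    DtwParams,
    LstmSpec,
    dtw_distance,
    extract_features,
    feature_names,
    lstm_embedding,
    statistical_features,
)
from copreserve.features import feature_type, lstm_weights
from copreserve.preprocess import PreprocessedTrial
from copreserve.template import HealthyTemplate

from .oracles import dtw_brute_force, dtw_full, lstm_reference, path_within_band

series_strategy = st.lists(
    st.floats(-10, 10, allow_nan=False, allow_infinity=False), min_size=3, max_size=25
).map(lambda v: np.asarray(v))


class TestDtw:
    @pytest.mark.parametrize("gamma", [0.5, 1.0, 1.5, 2.0])
    def test_zero_self_distance(self, rng, gamma):
        s = rng.normal(size=30)
        assert dtw_distance(s, s, DtwParams(gamma=gamma)) == 0.0

    def test_constant_offset_attained_on_diagonal(self):
        d = dtw_distance(np.ones(4), np.zeros(4), DtwParams(gamma=1.0))
        assert d == pytest.approx(4.0)

    def test_toy_alignment_warps_to_zero(self):
        # [0,1,0] vs [0,0,1,0] aligns perfectly once the single 1s match
        s1, s2 = np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0, 0.0])
        d = dtw_distance(s1, s2, DtwParams(gamma=1.0, band_fraction=1.0))
        assert d == pytest.approx(0.0)
        assert dtw_brute_force(s1, s2, 1.0) == pytest.approx(0.0)

    def test_unbanded_matches_brute_force_enumeration(self, rng):
        for _ in range(10):
            s1 = rng.normal(size=rng.integers(2, 6))
            s2 = rng.normal(size=rng.integers(2, 6))
            d = dtw_distance(s1, s2, DtwParams(gamma=1.0, band_fraction=1.0))
            assert d == pytest.approx(dtw_brute_force(s1, s2, 1.0), abs=1e-10)

    @given(series_strategy, series_strategy, st.sampled_from([0.5, 1.0, 1.5, 2.0]))
    def test_unbanded_matches_textbook_dp(self, s1, s2, gamma):
        d = dtw_distance(s1, s2, DtwParams(gamma=gamma, band_fraction=1.0))
        expected, _ = dtw_full(s1, s2, gamma)
        assert d == pytest.approx(expected, abs=1e-10)

    def test_banded_equals_oracle_when_optimal_path_in_band(self, rng):
        params = DtwParams(gamma=1.5, band_fraction=0.1)
        checked = 0
        for _ in range(100):
            n = int(rng.integers(20, 40))
            s1, s2 = rng.normal(size=n), rng.normal(size=n)
            expected, path = dtw_full(s1, s2, 1.5)
            if path_within_band(path, n, n, params.band_halfwidth(n, n)):
                assert dtw_distance(s1, s2, params) == pytest.approx(expected, abs=1e-10)
                checked += 1
        assert checked > 0

    def test_symmetric_for_equal_lengths(self, rng):
        s1, s2 = rng.normal(size=25), rng.normal(size=25)
        p = DtwParams(gamma=1.5)
        assert dtw_distance(s1, s2, p) == pytest.approx(dtw_distance(s2, s1, p))

    def test_non_negative(self, rng):
        assert dtw_distance(rng.normal(size=10), rng.normal(size=10)) >= 0.0

    def test_infeasible_band_raises_with_geometry(self):
        with pytest.raises(ValueError, match="band"):
            dtw_distance(np.zeros(5), np.zeros(50), DtwParams(band_fraction=0.1))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance(np.array([]), np.array([1.0]))

    def test_band_halfwidth_rule(self):
        p = DtwParams(band_fraction=0.1)
        assert p.band_halfwidth(2000, 2000) == 200  # 10% of full-length trials
        assert p.band_halfwidth(5, 5) == 1          # floor of 1 keeps toys feasible

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DtwParams(gamma=0.0)
        with pytest.raises(ValueError):
            DtwParams(band_fraction=0.0)


class TestLstm:
    def test_zero_input_is_a_fixed_point(self):
        np.testing.assert_array_equal(lstm_embedding(np.zeros(50)), np.zeros(2))

    def test_deterministic_across_calls(self, rng):
        x = rng.normal(size=200)
        np.testing.assert_array_equal(lstm_embedding(x), lstm_embedding(x))

    def test_weights_are_seeded_and_shared(self):
        wx1, wh1 = lstm_weights(LstmSpec(units=2, seed=42))
        wx2, wh2 = lstm_weights(LstmSpec(units=2, seed=42))
        np.testing.assert_array_equal(wx1, wx2)
        assert wx1.shape == (4, 2) and wh1.shape == (4, 2, 2)
        assert np.all(np.abs(wx1) <= 0.5) and np.all(np.abs(wh1) <= 0.5)

    def test_single_step_matches_manual_gate_equations(self):
        """One timestep with a hand-specified 2-unit weight set."""
        wx = np.array([[0.1, -0.2], [0.3, 0.4], [-0.5, 0.2], [0.25, -0.15]])
        wh = np.zeros((4, 2, 2))
        x = np.array([1.0])

        def sig(z):
            return 1.0 / (1.0 + math.exp(-z))

        # manual: h_0 = c_0 = 0 so recurrent terms vanish
        expected = []
        for u in range(2):
            i = sig(wx[0, u])
            f = sig(wx[1, u])
            g = math.tanh(wx[2, u])
            o = sig(wx[3, u])
            c = f * 0.0 + i * g
            expected.append(o * math.tanh(c))
        from copreserve._kernels import lstm_forward

        np.testing.assert_allclose(lstm_forward(x, wx, wh), expected, atol=1e-14)

    def test_matches_independent_reference_cell(self, rng):
        x = rng.normal(size=300)
        spec = LstmSpec(units=2, seed=42)
        wx, wh = lstm_weights(spec)
        np.testing.assert_allclose(lstm_embedding(x, spec), lstm_reference(x, wx, wh), atol=1e-12)

    @given(series_strategy)
    def test_embedding_bounded_by_unit_interval(self, x):
        emb = lstm_embedding(x)
        assert np.all(np.abs(emb) < 1.0)  # h = o * tanh(c)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            lstm_embedding(np.array([]))


class TestStatisticalFeatures:
    def test_constant_series(self):
        assert statistical_features(np.full(4, 5.0)) == (0.0, 0.0, 0.0)

    def test_hand_example_one_to_five(self):
        cv, slope, iqr = statistical_features(np.arange(1.0, 6.0))
        assert slope == pytest.approx(1.0)
        assert iqr == pytest.approx(2.0)
        assert cv == pytest.approx(np.sqrt(2.0) / 3.0)  # population sigma sqrt(2), mu 3

    def test_slope_linearity(self):
        t = np.arange(1.0, 51.0)
        assert statistical_features(2.0 * t)[1] == pytest.approx(2.0)

    def test_near_zero_mean_is_regularized(self):
        cv, _, _ = statistical_features(np.array([-1.0, 1.0, -1.0, 1.0]))
        assert np.isfinite(cv) and cv > 0


class TestExtractFeatures:
    def _trial_and_template(self, rng, T=60):
        standardized = {ch: rng.normal(size=T) for ch in CHANNELS}
        trial = PreprocessedTrial(
            subject_id="A", posture="ST", trial_index=1, sampling_rate_hz=100.0,
            translated={ch: v * 2.0 + 1.0 for ch, v in standardized.items()},
            standardized=standardized,
        )
        template = HealthyTemplate(
            posture="ST", curves={ch: rng.normal(size=T) for ch in CHANNELS}, n_controls=5
        )
        return trial, template

    def test_exactly_36_named_features(self, rng):
        trial, template = self._trial_and_template(rng)
        fv = extract_features(trial, template)
        assert list(fv.values) == feature_names()
        assert len(fv.values) == 36
        kinds = [feature_type(n) for n in fv.values]
        assert kinds.count("DTW") == 6
        assert kinds.count("LSTM") == 12
        assert kinds.count("Statistical") == 18

    def test_template_match_zeroes_all_dtw_entries(self, rng):
        trial, template = self._trial_and_template(rng)
        template = HealthyTemplate(posture="ST", curves=dict(trial.standardized), n_controls=1)
        fv = extract_features(trial, template)
        for ch in CHANNELS:
            assert fv.values[f"DTW-{ch}"] == 0.0

    def test_posture_mismatch_rejected(self, rng):
        trial, template = self._trial_and_template(rng)
        template.posture = "FT"
        with pytest.raises(ValueError, match="posture"):
            extract_features(trial, template)

    def test_dtw_entries_non_negative_and_iqr_non_negative(self, rng):
        trial, template = self._trial_and_template(rng)
        fv = extract_features(trial, template)
        for ch in CHANNELS:
            assert fv.values[f"DTW-{ch}"] >= 0.0
            assert fv.values[f"iqr_{ch}"] >= 0.0
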