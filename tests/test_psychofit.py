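"""Psychometric mixture model: prediction, likelihood, fitting, validity.

Threshold algebra under the high-threshold correction (p-g)/(1-g):
the corrected curve equals S whenever the lapse rate is zero, so the
corrected 0.5 crossing sits exactly at m for any false-alarm rate; a
positive lapse rate shifts it above m (corrected-0.5 is equivalent to
S = 0.5 (1-g)/(1-d-g), which exceeds 0.5 iff d > 0).
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vibropsych.psychofit import (
    BinomialData,
    PsychometricModel,
    PsychometricParams,
    false_alarm_correct,
    fit_ml,
    neg_log_likelihood,
    predict,
    threshold,
)

from conftest import simulate_binomial


class TestPredict:
    def test_half_at_threshold_and_095_at_half_width(self):
        p = PsychometricParams(m=3.0, w=2.0)
        assert predict(p, 3.0) == pytest.approx(0.5)
        assert predict(p, 4.0) == pytest.approx(0.95)
        assert predict(p, 2.0) == pytest.approx(0.05)

    def test_asymptotes(self):
        p = PsychometricParams(m=0.0, w=1.0, gamma=0.1, delta=0.05)
        assert predict(p, -1e9) == pytest.approx(0.1)
        assert predict(p, 1e9) == pytest.approx(0.95)

    @pytest.mark.parametrize("sigmoid", ["cumulative_gaussian", "logistic"])
    def test_width_definition_holds_for_both_sigmoids(self, sigmoid):
        p = PsychometricParams(m=0.0, w=4.0, sigmoid=sigmoid)
        assert predict(p, -2.0) == pytest.approx(0.05)
        assert predict(p, 2.0) == pytest.approx(0.95)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        m=st.floats(-5, 5),
        w=st.floats(0.5, 10),
        g=st.floats(0, 0.4),
        d=st.floats(0, 0.4),
    )
    def test_monotone_and_bounded(self, m, w, g, d):
        p = PsychometricParams(m, w, g, d)
        xs = np.linspace(m - 3 * w, m + 3 * w, 50)
        ys = np.asarray(predict(p, xs))
        assert np.all(np.diff(ys) >= 0)
        assert np.all((ys >= g - 1e-12) & (ys <= 1 - d + 1e-12))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PsychometricParams(0.0, -1.0)
        with pytest.raises(ValueError):
            PsychometricParams(0.0, 1.0, gamma=0.6)


class TestLikelihood:
    def test_closed_form_at_half(self):
        data = BinomialData([0.0, 1.0, 2.0, 3.0], [10, 10, 10, 10], [5, 5, 5, 5])
        p = PsychometricParams(m=-100.0, w=1.0, gamma=0.0, delta=0.5 - 1e-12)
        # every level predicts ~0.5 -> NLL = total_n * ln 2
        assert neg_log_likelihood(p, data) == pytest.approx(40 * np.log(2), rel=1e-6)

    def test_matches_per_trial_bernoulli_oracle(self):
        rng = np.random.default_rng(42)
        levels = np.arange(175.0, 245.0, 5.0)
        data = BinomialData(levels, np.full(14, 30), rng.integers(0, 31, 14))
        params = PsychometricParams(200.0, 30.0, 0.05, 0.03)
        # naive per-trial summation oracle
        total = 0.0
        for lv, n, k in zip(data.levels, data.n_trials, data.k_yes):
            p = np.clip(predict(params, lv), 1e-9, 1 - 1e-9)
            total -= k * np.log(p) + (n - k) * np.log(1 - p)
        assert neg_log_likelihood(params, data) == pytest.approx(total, abs=1e-10)

    def test_saturated_data_stays_finite_via_clamping(self):
        data = BinomialData([0.0, 1.0, 2.0, 3.0], [5, 5, 5, 5], [0, 0, 5, 5])
        p = PsychometricParams(m=1.5, w=1e-6)
        assert np.isfinite(neg_log_likelihood(p, data))

    def test_invalid_binomial_data_rejected(self):
        with pytest.raises(ValueError):
            BinomialData([1.0, 1.0], [5, 5], [1, 1])  # not strictly increasing
        with pytest.raises(ValueError):
            BinomialData([1.0, 2.0], [5, 5], [6, 1])  # k > n


class TestFalseAlarmCorrection:
    def test_identity_at_zero_gamma(self):
        assert false_alarm_correct(0.37, 0.0) == 0.37

    def test_gamma_maps_to_zero(self):
        assert false_alarm_correct(0.2, 0.2) == 0.0

    def test_corrected_half_attained_at_raw_half_plus_half_gamma(self):
        g = 0.24
        raw = g + 0.5 * (1 - g)
        assert false_alarm_correct(raw, g) == pytest.approx(0.5)

    def test_gamma_at_or_above_one_rejected(self):
        with pytest.raises(ValueError):
            false_alarm_correct(0.5, 1.0)


class TestThresholdExtraction:
    def _fit_from_truth(self, truth, shape_levels, seed=0, n=300):
        rng = np.random.default_rng(seed)
        data = simulate_binomial(truth, shape_levels, n, rng)
        return fit_ml(data, seed=seed)

    def test_threshold_equals_m_without_asymptotes(self):
        p = PsychometricParams(200.0, 30.0)
        res = fit_ml(
            BinomialData(
                np.arange(175.0, 245.0, 5.0),
                np.full(14, 1000),
                np.round(1000 * np.asarray(predict(p, np.arange(175.0, 245.0, 5.0)))).astype(int),
            ),
            seed=0,
        )
        assert res.valid
        assert res.threshold_corrected == pytest.approx(200.0, abs=0.5)

    def test_threshold_equals_m_for_any_gamma_when_no_lapse(self):
        # correction cancels gamma exactly: corrected curve is S itself
        from vibropsych.psychofit import _corrected_threshold

        for g in (0.0, 0.1, 0.3):
            p = PsychometricParams(200.0, 30.0, gamma=g, delta=0.0)
            thr = _corrected_threshold(p, (175.0, 240.0))
            assert thr == pytest.approx(200.0, abs=1e-6)

    def test_positive_lapse_shifts_threshold_above_m(self):
        from vibropsych.psychofit import _corrected_threshold

        p = PsychometricParams(200.0, 30.0, gamma=0.08, delta=0.08)
        thr = _corrected_threshold(p, (175.0, 240.0))
        assert thr > 200.0
        # brentq root agrees with the closed-form sigmoid inversion
        corrected = false_alarm_correct(float(predict(p, thr)), p.gamma)
        assert corrected == pytest.approx(0.5, abs=1e-9)

    def test_threshold_raises_outside_range(self):
        res = fit_ml(
            BinomialData([0.0, 1.0, 2.0, 3.0], [50] * 4, [25, 35, 45, 49]), seed=0
        )
        with pytest.raises(ValueError, match="range"):
            threshold(res, level_range=(10.0, 20.0))


class TestFitting:
    def test_recovers_ground_truth(self, shape_levels):
        rng = np.random.default_rng(7)
        truth = PsychometricParams(205.0, 40.0, 0.1, 0.02)
        errs = []
        for rep in range(20):
            data = simulate_binomial(truth, shape_levels, 30, rng)
            res = fit_ml(data, seed=rep)
            assert res.params is not None
            errs.append(abs(res.params.m - truth.m))
        assert np.median(errs) < truth.w / 4

    def test_all_no_responses_flagged_did_not_reach_half(self, shape_levels):
        data = BinomialData(shape_levels, np.full(14, 30), np.zeros(14, int))
        res = fit_ml(data, seed=1)
        assert not res.valid
        assert res.invalid_reason == "did_not_reach_half"
        assert res.threshold_corrected is None

    def test_threshold_beyond_range_flagged_on_limit(self, shape_levels):
        # raw curve crosses 0.5 inside the range but the corrected
        # crossing (= m, since lapse is zero) lies beyond the last level
        truth = PsychometricParams(241.0, 40.0, gamma=0.1, delta=0.0)
        k = np.round(300 * np.asarray(predict(truth, shape_levels))).astype(int)
        res = fit_ml(BinomialData(shape_levels, np.full(14, 300), k), seed=3)
        assert not res.valid
        assert res.invalid_reason == "threshold_on_limit"

    def test_deterministic_given_seed(self, shape_levels):
        rng = np.random.default_rng(0)
        data = simulate_binomial(PsychometricParams(205.0, 40.0, 0.05, 0.02), shape_levels, 30, rng)
        a = fit_ml(data, seed=11)
        b = fit_ml(data, seed=11)
        assert a.params == b.params and a.neg_log_lik == b.neg_log_lik

    def test_affine_invariance_of_fit(self, shape_levels):
        rng = np.random.default_rng(5)
        truth = PsychometricParams(205.0, 40.0, 0.05, 0.02)
        data = simulate_binomial(truth, shape_levels, 100, rng)
        a, b = 0.1, -17.0
        scaled = BinomialData(a * data.levels + b, data.n_trials, data.k_yes)
        r1 = fit_ml(data, seed=2)
        r2 = fit_ml(scaled, seed=2)
        assert r2.params.m == pytest.approx(a * r1.params.m + b, abs=0.05 * a * r1.params.w)
        assert r2.params.w == pytest.approx(a * r1.params.w, rel=0.05)

    def test_bias_and_rmse_shrink_with_more_trials(self, shape_levels):
        truth = PsychometricParams(205.0, 40.0, 0.05, 0.02)
        rmse = {}
        for n in (30, 300):
            rng = np.random.default_rng(123)
            errs = [
                fit_ml(simulate_binomial(truth, shape_levels, n, rng), seed=r).params.m - truth.m
                for r in range(15)
            ]
            rmse[n] = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse[300] < rmse[30]

    def test_ml_beats_coarse_grid_search_oracle(self, shape_levels):
        rng = np.random.default_rng(9)
        truth = PsychometricParams(205.0, 40.0, 0.05, 0.02)
        data = simulate_binomial(truth, shape_levels, 30, rng)
        res = fit_ml(data, seed=0)
        grid_best = min(
            neg_log_likelihood(PsychometricParams(m, w, g, d), data)
            for m, w, g, d in itertools.product(
                np.linspace(180, 235, 12),
                np.linspace(10, 120, 10),
                np.linspace(0, 0.1, 4),
                np.linspace(0, 0.1, 4),
            )
        )
        assert res.neg_log_lik <= grid_best + 1e-9

    def test_fixed_gamma_mode_uses_supplied_rate(self, shape_levels):
        rng = np.random.default_rng(4)
        truth = PsychometricParams(205.0, 40.0, 0.06, 0.02)
        data = simulate_binomial(truth, shape_levels, 100, rng)
        res = fit_ml(data, fix_gamma=0.06, seed=0)
        assert res.params.gamma == 0.06
        assert res.params.m == pytest.approx(truth.m, abs=truth.w / 4)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="4 levels"):
            PsychometricModel(BinomialData([0.0, 1.0, 2.0], [5] * 3, [1, 2, 3]))

    def test_summary_reports_fit(self, shape_levels):
        rng = np.random.default_rng(2)
        data = simulate_binomial(PsychometricParams(205.0, 40.0, 0.05, 0.02), shape_levels, 30, rng)
        res = fit_ml(data, seed=0)
        text = res.summary()
        assert "threshold m" in text and "width w" in text
        assert ("valid             True" in text) or ("valid             False" in text)

    def test_bootstrap_ci_covers_point_estimate(self, shape_levels):
        rng = np.random.default_rng(8)
        data = simulate_binomial(PsychometricParams(205.0, 40.0, 0.05, 0.02), shape_levels, 30, rng)
        res = fit_ml(data, seed=0)
        ci = res.bootstrap_ci(n_boot=30, seed=1)
        lo, hi = ci["m"]
        assert lo <= res.params.m <= hi
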