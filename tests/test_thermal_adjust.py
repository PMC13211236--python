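import numpy as np
import pytest
from sklearn.base import clone

from tasd.preprocessing import preprocess_record
from tasd.synthetic_data import SynthConfig, simulate_subject
from tasd.thermal_adjust import (
    AdaptiveScaler,
    AdjustmentParams,
    ProportionalAdjuster,
    adjust_session,
    apply_adaptive_scaling,
    apply_proportional_adjustment,
    estimate_lambda_prop,
    estimate_t_base,
)


class TestLambdaEstimate:
    def test_constant_temperature_gives_zero(self):
        lam = estimate_lambda_prop(np.array([1.0, 2.0, 3.0]), np.full(3, 34.0), 1e-4)
        assert lam == 0.0

    def test_perfect_linear_coupling(self):
        # eda = 2 * T with Var(T) = 1 under the (n-1) convention
        temp = np.array([33.0, 34.0, 35.0, 34.0, 33.0, 35.0, 34.0])
        temp = (temp - temp.mean()) / temp.std(ddof=1) + 34.0
        eda = 2.0 * temp
        lam = estimate_lambda_prop(eda, temp, 1e-4)
        assert lam == pytest.approx(2.0 / (1 + 1e-4), rel=1e-12)

    def test_orthogonal_series_give_zero(self):
        lam = estimate_lambda_prop(np.array([1.0, -1, 1, -1]), np.array([1.0, 1, -1, -1]), 1e-4)
        assert lam == pytest.approx(0.0, abs=1e-15)

    def test_matches_bruteforce_sample_moments(self):
        rng = np.random.default_rng(5)
        eda, temp = rng.normal(3, 1, 200), rng.normal(34, 0.4, 200)
        n = len(eda)
        cov = np.sum((eda - eda.mean()) * (temp - temp.mean())) / (n - 1)
        var = np.sum((temp - temp.mean()) ** 2) / (n - 1)
        assert estimate_lambda_prop(eda, temp, 1e-4) == pytest.approx(cov / (var + 1e-4))

    def test_shrinkage_monotone_in_epsilon(self):
        rng = np.random.default_rng(6)
        temp = rng.normal(34, 0.5, 500)
        eda = 0.8 * temp + rng.normal(0, 0.1, 500)  # positive covariance
        lams = [estimate_lambda_prop(eda, temp, eps) for eps in (0.0, 1e-4, 1e-2, 1.0)]
        assert all(a >= b for a, b in zip(lams, lams[1:]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            estimate_lambda_prop(np.ones(3), np.ones(4))


class TestProportionalAdjustment:
    def test_identity_at_zero_lambda(self):
        eda = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(apply_proportional_adjustment(eda, eda + 30, 0.0), eda)

    def test_direct_evaluation(self):
        out = apply_proportional_adjustment(np.array([5.0, 6, 7]), np.array([34.0, 35, 36]), 1.0)
        np.testing.assert_allclose(out, [-29.0, -29.0, -29.0])

    def test_residual_orthogonality_with_zero_epsilon(self):
        rng = np.random.default_rng(7)
        temp = rng.normal(34, 0.5, 1000)
        eda = 0.5 * temp + rng.normal(0, 0.2, 1000)
        lam = estimate_lambda_prop(eda, temp, 0.0)
        res = apply_proportional_adjustment(eda, temp, lam)
        assert abs(np.cov(res, temp, ddof=1)[0, 1]) < 1e-10

    def test_decorrelation_over_many_random_sessions(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(50, 500))
            temp = rng.normal(34, rng.uniform(0.1, 1.0), n)
            eda = rng.uniform(-1, 1) * temp + rng.normal(0, rng.uniform(0.05, 0.5), n)
            lam = estimate_lambda_prop(eda, temp, 0.0)
            res = apply_proportional_adjustment(eda, temp, lam)
            assert abs(np.corrcoef(res, temp)[0, 1]) < 1e-8


class TestTBase:
    def test_constant_any_strategy(self):
        temp = np.full(100, 34.0)
        for strategy in ("pre_task", "session_mean"):
            assert estimate_t_base(temp, strategy) == 34.0
        assert estimate_t_base(temp, "fixed", fixed_value=34.0) == 34.0

    def test_pre_task_mean_of_leading_fraction(self):
        temp = np.linspace(30, 40, 100)
        assert estimate_t_base(temp, "pre_task", 0.2) == pytest.approx(temp[:20].mean())

    def test_degenerate_fraction(self):
        with pytest.raises(ValueError):
            estimate_t_base(np.ones(10) * 34, "pre_task", 0.0)


class TestAdaptiveScaling:
    def test_identity_at_alpha_zero(self):
        eda = np.array([1.0, 2.0, 3.0])
        temp = np.array([34.0, 35.0, 36.0])
        out, trace = apply_adaptive_scaling(eda, temp, AdjustmentParams(alpha=0.0, t_base=34.0))
        np.testing.assert_array_equal(out, eda)
        np.testing.assert_array_equal(trace, 0.0)

    def test_identity_at_baseline_temperature(self):
        eda = np.array([1.0, 2.0, 3.0])
        temp = np.full(3, 34.0)
        out, _ = apply_adaptive_scaling(eda, temp, AdjustmentParams(alpha=5.0, t_base=34.0))
        np.testing.assert_allclose(out, eda)

    def test_direct_evaluation(self):
        out, _ = apply_adaptive_scaling(np.array([1.2]), np.array([36.0]),
                                        AdjustmentParams(alpha=0.1, t_base=34.0))
        assert out[0] == pytest.approx(1.0)

    def test_denominator_clamped_with_warning(self):
        params = AdjustmentParams(alpha=1.0, t_base=34.0, denom_floor=0.2)
        with pytest.warns(RuntimeWarning, match="clamped"):
            out, _ = apply_adaptive_scaling(np.array([1.0]), np.array([32.0]), params)
        assert out[0] == pytest.approx(1.0 / 0.2)

    def test_adaptation_does_not_increase_thermal_correlation(self):
        # nonlinear (multiplicative) coupling: adaptation should reduce, or at
        # worst preserve, the corr between scaled output and temp deviation
        rng = np.random.default_rng(0)
        n = 8000
        t = np.arange(n) / 4.0
        temp = 34 + 1.5 * np.sin(2 * np.pi * t / 600) + 0.3 * t / t[-1]
        t_base = float(temp[: n // 5].mean())
        base = 1.0 + 0.2 * rng.standard_normal(n).cumsum() / np.sqrt(n)
        eda = base * (1 + 0.3 * (temp - t_base))
        params = AdjustmentParams(t_base=t_base)
        ref, _ = apply_adaptive_scaling(eda, temp, params, mode="fixed_alpha")
        out, trace = apply_adaptive_scaling(eda, temp, params, mode="adaptive", window=120)
        c_ref = abs(np.corrcoef(ref, temp - t_base)[0, 1])
        c_out = abs(np.corrcoef(out, temp - t_base)[0, 1])
        assert c_out <= c_ref + 1e-9
        assert trace[-1] > 0  # alpha moved toward the injected sensitivity


class TestAdjustSession:
    def test_linear_confound_removed(self, one_subject):
        rec, _ = one_subject
        lam_true = 0.7
        synthetic = rec.copy(eda=np.clip(2.0 + lam_true * rec.temp_smooth, 0, None))
        adj = adjust_session(synthetic, AdjustmentParams(), mode="pa")
        assert np.var(adj.eda_pa) < 1e-4 * np.var(synthetic.eda)

    def test_lambda_recovery_across_seeds(self):
        hits = 0
        for seed in range(20):
            cfg = SynthConfig(seed=seed, schedule=((1, 2500.0),), scr_rates={1: 2.0})
            rec, truth = simulate_subject(cfg, 0)
            assert rec.n_samples == 10000
            adj = adjust_session(preprocess_record(rec), mode="tasd")
            if abs(adj.params.lambda_prop - truth.lambda_true) <= 0.05:
                hits += 1
        assert hits >= 18

    def test_mode_switches_select_signal(self, one_subject):
        rec, _ = one_subject
        params = AdjustmentParams()
        raw = adjust_session(rec, params, mode="raw")
        pa = adjust_session(rec, params, mode="pa")
        tasd = adjust_session(rec, params, mode="tasd")
        np.testing.assert_array_equal(raw.eda_adj, rec.eda)
        np.testing.assert_array_equal(pa.eda_adj, pa.eda_pa)
        np.testing.assert_array_equal(tasd.eda_adj, tasd.eda_as)

    def test_per_session_lambda_differs_with_coupling(self):
        recs = []
        for lam_true, seed in ((0.2, 11), (0.9, 12)):
            cfg = SynthConfig(seed=seed, lambda_true=lam_true,
                              schedule=((1, 600.0),), scr_rates={1: 1.0})
            rec, _ = simulate_subject(cfg, 0)
            recs.append(adjust_session(preprocess_record(rec)))
        assert recs[0].params.lambda_prop == pytest.approx(0.2, abs=0.05)
        assert recs[1].params.lambda_prop == pytest.approx(0.9, abs=0.05)

    def test_requires_preprocessing(self, small_cohort):
        rec = small_cohort[0][0]
        with pytest.raises(ValueError, match="temp_smooth"):
            adjust_session(rec)


class TestSklearnEstimators:
    def test_proportional_adjuster_round_trip(self):
        rng = np.random.default_rng(13)
        temp = rng.normal(34, 0.5, 300)
        eda = 0.5 * temp + rng.normal(0, 0.05, 300)
        X = np.column_stack([eda, temp])
        est = ProportionalAdjuster(epsilon=0.0).fit(X)
        assert est.lambda_prop_ == pytest.approx(0.5, abs=0.05)
        resid = est.transform(X).ravel()
        assert abs(np.corrcoef(resid, temp)[0, 1]) < 1e-8
        # sklearn contract: cloneable with identical params
        assert clone(est).get_params() == est.get_params()

    def test_adaptive_scaler_contract(self):
        rng = np.random.default_rng(14)
        temp = 34 + rng.normal(0, 0.3, 400)
        eda = rng.uniform(1, 2, 400)
        X = np.column_stack([eda, temp])
        est = AdaptiveScaler(adaptive=False, alpha=0.0).fit(X)
        np.testing.assert_allclose(est.transform(X).ravel(), eda)
        assert clone(est).get_params() == est.get_params()
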