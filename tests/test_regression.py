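"""Replicate splits, metrics, stage VI models, PLSR and GPR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ricespec import ExperimentDesign, generate_experiment
from ricespec.regression import (
    GPNitrogenRegressor,
    PLSNitrogenRegressor,
    StageVIRegressor,
    evaluate,
    fit_stage_vi_model,
    spearman_rho2,
    split_by_replicate,
)


@pytest.fixture(scope="module")
def sample_table():
    """Metadata-only sample table of the full two-year design (432 rows)."""
    recs = list(generate_experiment(ExperimentDesign(), seed=0, render=False))
    return pd.DataFrame([{k: v for k, v in r.items() if k not in ("cube", "class_map")}
                         for r in recs])


class TestSplits:
    def test_global_split_counts(self, sample_table):
        split = split_by_replicate(sample_table, "global")
        assert len(split.calibration) == 288
        assert len(split.validation) == 144

    def test_reproductive_group_counts(self, sample_table):
        split = split_by_replicate(sample_table, "reproductive")
        assert len(split.calibration) == 144
        assert len(split.validation) == 72

    def test_single_stage_date_counts(self, sample_table):
        split = split_by_replicate(sample_table, "ET:2014")
        assert len(split.calibration) == 24
        assert len(split.validation) == 12

    def test_disjoint_and_ratio(self, sample_table):
        split = split_by_replicate(sample_table, "global")
        assert set(split.calibration.index).isdisjoint(split.validation.index)
        assert len(split.calibration) == 2 * len(split.validation)

    def test_empty_scope_raises(self, sample_table):
        with pytest.raises(ValueError, match="no samples"):
            split_by_replicate(sample_table[sample_table.year == 1999], "global")

    def test_bare_stage_scope_rejected(self, sample_table):
        with pytest.raises(ValueError, match="stage scope"):
            split_by_replicate(sample_table, "ET")


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman_rho2(x, x ** 3 + 1) == pytest.approx(1.0)

    def test_rank_invariance_under_exp(self, rng):
        x = rng.uniform(-2, 2, 30)
        y = rng.uniform(0, 1, 30)
        assert spearman_rho2(x, y) == pytest.approx(spearman_rho2(np.exp(x), y))

    def test_six_point_hand_ranked(self):
        """Direct rank formula: rho = 1 - 6*sum(d^2)/(n(n^2-1)) without ties."""
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.8, 0.3])
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        d2 = np.sum((rx - ry) ** 2)
        rho = 1 - 6 * d2 / (6 * (36 - 1))
        assert spearman_rho2(x, y) == pytest.approx(rho ** 2)

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(spearman_rho2(np.ones(5), np.arange(5.0)))


class TestEvaluate:
    def test_perfect_predictions(self):
        model = StageVIRegressor().fit(np.arange(5.0), 2 * np.arange(5.0) + 1)
        m = evaluate(model, np.arange(5.0), 2 * np.arange(5.0) + 1)
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0, abs=1e-10)

    def test_constant_prediction_r2_zero(self):
        class Mean:
            def predict(self, X):
                return np.full(len(X), 2.0)
        y = np.array([1.0, 2.0, 3.0])
        m = evaluate(Mean(), np.zeros((3, 1)), y)
        assert m.r2 == pytest.approx(0.0)

    def test_four_point_hand_computation(self):
        class Fixed:
            def predict(self, X):
                return np.array([1.0, 2.0, 2.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        m = evaluate(Fixed(), np.zeros((4, 1)), y)
        ss_res = 0.0 + 1.0 + 0.0 + 1.0
        ss_tot = np.sum((y - 2.5) ** 2)
        assert m.r2 == pytest.approx(1 - ss_res / ss_tot)
        assert m.rmse == pytest.approx(np.sqrt(ss_res / 4))


class TestStageVIModel:
    def test_noiseless_linear_relation(self):
        x = np.linspace(1, 3, 24)
        y = 1.8 * x + 0.4
        df = pd.DataFrame({"MTCI": x, "lnc": y, "replicate": [1, 2, 3] * 8,
                           "stage": "JT", "year": 2014})
        from ricespec.regression import DataSplit
        split = DataSplit(df[df.replicate != 3], df[df.replicate == 3], "JT:2014")
        model, metrics = fit_stage_vi_model(split, "MTCI")
        assert metrics.r2 == pytest.approx(1.0)
        assert metrics.rmse == pytest.approx(0.0, abs=1e-10)
        assert model.slope_ == pytest.approx(1.8)

    def test_slope_recovery_within_two_sd(self):
        """Fitted slopes over 30 noisy replicates bracket the true slope."""
        slopes = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x = rng.uniform(1, 3, 24)
            y = 1.8 * x + 0.4 + rng.normal(0, 0.15, 24)
            slopes.append(StageVIRegressor().fit(x, y).slope_)
        assert abs(np.mean(slopes) - 1.8) < 2 * np.std(slopes)

    def test_null_relation_gives_low_validation_r2(self):
        """With pure-noise LNC the validation R^2 at n=24/12 stays <= 0.2 in
        at least 95% of seeds (it is usually strongly negative)."""
        count = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            model = StageVIRegressor().fit(rng.uniform(0, 1, 24), rng.normal(2.5, 0.5, 24))
            m = evaluate(model, rng.uniform(0, 1, 12), rng.normal(2.5, 0.5, 12))
            count += m.r2 <= 0.2
        assert count >= 0.95 * n_seeds

    def test_zero_variance_vi_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            StageVIRegressor().fit(np.ones(10), np.arange(10.0))


class TestPLSR:
    def _low_rank(self, rng, n=60, d=40, n_val=30):
        B = rng.standard_normal((2, d))
        T, Tv = rng.standard_normal((n, 2)), rng.standard_normal((n_val, 2))
        w = np.array([1.5, -0.8])
        return T @ B, T @ w, Tv @ B, Tv @ w

    def test_two_latent_map_recovered(self, rng):
        X, y, Xv, yv = self._low_rank(rng)
        model = PLSNitrogenRegressor(max_components=8).fit(X, y)
        assert model.n_components_ <= 3
        assert evaluate(model, Xv, yv).r2 > 0.99

    def test_duplicating_samples_gives_identical_model(self, rng):
        X, y, _, _ = self._low_rank(rng)
        a = PLSNitrogenRegressor(max_components=6).fit(X, y)
        b = PLSNitrogenRegressor(max_components=6).fit(np.vstack([X, X]),
                                                       np.concatenate([y, y]))
        assert a.n_components_ == b.n_components_
        np.testing.assert_allclose(a.coef_, b.coef_, atol=1e-8)

    def test_pure_noise_targets_near_zero_r2(self, rng):
        X = rng.standard_normal((40, 30))
        y = rng.normal(2.5, 0.5, 40)
        model = PLSNitrogenRegressor(max_components=8).fit(X, y)
        m = evaluate(model, rng.standard_normal((20, 30)), rng.normal(2.5, 0.5, 20))
        assert m.r2 < 0.3

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 5"):
            PLSNitrogenRegressor().fit(rng.standard_normal((4, 10)), np.arange(4.0))

    def test_band_coefficients_exposed(self, rng):
        X, y, _, _ = self._low_rank(rng)
        model = PLSNitrogenRegressor().fit(X, y)
        assert model.coef_.shape == (X.shape[1],)


class TestGPR:
    def test_smooth_three_band_function_recovered(self, rng):
        """Validation R^2 > 0.99 and the three informative bands get the
        smallest ARD lengthscales."""
        n, d = 80, 12
        X = rng.uniform(-1, 1, (n, d))
        f = lambda Z: np.sin(1.5 * Z[:, 2]) + 0.8 * Z[:, 5] ** 2 + 1.2 * Z[:, 9]
        Xv = rng.uniform(-1, 1, (40, d))
        model = GPNitrogenRegressor(n_restarts=2).fit(X, f(X))
        assert evaluate(model, Xv, f(Xv)).r2 > 0.99
        assert set(model.relevance_rank_[:3]) == {2, 5, 9}

    def test_interpolation_limit_reproduces_training_targets(self, rng):
        X = rng.uniform(-1, 1, (25, 4))
        y = np.sin(X[:, 0]) + X[:, 2]
        model = GPNitrogenRegressor().fit(X, y)
        np.testing.assert_allclose(model.predict(X), y,
                                   atol=50 * np.sqrt(model.noise_level_) + 1e-6)

    def test_band_relevance_stable_across_seeds(self, rng):
        """Spearman correlation of the lengthscale rankings across restarts
        seeds stays high on a fixed dataset."""
        n, d = 60, 8
        X = rng.uniform(-1, 1, (n, d))
        y = np.sin(1.5 * X[:, 1]) + X[:, 4] ** 2
        rankings = []
        for seed in range(5):
            model = GPNitrogenRegressor(random_state=seed).fit(X, y)
            rankings.append(stats.rankdata(model.band_lengthscales_))
        rhos = [stats.spearmanr(rankings[0], r).statistic for r in rankings[1:]]
        assert min(rhos) > 0.8

    def test_gpr_beats_plsr_on_nonlinear_maps_in_expectation(self):
        """On nonlinear LNC~spectrum maps the kernel model outperforms the
        linear latent model, in expectation over 20 replicates."""
        diffs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            n, d = 50, 15
            X = r.uniform(0, 1, (n, d))
            w = r.standard_normal(d) * 0.3
            f = lambda Z: np.sin(2.5 * Z[:, 3]) + 3 * (Z[:, 10] - 0.5) ** 2 + 0.3 * Z @ w
            Xv = r.uniform(0, 1, (25, d))
            g = evaluate(GPNitrogenRegressor().fit(X, f(X)), Xv, f(Xv)).r2
            p = evaluate(PLSNitrogenRegressor(max_components=8).fit(X, f(X)), Xv, f(Xv)).r2
            diffs.append(g - p)
        assert np.mean(diffs) > 0
        assert np.mean(np.array(diffs) >= 0) >= 0.8

    def test_leakage_validation_targets_do_not_affect_model(self, rng):
        X = rng.uniform(-1, 1, (30, 5))
        y = X @ rng.standard_normal(5)
        Xv = rng.uniform(-1, 1, (15, 5))
        yv = Xv @ np.ones(5)
        model = GPNitrogenRegressor().fit(X, y)
        before = model.band_lengthscales_.copy()
        m1 = evaluate(model, Xv, yv)
        m2 = evaluate(model, Xv, yv[::-1])
        np.testing.assert_array_equal(model.band_lengthscales_, before)
        assert m1.r2 != m2.r2
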