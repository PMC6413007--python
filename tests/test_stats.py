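"""LDA / OLS machinery with priors, Wilks lambda, LOO Q^2, y-scrambling,
classification metrics and the pharmacological distribution diagram —
cross-checked against scikit-learn, statsmodels and explicit refit oracles."""

import math

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from topoqsar.stats import (
    ClassMetrics,
    LinearDiscriminant,
    OLSRegression,
    class_metrics,
    loo_q2,
    pdd,
    y_scramble,
)

from oracles import loo_refit_q2_oracle


def _two_clouds(seed=0, n=200, sep=8.0):
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0.0, 1.0, size=(n // 2, 3))
    x1 = rng.normal(sep, 1.0, size=(n // 2, 3))
    X = np.vstack([x0, x1])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


class TestLinearDiscriminant:
    def test_separated_clouds_perfect_resubstitution(self):
        X, y = _two_clouds()
        lda = LinearDiscriminant().fit(X, y)
        assert (lda.predict(X) == y).all()
        assert lda.wilks_lambda_ < 0.05
        assert lda.p_value_ < 1e-10

    def test_direction_matches_sklearn(self):
        X, y = _two_clouds(seed=3, sep=2.0)
        ours = LinearDiscriminant(priors=(0.306, 0.694)).fit(X, y)
        sk = LinearDiscriminantAnalysis(priors=[0.306, 0.694]).fit(X, y)
        # same direction up to the pooled-covariance normalisation factor
        ratio = sk.coef_.ravel() / ours.coef_
        np.testing.assert_allclose(ratio, ratio[0] * np.ones(3), rtol=1e-6)
        # same decisions everywhere
        assert (ours.predict(X) == sk.predict(X)).all()

    def test_symmetric_data_boundary_at_midpoint(self):
        X, y = _two_clouds(seed=5, sep=4.0)
        lda = LinearDiscriminant().fit(X, y)
        midpoint = X[y == 0].mean(axis=0) / 2 + X[y == 1].mean(axis=0) / 2
        assert lda.decision_function(midpoint[None, :])[0] == pytest.approx(0.0, abs=1e-9)

    def test_priors_shift_boundary_by_log_odds(self):
        X, y = _two_clouds(seed=7, sep=3.0)
        equal = LinearDiscriminant((0.5, 0.5)).fit(X, y)
        skew = LinearDiscriminant((0.306, 0.694)).fit(X, y)
        np.testing.assert_allclose(equal.coef_, skew.coef_, rtol=1e-12)
        shift = skew.intercept_ - equal.intercept_
        assert shift == pytest.approx(math.log(0.694 / 0.306))

    def test_coefficient_recovery_closed_form(self):
        # the fitted direction must equal Sw^-1 (mu1 - mu0) computed directly
        X, y = _two_clouds(seed=9, sep=2.0)
        x0, x1 = X[y == 0], X[y == 1]
        sw = (np.cov(x0.T, bias=False) * (len(x0) - 1) + np.cov(x1.T, bias=False) * (len(x1) - 1)) / (len(X) - 2)
        want = np.linalg.solve(sw, x1.mean(0) - x0.mean(0))
        got = LinearDiscriminant().fit(X, y).coef_
        np.testing.assert_allclose(got, want, rtol=1e-6)

    def test_invalid_inputs(self):
        X, y = _two_clouds()
        with pytest.raises(ValueError):
            LinearDiscriminant((0.6, 0.6))
        with pytest.raises(ValueError):
            LinearDiscriminant().fit(X, np.zeros(len(X)))

    def test_to_model_round_trip(self):
        X, y = _two_clouds()
        lda = LinearDiscriminant().fit(X, y)
        model = lda.to_model(["a", "b", "c"], domain_window=(-8, 8))
        row = dict(zip(["a", "b", "c"], X[0]))
        assert model.predict(row) == pytest.approx(lda.decision_function(X[:1])[0])


class TestOLS:
    def test_exact_recovery_and_q2(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 4))
        beta = np.array([2.0, -1.5, 0.5, 3.0])
        y = 7.0 + X @ beta  # noise-free
        fit = OLSRegression().fit(X, y)
        np.testing.assert_allclose(fit.coef_, beta, atol=1e-6)
        assert fit.intercept_ == pytest.approx(7.0, abs=1e-6)
        assert fit.r2_ == pytest.approx(1.0)
        assert loo_q2(X, y) == pytest.approx(1.0)

    def test_against_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        y = 1.0 + X @ np.array([0.5, -2.0, 1.0]) + rng.normal(0, 0.5, 60)
        fit = OLSRegression().fit(X, y)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.coef_, ref.params[1:], rtol=1e-8)
        assert fit.r2_ == pytest.approx(ref.rsquared)
        assert fit.see_ == pytest.approx(np.sqrt(ref.mse_resid))
        assert fit.f_stat_ == pytest.approx(ref.fvalue)

    def test_loo_identity_matches_refit_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 3))
        y = X @ np.array([1.0, 2.0, -1.0]) + rng.normal(0, 1.0, 25)
        assert loo_q2(X, y) == pytest.approx(loo_refit_q2_oracle(X, y), abs=1e-10)

    def test_q2_below_r2_on_noisy_data(self):
        rng = np.random.default_rng(4)
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(30, 3))
            y = X @ np.array([1.0, -1.0, 0.5]) + r.normal(0, 1.0, 30)
            assert loo_q2(X, y) <= OLSRegression().fit(X, y).r2_ + 1e-12

    def test_rank_deficiency_raises(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError):
            OLSRegression().fit(X, np.arange(10.0))

    def test_y_scrambling_null_band(self):
        # pure noise: scrambled R^2 concentrates near p/(n-1) and the true fit
        # is indistinguishable from the scrambled distribution
        rng = np.random.default_rng(5)
        n, p = 50, 5
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        r2s = y_scramble(X, y, n_perm=100, seed=6)
        assert abs(r2s.mean() - p / (n - 1)) < 0.05
        true_r2 = OLSRegression().fit(X, y).r2_
        lo, hi = np.quantile(r2s, [0.01, 0.99])
        assert lo - 0.05 <= true_r2 <= hi + 0.15


class TestClassMetrics:
    def test_perfect(self):
        m = class_metrics([1, 0, 1], [1, 0, 1])
        assert (m.sensitivity, m.specificity, m.accuracy) == (100.0, 100.0, 100.0)

    def test_all_predicted_inactive(self):
        m = class_metrics([1, 0, 0, 0], [0, 0, 0, 0])
        assert (m.sensitivity, m.specificity, m.accuracy) == (0.0, 100.0, 75.0)

    def test_empty_class_undefined(self):
        m = class_metrics([1, 1], [1, 0])
        assert math.isnan(m.specificity)

    def test_matches_confusion_tally(self):
        rng = np.random.default_rng(8)
        truth = rng.integers(0, 2, 50)
        pred = rng.integers(0, 2, 50)
        m = class_metrics(truth, pred)
        tp = ((truth == 1) & (pred == 1)).sum()
        tn = ((truth == 0) & (pred == 0)).sum()
        assert m.sensitivity == pytest.approx(100 * tp / (truth == 1).sum())
        assert m.specificity == pytest.approx(100 * tn / (truth == 0).sum())
        assert m.accuracy == pytest.approx(100 * (tp + tn) / 50)
        # accuracy between the class-wise rates
        assert min(m.sensitivity, m.specificity) <= m.accuracy <= max(m.sensitivity, m.specificity)


class TestPdd:
    def test_expectancy_formula(self):
        # one bin holding 40% of actives and 10% of inactives
        df = np.array([0.5] * 4 + [5.5] * 6 + [0.5] * 1 + [5.5] * 9, dtype=float)
        truth = np.array([1] * 10 + [0] * 10)
        bins = pdd(df, truth, bin_width=1.0)
        b = next(b for b in bins if b.low == 0.0)
        assert b.expectancy_active == pytest.approx(0.4 / 1.1)

    def test_pure_active_bin(self):
        df = np.array([0.5, 0.5, 7.5])
        truth = np.array([1, 1, 0])
        bins = pdd(df, truth, bin_width=1.0)
        b = bins[0]
        assert b.expectancy_active == pytest.approx(1.0)

    def test_fractions_integrate_to_one(self):
        rng = np.random.default_rng(9)
        df = rng.normal(0, 4, 200)
        truth = (df + rng.normal(0, 2, 200) > 0).astype(int)
        bins = pdd(df, truth, bin_width=1.0)
        a_total = sum(b.n_active for b in bins)
        i_total = sum(b.n_inactive for b in bins)
        assert a_total == truth.sum() and i_total == (1 - truth).sum()

    def test_monotone_in_active_fraction(self):
        vals = [a / (0.1 + 1.0) for a in (0.1, 0.3, 0.7)]
        assert vals == sorted(vals)

    def test_empty_inputs(self):
        assert pdd([], [], 1.0) == []
        assert pdd([1.0], [1], 1.0) == []  # no inactives
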