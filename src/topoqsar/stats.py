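"""Generic two-group linear discriminant analysis and multilinear regression,
with the validation machinery used in QSAR practice: Wilks lambda and its F
transform, leave-one-out Q^2 and response scrambling (y-randomisation), plus
classification metrics and the pharmacological distribution diagram.

Both estimators follow the scikit-learn idiom (``fit`` populating
trailing-underscore attributes) and export their fitted coefficients as a
:class:`~topoqsar.models.LinearQsarModel`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .models import LinearQsarModel


# ---------------------------------------------------------------------------
# linear discriminant analysis
# ---------------------------------------------------------------------------

class LinearDiscriminant:
    """Two-class linear discriminant with class priors.

    The discriminant direction is Sw^-1 (mu1 - mu0) with Sw the pooled
    within-class covariance; the intercept places the boundary at the
    midpoint of the projected class means shifted by the prior log-odds
    ln(p1/p0).  Scores are positive for class 1.

    Fitted attributes: ``coef_``, ``intercept_``, ``wilks_lambda_``,
    ``f_stat_``, ``df_``, ``p_value_``.
    """

    def __init__(self, priors: tuple[float, float] = (0.5, 0.5)):
        if not math.isclose(sum(priors), 1.0, abs_tol=1e-9):
            raise ValueError("priors must sum to 1")
        self.priors = priors

    def fit(self, X, y) -> "LinearDiscriminant":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary 0/1")
        n, p = X.shape
        x0, x1 = X[y == 0], X[y == 1]
        if len(x0) == 0 or len(x1) == 0:
            raise ValueError("both classes must be non-empty")
        mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
        w_sscp = (x0 - mu0).T @ (x0 - mu0) + (x1 - mu1).T @ (x1 - mu1)
        sw = w_sscp / (n - 2)
        try:
            direction = np.linalg.solve(sw, mu1 - mu0)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular within-class scatter; prune collinear descriptors"
            ) from exc
        self.coef_ = direction
        self.intercept_ = (
            -0.5 * direction @ (mu0 + mu1) + math.log(self.priors[1] / self.priors[0])
        )
        # Wilks lambda = |W| / |T| from the SSCP matrices
        mu = X.mean(axis=0)
        t_sscp = (X - mu).T @ (X - mu)
        sign_w, logdet_w = np.linalg.slogdet(w_sscp)
        sign_t, logdet_t = np.linalg.slogdet(t_sscp)
        if sign_w <= 0 or sign_t <= 0:
            raise ValueError("degenerate scatter matrices (rank deficiency)")
        lam = math.exp(logdet_w - logdet_t)
        self.wilks_lambda_ = lam
        df1, df2 = p, n - p - 1
        self.df_ = (df1, df2)
        self.f_stat_ = (1.0 - lam) / lam * df2 / df1
        self.p_value_ = float(sps.f.sf(self.f_stat_, df1, df2))
        return self

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    def to_model(self, names, name="lda", domain_window=None) -> LinearQsarModel:
        return LinearQsarModel(
            name=name,
            intercept=float(self.intercept_),
            terms={nm: float(c) for nm, c in zip(names, self.coef_)},
            response="discriminant score",
            domain_window=domain_window,
        )


# ---------------------------------------------------------------------------
# ordinary least squares with QSAR validation statistics
# ---------------------------------------------------------------------------

class OLSRegression:
    """Ordinary least squares with R^2, standard error of estimate, F test.

    Fitted attributes: ``coef_``, ``intercept_``, ``r2_``, ``see_``,
    ``f_stat_``, ``p_value_``, ``hat_diag_``, ``residuals_``.
    """

    def fit(self, X, y) -> "OLSRegression":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n <= p + 1:
            raise ValueError("need n > p + 1 observations")
        xd = np.column_stack([np.ones(n), X])
        q, r = np.linalg.qr(xd)
        if np.abs(np.diag(r)).min() < 1e-10 * np.abs(np.diag(r)).max():
            raise ValueError("rank-deficient design matrix")
        beta = np.linalg.solve(r, q.T @ y)
        self.intercept_ = beta[0]
        self.coef_ = beta[1:]
        fitted = xd @ beta
        resid = y - fitted
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        self.see_ = math.sqrt(ss_res / (n - p - 1))
        if ss_res > 0:
            self.f_stat_ = (ss_tot - ss_res) / p / (ss_res / (n - p - 1))
            self.p_value_ = float(sps.f.sf(self.f_stat_, p, n - p - 1))
        else:
            self.f_stat_, self.p_value_ = float("inf"), 0.0
        self.hat_diag_ = (q * q).sum(axis=1)
        self.residuals_ = resid
        self._y = y
        return self

    def predict(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def to_model(self, names, name="mlr", response="") -> LinearQsarModel:
        return LinearQsarModel(
            name=name,
            intercept=float(self.intercept_),
            terms={nm: float(c) for nm, c in zip(names, self.coef_)},
            response=response,
        )


def loo_q2(X, y) -> float:
    """Leave-one-out Q^2 = 1 - PRESS / SS_tot.

    Each deleted-case prediction comes from the model fit without that case;
    computed through the exact OLS hat-matrix identity
    e_(i) = e_i / (1 - h_ii).
    """
    fit = OLSRegression().fit(X, y)
    h = fit.hat_diag_
    press_resid = fit.residuals_ / (1.0 - h)
    press = float(press_resid @ press_resid)
    y = np.asarray(y, dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss_tot


def y_scramble(X, y, n_perm: int = 100, seed: int | None = None) -> np.ndarray:
    """R^2 distribution after random permutation of the response: detects
    chance correlation (a sound model's true R^2 should sit far above it)."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    out = np.empty(n_perm)
    for i in range(n_perm):
        out[i] = OLSRegression().fit(X, rng.permutation(y)).r2_
    return out


# ---------------------------------------------------------------------------
# classification metrics and the pharmacological distribution diagram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassMetrics:
    """Percent-scale sensitivity / specificity / accuracy; NaN marks a metric
    undefined because its class is empty."""

    sensitivity: float
    specificity: float
    accuracy: float


def class_metrics(truth, predicted) -> ClassMetrics:
    truth = np.asarray(truth).astype(int)
    predicted = np.asarray(predicted).astype(int)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have the same length")
    pos, neg = truth == 1, truth == 0
    sens = 100.0 * (predicted[pos] == 1).mean() if pos.any() else float("nan")
    spec = 100.0 * (predicted[neg] == 0).mean() if neg.any() else float("nan")
    acc = 100.0 * (predicted == truth).mean() if truth.size else float("nan")
    return ClassMetrics(float(sens), float(spec), float(acc))


@dataclass(frozen=True)
class PddBin:
    low: float
    high: float
    expectancy_active: float
    expectancy_inactive: float
    n_active: int
    n_inactive: int


def pdd(df_values, truth, bin_width: float = 1.0) -> list[PddBin]:
    """Pharmacological distribution diagram.

    Per score interval, with a and i the *fractions* of all actives and all
    inactives falling in the bin: E_a = a / (i + 1) and E_i = i / (a + 1).
    Returns an empty list when either class is absent.
    """
    df_values = np.asarray(df_values, dtype=float)
    truth = np.asarray(truth).astype(int)
    n_act, n_inact = int((truth == 1).sum()), int((truth == 0).sum())
    if df_values.size == 0 or n_act == 0 or n_inact == 0:
        return []
    lo = math.floor(df_values.min() / bin_width) * bin_width
    hi = math.ceil(df_values.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    bins = []
    for low, high in zip(edges[:-1], edges[1:]):
        in_bin = (df_values >= low) & (df_values < high)
        # the last bin is closed on the right so every value lands somewhere
        if high == edges[-1]:
            in_bin |= df_values == high
        ca = int((in_bin & (truth == 1)).sum())
        ci = int((in_bin & (truth == 0)).sum())
        a, i = ca / n_act, ci / n_inact
        bins.append(
            PddBin(float(low), float(high), a / (i + 1.0), i / (a + 1.0), ca, ci)
        )
    return bins
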