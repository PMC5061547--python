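"""Ordinary-least-squares helpers shared by behavioral and neuronal analyses.

Multiple regressions go through :mod:`statsmodels`; the vectorized
single-regressor path (used per sliding window, where thousands of fits are
needed) computes the identical t-test from the Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class RegressionFit:
    """Result of one OLS fit of trial activity (or reaction time) on task regressors.

    ``params``/``pvalues`` include the intercept under ``"const"``;
    ``standardized`` holds x_i * (s_i / s_y) slope coefficients (intercept
    excluded), the conventional standardization for comparing regressors
    measured in different units.
    """

    model_id: str
    params: pd.Series
    pvalues: pd.Series
    standardized: pd.Series
    r_squared: float
    residuals: np.ndarray
    n_trials: int
    neuron_id: str | None = None
    period: str | None = None
    degenerate: bool = False
    retained: list[str] = field(default_factory=list)
    model_pvalue: float = 1.0  # F-test of all slopes jointly
    n_params: int = 2  # fitted columns including the (possibly implicit) intercept

    @property
    def adjusted_r_squared(self) -> float:
        """R² penalized for parameter count — comparable across models of
        different flexibility (a step-indicator model nests any monotone
        tuning, so raw R² would always favor it)."""
        n, k = self.n_trials, self.n_params
        if n - k <= 0:
            return float("-inf")
        return 1.0 - (1.0 - self.r_squared) * (n - 1) / (n - k)

    @property
    def bic(self) -> float:
        """Bayesian information criterion (Gaussian errors): n ln(RSS/n) + k ln n.

        Unlike raw or adjusted R², the ln(n) parsimony penalty resolves
        nested model contests (e.g. step indicators vs a linear tuning they
        can mimic) in favor of the simpler model when fits are equal.
        """
        n, k = self.n_trials, self.n_params
        rss = float(np.sum(self.residuals**2))
        if rss <= 0:
            return float("-inf")
        return n * np.log(rss / n) + k * np.log(n)

    @property
    def slope(self) -> float:
        """First non-intercept coefficient (convenience for single-regressor models)."""
        names = [n for n in self.params.index if n != "const"]
        return float(self.params[names[0]]) if names else float("nan")

    @property
    def slope_pvalue(self) -> float:
        names = [n for n in self.pvalues.index if n != "const"]
        return float(self.pvalues[names[0]]) if names else float("nan")

    def is_significant(self, alpha: float = 0.05) -> bool:
        """Any non-intercept coefficient with two-sided p < alpha."""
        names = [n for n in self.pvalues.index if n != "const"]
        if not names:
            return False
        return bool((self.pvalues[names] < alpha).any())


def standardized_coefficients(params: pd.Series, X: pd.DataFrame, y: np.ndarray) -> pd.Series:
    sy = float(np.std(y, ddof=1))
    out = {}
    for name in params.index:
        if name == "const":
            continue
        si = float(np.std(np.asarray(X[name], dtype=float), ddof=1))
        out[name] = float(params[name]) * (si / sy if sy > 0 else 0.0)
    return pd.Series(out, dtype=float)


def ols_fit(
    X: pd.DataFrame,
    y: np.ndarray,
    model_id: str = "ols",
    neuron_id: str | None = None,
    period: str | None = None,
) -> RegressionFit:
    """Fit y = b0 + X b + e by OLS with two-sided t-tests on coefficients.

    A design whose columns are (numerically) collinear or constant is flagged
    ``degenerate``; coefficients are still returned from the pseudoinverse fit
    but should not be interpreted.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("design matrix and response length mismatch")
    if n < X.shape[1] + 2:
        raise ValueError(f"too few trials ({n}) for {X.shape[1]} regressors")
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    res = sm.OLS(y, Xc).fit()
    rank = np.linalg.matrix_rank(np.asarray(Xc, dtype=float))
    degenerate = rank < Xc.shape[1]
    if np.allclose(y, y[0]):
        # constant response: define a flat fit rather than 0/0 noise
        params = pd.Series(0.0, index=Xc.columns)
        params["const"] = float(y[0])
        pvals = pd.Series(1.0, index=Xc.columns)
        return RegressionFit(
            model_id=model_id, params=params, pvalues=pvals,
            standardized=pd.Series(0.0, index=[c for c in Xc.columns if c != "const"]),
            r_squared=0.0, residuals=np.zeros(n), n_trials=n,
            neuron_id=neuron_id, period=period, degenerate=degenerate,
            n_params=1,
        )
    r2 = float(res.rsquared)
    f_p = float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 1.0
    return RegressionFit(
        model_id=model_id,
        params=pd.Series(res.params, index=Xc.columns),
        pvalues=pd.Series(res.pvalues, index=Xc.columns),
        standardized=standardized_coefficients(pd.Series(res.params, index=Xc.columns), Xc, y),
        r_squared=max(0.0, min(1.0, r2)),
        residuals=np.asarray(res.resid),
        n_trials=n,
        neuron_id=neuron_id,
        period=period,
        degenerate=degenerate,
        model_pvalue=f_p,
        n_params=Xc.shape[1],
    )


def simple_regression_pvalues(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Two-sided slope p-values for many simple regressions sharing one regressor.

    Parameters
    ----------
    x : (n,) regressor.
    Y : (n, k) responses, one column per fit.

    Returns (k,) p-values; a column (or x) with zero variance yields p = 1.
    Equivalent to the OLS slope t-test: t = r sqrt((n-2)/(1-r^2)).
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != x.shape[0]:
        Y = Y.T
    n = x.shape[0]
    if n < 3:
        return np.ones(Y.shape[1])
    xc = x - x.mean()
    sx = np.sqrt((xc**2).sum())
    Yc = Y - Y.mean(axis=0)
    sy = np.sqrt((Yc**2).sum(axis=0))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ Yc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[~np.isfinite(p)] = 1.0
    p[denom == 0] = 1.0
    # exact fits: p -> 0
    p[np.isclose(np.abs(r), 1.0) & (denom > 0)] = 0.0
    return p
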