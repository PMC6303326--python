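"""Per-unit bivariate BPR analysis.

Within each climatic unit, log productivity is regressed on species richness
with a Gaussian GLM; a linear model (intercept + S) and a quadratic model
(intercept + S + S^2) are compared by AIC and the winner's richness term
decides the BPR type:

* linear selected: ``linear_positive`` / ``linear_negative`` when the slope is
  significant (two-sided z-test), else ``non_significant``;
* quadratic selected: ``concave_negative`` / ``concave_positive`` when the
  quadratic term is significant, else ``non_significant``.

Conventions (matching R's ``glm``/``logLik`` for the gaussian family): the
log-likelihood is evaluated at the ML residual variance RSS/n; AIC counts the
error variance as an estimated parameter (k = p + 1); coefficient standard
errors use the dispersion RSS/(n - p); tests are z (normal), as large-n
equivalents of t-tests.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .climate import ClimateGrid
from .table import PlotTable


class BPRType(str, enum.Enum):
    """The five possible biodiversity-productivity relationship labels."""

    linear_positive = "linear_positive"
    linear_negative = "linear_negative"
    concave_negative = "concave_negative"
    concave_positive = "concave_positive"
    non_significant = "non_significant"


@dataclass
class ModelFit:
    """One Gaussian fit: coefficients in increasing polynomial order."""

    params: np.ndarray  # (intercept, b1[, b2])
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    aic: float


@dataclass
class BivariateFit:
    unit: int | None
    n: int
    n_dropped_nonpositive: int
    linear: ModelFit | None
    quadratic: ModelFit | None
    selected: str | None  # 'linear' | 'quadratic' | None
    estimable: bool
    reason: str | None = None

    @property
    def selected_fit(self) -> ModelFit | None:
        if self.selected == "linear":
            return self.linear
        if self.selected == "quadratic":
            return self.quadratic
        return None


def _gaussian_glm(y: np.ndarray, X: np.ndarray) -> ModelFit:
    """OLS coefficients with R-glm-style likelihood, AIC and z-tests."""
    n, p = X.shape
    res = sm.OLS(y, X).fit()
    # statsmodels OLS: llf is the gaussian log-likelihood at sigma^2 = RSS/n
    # (identical to R's logLik.glm); bse uses dispersion RSS/(n-p).
    loglik = float(res.llf)
    aic = -2.0 * loglik + 2.0 * (p + 1)  # +1: error variance is estimated
    se = np.asarray(res.bse)
    params = np.asarray(res.params)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = params / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return ModelFit(params=params, se=se, z=z, p=pvals, loglik=loglik, aic=aic)


def fit_bivariate(
    richness,
    log_productivity,
    unit: int | None = None,
    min_n: int = 4,
    n_dropped_nonpositive: int = 0,
) -> BivariateFit:
    """Fit linear and quadratic Gaussian GLMs of log productivity on richness.

    Inputs must already be finite (callers drop non-positive-productivity rows
    before taking logs and pass the dropped count). Returns a non-estimable
    fit (never raises) when n < ``min_n`` or richness has zero variance.
    """
    S = np.asarray(richness, dtype=float)
    y = np.asarray(log_productivity, dtype=float)
    if S.shape != y.shape:
        raise ValueError("richness and log_productivity lengths differ")
    n = len(S)

    def not_estimable(reason: str) -> BivariateFit:
        return BivariateFit(
            unit=unit,
            n=n,
            n_dropped_nonpositive=n_dropped_nonpositive,
            linear=None,
            quadratic=None,
            selected=None,
            estimable=False,
            reason=reason,
        )

    if n < min_n:
        return not_estimable(f"n={n} below minimum {min_n}")
    if np.ptp(S) == 0:
        return not_estimable("zero variance in richness")

    Xl = np.column_stack([np.ones(n), S])
    linear = _gaussian_glm(y, Xl)

    if len(np.unique(S)) < 3:
        # quadratic design singular with <3 distinct richness values
        return BivariateFit(
            unit=unit,
            n=n,
            n_dropped_nonpositive=n_dropped_nonpositive,
            linear=linear,
            quadratic=None,
            selected="linear",
            estimable=True,
            reason="quadratic not estimable (<3 distinct richness values)",
        )

    Xq = np.column_stack([np.ones(n), S, S**2])
    quadratic = _gaussian_glm(y, Xq)
    # AIC tie -> the simpler (linear) model
    selected = "quadratic" if quadratic.aic < linear.aic else "linear"
    return BivariateFit(
        unit=unit,
        n=n,
        n_dropped_nonpositive=n_dropped_nonpositive,
        linear=linear,
        quadratic=quadratic,
        selected=selected,
        estimable=True,
    )


def classify_bivariate(fit: BivariateFit, alpha: float = 0.05) -> BPRType:
    """Map a bivariate fit to its BPR type under the z-test significance rule."""
    if not fit.estimable:
        return BPRType.non_significant
    if fit.selected == "linear":
        b1, p1 = fit.linear.params[1], fit.linear.p[1]
        if p1 <= alpha:
            return BPRType.linear_positive if b1 > 0 else BPRType.linear_negative
        return BPRType.non_significant
    b2, p2 = fit.quadratic.params[2], fit.quadratic.p[2]
    if p2 <= alpha:
        return BPRType.concave_negative if b2 < 0 else BPRType.concave_positive
    return BPRType.non_significant


def bivariate_by_unit(
    table: PlotTable,
    grid: ClimateGrid,
    alpha: float = 0.05,
    min_n: int = 4,
) -> pd.DataFrame:
    """Classify the BPR of every populated climatic unit.

    Returns one row per populated unit with the fitted coefficients of both
    models, AICs, the selected model and the BPR type. Plots with missing or
    non-positive productivity are dropped (log undefined) and counted.
    """
    if grid.assignment is None:
        raise ValueError("grid has no assignment; call assign_units first")
    df = table.df.merge(grid.assignment[["plot_id", "unit"]], on="plot_id")
    rows = []
    for unit, g in df.groupby("unit", sort=True):
        usable = g["productivity"].notna() & (g["productivity"] > 0) & g["richness"].notna()
        dropped = int((~usable).sum())
        sub = g.loc[usable]
        fit = fit_bivariate(
            sub["richness"].to_numpy(dtype=float),
            np.log(sub["productivity"].to_numpy(dtype=float)),
            unit=int(unit),
            min_n=min_n,
            n_dropped_nonpositive=dropped,
        )
        bpr = classify_bivariate(fit, alpha=alpha)
        lin, quad = fit.linear, fit.quadratic
        rows.append(
            {
                "unit": int(unit),
                "n": fit.n,
                "n_dropped": dropped,
                "estimable": fit.estimable,
                "selected": fit.selected,
                "b1_linear": lin.params[1] if lin else np.nan,
                "p1_linear": lin.p[1] if lin else np.nan,
                "aic_linear": lin.aic if lin else np.nan,
                "b1_quadratic": quad.params[1] if quad else np.nan,
                "b2_quadratic": quad.params[2] if quad else np.nan,
                "p2_quadratic": quad.p[2] if quad else np.nan,
                "aic_quadratic": quad.aic if quad else np.nan,
                "bpr_type": bpr.value,
            }
        )
    return pd.DataFrame(rows)
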