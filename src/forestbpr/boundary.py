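"""Logistic boundary between linear-positive and concave-negative units.

Each classified climatic unit contributes one observation at its (mean MAT,
mean TAP); a binomial logit of type (concave_negative = 1) on MAT and TAP is
fitted by maximum likelihood and the P = 0.5 contour — the line
``intercept + coef_mat * MAT + coef_tap * TAP = 0`` — is the division between
the two BPR regimes in climate space.

With ~100 units and near-clean spatial separation the ML estimates can
diverge (complete separation); this is detected and a small ridge-penalized
fit is substituted, flagged, so a boundary is always reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bivariate import BPRType

#: The two BPR types the boundary separates; concave_negative codes as 1.
BOUNDARY_TYPES = (BPRType.linear_positive.value, BPRType.concave_negative.value)


class BoundaryError(ValueError):
    """Raised when the two-class logistic boundary cannot be fitted."""


@dataclass
class BoundaryFit:
    intercept: float
    coef_mat: float
    coef_tap: float
    converged: bool
    separation: bool
    penalized: bool
    p_values: np.ndarray | None  # (intercept, mat, tap); None when penalized
    n_linear_positive: int
    n_concave_negative: int

    @property
    def params(self) -> np.ndarray:
        return np.array([self.intercept, self.coef_mat, self.coef_tap])

    def predict_proba(self, mat, tap) -> np.ndarray:
        """P(concave_negative) at the given climate coordinates."""
        eta = self.intercept + self.coef_mat * np.asarray(mat) + self.coef_tap * np.asarray(tap)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_type_boundary(
    unit_summaries: pd.DataFrame,
    unit_types: pd.DataFrame,
    weight_by_n: bool = False,
    ridge_alpha: float = 1e-4,
) -> BoundaryFit:
    """Fit the two-class logistic boundary on unit-level climate means.

    ``unit_summaries`` needs columns unit, mean_mat, mean_tap (and n_plots if
    ``weight_by_n``); ``unit_types`` needs unit, bpr_type. Units whose type is
    not one of the two boundary classes are excluded. Requires >= 2 units of
    each class.
    """
    merged = unit_summaries.merge(unit_types[["unit", "bpr_type"]], on="unit")
    merged = merged[merged["bpr_type"].isin(BOUNDARY_TYPES)]
    y = (merged["bpr_type"] == BPRType.concave_negative.value).to_numpy(dtype=float)
    n_pos = int(y.sum())
    n_lin = int(len(y) - y.sum())
    if n_lin < 2 or n_pos < 2:
        raise BoundaryError(
            "need >= 2 units of each boundary class; got "
            f"{n_lin} linear_positive, {n_pos} concave_negative"
        )
    X = sm.add_constant(merged[["mean_mat", "mean_tap"]].to_numpy(dtype=float))
    freq = merged["n_plots"].to_numpy(dtype=float) if weight_by_n else None

    separation = False
    converged = False
    params = None
    p_values = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=freq)
            res = model.fit(maxiter=100)
            params = np.asarray(res.params)
            p_values = np.asarray(res.pvalues)
            converged = bool(res.converged)
            # diverging coefficients / vanishing residual deviance indicate
            # (quasi-)complete separation even when IRLS "converges"
            mu = res.predict(X)
            if np.max(np.abs(params[1:])) > 1e3 or np.all(np.abs(y - mu) < 1e-6):
                separation = True
        except Exception:
            separation = True

    penalized = separation or not converged
    if penalized:
        model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=freq)
        res = model.fit_regularized(alpha=ridge_alpha, L1_wt=0.0, maxiter=500)
        params = np.asarray(res.params)
        p_values = None
        converged = True

    return BoundaryFit(
        intercept=float(params[0]),
        coef_mat=float(params[1]),
        coef_tap=float(params[2]),
        converged=converged,
        separation=separation,
        penalized=penalized,
        p_values=p_values,
        n_linear_positive=n_lin,
        n_concave_negative=n_pos,
    )


def boundary_line(fit: BoundaryFit, mat_grid) -> pd.DataFrame:
    """The P = 0.5 locus as TAP(MAT) over ``mat_grid``.

    Returns a DataFrame with columns mat, tap. If the TAP coefficient is zero
    the boundary is vertical in climate space; the constant MAT is reported
    instead (columns mat, tap with tap = NaN).
    """
    mat_grid = np.asarray(mat_grid, dtype=float)
    if fit.coef_tap == 0.0:
        if fit.coef_mat == 0.0:
            raise BoundaryError("degenerate boundary: both climate coefficients are zero")
        mat_const = -fit.intercept / fit.coef_mat
        return pd.DataFrame({"mat": np.full_like(mat_grid, mat_const), "tap": np.nan})
    tap = -(fit.intercept + fit.coef_mat * mat_grid) / fit.coef_tap
    return pd.DataFrame({"mat": mat_grid, "tap": tap})
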