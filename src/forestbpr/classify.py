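"""Posterior BPR classification and coefficient maps across climate space.

A unit's BPR type is decided from the posterior draws of the linear (b17) and
quadratic (b18) richness terms of the productivity sub-model:

* concave negative: b18 < 0 with P(b18 < 0) > 0.95;
* concave positive: b18 > 0 with P(b18 > 0) > 0.95;
* linear positive: P(b17 > 0) > 0.95 and the 95% CI for b18 overlaps zero;
* linear negative (extension): P(b17 < 0) > 0.95 and the b18 CI overlaps
  zero — the published rules leave this corner unlabelled; it is labelled
  explicitly here rather than silently folded into non-significant;
* non-significant otherwise (both CIs overlap zero).

The concavity rules take precedence (a strong hump usually has a significant
linear term too); credible intervals are equal-tailed. Both choices are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bivariate import BPRType
from .hierarchical import SLOPE_NAMES, PosteriorSummary


@dataclass
class PosteriorBPR:
    unit: int | None
    bpr_type: BPRType
    p_b17_gt0: float
    p_b18_gt0: float
    ci_b17: tuple
    ci_b18: tuple


def _equal_tailed_ci(draws: np.ndarray, level: float) -> tuple:
    lo = (1.0 - level) / 2.0
    return tuple(np.quantile(draws, [lo, 1.0 - lo]))


def classify_posterior(
    draws_b17,
    draws_b18,
    level: float = 0.95,
    unit: int | None = None,
    concavity_precedence: bool = True,
) -> PosteriorBPR:
    """Classify a unit's BPR from posterior draws of b17 and b18."""
    b17 = np.asarray(draws_b17, dtype=float)
    b18 = np.asarray(draws_b18, dtype=float)
    if b17.shape != b18.shape:
        raise ValueError(f"draw vectors differ in length: {b17.shape} vs {b18.shape}")
    if len(b17) < 100:
        raise ValueError(f"need >= 100 draws, got {len(b17)}")

    p17 = float(np.mean(b17 > 0))
    p18 = float(np.mean(b18 > 0))
    ci17 = _equal_tailed_ci(b17, level)
    ci18 = _equal_tailed_ci(b18, level)
    ci18_overlaps_zero = ci18[0] <= 0.0 <= ci18[1]

    concave_negative = (1.0 - p18) > level
    concave_positive = p18 > level
    linear_positive = p17 > level and ci18_overlaps_zero
    linear_negative = (1.0 - p17) > level and ci18_overlaps_zero

    order = (
        [
            (concave_negative, BPRType.concave_negative),
            (concave_positive, BPRType.concave_positive),
            (linear_positive, BPRType.linear_positive),
            (linear_negative, BPRType.linear_negative),
        ]
        if concavity_precedence
        else [
            (linear_positive, BPRType.linear_positive),
            (linear_negative, BPRType.linear_negative),
            (concave_negative, BPRType.concave_negative),
            (concave_positive, BPRType.concave_positive),
        ]
    )
    bpr = next((label for cond, label in order if cond), BPRType.non_significant)
    return PosteriorBPR(
        unit=unit, bpr_type=bpr, p_b17_gt0=p17, p_b18_gt0=p18, ci_b17=ci17, ci_b18=ci18
    )


def classify_all_posterior(
    summaries: dict, level: float = 0.95, concavity_precedence: bool = True
) -> pd.DataFrame:
    """Posterior BPR classification for every fitted unit."""
    rows = []
    for unit, summary in sorted(summaries.items()):
        res = classify_posterior(
            summary.draws["b17"],
            summary.draws["b18"],
            level=level,
            unit=unit,
            concavity_precedence=concavity_precedence,
        )
        rows.append(
            {
                "unit": unit,
                "bpr_type": res.bpr_type.value,
                "p_b17_gt0": res.p_b17_gt0,
                "p_b18_gt0": res.p_b18_gt0,
                "ci17_lo": res.ci_b17[0],
                "ci17_hi": res.ci_b17[1],
                "ci18_lo": res.ci_b18[0],
                "ci18_hi": res.ci_b18[1],
            }
        )
    return pd.DataFrame(rows)


def coefficient_map(
    summaries: dict, unit_summaries: pd.DataFrame, coefficient: str
) -> pd.DataFrame:
    """Per-unit map of one slope coefficient across climate space.

    ``summaries`` maps unit -> PosteriorSummary; ``unit_summaries`` is the
    output of summarize_units. Rows carry the unit's climate means, the
    posterior mean, the CI-based significance flag and log n for rendering.
    """
    if coefficient not in SLOPE_NAMES:
        raise KeyError(
            f"unknown coefficient {coefficient!r}; valid labels: {SLOPE_NAMES}"
        )
    meta = unit_summaries.set_index("unit")
    rows = []
    for unit, summary in sorted(summaries.items()):
        coef = summary.coefficient(coefficient)
        m = meta.loc[unit]
        rows.append(
            {
                "unit": unit,
                "mean_mat": float(m["mean_mat"]),
                "mean_tap": float(m["mean_tap"]),
                "mean": float(coef["mean"]),
                "ci_lo": float(coef["ci_lo"]),
                "ci_hi": float(coef["ci_hi"]),
                "significant": bool(coef["significant"]),
                "log_n": float(m["log_n"]),
            }
        )
    return pd.DataFrame(rows)
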