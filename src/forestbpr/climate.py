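"""Climatic-space binning: the 10 x 10 MAT x TAP quantile grid.

Plots are placed in a grid formed by crossing ``k`` quantile classes of mean
annual temperature with ``k`` quantile classes of total annual precipitation
(k=10 gives the canonical 100 climatic units). Each unit is summarized by its
plot count and covariate means and labelled by the aridity class of its mean
aridity index.

Interval convention (fixed for reproducibility): classes are half-open
``[b_i, b_{i+1})`` with the final interval closed; a value exactly at an
interior breakpoint goes to the upper class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import PlotTable, require_nonempty

#: Aridity-index class thresholds: [0.03, 0.2) arid, [0.2, 0.5) semi-arid,
#: [0.5, 0.65) dry sub-humid, >= 0.65 humid.
ARIDITY_THRESHOLDS = (0.03, 0.2, 0.5, 0.65)
ARIDITY_CLASSES = ("arid", "semi-arid", "dry sub-humid", "humid")
DRY_CLASSES = ("arid", "semi-arid")


class ClimateGridError(ValueError):
    """Raised for invalid binning inputs (too few distinct values, out-of-range plots)."""


@dataclass
class ClimateGrid:
    """Quantile breakpoints for MAT and TAP plus the plot -> unit assignment.

    ``unit`` ids run 1..k_mat*k_tap with ``unit = (mat_class-1)*k_tap + tap_class``.
    """

    mat_breaks: np.ndarray
    tap_breaks: np.ndarray
    k: int
    assignment: pd.DataFrame | None = None  # plot_id, mat_class, tap_class, unit

    @property
    def k_mat(self) -> int:
        return len(self.mat_breaks) - 1

    @property
    def k_tap(self) -> int:
        return len(self.tap_breaks) - 1

    def unit_id(self, mat_class: np.ndarray, tap_class: np.ndarray) -> np.ndarray:
        return (np.asarray(mat_class) - 1) * self.k_tap + np.asarray(tap_class)

    def to_dict(self) -> dict:
        d = {
            "k": self.k,
            "mat_breaks": [float(b) for b in self.mat_breaks],
            "tap_breaks": [float(b) for b in self.tap_breaks],
        }
        if self.assignment is not None:
            d["assignment"] = {
                col: self.assignment[col].tolist() for col in self.assignment.columns
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClimateGrid":
        grid = cls(
            mat_breaks=np.asarray(d["mat_breaks"], dtype=float),
            tap_breaks=np.asarray(d["tap_breaks"], dtype=float),
            k=int(d["k"]),
        )
        if "assignment" in d:
            grid.assignment = pd.DataFrame(d["assignment"])
        return grid


@dataclass
class UnitSummary:
    unit: int
    n_plots: int
    mean_mat: float
    mean_tap: float
    mean_aridity: float
    aridity_class: str
    log_n: float


def quantile_breaks(values, k: int) -> np.ndarray:
    """k+1 empirical-quantile breakpoints (first = min, last = max).

    Quantiles use linear interpolation between order statistics (R type 7).
    Duplicate breakpoints (heavy ties) are collapsed with a warning, yielding
    fewer effective classes.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if k < 2:
        raise ClimateGridError(f"k must be >= 2, got {k}")
    n_distinct = len(np.unique(x))
    if n_distinct < k:
        raise ClimateGridError(
            f"need at least {k} distinct values for {k} quantile classes, "
            f"got {n_distinct}"
        )
    breaks = np.quantile(x, np.linspace(0.0, 1.0, k + 1))
    dedup = np.unique(breaks)
    if len(dedup) < len(breaks):
        warnings.warn(
            f"collapsed {len(breaks) - len(dedup)} duplicate quantile "
            f"breakpoint(s); {len(dedup) - 1} effective classes instead of {k}",
            stacklevel=2,
        )
    return dedup


def assign_classes(values, breaks: np.ndarray) -> np.ndarray:
    """Map values to 1-based classes under the stated interval convention."""
    x = np.asarray(values, dtype=float)
    lo, hi = breaks[0], breaks[-1]
    out_of_range = (x < lo) | (x > hi)
    if np.any(out_of_range):
        bad = x[out_of_range][0]
        raise ClimateGridError(
            f"value {bad} outside breakpoint range [{lo}, {hi}]; "
            "breakpoints must come from the same data or an enclosing range"
        )
    # side='right': a value exactly at an interior breakpoint ascends.
    cls = np.searchsorted(breaks[1:-1], x, side="right") + 1
    return cls.astype(int)


def build_grid(table: PlotTable, k: int = 10) -> ClimateGrid:
    """Build breakpoints from the table's MAT/TAP and assign every plot."""
    require_nonempty(table, "build_grid")
    grid = ClimateGrid(
        mat_breaks=quantile_breaks(table.df["mat"], k),
        tap_breaks=quantile_breaks(table.df["tap"], k),
        k=k,
    )
    return assign_units(table, grid)


def assign_units(table: PlotTable, grid: ClimateGrid) -> ClimateGrid:
    """Populate ``grid.assignment`` for every (non-missing) plot in the table."""
    df = table.df
    ok = df["mat"].notna() & df["tap"].notna()
    mat_class = assign_classes(df.loc[ok, "mat"], grid.mat_breaks)
    tap_class = assign_classes(df.loc[ok, "tap"], grid.tap_breaks)
    grid.assignment = pd.DataFrame(
        {
            "plot_id": df.loc[ok, "plot_id"].to_numpy(),
            "mat_class": mat_class,
            "tap_class": tap_class,
            "unit": grid.unit_id(mat_class, tap_class),
        }
    )
    return grid


def aridity_class(aridity):
    """Aridity class label(s) from the aridity index.

    Scalar in, scalar out; array in, object array out. Values below 0.03 are
    labelled arid with a warning (the scale nominally starts at 0.03).
    """
    x = np.asarray(aridity, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x <= 0):
        raise ClimateGridError("aridity index must be positive")
    if np.any(x < ARIDITY_THRESHOLDS[0]):
        warnings.warn(
            "aridity value(s) below 0.03 labelled 'arid'", stacklevel=2
        )
    _, t_semi, t_dsh, t_humid = ARIDITY_THRESHOLDS
    labels = np.where(
        x >= t_humid,
        ARIDITY_CLASSES[3],
        np.where(x >= t_dsh, ARIDITY_CLASSES[2], np.where(x >= t_semi, ARIDITY_CLASSES[1], ARIDITY_CLASSES[0])),
    )
    return labels[0] if scalar else labels


def summarize_units(
    table: PlotTable, grid: ClimateGrid, aggregate: str = "mean"
) -> pd.DataFrame:
    """One row per populated unit: n, climate means, aridity class, log n.

    ``aggregate`` ('mean' or 'median') controls how per-plot aridity is
    reduced to the unit aridity used for classification; the unit is coloured
    as a whole so an aggregate is required.
    """
    if grid.assignment is None:
        raise ClimateGridError("grid has no assignment; call assign_units first")
    if aggregate not in ("mean", "median"):
        raise ClimateGridError(f"aggregate must be 'mean' or 'median', got {aggregate!r}")
    merged = table.df.merge(grid.assignment[["plot_id", "unit"]], on="plot_id")
    rows = []
    for unit, g in merged.groupby("unit", sort=True):
        agg = g["aridity"].mean() if aggregate == "mean" else g["aridity"].median()
        rows.append(
            {
                "unit": int(unit),
                "n_plots": len(g),
                "mean_mat": g["mat"].mean(),
                "mean_tap": g["tap"].mean(),
                "mean_aridity": agg,
                "aridity_class": aridity_class(agg) if np.isfinite(agg) else "NA",
                "log_n": float(np.log(len(g))),
            }
        )
    return pd.DataFrame(rows)
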