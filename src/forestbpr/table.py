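"""Plot-level forest-inventory tables: data model, I/O, derived variables, filtering.

The canonical table has one row per forest plot with columns
``plot_id, ecoregion, mat, tap, aridity, soil_cn, stem_density, stand_age,
agb, richness`` (and, after :func:`derive_productivity`, ``productivity``).
Units: ``mat`` degC, ``tap`` mm, ``stand_age`` years, ``agb`` above-ground
live biomass in the source's mass unit, ``productivity`` = agb / stand_age
(mass per year). ``richness`` is a tree species count (>= 1 on a forested
plot). Missing values are written as ``NA``; ``NA``, the empty string and
``NaN`` are accepted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Mandatory columns, in canonical order.
COLUMNS = [
    "plot_id",
    "ecoregion",
    "mat",
    "tap",
    "aridity",
    "soil_cn",
    "stem_density",
    "stand_age",
    "agb",
    "richness",
]

#: Numeric columns (everything except the two identifier/label columns).
NUMERIC_COLUMNS = COLUMNS[2:]

#: Tokens accepted as missing on read.
NA_TOKENS = ("NA", "", "NaN", "nan")

#: Units carried as metadata (the analysis is unit-covariant after logs).
DEFAULT_UNITS = {
    "mat": "degC",
    "tap": "mm",
    "aridity": "dimensionless",
    "soil_cn": "dimensionless",
    "stem_density": "stems/area",
    "stand_age": "yr",
    "agb": "mass",
    "richness": "species",
    "productivity": "mass/yr",
}


class PlotTableError(ValueError):
    """Raised for malformed plot tables (missing columns, bad cells...)."""


@dataclass
class PlotTable:
    """An ordered collection of plot records backed by a pandas DataFrame.

    ``df`` always contains the canonical columns (plus ``productivity`` once
    derived); unknown columns are preserved but ignored by the analysis.
    ``notes`` carries provenance (source path, generator seed, derivation
    reports).
    """

    df: pd.DataFrame
    units: dict = field(default_factory=lambda: dict(DEFAULT_UNITS))
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise PlotTableError(f"missing mandatory column(s): {missing}")
        ids = self.df["plot_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise PlotTableError(f"duplicate plot_id: {dup!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def columns(self) -> list:
        return list(self.df.columns)

    def copy(self) -> "PlotTable":
        return PlotTable(self.df.copy(), dict(self.units), dict(self.notes))


@dataclass
class FilterReport:
    """Row accounting for a complete-case filter."""

    n_input: int
    n_kept: int
    removed_per_column: dict

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept


def read_plot_table(path, dialect: str | None = None) -> PlotTable:
    """Read a delimited plot table (TSV by default, CSV accepted).

    ``dialect`` may be ``"tsv"``, ``"csv"`` or None (inferred from the file
    suffix, defaulting to TSV). Cells equal to one of :data:`NA_TOKENS` parse
    as missing. Malformed numeric cells raise with their 1-based file line
    numbers (header is line 1). Rows with richness == 0 (unforested plots)
    are dropped with a warning; the count is recorded in ``notes``.
    """
    sep = _resolve_sep(path, dialect)
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except OSError as exc:  # unreadable file
        raise
    except Exception as exc:
        raise PlotTableError(f"could not parse {path}: {exc}") from exc

    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise PlotTableError(
            f"{path}: missing mandatory column(s): {missing}"
        )

    df = raw.copy()
    bad: list[str] = []
    for col in NUMERIC_COLUMNS:
        cleaned = raw[col].str.strip()
        is_na = cleaned.isin(NA_TOKENS)
        parsed = pd.to_numeric(cleaned.where(~is_na), errors="coerce")
        malformed = parsed.isna() & ~is_na
        if malformed.any():
            for idx in np.flatnonzero(malformed.to_numpy())[:10]:
                # +2: 1-based numbering and the header row
                bad.append(f"column {col!r}, line {idx + 2}: {raw[col].iloc[idx]!r}")
        df[col] = parsed
    if bad:
        raise PlotTableError(f"{path}: malformed numeric cell(s): " + "; ".join(bad))

    df["richness"] = df["richness"].astype("Float64")
    unforested = (df["richness"] == 0).fillna(False)
    n_unforested = int(unforested.sum())
    if n_unforested:
        warnings.warn(
            f"{path}: dropped {n_unforested} row(s) with richness == 0 "
            "(unforested plots)",
            stacklevel=2,
        )
        df = df.loc[~unforested].reset_index(drop=True)

    notes = {"source": str(path), "n_unforested_dropped": n_unforested}
    return PlotTable(df, notes=notes)


def write_plot_table(table: PlotTable, path, dialect: str | None = None) -> None:
    """Write a plot table as delimited text with ``NA`` for missing values."""
    sep = _resolve_sep(path, dialect)
    table.df.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%.10g")


def derive_productivity(table: PlotTable) -> PlotTable:
    """Add ``productivity = agb / stand_age`` (mass per year).

    Rows with missing or non-positive ``stand_age`` get missing productivity;
    their count is recorded under ``notes["productivity_flagged"]``.
    """
    out = table.copy()
    age = out.df["stand_age"]
    agb = out.df["agb"]
    valid = age.notna() & (age > 0) & agb.notna()
    prod = pd.Series(np.nan, index=out.df.index, dtype=float)
    prod[valid] = agb[valid].astype(float) / age[valid].astype(float)
    out.df["productivity"] = prod
    out.notes["productivity_flagged"] = int((~valid).sum())
    out.units.setdefault("productivity", "mass/yr")
    return out


def filter_complete(
    table: PlotTable, required_columns: list | None = None
) -> tuple[PlotTable, FilterReport]:
    """Keep rows with no missing value in any required column (order preserved).

    Mirrors the exclusion of plots with missing covariates before analysis.
    The report counts, per column, how many rows had that cell missing among
    the removed rows (a row missing several cells is counted once per column).
    """
    required = list(required_columns) if required_columns is not None else list(COLUMNS)
    unknown = [c for c in required if c not in table.df.columns]
    if unknown:
        raise PlotTableError(f"required column(s) not in table: {unknown}")

    df = table.df
    missing_mask = df[required].isna()
    keep = ~missing_mask.any(axis=1)
    removed_per_column = {
        c: int(missing_mask.loc[~keep, c].sum())
        for c in required
        if missing_mask.loc[~keep, c].any()
    }
    out = table.copy()
    out.df = df.loc[keep].reset_index(drop=True)
    report = FilterReport(
        n_input=len(df), n_kept=int(keep.sum()), removed_per_column=removed_per_column
    )
    out.notes["filter_report"] = report
    return out, report


def require_nonempty(table: PlotTable, stage: str) -> None:
    """Refuse to hand an empty table to a downstream stage."""
    if len(table) == 0:
        raise PlotTableError(f"{stage}: empty plot table (all rows filtered?)")


def _resolve_sep(path, dialect: str | None) -> str:
    if dialect is not None:
        d = dialect.lower()
        if d == "tsv":
            return "\t"
        if d == "csv":
            return ","
        raise PlotTableError(f"unknown dialect {dialect!r} (use 'tsv' or 'csv')")
    return "," if str(path).lower().endswith(".csv") else "\t"
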