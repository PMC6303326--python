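"""End-to-end pipeline orchestration and figure/report generation.

Stages: simulate (optional) -> read/derive/filter -> bin -> bivariate ->
boundary -> hierarchical fit -> posterior classification -> report. Every
stage writes its output as delimited text under the configured output
directory; all randomness funnels through one base seed, so a rerun with the
same configuration is byte-identical (no timestamps in outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .bivariate import BPRType, bivariate_by_unit
from .boundary import BoundaryError, boundary_line, fit_type_boundary
from .classify import classify_all_posterior
from .climate import build_grid, summarize_units
from .hierarchical import McmcSettings, fit_all_units
from .table import (
    PlotTable,
    derive_productivity,
    filter_complete,
    read_plot_table,
    require_nonempty,
    write_plot_table,
)

log = logging.getLogger("forestbpr")

#: Fig-style colors per BPR type (also emitted in the plotted table).
BPR_COLORS = {
    BPRType.linear_positive.value: "#d7301f",
    BPRType.linear_negative.value: "#7b3294",
    BPRType.concave_negative.value: "#0571b0",
    BPRType.concave_positive.value: "#1a9641",
    BPRType.non_significant.value: "#bdbdbd",
}


class PipelineError(RuntimeError):
    """A stage precondition failed; carries the stage name and cause."""


@dataclass
class PipelineConfig:
    """Configuration for a full run (YAML-serializable; CLI can override)."""

    input_table: str | None = None  # path; exclusive with scenario
    scenario: str | None = "continental"
    n_plots: int = 20_000
    k: int = 10
    alpha: float = 0.05
    ci_level: float = 0.95
    mcmc_profile: str = "desk"  # 'desk' | 'paper'
    hbm_min_n: int = 30
    seed: int = 0
    out_dir: str = "forestbpr_out"
    run_bivariate: bool = True
    run_boundary: bool = True
    run_hbm: bool = False  # MCMC across all units is the expensive stage
    make_figure: bool = True

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.input_table is None and self.scenario is None:
            raise ValueError("need either input_table or scenario")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def fingerprint(self) -> str:
        """Hash of the analysis-relevant configuration (output paths excluded)."""
        d = asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    config_fingerprint: str
    counts: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    skipped_units: list = field(default_factory=list)
    non_converged_units: list = field(default_factory=list)

    def reconciles(self) -> bool:
        c = self.counts
        return c.get("rows_input", -1) == c.get("rows_kept", -2) + c.get("rows_removed", -3)


def mcmc_settings_for(profile: str, seed: int) -> McmcSettings:
    if profile == "desk":
        return McmcSettings.desk_profile(seed=seed)
    if profile == "paper":
        return McmcSettings(chains=3, iterations=100_000, burn_in=5_000, seed=seed)
    raise ValueError(f"unknown MCMC profile {profile!r} (use 'desk' or 'paper')")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages; write all outputs under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_fingerprint=config.fingerprint())

    def stage(name):
        log.info("stage: %s", name)
        report.stages.append(name)

    try:
        if config.input_table:
            stage("read")
            table = read_plot_table(config.input_table)
        else:
            stage("simulate")
            params = synthetic.default_params(
                config.scenario, n_plots=config.n_plots, seed=config.seed
            )
            table = synthetic.simulate(params=params)
            write_plot_table(table, out / "plots.tsv")
            synthetic.write_truth(table, out / "truth.json")
        report.counts["rows_input"] = len(table)

        stage("derive")
        table = derive_productivity(table)

        stage("filter")
        table, filt = filter_complete(table)
        report.counts["rows_kept"] = filt.n_kept
        report.counts["rows_removed"] = filt.n_removed
        require_nonempty(table, "filter")
        write_plot_table(table, out / "plots_complete.tsv")

        stage("bin")
        grid = build_grid(table, k=config.k)
        units = summarize_units(table, grid)
        report.counts["populated_units"] = len(units)
        units.to_csv(out / "units.tsv", sep="\t", index=False, float_format="%.10g")
        with open(out / "grid.json", "w") as fh:
            json.dump(grid.to_dict(), fh)

        bpr_units = None
        if config.run_bivariate:
            stage("bivariate")
            bpr_units = bivariate_by_unit(table, grid, alpha=config.alpha)
            report.counts["classified_units"] = len(bpr_units)
            bpr_units.to_csv(
                out / "bpr_units.tsv", sep="\t", index=False, float_format="%.10g"
            )

        bfit = None
        if config.run_boundary and bpr_units is not None:
            stage("boundary")
            try:
                bfit = fit_type_boundary(units, bpr_units)
                mat_grid = np.linspace(
                    float(table.df["mat"].min()), float(table.df["mat"].max()), 50
                )
                line = boundary_line(bfit, mat_grid)
                line.to_csv(
                    out / "boundary.tsv", sep="\t", index=False, float_format="%.10g"
                )
                pd.DataFrame(
                    [
                        {
                            "intercept": bfit.intercept,
                            "coef_mat": bfit.coef_mat,
                            "coef_tap": bfit.coef_tap,
                            "penalized": bfit.penalized,
                            "separation": bfit.separation,
                        }
                    ]
                ).to_csv(
                    out / "boundary_coefficients.tsv",
                    sep="\t",
                    index=False,
                    float_format="%.10g",
                )
            except BoundaryError as exc:
                log.warning("boundary stage skipped: %s", exc)
                report.counts["boundary_skipped"] = 1

        if config.run_hbm:
            stage("hbm")
            settings = mcmc_settings_for(config.mcmc_profile, config.seed)
            summaries, hbm_report = fit_all_units(
                table,
                grid,
                settings=settings,
                min_n=config.hbm_min_n,
                ci_level=config.ci_level,
            )
            hbm_report.to_csv(out / "hbm_report.tsv", sep="\t", index=False)
            report.skipped_units = hbm_report.loc[
                hbm_report["status"] == "skipped", "unit"
            ].tolist()
            report.non_converged_units = hbm_report.loc[
                hbm_report["status"] == "non-converged", "unit"
            ].tolist()
            rows = []
            for unit, s in sorted(summaries.items()):
                t = s.table.copy()
                t.insert(0, "unit", unit)
                rows.append(t)
            if rows:
                pd.concat(rows, ignore_index=True).to_csv(
                    out / "posterior.tsv", sep="\t", index=False, float_format="%.8g"
                )
            stage("classify")
            post = classify_all_posterior(summaries, level=config.ci_level)
            post.to_csv(
                out / "bpr_posterior.tsv", sep="\t", index=False, float_format="%.10g"
            )

        if config.make_figure and bpr_units is not None:
            stage("figure")
            typed_units = units.merge(bpr_units[["unit", "bpr_type"]], on="unit")
            render_climate_figure(typed_units, bfit, out / "climate_figure.png")
            # numeric figure inputs also go out as a table: tests never read pixels
            plotted = typed_units.assign(
                color=typed_units["bpr_type"].map(BPR_COLORS),
                radius=typed_units["log_n"],
            )
            plotted.to_csv(
                out / "climate_figure_table.tsv",
                sep="\t",
                index=False,
                float_format="%.10g",
            )

        stage("report")
        with open(out / "run_report.json", "w") as fh:
            json.dump(
                {
                    "config_fingerprint": report.config_fingerprint,
                    "counts": report.counts,
                    "stages": report.stages,
                    "skipped_units": report.skipped_units,
                    "non_converged_units": report.non_converged_units,
                },
                fh,
                indent=1,
            )
    except PipelineError:
        raise
    except Exception as exc:
        current = report.stages[-1] if report.stages else "init"
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc
    return report


def render_climate_figure(typed_units: pd.DataFrame, boundary_fit, path) -> None:
    """Scatter of units in MAT-TAP space: radius ~ log n, color = BPR type."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if typed_units.empty:
        raise ValueError("empty unit table; nothing to render")
    fig, ax = plt.subplots(figsize=(7, 5))
    for bpr, g in typed_units.groupby("bpr_type"):
        ax.scatter(
            g["mean_mat"],
            g["mean_tap"],
            s=40 * np.maximum(g["log_n"], 0.3),
            c=BPR_COLORS.get(bpr, "#000000"),
            label=bpr,
            alpha=0.8,
            edgecolors="none",
        )
    if boundary_fit is not None and boundary_fit.coef_tap != 0:
        mat_grid = np.linspace(
            typed_units["mean_mat"].min(), typed_units["mean_mat"].max(), 50
        )
        line = boundary_line(boundary_fit, mat_grid)
        ax.plot(line["mat"], line["tap"], "k--", lw=1.5, label="type boundary")
    ax.set_xlabel("mean annual temperature (degC)")
    ax.set_ylabel("total annual precipitation (mm)")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
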