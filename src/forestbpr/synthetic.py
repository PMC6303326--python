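"""Synthetic FIA-like plot generator with known structural truth.

Generates plot tables with the exact statistical structure the analysis
assumes — correlated truncated-normal climate, ecoregion clustering in
climate space, normal log density / log age / log soil C:N responses to
climate, Poisson species richness with a log link, and lognormal
productivity with a climate-dependent (linear or hump-shaped) richness
effect — so every downstream stage can be tested against stored truth
without external data.

Scenario presets
----------------
``null``          all 18 structural slopes zero (noise and ecoregion
                  intercepts remain): the type-I-error control condition.
``dry_positive``  positive linear richness effect everywhere, no quadratic.
``mesic_hump``    negative quadratic richness effect everywhere.
``continental``   climate spanning MAT -3.8..23.9 degC and TAP 79..3375 mm
                  with a logistic regime blend in the aridity index:
                  arid/semi-arid plots get the pure linear-positive effect,
                  humid plots the pure hump, with a smooth transition
                  centered mid dry-sub-humid (aridity 0.575).

Richness effects are planted on the 2-SD-standardized richness scale (the
scale the hierarchical model estimates on): the contribution to log
productivity is ``b17* z + b18* z^2`` with ``z = (S - mean S)/(2 sd S)``
over the generated table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .hierarchical import EDGE_NAMES, EDGES
from .table import COLUMNS, PlotTable

SCENARIOS = ("null", "dry_positive", "mesic_hump", "continental")

#: Potential-evapotranspiration proxy: PET(MAT) = PET0 + PET_SLOPE * MAT (mm).
#: The aridity index is TAP / PET — monotone increasing in TAP, decreasing in
#: MAT, and positive over the supported MAT range.
PET0 = 500.0
PET_SLOPE = 60.0

#: Sub-model intercepts on the response (log/link) scale: ~800 stems, 60 yr
#: stands, soil C:N 15, 10 species, productivity 2.5 mass/yr.
DEFAULT_INTERCEPTS = {
    "density": float(np.log(800.0)),
    "age": float(np.log(60.0)),
    "soil_cn": float(np.log(15.0)),
    "richness": float(np.log(10.0)),
    "productivity": float(np.log(2.5)),
}

#: Residual SDs per normal sub-model (log scale).
DEFAULT_NOISE_SDS = {"density": 0.5, "age": 0.6, "soil_cn": 0.25, "productivity": 0.35}

#: Default structural slopes (2-SD-standardized predictor scale). Climate
#: effects follow the broad empirical pattern: density down with MAT and up
#: with TAP, richness up with both, productivity declining with stand age
#: (it is biomass / age).
DEFAULT_BETAS = {
    "mat->density": -0.3,
    "tap->density": 0.3,
    "mat->age": -0.1,
    "tap->age": 0.1,
    "mat->soil_cn": -0.15,
    "tap->soil_cn": 0.1,
    "mat->richness": 0.3,
    "tap->richness": 0.5,
    "log_density->richness": 0.2,
    "log_age->richness": 0.2,
    "log_cn->richness": -0.1,
    "mat->productivity": 0.2,
    "tap->productivity": 0.3,
    "log_density->productivity": 0.3,
    "log_age->productivity": -0.4,
    "log_cn->productivity": -0.1,
}

#: Planted richness-effect magnitudes (standardized scale).
B17_DRY = 0.9
B18_MESIC = -1.0


def aridity_index(mat, tap) -> np.ndarray:
    """Deterministic aridity proxy TAP / PET(MAT) (higher = wetter)."""
    return np.asarray(tap, float) / (PET0 + PET_SLOPE * np.asarray(mat, float))


@dataclass(frozen=True)
class RegimeMap:
    """Maps a plot's (MAT, TAP) to its true richness-effect pair (b17*, b18*).

    ``constant`` kind applies (b17, b18) everywhere. ``logistic_aridity``
    blends a dry regime (b17_dry, 0) into a mesic regime (0, b18_mesic) with
    a logistic weight in the aridity index; weights outside [clip, 1-clip]
    snap to exactly 0/1 so the planted truth is exact away from the
    transition zone.
    """

    kind: str = "constant"
    b17: float = 0.0
    b18: float = 0.0
    b17_dry: float = B17_DRY
    b18_mesic: float = B18_MESIC
    center: float = 0.575
    width: float = 0.025
    clip: float = 0.05

    def __call__(self, mat, tap) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns (b17*, b18*, mesic weight w) elementwise."""
        mat = np.asarray(mat, float)
        if self.kind == "constant":
            shape = mat.shape
            return (
                np.full(shape, self.b17),
                np.full(shape, self.b18),
                np.zeros(shape),
            )
        if self.kind != "logistic_aridity":
            raise ValueError(f"unknown regime map kind {self.kind!r}")
        ai = aridity_index(mat, tap)
        w = 1.0 / (1.0 + np.exp(-(ai - self.center) / self.width))
        w = np.where(w < self.clip, 0.0, np.where(w > 1.0 - self.clip, 1.0, w))
        return (1.0 - w) * self.b17_dry, w * self.b18_mesic, w

    def boundary_tap(self, mat) -> np.ndarray:
        """TAP of the planted regime boundary (w = 0.5) at the given MAT."""
        if self.kind != "logistic_aridity":
            raise ValueError("only logistic_aridity maps have a planted boundary")
        return self.center * (PET0 + PET_SLOPE * np.asarray(mat, float))


@dataclass
class GeneratorParams:
    """Everything the generator needs, including the structural truth."""

    n_plots: int = 10_000
    n_ecoregions: int = 194  # the empirical US ecoregion count
    mat_range: tuple = (-3.8, 23.9)
    tap_range: tuple = (79.0, 3375.0)
    #: cloud location/spread before truncation; None = mid-range / span/5
    mat_mean: float | None = None
    mat_sd: float | None = None
    tap_mean: float | None = None
    tap_sd: float | None = None
    climate_correlation: float = 0.3
    #: SD of the latent "geography" jitter (in standardized-climate units)
    #: added before clustering plots into ecoregions. Ecoregions align only
    #: loosely with climate, so plots of one climatic unit span many
    #: ecoregions — the premise of the ecoregion random intercept.
    eco_geo_jitter: float = 1.0
    ecoregion_sd: float = 0.2
    structural_betas: dict = field(default_factory=lambda: dict(DEFAULT_BETAS))
    regime_map: RegimeMap = field(default_factory=RegimeMap)
    intercepts: dict = field(default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    noise_sds: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SDS))
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        if self.n_ecoregions < 1:
            raise ValueError("n_ecoregions must be >= 1")
        for name, rng_ in (("mat_range", self.mat_range), ("tap_range", self.tap_range)):
            if not rng_[0] < rng_[1]:
                raise ValueError(f"{name} must be an ordered (low, high) pair")
        if not -1.0 < self.climate_correlation < 1.0:
            raise ValueError("climate_correlation must be in (-1, 1)")
        if self.ecoregion_sd < 0:
            raise ValueError("ecoregion_sd must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        wanted = {EDGE_NAMES[label] for label, *_ in EDGES}
        have = set(self.structural_betas)
        # b17/b18 live in the regime map; the dict carries the other 16
        fixed = wanted - {"richness->productivity", "richness_sq->productivity"}
        if have != fixed:
            raise ValueError(
                f"structural_betas must have exactly the 16 non-richness edges; "
                f"missing {sorted(fixed - have)}, unexpected {sorted(have - fixed)}"
            )

    def n_structural_slopes(self) -> int:
        """16 fixed slopes + the two regime-mapped richness effects."""
        return len(self.structural_betas) + 2


def default_params(scenario: str, **overrides) -> GeneratorParams:
    """Preset generator parameters for a named scenario."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; valid scenarios: {SCENARIOS}")
    kw: dict = {}
    if scenario == "null":
        # a true null for the richness-productivity margin: no structural
        # effects and no shared spatial heterogeneity, so the classifier's
        # false-positive rate is its nominal one
        kw["structural_betas"] = {k: 0.0 for k in DEFAULT_BETAS}
        kw["regime_map"] = RegimeMap(kind="constant", b17=0.0, b18=0.0)
        kw["ecoregion_sd"] = 0.0
    elif scenario == "dry_positive":
        kw["regime_map"] = RegimeMap(kind="constant", b17=B17_DRY, b18=0.0)
    elif scenario == "mesic_hump":
        kw["regime_map"] = RegimeMap(kind="constant", b17=0.0, b18=B18_MESIC)
    else:  # continental
        kw["regime_map"] = RegimeMap(kind="logistic_aridity")
        kw["missing_rate"] = 0.02
        # drier, wider precipitation cloud so every aridity class (arid ..
        # humid) is represented, as in the empirical plot distribution
        kw.update(mat_mean=10.0, mat_sd=5.5, tap_mean=900.0, tap_sd=700.0)
    kw.update(overrides)
    return GeneratorParams(**kw)


def generate_climate(params: GeneratorParams) -> PlotTable:
    """Climate-only table: correlated truncated-normal (MAT, TAP) + ecoregions.

    MAT and TAP are drawn from a bivariate normal centered mid-range with SD
    = span/5 and the configured correlation, rejection-sampled into the
    stated ranges; the aridity index is the deterministic TAP/PET(MAT)
    transform; ecoregions are k-means clusters in standardized climate space.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    n = params.n_plots
    lo = np.array([params.mat_range[0], params.tap_range[0]])
    hi = np.array([params.mat_range[1], params.tap_range[1]])
    mid, span5 = (lo + hi) / 2.0, (hi - lo) / 5.0
    mean = np.array(
        [
            mid[0] if params.mat_mean is None else params.mat_mean,
            mid[1] if params.tap_mean is None else params.tap_mean,
        ]
    )
    sd = np.array(
        [
            span5[0] if params.mat_sd is None else params.mat_sd,
            span5[1] if params.tap_sd is None else params.tap_sd,
        ]
    )
    rho = params.climate_correlation
    cov = np.array(
        [
            [sd[0] ** 2, rho * sd[0] * sd[1]],
            [rho * sd[0] * sd[1], sd[1] ** 2],
        ]
    )
    out = np.empty((0, 2))
    while len(out) < n:
        draw = rng.multivariate_normal(mean, cov, size=max(2 * (n - len(out)), 1000))
        keep = np.all((draw >= lo) & (draw <= hi), axis=1)
        out = np.vstack([out, draw[keep]])
    mat, tap = out[:n, 0], out[:n, 1]

    if params.n_ecoregions == 1:
        eco_codes = np.zeros(n, dtype=int)
    else:
        Z = np.column_stack([(mat - mat.mean()) / mat.std(), (tap - tap.mean()) / tap.std()])
        Z = Z + params.eco_geo_jitter * rng.standard_normal(Z.shape)
        km = KMeans(
            n_clusters=min(params.n_ecoregions, n),
            n_init=4,
            random_state=int(rng.integers(2**31 - 1)),
        )
        eco_codes = km.fit_predict(Z)

    width = len(str(n))
    df = pd.DataFrame(
        {
            "plot_id": [f"p{i + 1:0{width}d}" for i in range(n)],
            "ecoregion": [f"eco{c + 1:03d}" for c in eco_codes],
            "mat": mat,
            "tap": tap,
            "aridity": aridity_index(mat, tap),
        }
    )
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    table = PlotTable(df[COLUMNS])
    table.notes["generator_seed"] = params.seed
    table.notes["scenario_regime"] = params.regime_map.kind
    return table


def _standardize2(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    m = float(np.mean(x))
    s = float(np.std(x, ddof=1))
    if s == 0:
        return np.zeros_like(x), m, s
    return (x - m) / (2.0 * s), m, s


def generate_plots(climate: PlotTable, params: GeneratorParams) -> PlotTable:
    """Complete the table: stand structure, soil, richness, biomass, missingness.

    Simulation follows the causal order of the structural model; the realized
    truth (slopes, intercept draws, per-plot regime coefficients, richness
    standardization constants) is stored under ``table.notes["truth"]`` for
    recovery tests. Biomass is back-computed as productivity x stand age, so
    the productivity derivation downstream is an exact inverse.
    """
    for col in ("mat", "tap", "ecoregion"):
        if col not in climate.df.columns or climate.df[col].isna().all():
            raise ValueError(f"climate table lacks populated column {col!r}")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    df = climate.df.copy()
    n = len(df)
    mat = df["mat"].to_numpy(float)
    tap = df["tap"].to_numpy(float)
    eco_codes, eco_labels = pd.factorize(df["ecoregion"], sort=True)
    E = len(eco_labels)
    b = {EDGE_BY_DST[k]: v for k, v in params.structural_betas.items()}  # b-label keyed
    ic = params.intercepts
    ns = params.noise_sds

    z_mat, *_ = _standardize2(mat)
    z_tap, *_ = _standardize2(tap)

    # independent ecoregion intercepts per sub-model
    u = {
        name: rng.normal(0.0, params.ecoregion_sd, size=E)
        for name in ("density", "age", "soil_cn", "richness", "productivity")
    }

    log_density = (
        ic["density"]
        + b["b1"] * z_mat
        + b["b2"] * z_tap
        + u["density"][eco_codes]
        + rng.normal(0.0, ns["density"], n)
    )
    log_age = (
        ic["age"]
        + b["b3"] * z_mat
        + b["b4"] * z_tap
        + u["age"][eco_codes]
        + rng.normal(0.0, ns["age"], n)
    )
    log_cn = (
        ic["soil_cn"]
        + b["b5"] * z_mat
        + b["b6"] * z_tap
        + u["soil_cn"][eco_codes]
        + rng.normal(0.0, ns["soil_cn"], n)
    )
    z_ld, *_ = _standardize2(log_density)
    z_la, *_ = _standardize2(log_age)
    z_lc, *_ = _standardize2(log_cn)

    log_lam = (
        ic["richness"]
        + b["b7"] * z_mat
        + b["b8"] * z_tap
        + b["b9"] * z_ld
        + b["b10"] * z_la
        + b["b11"] * z_lc
        + u["richness"][eco_codes]
    )
    richness = np.maximum(1, rng.poisson(np.exp(np.clip(log_lam, -20, 20)))).astype(float)

    z_rich, rich_mean, rich_sd = _standardize2(richness)
    b17_star, b18_star, regime_w = params.regime_map(mat, tap)
    log_prod = (
        ic["productivity"]
        + b["b12"] * z_mat
        + b["b13"] * z_tap
        + b["b14"] * z_ld
        + b["b15"] * z_la
        + b["b16"] * z_lc
        + b17_star * z_rich
        + b18_star * z_rich**2
        + u["productivity"][eco_codes]
        + rng.normal(0.0, ns["productivity"], n)
    )
    productivity = np.exp(log_prod)
    stand_age = np.exp(log_age)

    out = df.copy()
    out["soil_cn"] = np.exp(log_cn)
    out["stem_density"] = np.exp(log_density)
    out["stand_age"] = stand_age
    out["agb"] = productivity * stand_age
    out["richness"] = richness

    if params.missing_rate > 0:
        miss_cols = ["mat", "tap", "aridity", "soil_cn", "stem_density", "stand_age"]
        mask = rng.random((n, len(miss_cols))) < params.missing_rate
        for j, col in enumerate(miss_cols):
            out.loc[mask[:, j], col] = np.nan

    table = PlotTable(out, notes=dict(climate.notes))
    table.notes["truth"] = {
        "params": params_to_dict(params),
        "ecoregion_intercepts": {k: v.tolist() for k, v in u.items()},
        "richness_scaling": {"mean": rich_mean, "sd": rich_sd},
        "b17_star": b17_star,
        "b18_star": b18_star,
        "regime_weight": regime_w,
    }
    return table


def simulate(
    scenario: str | None = None, params: GeneratorParams | None = None, **overrides
) -> PlotTable:
    """Convenience: default_params + generate_climate + generate_plots."""
    if params is None:
        params = default_params(scenario or "continental", **overrides)
    return generate_plots(generate_climate(params), params)


def params_to_dict(params: GeneratorParams) -> dict:
    d = asdict(params)
    d["regime_map"] = asdict(params.regime_map)
    return d


def write_truth(table: PlotTable, path) -> None:
    """Serialize the stored generative truth (params + per-plot regime) as JSON."""
    truth = table.notes.get("truth")
    if truth is None:
        raise ValueError("table carries no generator truth")
    ser = dict(truth)
    for key in ("b17_star", "b18_star", "regime_weight"):
        ser[key] = np.asarray(truth[key]).tolist()
    with open(path, "w") as fh:
        json.dump(ser, fh, indent=1)


#: edge-name -> b-label lookup used when applying structural betas
EDGE_BY_DST = {name: label for label, name in EDGE_NAMES.items()}
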