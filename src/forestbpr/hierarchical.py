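"""Hierarchical Bayesian BPR model: five sub-models, 18 slopes, ecoregion intercepts.

Within one climatic unit the system is, in causal order (responses on the
left, every predictor 2-SD standardized, density/age/soil C:N/productivity
log-transformed first):

* ``log density     ~ N(a_d + b1*MAT + b2*TAP + u_d[eco], sigma_d)``
* ``log age         ~ N(a_a + b3*MAT + b4*TAP + u_a[eco], sigma_a)``
* ``log soil C:N    ~ N(a_c + b5*MAT + b6*TAP + u_c[eco], sigma_c)``
* ``richness        ~ Poisson(exp(a_r + b7*MAT + ... + b11*soilCN + u_r[eco]))``
* ``log productivity~ N(a_p + b12*MAT + ... + b16*soilCN
  + b17*richness + b18*richness^2 + u_p[eco], sigma_p)``

Richness is standardized first and then squared, so b17/b18 are interpretable
at the richness mean. Each sub-model has its own ecoregion random intercept
``u[eco] ~ N(0, sigma_u)`` (non-centered in the sampler). Priors: N(0,
variance 1000) on intercepts and slopes; half-normal on the random-intercept
and residual SDs (their priors are an open modelling choice, kept weakly
informative on the standardized scale and configurable).

The five sub-models share no parameters, so the joint posterior factorizes
and they are sampled independently — with `emcee`'s affine-invariant
ensemble sampler, three independent seeded runs standing in for the three
parallel chains. A fit is flagged non-converged when any monitored
coefficient has split-Rhat > 1.05 or effective sample size < 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln

from .climate import ClimateGrid
from .table import PlotTable

__all__ = [
    "EDGES",
    "SLOPE_NAMES",
    "ModelGraph",
    "PriorSpec",
    "McmcSettings",
    "SubModel",
    "HierarchicalModel",
    "PosteriorSummary",
    "default_graph",
    "standardize_predictors",
    "build_model",
    "sample_submodel",
    "sample_posterior",
    "fit_all_units",
]

#: The 18 structural slope edges (label, source node, target sub-model).
EDGES = [
    ("b1", "mat", "density"),
    ("b2", "tap", "density"),
    ("b3", "mat", "age"),
    ("b4", "tap", "age"),
    ("b5", "mat", "soil_cn"),
    ("b6", "tap", "soil_cn"),
    ("b7", "mat", "richness"),
    ("b8", "tap", "richness"),
    ("b9", "log_density", "richness"),
    ("b10", "log_age", "richness"),
    ("b11", "log_cn", "richness"),
    ("b12", "mat", "productivity"),
    ("b13", "tap", "productivity"),
    ("b14", "log_density", "productivity"),
    ("b15", "log_age", "productivity"),
    ("b16", "log_cn", "productivity"),
    ("b17", "richness", "productivity"),
    ("b18", "richness_sq", "productivity"),
]

SLOPE_NAMES = [e[0] for e in EDGES]

#: Human-readable edge names, usable as structural-beta keys.
EDGE_NAMES = {label: f"{src}->{dst}" for label, src, dst in EDGES}
EDGE_BY_NAME = {v: k for k, v in EDGE_NAMES.items()}


class ModelBuildError(ValueError):
    """Raised when a unit table cannot support the hierarchical model."""


@dataclass(frozen=True)
class SubmodelSpec:
    name: str
    response: str  # column of the (derived) unit table
    family: str  # 'normal' | 'poisson'
    predictors: tuple  # predictor node names, order fixes the slope order
    slopes: tuple  # b-labels, aligned with predictors


def default_graph() -> "ModelGraph":
    return ModelGraph(
        submodels=(
            SubmodelSpec("density", "log_density", "normal", ("mat", "tap"), ("b1", "b2")),
            SubmodelSpec("age", "log_age", "normal", ("mat", "tap"), ("b3", "b4")),
            SubmodelSpec("soil_cn", "log_cn", "normal", ("mat", "tap"), ("b5", "b6")),
            SubmodelSpec(
                "richness",
                "richness",
                "poisson",
                ("mat", "tap", "log_density", "log_age", "log_cn"),
                ("b7", "b8", "b9", "b10", "b11"),
            ),
            SubmodelSpec(
                "productivity",
                "log_productivity",
                "normal",
                ("mat", "tap", "log_density", "log_age", "log_cn", "richness", "richness_sq"),
                ("b12", "b13", "b14", "b15", "b16", "b17", "b18"),
            ),
        )
    )


@dataclass(frozen=True)
class ModelGraph:
    """The five-sub-model structure with its 18 labelled slope edges."""

    submodels: tuple

    @property
    def n_submodels(self) -> int:
        return len(self.submodels)

    @property
    def slope_names(self) -> list:
        return [b for s in self.submodels for b in s.slopes]

    @property
    def n_slopes(self) -> int:
        return len(self.slope_names)

    def validate(self) -> None:
        names = self.slope_names
        if len(set(names)) != len(names):
            raise ModelBuildError("duplicate slope labels in graph")
        # causal (acyclic) order: a sub-model may only use nodes produced
        # earlier (climate is exogenous)
        produced = {"mat", "tap"}
        response_node = {
            "log_density": "log_density",
            "log_age": "log_age",
            "log_cn": "log_cn",
            "richness": "richness",
            "log_productivity": "log_productivity",
        }
        for s in self.submodels:
            for p in s.predictors:
                base = p[:-3] if p.endswith("_sq") else p
                if base not in produced:
                    raise ModelBuildError(
                        f"sub-model {s.name} uses {p} before it is produced (cycle?)"
                    )
            produced.add(response_node[s.response])


@dataclass(frozen=True)
class PriorSpec:
    """Priors: N(0, slope_variance) on intercepts/slopes, half-normal SDs."""

    slope_variance: float = 1000.0
    re_sd_scale: float = 1.0
    resid_sd_scale: float = 1.0

    def __post_init__(self):
        if min(self.slope_variance, self.re_sd_scale, self.resid_sd_scale) <= 0:
            raise ValueError("all prior variances/scales must be positive")


@dataclass(frozen=True)
class McmcSettings:
    """Ensemble-MCMC settings; ``iterations`` are ensemble steps per chain."""

    chains: int = 3
    iterations: int = 100_000
    burn_in: int = 5_000
    thinning: int = 1
    seed: int = 0
    nwalkers: int | None = None  # default: 2 * ndim (even), min 16

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")

    @classmethod
    def desk_profile(cls, seed: int = 0) -> "McmcSettings":
        """Reduced settings for desk-scale runs: 3 chains x 2000, 500 burn-in."""
        return cls(chains=3, iterations=2_000, burn_in=500, seed=seed)


def standardize_predictors(values) -> tuple[np.ndarray, float, float]:
    """2-SD standardization: (x - mean) / (2 * sd), sd with n-1 denominator.

    Returns (standardized, mean, sd) so the transform can be inverted; the
    output has mean 0 and sample SD 0.5, making a 1-unit change span roughly
    the central 95% of the predictor's range and effect sizes comparable
    across predictors.
    """
    x = np.asarray(values, dtype=float)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("cannot standardize a constant predictor")
    return (x - mean) / (2.0 * sd), mean, sd


# ---------------------------------------------------------------------------
# sub-model container and log-density
# ---------------------------------------------------------------------------


@dataclass
class SubModel:
    """One regression of the system, ready for sampling.

    Parameter vector layout: ``[intercept, beta_1..p, (log_sigma_u, z_1..E
    when E > 1), (log_sigma for normal families)]`` with the random intercept
    non-centered (u = sigma_u * z).
    """

    name: str
    family: str  # 'normal' | 'poisson'
    y: np.ndarray
    X: np.ndarray  # (n, p); p may be 0
    groups: np.ndarray | None  # ecoregion codes 0..E-1, or None (single group)
    n_groups: int
    slope_names: tuple
    priors: PriorSpec
    _group_onehot: np.ndarray | None = None
    _group_sizes: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def has_re(self) -> bool:
        return self.groups is not None and self.n_groups > 1

    @property
    def ndim(self) -> int:
        d = 1 + self.p
        if self.has_re:
            d += 1 + self.n_groups
        if self.family == "normal":
            d += 1
        return d

    @property
    def param_names(self) -> list:
        names = [f"intercept:{self.name}"] + list(self.slope_names)
        if self.has_re:
            names += [f"sigma_u:{self.name}"] + [
                f"u[{g}]:{self.name}" for g in range(self.n_groups)
            ]
        if self.family == "normal":
            names += [f"sigma:{self.name}"]
        return names

    # -- packing ------------------------------------------------------------
    def pack(self, intercept, beta, sigma=None, sigma_u=None, z=None) -> np.ndarray:
        parts = [np.atleast_1d(float(intercept)), np.atleast_1d(np.asarray(beta, float))]
        if self.has_re:
            parts += [np.atleast_1d(np.log(float(sigma_u))), np.asarray(z, float)]
        if self.family == "normal":
            parts += [np.atleast_1d(np.log(float(sigma)))]
        return np.concatenate([p for p in parts if p.size])

    def unpack(self, theta: np.ndarray) -> dict:
        theta = np.atleast_2d(theta)
        i = 0
        out = {"intercept": theta[:, 0]}
        i = 1
        out["beta"] = theta[:, i : i + self.p]
        i += self.p
        if self.has_re:
            out["sigma_u"] = np.exp(theta[:, i])
            out["z"] = theta[:, i + 1 : i + 1 + self.n_groups]
            i += 1 + self.n_groups
        if self.family == "normal":
            out["sigma"] = np.exp(theta[:, i])
        return out

    # -- log density --------------------------------------------------------
    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        """Vectorized joint log-density (likelihood + priors) for walkers."""
        theta = np.atleast_2d(np.asarray(theta, float))
        q = self.unpack(theta)
        W = theta.shape[0]
        pr = self.priors

        eta = q["intercept"][None, :] + (
            self.X @ q["beta"].T if self.p else 0.0
        )  # (n, W)
        lp = np.zeros(W)

        # slope/intercept priors: N(0, slope_variance)
        coefs = np.column_stack([q["intercept"], q["beta"]]) if self.p else q[
            "intercept"
        ].reshape(-1, 1)
        lp += -0.5 * np.sum(coefs**2, axis=1) / pr.slope_variance
        lp += -0.5 * coefs.shape[1] * np.log(2 * np.pi * pr.slope_variance)

        if self.has_re:
            sigma_u = q["sigma_u"]
            z = q["z"]
            u = sigma_u[:, None] * z  # (W, E)
            eta = eta + u.T[self.groups, :]
            # z ~ N(0,1)
            lp += -0.5 * np.sum(z**2, axis=1) - 0.5 * self.n_groups * np.log(2 * np.pi)
            # sigma_u ~ half-normal(re_sd_scale), + Jacobian of log transform
            lp += _halfnormal_logpdf(sigma_u, pr.re_sd_scale) + np.log(sigma_u)

        if self.family == "normal":
            sigma = q["sigma"]
            resid = self.y[:, None] - eta
            lp += (
                -0.5 * np.sum(resid**2, axis=0) / sigma**2
                - self.n * np.log(sigma)
                - 0.5 * self.n * np.log(2 * np.pi)
            )
            lp += _halfnormal_logpdf(sigma, pr.resid_sd_scale) + np.log(sigma)
        elif self.family == "poisson":
            eta_c = np.clip(eta, -50.0, 50.0)
            lp += np.sum(
                self.y[:, None] * eta_c - np.exp(eta_c) - gammaln(self.y + 1.0)[:, None],
                axis=0,
            )
        else:  # pragma: no cover
            raise ValueError(f"unknown family {self.family!r}")
        return lp if theta.shape[0] > 1 else lp

    # -- sampling parameterization ------------------------------------------
    #
    # Sub-models with a random intercept are sampled on the marginalized
    # scale: u is integrated out — analytically for normal responses
    # (per-group compound-symmetry covariance), by adaptive-free
    # Gauss-Hermite quadrature for Poisson responses (each group's
    # likelihood depends on u only through sum(y) and sum(exp(eta)), so the
    # 1-D integral is cheap and accurate). This removes the funnel geometry
    # and cuts the sampling dimension to p + 2..3. The z-explicit log_prob
    # above remains the reference joint density.

    @property
    def marginalized(self) -> bool:
        return self.has_re

    @property
    def sampling_ndim(self) -> int:
        if self.marginalized:
            return 1 + self.p + 1 + (1 if self.family == "normal" else 0)
        return self.ndim

    @property
    def sampling_param_names(self) -> list:
        if self.marginalized:
            names = [f"intercept:{self.name}"] + list(self.slope_names)
            names.append(f"sigma_u:{self.name}")
            if self.family == "normal":
                names.append(f"sigma:{self.name}")
            return names
        return self.param_names

    def _group_arrays(self):
        if self._group_onehot is None:
            G = np.zeros((self.n_groups, self.n))
            G[self.groups, np.arange(self.n)] = 1.0
            self._group_onehot = G
            self._group_sizes = G.sum(axis=1)
        return self._group_onehot, self._group_sizes

    def sampling_log_prob(self, theta: np.ndarray) -> np.ndarray:
        if not self.marginalized:
            return self.log_prob(theta)
        theta = np.atleast_2d(np.asarray(theta, float))
        pr = self.priors
        intercept = theta[:, 0]
        beta = theta[:, 1 : 1 + self.p]
        sigma_u = np.exp(theta[:, 1 + self.p])
        G, ng_flat = self._group_arrays()

        eta = intercept[None, :] + (self.X @ beta.T if self.p else 0.0)  # (n, W)

        if self.family == "normal":
            sigma = np.exp(theta[:, 2 + self.p])
            resid = self.y[:, None] - eta
            gsum = G @ resid  # (E, W)
            ng = ng_flat[:, None]
            s2, su2 = sigma**2, sigma_u**2
            denom = s2[None, :] + ng * su2[None, :]
            logdet = (self.n - self.n_groups) * np.log(s2) + np.sum(
                np.log(denom), axis=0
            )
            quad = np.sum(resid**2, axis=0) / s2 - np.sum(
                su2[None, :] * gsum**2 / (s2[None, :] * denom), axis=0
            )
            lp = -0.5 * (self.n * np.log(2 * np.pi) + logdet + quad)
            lp += _halfnormal_logpdf(sigma, pr.resid_sd_scale) + np.log(sigma)
        else:  # poisson: adaptive Gauss-Hermite marginalization of u per group
            eta_c = np.clip(eta, -50.0, 50.0)
            W = eta.shape[1]
            A = (G @ self.y)[:, None] * np.ones((1, W))  # (E, W) sum y
            T = G @ (self.y[:, None] * eta_c)  # (E, W) sum y*eta
            S = G @ np.exp(eta_c)  # (E, W) sum exp(eta)
            su2 = np.maximum(sigma_u**2, 1e-12)[None, :]
            # integrand g(u) = T + A*u - S*e^u - u^2/(2 su2) - log(su*sqrt(2pi));
            # Newton for the mode: g'(u) = A - S e^u - u/su2
            u_hat = np.log(np.maximum(A, 0.5) / S)  # start near Poisson mode
            for _ in range(30):
                eu = np.exp(np.clip(u_hat, -60, 60))
                grad = A - S * eu - u_hat / su2
                hess = -S * eu - 1.0 / su2
                u_hat = u_hat - grad / hess
            eu = np.exp(np.clip(u_hat, -60, 60))
            tau = 1.0 / np.sqrt(S * eu + 1.0 / su2)  # curvature scale at mode
            x, wq = _GH_NODES
            uk = u_hat[None] + np.sqrt(2.0) * tau[None] * x[:, None, None]  # (K,E,W)
            g = (
                T[None]
                + A[None] * uk
                - S[None] * np.exp(np.clip(uk, -60, 60))
                - uk**2 / (2 * su2[None])
            )
            gmax = np.max(g, axis=0)
            integ = np.tensordot(wq, np.exp(g - gmax[None] + x[:, None, None] ** 2), axes=(0, 0))
            lp_groups = gmax + np.log(np.sqrt(2.0) * tau * integ) - 0.5 * np.log(
                2 * np.pi * su2
            )
            lp = np.sum(lp_groups, axis=0) - float(np.sum(gammaln(self.y + 1.0)))

        coefs = np.column_stack([intercept, beta]) if self.p else intercept.reshape(-1, 1)
        lp += -0.5 * np.sum(coefs**2, axis=1) / pr.slope_variance
        lp += -0.5 * coefs.shape[1] * np.log(2 * np.pi * pr.slope_variance)
        lp += _halfnormal_logpdf(sigma_u, pr.re_sd_scale) + np.log(sigma_u)
        return lp

    def initial_sampling_point(self) -> np.ndarray:
        if not self.marginalized:
            return self.initial_point()
        Xc = sm.add_constant(self.X, has_constant="add") if self.p else np.ones((self.n, 1))
        log_su0 = np.log(0.3 * self.priors.re_sd_scale)
        if self.family == "normal":
            coef, *_ = np.linalg.lstsq(Xc, self.y, rcond=None)
            sigma = max(float(np.std(self.y - Xc @ coef)), 1e-3)
            return np.concatenate([coef, [log_su0], [np.log(sigma)]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                coef = np.asarray(
                    sm.GLM(self.y, Xc, family=sm.families.Poisson()).fit(maxiter=50).params
                )
            except Exception:
                coef = np.zeros(Xc.shape[1])
                coef[0] = np.log(max(np.mean(self.y), 0.5))
        return np.concatenate([coef, [log_su0]])

    def initial_sampling_scale(self) -> np.ndarray:
        """Per-parameter jitter for the walker cloud (~2x the ML SEs)."""
        Xc = sm.add_constant(self.X, has_constant="add") if self.p else np.ones((self.n, 1))
        try:
            if self.family == "normal":
                coef, *_ = np.linalg.lstsq(Xc, self.y, rcond=None)
                sigma = max(float(np.std(self.y - Xc @ coef)), 1e-3)
                se = sigma * np.sqrt(np.diag(np.linalg.pinv(Xc.T @ Xc)))
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.GLM(self.y, Xc, family=sm.families.Poisson()).fit(maxiter=50)
                se = np.asarray(res.bse)
            se = np.clip(2.0 * se, 1e-4, 0.5)
        except Exception:
            se = np.full(1 + self.p, 0.05)
        if self.marginalized:
            tail = [0.15, 0.15] if self.family == "normal" else [0.15]
            return np.concatenate([se, tail])
        parts = [se]
        if self.family == "normal":
            parts += [[0.15]]
        return np.concatenate(parts)

    def initial_point(self) -> np.ndarray:
        """A cheap ML-flavoured starting point for the ensemble."""
        Xc = sm.add_constant(self.X, has_constant="add") if self.p else np.ones(
            (self.n, 1)
        )
        if self.family == "normal":
            coef, *_ = np.linalg.lstsq(Xc, self.y, rcond=None)
            resid = self.y - Xc @ coef
            sigma = max(float(np.std(resid)), 1e-3)
            return self.pack(
                coef[0],
                coef[1:],
                sigma=sigma,
                sigma_u=0.1 * self.priors.re_sd_scale if self.has_re else None,
                z=np.zeros(self.n_groups) if self.has_re else None,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(self.y, Xc, family=sm.families.Poisson()).fit(maxiter=50)
                coef = np.asarray(res.params)
            except Exception:
                coef = np.zeros(Xc.shape[1])
                coef[0] = np.log(max(np.mean(self.y), 0.5))
        return self.pack(
            coef[0],
            coef[1:],
            sigma_u=0.1 * self.priors.re_sd_scale if self.has_re else None,
            z=np.zeros(self.n_groups) if self.has_re else None,
        )


def _halfnormal_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    return 0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2


#: Gauss-Hermite nodes/weights for the Poisson random-intercept integral.
_GH_NODES = np.polynomial.hermite.hermgauss(31)


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------


@dataclass
class HierarchicalModel:
    """The assembled per-unit system: five SubModels sharing a design table."""

    submodels: dict  # name -> SubModel
    graph: ModelGraph
    priors: PriorSpec
    scaling: dict  # predictor node -> (mean, sd) used for 2-SD standardization
    n_obs: int
    n_ecoregions: int
    unit: int | None = None

    @property
    def n_submodels(self) -> int:
        return len(self.submodels)

    @property
    def slope_names(self) -> list:
        return [b for sm_ in self.submodels.values() for b in sm_.slope_names]

    @property
    def n_slopes(self) -> int:
        return len(self.slope_names)

    def log_density(self, params: dict) -> float:
        """Joint log-density at a parameter point.

        ``params`` maps sub-model name -> dict(intercept, beta, sigma,
        sigma_u, z); the joint density is the sum over sub-models (they share
        no parameters).
        """
        total = 0.0
        for name, sub in self.submodels.items():
            p = params[name]
            theta = sub.pack(
                p["intercept"],
                p["beta"],
                sigma=p.get("sigma"),
                sigma_u=p.get("sigma_u"),
                z=p.get("z"),
            )
            total += float(sub.log_prob(theta)[0])
        return total


def build_model(
    unit_table: PlotTable,
    graph: ModelGraph | None = None,
    priors: PriorSpec | None = None,
    min_n: int = 30,
    unit: int | None = None,
) -> HierarchicalModel:
    """Assemble the five-sub-model system for one climatic unit.

    The table must be complete-case with positive density/age/soil C:N/
    productivity and richness >= 1. Raises ModelBuildError below ``min_n``;
    with a single ecoregion the random intercept degenerates to the fixed
    intercept (warning).
    """
    graph = graph or default_graph()
    graph.validate()
    priors = priors or PriorSpec()
    df = unit_table.df
    n = len(df)
    if n < min_n:
        raise ModelBuildError(f"unit has n={n} < minimum {min_n}")

    need = ["mat", "tap", "soil_cn", "stem_density", "stand_age", "richness", "productivity"]
    missing_cols = [c for c in need if c not in df.columns]
    if missing_cols:
        raise ModelBuildError(f"unit table lacks column(s): {missing_cols}")
    if df[need].isna().any().any():
        raise ModelBuildError("unit table must be complete-case (run filter_complete)")
    for col in ("soil_cn", "stem_density", "stand_age", "productivity"):
        if (df[col] <= 0).any():
            raise ModelBuildError(f"non-positive {col}; cannot log-transform")

    # log transforms, then 2-SD standardization of every predictor role
    nodes = {
        "mat": df["mat"].to_numpy(float),
        "tap": df["tap"].to_numpy(float),
        "log_density": np.log(df["stem_density"].to_numpy(float)),
        "log_age": np.log(df["stand_age"].to_numpy(float)),
        "log_cn": np.log(df["soil_cn"].to_numpy(float)),
        "richness": df["richness"].to_numpy(float),
        "log_productivity": np.log(df["productivity"].to_numpy(float)),
    }
    z, scaling = {}, {}
    for name in ("mat", "tap", "log_density", "log_age", "log_cn", "richness"):
        try:
            z[name], m, s = standardize_predictors(nodes[name])
        except ValueError as exc:
            raise ModelBuildError(f"predictor {name}: {exc}") from exc
        scaling[name] = (m, s)
    z["richness_sq"] = z["richness"] ** 2  # standardize first, then square

    codes, uniques = pd.factorize(df["ecoregion"], sort=True)
    n_eco = len(uniques)
    if n_eco < 2:
        warnings.warn(
            "single ecoregion: random intercept degenerates to the fixed intercept",
            stacklevel=2,
        )
        groups = None
    else:
        groups = codes.astype(int)

    submodels = {}
    for spec in graph.submodels:
        X = np.column_stack([z[p] for p in spec.predictors]) if spec.predictors else np.empty((n, 0))
        y = nodes[spec.response]
        submodels[spec.name] = SubModel(
            name=spec.name,
            family=spec.family,
            y=y,
            X=X,
            groups=groups,
            n_groups=n_eco,
            slope_names=tuple(spec.slopes),
            priors=priors,
        )
    return HierarchicalModel(
        submodels=submodels,
        graph=graph,
        priors=priors,
        scaling=scaling,
        n_obs=n,
        n_ecoregions=n_eco,
        unit=unit,
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSummary:
    """Posterior summaries, draws and diagnostics for one unit's fit."""

    unit: int | None
    table: pd.DataFrame  # param, submodel, mean, sd, ci_lo, ci_hi, p_gt0, rhat, ess, significant
    draws: dict  # param name -> pooled 1-D draws (possibly thinned)
    converged: bool
    ci_level: float
    n_obs: int

    def coefficient(self, name: str) -> pd.Series:
        row = self.table[self.table["param"] == name]
        if row.empty:
            raise KeyError(f"no parameter {name!r}; known: {list(self.table['param'])}")
        return row.iloc[0]


def sample_submodel(
    sub: SubModel, settings: McmcSettings, seed_seq: np.random.SeedSequence | None = None
) -> dict:
    """Sample one sub-model: ``settings.chains`` independent ensemble runs.

    Returns ``{"chains": array (chains*walkers, kept, ndim), "names": [...]}``
    with burn-in discarded and thinning applied.
    """
    ndim = sub.sampling_ndim
    nwalkers = settings.nwalkers or max(2 * ndim, 24)
    if nwalkers % 2:
        nwalkers += 1
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(settings.seed)
    center = sub.initial_sampling_point()
    scale = sub.initial_sampling_scale()
    # differential-evolution moves mix much faster than the stretch move on
    # the correlated coefficient posteriors here
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    all_runs = []
    for chain_seq in seed_seq.spawn(settings.chains):
        init_state, run_state = chain_seq.spawn(2)
        rng = np.random.default_rng(init_state)
        p0 = center[None, :] + scale * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, sub.sampling_log_prob, vectorize=True, moves=moves
        )
        sampler.random_state = np.random.RandomState(
            run_state.generate_state(4)
        ).get_state()
        sampler.run_mcmc(p0, settings.iterations, progress=False, skip_initial_state_check=True)
        chain = sampler.get_chain(discard=settings.burn_in, thin=settings.thinning)
        # (kept, walkers, ndim) -> (walkers, kept, ndim): each walker a chain
        all_runs.append(np.moveaxis(chain, 0, 1))
    return {"chains": np.concatenate(all_runs, axis=0), "names": sub.sampling_param_names}


def _summarize_chains(
    chains: np.ndarray,
    names: list,
    submodel: str,
    ci_level: float,
) -> tuple[pd.DataFrame, dict]:
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    rows, draws = [], {}
    for j, name in enumerate(names):
        c = chains[:, :, j]
        pooled = c.reshape(-1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = float(az.rhat(c))
            ess = float(az.ess(c))
        ci_lo, ci_hi = np.quantile(pooled, [lo_q, hi_q])
        rows.append(
            {
                "param": name,
                "submodel": submodel,
                "mean": float(pooled.mean()),
                "sd": float(pooled.std(ddof=1)),
                "ci_lo": float(ci_lo),
                "ci_hi": float(ci_hi),
                "p_gt0": float(np.mean(pooled > 0)),
                "rhat": rhat,
                "ess": ess,
                "significant": bool(ci_lo > 0 or ci_hi < 0),
            }
        )
        draws[name] = pooled
    return pd.DataFrame(rows), draws


def sample_posterior(
    model: HierarchicalModel,
    settings: McmcSettings,
    submodels: list | None = None,
    ci_level: float = 0.95,
    max_stored_draws: int = 20_000,
) -> PosteriorSummary:
    """Sample the (factorized) posterior and summarize every coefficient.

    ``submodels`` restricts sampling to a subset of sub-model names (the
    joint posterior factorizes, so a subset fit is exact for its own
    parameters). Sub-model ecoregion SDs are sampled on the log scale; the
    reported ``sigma_u``/``sigma`` summaries are on the natural scale.
    """
    wanted = list(model.submodels) if submodels is None else list(submodels)
    unknown = [s for s in wanted if s not in model.submodels]
    if unknown:
        raise ValueError(f"unknown sub-model(s) {unknown}; have {list(model.submodels)}")
    base_seq = np.random.SeedSequence(
        [settings.seed, 0 if model.unit is None else int(model.unit)]
    )
    sub_seqs = dict(zip(model.submodels, base_seq.spawn(len(model.submodels))))
    tables, all_draws = [], {}
    for name in wanted:
        sub = model.submodels[name]
        res = sample_submodel(sub, settings, seed_seq=sub_seqs[name])
        chains = res["chains"]
        # report SDs on the natural scale
        for j, pname in enumerate(res["names"]):
            if pname.startswith(("sigma_u:", "sigma:")):
                chains[:, :, j] = np.exp(chains[:, :, j])
        tbl, draws = _summarize_chains(chains, res["names"], name, ci_level)
        tables.append(tbl)
        for k, v in draws.items():
            if len(v) > max_stored_draws:
                stride = int(np.ceil(len(v) / max_stored_draws))
                v = v[::stride]
            all_draws[k] = v
    table = pd.concat(tables, ignore_index=True)
    monitored = table[~table["param"].str.startswith("u[")]
    converged = bool(
        np.all(np.isfinite(monitored["rhat"]))
        and (monitored["rhat"] <= 1.05).all()
        and (monitored["ess"] >= 100).all()
    )
    return PosteriorSummary(
        unit=model.unit,
        table=table,
        draws=all_draws,
        converged=converged,
        ci_level=ci_level,
        n_obs=model.n_obs,
    )


def fit_all_units(
    table: PlotTable,
    grid: ClimateGrid,
    graph: ModelGraph | None = None,
    priors: PriorSpec | None = None,
    settings: McmcSettings | None = None,
    min_n: int = 30,
    submodels: list | None = None,
    ci_level: float = 0.95,
) -> tuple[dict, pd.DataFrame]:
    """Fit the hierarchical model independently in every populated unit.

    Returns (unit -> PosteriorSummary, run report). Per-unit failures are
    isolated and recorded with a reason; seeds derive deterministically from
    ``settings.seed`` and the unit id.
    """
    if grid.assignment is None:
        raise ValueError("grid has no assignment; call assign_units first")
    settings = settings or McmcSettings.desk_profile()
    merged = table.df.merge(grid.assignment[["plot_id", "unit"]], on="plot_id")
    results, report_rows = {}, []
    for unit, g in merged.groupby("unit", sort=True):
        sub_table = PlotTable(g.drop(columns=["unit"]).reset_index(drop=True))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = build_model(sub_table, graph=graph, priors=priors, min_n=min_n, unit=int(unit))
                summary = sample_posterior(
                    model, settings, submodels=submodels, ci_level=ci_level
                )
        except ModelBuildError as exc:
            report_rows.append({"unit": int(unit), "n": len(g), "status": "skipped", "reason": str(exc)})
            continue
        except Exception as exc:  # sampler failure: isolate, flag
            report_rows.append({"unit": int(unit), "n": len(g), "status": "failed", "reason": str(exc)})
            continue
        results[int(unit)] = summary
        report_rows.append(
            {
                "unit": int(unit),
                "n": len(g),
                "status": "fitted" if summary.converged else "non-converged",
                "reason": "",
            }
        )
    return results, pd.DataFrame(report_rows)
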