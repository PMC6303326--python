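import warnings

import numpy as np
import pytest

from forestbpr.hierarchical import (
    McmcSettings,
    ModelBuildError,
    PriorSpec,
    SubModel,
    build_model,
    default_graph,
    sample_posterior,
    sample_submodel,
    standardize_predictors,
)
from forestbpr.synthetic import RegimeMap, default_params, simulate
from forestbpr.table import derive_productivity

from oracles import joint_log_density_oracle

FAST = McmcSettings(chains=2, iterations=800, burn_in=200, seed=3)


def recovery_table(n=600, seed=0, **kw):
    params = default_params(
        "dry_positive",
        n_plots=n,
        seed=seed,
        n_ecoregions=kw.pop("n_ecoregions", 6),
        regime_map=kw.pop("regime_map", RegimeMap(kind="constant", b17=0.3, b18=-0.05)),
        **kw,
    )
    return derive_productivity(simulate(params=params))


class TestStandardize:
    def test_two_point_example(self):
        z, mean, sd = standardize_predictors([0.0, 2.0])
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(np.sqrt(2.0))
        np.testing.assert_allclose(z, [-0.35355339, 0.35355339], atol=1e-8)

    def test_output_moments(self, rng):
        z, *_ = standardize_predictors(rng.normal(5, 3, 500))
        assert abs(z.mean()) < 1e-12
        assert np.std(z, ddof=1) == pytest.approx(0.5, abs=1e-12)

    def test_fixed_point(self, rng):
        z, *_ = standardize_predictors(rng.normal(0, 1, 200))
        z2, *_ = standardize_predictors(z)
        np.testing.assert_allclose(z2, z, atol=1e-12)

    def test_constant_errors(self):
        with pytest.raises(ValueError, match="constant"):
            standardize_predictors(np.ones(10))


class TestGraphAndBuild:
    def test_structure_counts(self):
        graph = default_graph()
        assert graph.n_submodels == 5
        assert graph.n_slopes == 18
        graph.validate()

    def test_built_model_counts(self):
        model = build_model(recovery_table(), min_n=30)
        assert model.n_submodels == 5
        assert model.n_slopes == 18
        prod = model.submodels["productivity"]
        assert prod.p == 7 and prod.family == "normal"
        assert model.submodels["richness"].family == "poisson"

    def test_below_min_n_refused(self):
        with pytest.raises(ModelBuildError, match="minimum"):
            build_model(recovery_table(n=200), min_n=500)

    def test_incomplete_rows_refused(self):
        table = recovery_table(n=100)
        table.df.loc[3, "soil_cn"] = np.nan
        with pytest.raises(ModelBuildError, match="complete-case"):
            build_model(table, min_n=30)

    def test_single_ecoregion_degenerates_with_warning(self):
        table = recovery_table(n=120, n_ecoregions=1)
        with pytest.warns(UserWarning, match="single ecoregion"):
            model = build_model(table, min_n=30)
        assert not model.submodels["productivity"].has_re

    def test_joint_log_density_matches_term_oracle(self, rng):
        model = build_model(recovery_table(n=80, n_ecoregions=3), min_n=30)
        for _ in range(5):
            params = {}
            for name, sub in model.submodels.items():
                params[name] = {
                    "intercept": float(rng.normal(0, 1)),
                    "beta": rng.normal(0, 0.3, sub.p),
                    "sigma": float(rng.uniform(0.2, 1.5)),
                    "sigma_u": float(rng.uniform(0.05, 0.8)),
                    "z": rng.normal(0, 1, sub.n_groups),
                }
            got = model.log_density(params)
            want = joint_log_density_oracle(model, params)
            assert got == pytest.approx(want, abs=1e-8)

    def test_joint_density_is_sum_of_submodels(self, rng):
        model = build_model(recovery_table(n=80, n_ecoregions=3), min_n=30)
        params = {
            name: {
                "intercept": 0.5,
                "beta": np.full(sub.p, 0.1),
                "sigma": 0.7,
                "sigma_u": 0.3,
                "z": np.linspace(-1, 1, sub.n_groups),
            }
            for name, sub in model.submodels.items()
        }
        total = model.log_density(params)
        parts = 0.0
        for name, sub in model.submodels.items():
            p = params[name]
            theta = sub.pack(
                p["intercept"], p["beta"], sigma=p["sigma"], sigma_u=p["sigma_u"], z=p["z"]
            )
            parts += float(sub.log_prob(theta)[0])
        assert total == pytest.approx(parts, abs=1e-10)


class TestSampling:
    def test_conjugate_limit_normal_mean(self, rng):
        # y ~ N(mu, 1) with a flat-ish N(0, 1000) prior on mu: the posterior
        # mean of mu must match the closed-form conjugate answer
        y = rng.normal(1.3, 1.0, 150)
        sub = SubModel(
            name="mu",
            family="normal",
            y=y,
            X=np.empty((150, 0)),
            groups=None,
            n_groups=1,
            slope_names=(),
            priors=PriorSpec(),
        )
        res = sample_submodel(sub, McmcSettings(chains=2, iterations=1500, burn_in=300, seed=9))
        idx = res["names"].index("intercept:mu")
        draws = res["chains"][:, :, idx].ravel()
        n = len(y)
        conj_mean = y.sum() / (n + 1.0 / 1000.0)  # known sigma=1 limit
        mc_err = draws.std() / np.sqrt(200)  # very conservative ESS floor
        assert abs(draws.mean() - conj_mean) < max(4 * mc_err, 0.02)

    def test_seeded_runs_identical(self):
        table = recovery_table(n=300)
        model = build_model(table, min_n=30)
        a = sample_posterior(model, FAST, submodels=["density"])
        b = sample_posterior(model, FAST, submodels=["density"])
        assert (a.table["mean"] == b.table["mean"]).all()
        assert (a.table["ci_lo"] == b.table["ci_lo"]).all()

    def test_affine_rescaling_of_climate_is_invisible(self):
        table = recovery_table(n=300)
        scaled = table.copy()
        scaled.df["mat"] = scaled.df["mat"] * 0.1  # degC -> other unit
        a = sample_posterior(build_model(table, min_n=30), FAST, submodels=["density"])
        b = sample_posterior(build_model(scaled, min_n=30), FAST, submodels=["density"])
        # standardization absorbs the rescaling exactly up to float round-off;
        # the remaining difference is Monte-Carlo level only
        assert abs(a.coefficient("b1")["mean"] - b.coefficient("b1")["mean"]) < 0.01
        za, *_ = standardize_predictors(table.df["mat"].to_numpy())
        zb, *_ = standardize_predictors(scaled.df["mat"].to_numpy())
        np.testing.assert_allclose(za, zb, atol=1e-12)

    def test_slope_recovery_density_submodel(self):
        # planted b1 (MAT -> log density) = -0.3
        table = recovery_table(n=1500, seed=4)
        model = build_model(table, min_n=30)
        s = sample_posterior(model, FAST, submodels=["density"])
        c = s.coefficient("b1")
        assert c["ci_lo"] < -0.3 < c["ci_hi"] or abs(c["mean"] + 0.3) < 0.1

    def test_unknown_submodel_name_errors(self):
        model = build_model(recovery_table(n=200), min_n=30)
        with pytest.raises(ValueError, match="unknown sub-model"):
            sample_posterior(model, FAST, submodels=["nope"])


class TestSettings:
    def test_validation(self):
        with pytest.raises(ValueError, match="burn_in"):
            McmcSettings(iterations=100, burn_in=100)
        with pytest.raises(ValueError, match="chains"):
            McmcSettings(chains=1)

    def test_desk_profile_values(self):
        s = McmcSettings.desk_profile(seed=7)
        assert (s.chains, s.iterations, s.burn_in) == (3, 2000, 500)

    def test_paper_defaults(self):
        s = McmcSettings()
        assert (s.chains, s.iterations, s.burn_in) == (3, 100_000, 5_000)
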