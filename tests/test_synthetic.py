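import numpy as np
import pandas as pd
import pytest

from forestbpr.synthetic import (
    GeneratorParams,
    RegimeMap,
    aridity_index,
    default_params,
    generate_climate,
    generate_plots,
    simulate,
    write_truth,
)
from forestbpr.table import derive_productivity


class TestParams:
    def test_null_scenario_zeroes_richness_effects(self):
        p = default_params("null")
        b17, b18, _ = p.regime_map(np.array([10.0]), np.array([800.0]))
        assert b17[0] == 0.0 and b18[0] == 0.0
        assert all(v == 0.0 for v in p.structural_betas.values())

    def test_continental_ranges_match_study_domain(self):
        p = default_params("continental")
        assert p.mat_range == (-3.8, 23.9)
        assert p.tap_range == (79.0, 3375.0)

    def test_dry_positive_and_mesic_hump_signs(self):
        dry = default_params("dry_positive").regime_map(np.r_[10.0], np.r_[300.0])
        assert dry[0][0] > 0 and dry[1][0] == 0.0
        hump = default_params("mesic_hump").regime_map(np.r_[10.0], np.r_[2000.0])
        assert hump[1][0] < 0

    def test_unknown_scenario_lists_valid_names(self):
        with pytest.raises(ValueError, match="continental"):
            default_params("tropical")

    @pytest.mark.parametrize(
        "kw",
        [
            {"n_plots": 0},
            {"missing_rate": 1.0},
            {"climate_correlation": 1.0},
            {"mat_range": (5.0, 5.0)},
            {"ecoregion_sd": -0.1},
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            GeneratorParams(**kw)

    def test_structural_betas_must_cover_all_fixed_edges(self):
        with pytest.raises(ValueError, match="16 non-richness"):
            GeneratorParams(structural_betas={"mat->density": 0.1})


class TestClimate:
    def test_truncation_to_stated_ranges(self):
        p = default_params("continental", n_plots=5000, seed=2)
        t = generate_climate(p)
        assert t.df["mat"].between(-3.8, 23.9).all()
        assert t.df["tap"].between(79.0, 3375.0).all()

    def test_zero_correlation_recovered(self):
        p = default_params("continental", n_plots=10_000, seed=1, climate_correlation=0.0)
        t = generate_climate(p)
        r = np.corrcoef(t.df["mat"], t.df["tap"])[0, 1]
        assert abs(r) < 0.05

    def test_deterministic_given_seed(self):
        p = default_params("continental", n_plots=800, seed=5)
        a, b = generate_climate(p), generate_climate(p)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_ecoregion_count(self):
        p = default_params("continental", n_plots=2000, seed=3, n_ecoregions=12)
        t = generate_climate(p)
        assert t.df["ecoregion"].nunique() == 12

    def test_aridity_monotone_in_tap_and_mat(self):
        assert aridity_index(10.0, 900.0) < aridity_index(10.0, 1000.0)
        assert aridity_index(15.0, 900.0) < aridity_index(5.0, 900.0)


class TestPlots:
    def test_constant_poisson_mean_when_all_effects_off(self):
        p = default_params(
            "null",
            n_plots=10_000,
            seed=4,
            ecoregion_sd=0.0,
            noise_sds={"density": 1e-8, "age": 1e-8, "soil_cn": 1e-8, "productivity": 1e-8},
        )
        t = simulate(params=p)
        lam = np.exp(p.intercepts["richness"])
        se = np.sqrt(lam / len(t))
        assert abs(t.df["richness"].mean() - lam) < 3 * se

    def test_biomass_is_exact_inverse_of_productivity(self):
        t = derive_productivity(simulate("continental", n_plots=500, seed=6))
        ok = t.df["productivity"].notna()
        np.testing.assert_allclose(
            t.df.loc[ok, "productivity"] * t.df.loc[ok, "stand_age"],
            t.df.loc[ok, "agb"],
            rtol=1e-12,
        )

    def test_marginal_ranges(self):
        t = simulate("continental", n_plots=3000, seed=7)
        assert (t.df["richness"] >= 1).all()
        assert (t.df["stand_age"].dropna() > 0).all()
        assert (t.df["agb"] > 0).all()

    def test_missingness_rate_matches_expectation(self):
        p = default_params("continental", n_plots=10_000, seed=8, missing_rate=0.02)
        t = simulate(params=p)
        miss_cols = ["mat", "tap", "aridity", "soil_cn", "stem_density", "stand_age"]
        frac = t.df[miss_cols].isna().any(axis=1).mean()
        expected = 1 - (1 - 0.02) ** len(miss_cols)
        assert abs(frac - expected) < 0.02

    def test_regime_fidelity_on_stored_truth(self):
        t = simulate("continental", n_plots=8000, seed=9)
        truth = t.notes["truth"]
        ai = aridity_index(t.df["mat"].to_numpy(float), t.df["tap"].to_numpy(float))
        b17s = np.asarray(truth["b17_star"])
        b18s = np.asarray(truth["b18_star"])
        ok = ~np.isnan(ai)
        dry = ok & (ai < 0.5)
        humid = ok & (ai >= 0.65)
        assert (b18s[dry] == 0.0).all() and (b17s[dry] > 0).all()
        assert (b18s[humid] < 0).all()

    def test_two_calls_identical(self):
        p = default_params("continental", n_plots=600, seed=11)
        a = simulate(params=p)
        b = simulate(params=p)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_missing_climate_columns_error(self):
        p = default_params("continental", n_plots=50, seed=1)
        t = generate_climate(p)
        t.df["mat"] = np.nan
        with pytest.raises(ValueError, match="mat"):
            generate_plots(t, p)

    def test_truth_serializes(self, tmp_path):
        t = simulate("continental", n_plots=100, seed=13)
        path = tmp_path / "truth.json"
        write_truth(t, path)
        import json

        truth = json.loads(path.read_text())
        assert len(truth["b17_star"]) == 100
        assert truth["params"]["seed"] == 13
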