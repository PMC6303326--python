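import numpy as np
import pytest

from forestbpr.bivariate import (
    BPRType,
    BivariateFit,
    ModelFit,
    bivariate_by_unit,
    classify_bivariate,
    fit_bivariate,
)
from forestbpr.climate import build_grid
from forestbpr.table import derive_productivity

from conftest import make_table
from oracles import gaussian_glm_oracle


class TestFit:
    def test_exact_colinear_points(self):
        S = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_bivariate(S, S.copy())
        assert fit.linear.params[1] == pytest.approx(1.0, abs=1e-10)
        assert fit.linear.params[0] == pytest.approx(0.0, abs=1e-10)
        assert fit.selected == "linear"

    def test_slope_recovery_under_generating_model(self, rng):
        S = rng.integers(1, 25, 500).astype(float)
        y = 2.0 + 0.5 * S + rng.normal(0, 1.0, 500)
        fit = fit_bivariate(S, y)
        b1, se = fit.linear.params[1], fit.linear.se[1]
        assert abs(b1 - 0.5) < 3 * se

    def test_oracle_equivalence_both_models(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            S = rng.integers(1, 15, n).astype(float)
            y = rng.normal(1.0 + 0.05 * S, 0.4)
            fit = fit_bivariate(S, y)
            for model, X in (
                (fit.linear, np.column_stack([np.ones(n), S])),
                (fit.quadratic, np.column_stack([np.ones(n), S, S**2])),
            ):
                ora = gaussian_glm_oracle(y, X)
                np.testing.assert_allclose(model.params, ora["beta"], atol=1e-8)
                np.testing.assert_allclose(model.se, ora["se"], atol=1e-8)
                assert model.loglik == pytest.approx(ora["loglik"], abs=1e-8)
                assert model.aic == pytest.approx(ora["aic"], abs=1e-8)

    def test_quadratic_never_fits_worse(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 40))
            S = rng.integers(1, 12, n).astype(float)
            y = rng.normal(0, 1, n)
            fit = fit_bivariate(S, y)
            assert fit.quadratic.loglik >= fit.linear.loglik - 1e-9

    def test_shift_invariance_of_classification(self, rng):
        S = rng.integers(1, 20, 300).astype(float)
        y = 1.0 + 0.08 * S - 0.003 * S**2 + rng.normal(0, 0.3, 300)
        a = fit_bivariate(S, y)
        b = fit_bivariate(S, y + 5.0)
        assert classify_bivariate(a) == classify_bivariate(b)
        np.testing.assert_allclose(a.linear.params[1], b.linear.params[1], atol=1e-10)

    def test_small_n_and_zero_variance_not_estimable(self):
        fit = fit_bivariate(np.array([1.0, 2.0]), np.array([0.5, 0.6]))
        assert not fit.estimable and "below minimum" in fit.reason
        fit = fit_bivariate(np.full(10, 4.0), np.arange(10.0))
        assert not fit.estimable and "zero variance" in fit.reason

    def test_two_distinct_richness_values_fall_back_to_linear(self, rng):
        S = np.array([2.0, 5.0] * 10)
        y = rng.normal(0.1 * S, 0.2)
        fit = fit_bivariate(S, y)
        assert fit.estimable and fit.quadratic is None and fit.selected == "linear"

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="lengths"):
            fit_bivariate(np.arange(5.0), np.arange(6.0))


def _fake_fit(selected, b1=0.0, p1=1.0, b2=0.0, p2=1.0):
    lin = ModelFit(np.array([0.0, b1]), np.ones(2), np.ones(2), np.array([1.0, p1]), 0.0, 0.0)
    quad = ModelFit(
        np.array([0.0, b1, b2]), np.ones(3), np.ones(3), np.array([1.0, p1, p2]), 0.0, 0.0
    )
    return BivariateFit(None, 100, 0, lin, quad, selected, True)


class TestClassification:
    @pytest.mark.parametrize(
        "selected,b1,p1,b2,p2,expected",
        [
            # linear model selected: only the linear term is consulted
            ("linear", 0.4, 0.001, 0.0, 1.0, BPRType.linear_positive),
            ("linear", -0.4, 0.001, 0.0, 1.0, BPRType.linear_negative),
            ("linear", 0.4, 0.2, 0.0, 1.0, BPRType.non_significant),
            ("linear", -0.4, 0.2, 0.0, 1.0, BPRType.non_significant),
            ("linear", 0.0, 1.0, 0.0, 1.0, BPRType.non_significant),
            # quadratic model selected: only the quadratic term is consulted
            ("quadratic", 0.4, 0.001, -0.02, 0.0003, BPRType.concave_negative),
            ("quadratic", 0.0, 1.0, 0.02, 0.0003, BPRType.concave_positive),
            ("quadratic", 0.4, 0.001, -0.02, 0.3, BPRType.non_significant),
            ("quadratic", 0.0, 1.0, 0.0, 1.0, BPRType.non_significant),
        ],
    )
    def test_decision_rules_exhaustive(self, selected, b1, p1, b2, p2, expected):
        assert classify_bivariate(_fake_fit(selected, b1, p1, b2, p2)) == expected

    def test_alpha_boundary_inclusive(self):
        fit = _fake_fit("linear", 0.4, 0.05)
        assert classify_bivariate(fit, alpha=0.05) == BPRType.linear_positive

    def test_non_estimable_is_non_significant(self):
        fit = BivariateFit(None, 2, 0, None, None, None, False, "too small")
        assert classify_bivariate(fit) == BPRType.non_significant


class TestByUnit:
    def test_one_classification_per_populated_unit(self):
        table = derive_productivity(make_table(n=400, seed=9))
        grid = build_grid(table, k=3)
        out = bivariate_by_unit(table, grid)
        assert len(out) == grid.assignment["unit"].nunique()
        assert set(out["bpr_type"]).issubset({t.value for t in BPRType})

    def test_small_units_marked_non_estimable(self):
        table = derive_productivity(make_table(n=30, seed=9))
        grid = build_grid(table, k=3)
        out = bivariate_by_unit(table, grid, min_n=40)
        assert (~out["estimable"]).all()
        assert (out["bpr_type"] == BPRType.non_significant.value).all()
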