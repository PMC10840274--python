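"""Poisson model families: closed forms, nesting, recovery, LRT."""

import numpy as np
import pandas as pd
import pytest

from cnimpact.containers import ExpressionMatrix, SampleGroups
from cnimpact.models import (
    classify_interaction,
    estimate_sample_scales,
    fit_constant,
    fit_linear,
    fit_monotonic,
    fit_stacked_monotonic,
    lrt,
    predict_mean,
)
from conftest import dispersed_cn


class TestSampleScales:
    def test_column_sum_estimator(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"S1": [60, 40], "S2": [200, 100]}, index=["G1", "G2"])
        )
        g = estimate_sample_scales(expr)
        assert np.allclose(g.values, [0.5, 1.5])
        assert g.g.mean() == pytest.approx(1.0)

    def test_zero_count_sample_named(self):
        expr = ExpressionMatrix(pd.DataFrame({"S1": [1], "S2": [0]}, index=["G1"]))
        with pytest.raises(ValueError, match="S2"):
            estimate_sample_scales(expr)


class TestConstant:
    @pytest.mark.parametrize(
        "x,g,b0",
        [([2, 4], [1, 1], 3.0), ([3], [0.5], 6.0), ([0, 0, 0], [1, 1, 1], 0.0)],
    )
    def test_closed_form(self, x, g, b0):
        fit = fit_constant(x, g)
        assert fit.params["b0"] == pytest.approx(b0, abs=1e-12)
        assert fit.rank == 1
        if b0 == 0:
            assert fit.deviance == 0.0


class TestLinear:
    def test_parameter_recovery(self, rng):
        n = 500
        total = rng.integers(0, 7, size=n)
        B = np.floor(total / 2.0)
        A = total - B
        x = rng.poisson(5.0 + 2.0 * (A + B))
        fit = fit_linear(x, A, B, np.ones(n))
        assert fit.converged
        assert abs(fit.params["a"] - 2.0) / 2.0 < 0.10
        assert abs(fit.params["b0"] - 5.0) / 5.0 < 0.10

    def test_constant_cn_reduces_to_constant_model(self, rng):
        n = 100
        x = rng.poisson(10.0, size=n)
        A, B = np.full(n, 2.0), np.full(n, 1.0)
        lin = fit_linear(x, A, B, np.ones(n))
        con = fit_constant(x, np.ones(n))
        assert lin.loglik == pytest.approx(con.loglik, abs=1e-6)
        assert lin.rank == 1

    def test_all_zero_counts(self):
        fit = fit_linear([0, 0, 0], [1, 2, 3], [0, 1, 1], [1, 1, 1], with_interaction=True)
        assert fit.params == {"b0": 0.0, "a": 0.0, "c": 0.0}
        assert fit.deviance == 0.0

    def test_classify_interaction_tolerance_band(self):
        base = fit_linear([1, 2], [1, 2], [0, 1], [1, 1], with_interaction=True)
        from dataclasses import replace

        assert classify_interaction(replace(base, params={**base.params, "c": 0.5})) == "synergistic"
        assert classify_interaction(replace(base, params={**base.params, "c": 0.0})) == "linear"
        assert classify_interaction(replace(base, params={**base.params, "c": -1e-9})) == "linear"
        assert classify_interaction(replace(base, params={**base.params, "c": -0.2})) == "antagonistic"
        lin = fit_linear([1, 2], [1, 2], [0, 1], [1, 1])
        with pytest.raises(ValueError):
            classify_interaction(lin)


class TestMonotonic:
    def test_step_recovery_median(self, rng):
        errors = []
        for _ in range(20):
            n = 400
            total = rng.integers(0, 7, size=n)
            B = np.floor(total / 2.0)
            A = total - B
            mu = 1.0 + 3.0 * ((A >= 2).astype(float) + (B >= 2).astype(float))
            x = rng.poisson(mu)
            fit = fit_monotonic(x, A, B, np.ones(n), k_max=8)
            errors.append(abs(fit.params["a_2-1"] - 3.0) / 3.0)
        assert np.median(errors) < 0.15

    def test_single_cn_state_only_intercept_identifiable(self, rng):
        n = 60
        x = rng.poisson(7.0, size=n)
        fit = fit_monotonic(x, np.ones(n), np.ones(n), np.ones(n))
        con = fit_constant(x, np.ones(n))
        assert fit.rank == 1
        assert fit.loglik == pytest.approx(con.loglik, abs=1e-6)

    def test_all_zero_counts(self):
        fit = fit_monotonic([0, 0, 0, 0], [1, 2, 3, 0], [1, 1, 0, 0], [1, 1, 1, 1])
        assert all(v == 0.0 for v in fit.params.values())

    def test_nesting_over_random_genes(self, rng):
        for _ in range(200):
            n = 50
            A, B = dispersed_cn(rng, n)
            x = rng.poisson(rng.uniform(1, 30), size=n)
            g = np.exp(rng.normal(0, 0.3, n))
            g /= g.mean()
            mono = fit_monotonic(x, A, B, g)
            con = fit_constant(x, g)
            assert mono.loglik >= con.loglik - 1e-6

    def test_predicted_means_non_decreasing_in_each_allele(self, rng):
        n = 300
        A, B = dispersed_cn(rng, n)
        x = rng.poisson((2.0 + 1.5 * (A + B)))
        fit = fit_monotonic(x, A, B, np.ones(n), k_max=8)
        grid = np.arange(0, 9)
        for b in range(0, 9):
            a_vals = np.arange(b, 9)  # respect A >= B
            mu = predict_mean(fit, a_vals, np.full_like(a_vals, b), 1.0)
            assert np.all(np.diff(mu) >= -1e-9)
        for a in range(0, 9):
            b_vals = np.arange(0, a + 1)
            mu = predict_mean(fit, np.full_like(b_vals, a), b_vals, 1.0)
            assert np.all(np.diff(mu) >= -1e-9)

    def test_scale_invariance_of_deviance_and_lrt(self, rng):
        n = 150
        A, B = dispersed_cn(rng, n)
        g = np.exp(rng.normal(0, 0.3, n))
        x = rng.poisson((3.0 + 2.0 * (A + B)) * g)
        f1 = fit_monotonic(x, A, B, g)
        c1 = fit_constant(x, g)
        f2 = fit_monotonic(x, A, B, 10.0 * g)
        c2 = fit_constant(x, 10.0 * g)
        assert f1.deviance == pytest.approx(f2.deviance, abs=1e-6)
        assert lrt(c1, f1).statistic == pytest.approx(lrt(c2, f2).statistic, abs=1e-6)


class TestStacked:
    def test_direction_recovery_single(self, rng):
        n = 200
        labels = np.array(["good", "poor"] * (n // 2))
        A, B = dispersed_cn(rng, n)
        s2 = (A >= 2).astype(float) + (B >= 2).astype(float)
        mu = 10.0 + 2.0 * (A + B) + (labels == "poor") * 3.0 * s2
        x = rng.poisson(mu)
        fit = fit_stacked_monotonic(x, A, B, np.ones(n), labels)
        assert fit.direction == "poor"
        assert fit.loglik >= fit_monotonic(x, A, B, np.ones(n)).loglik - 1e-6

    def test_null_data_deviations_near_zero(self, rng):
        n = 200
        labels = np.array(["g1", "g2"] * (n // 2))
        A, B = dispersed_cn(rng, n)
        x = rng.poisson(20.0, size=n)
        fit = fit_stacked_monotonic(x, A, B, np.ones(n), labels)
        mono = fit_monotonic(x, A, B, np.ones(n))
        # extra loglik must stay within chi-square-scale noise of unstacked fit
        assert 0 <= fit.loglik - mono.loglik < 10.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_stacked_monotonic(
                [1, 2, 3], [1, 1, 1], [1, 1, 1], [1, 1, 1], np.array(["a", "a", "b"])
            )


class TestPredictAndLrt:
    def test_constant_prediction(self):
        fit = fit_constant([3, 3], [1, 1])
        assert np.allclose(predict_mean(fit, g=[1.0, 2.0]), [3.0, 6.0])

    def test_monotonic_hand_evaluation(self):
        from dataclasses import replace

        fit = fit_monotonic([1, 1, 1, 1], [1, 1, 0, 2], [0, 1, 0, 1], [1, 1, 1, 1], k_max=2)
        params = {"b0": 1.0, "a_1-0": 2.0, "a_2-1": 0.0}
        fit = replace(fit, params=params)
        assert predict_mean(fit, [1], [1], 1.0)[0] == pytest.approx(5.0)

    def test_zero_parameter_fit_predicts_zero(self):
        fit = fit_constant([0, 0], [1, 1])
        assert np.allclose(predict_mean(fit, g=[1.0, 3.0]), 0.0)

    def test_stacked_prediction_requires_groups(self, rng):
        n = 20
        labels = np.array(["a", "b"] * (n // 2))
        fit = fit_stacked_monotonic(
            rng.poisson(5, n), np.ones(n), np.ones(n), np.ones(n), labels
        )
        with pytest.raises(ValueError, match="group"):
            predict_mean(fit, np.ones(n), np.ones(n), 1.0)

    def test_lrt_reference_values(self):
        c = fit_constant([4, 6], [1, 1])
        res = lrt(c, c)
        assert res.statistic == 0.0 and res.p == 1.0 and res.df == 0
        from dataclasses import replace

        alt = replace(c, rank=2, loglik=c.loglik + 3.841 / 2.0)
        assert lrt(c, alt).p == pytest.approx(0.05, abs=5e-4)

    def test_lrt_negative_statistic_clamped(self):
        from dataclasses import replace

        c = fit_constant([4, 6], [1, 1])
        worse = replace(c, loglik=c.loglik - 1e-9, rank=2)
        res = lrt(c, worse)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_lrt_rank_order_enforced(self):
        from dataclasses import replace

        c = fit_constant([4, 6], [1, 1])
        with pytest.raises(ValueError):
            lrt(replace(c, rank=3), c)
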