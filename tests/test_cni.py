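"""Explained variance, CNI, pathway pooling, multiple testing."""

from dataclasses import replace

import numpy as np
import pytest

from cnimpact.cni import (
    GeneCNI,
    adjust_pvalues,
    explained_variance,
    gene_cni,
    pathway_cni,
    residual_deviance,
)
from cnimpact.models import LrtResult, fit_constant
from conftest import dispersed_cn


class TestResidualDeviance:
    def test_perfect_fit_zero(self):
        assert residual_deviance([3, 5], [3.0, 5.0]) == pytest.approx(0.0)

    def test_hand_values(self):
        assert residual_deviance([2], [1.0]) == pytest.approx(2 * (2 * np.log(2) - 1))
        assert residual_deviance([0], [1.0]) == pytest.approx(2.0)

    def test_invalid_mu(self):
        with pytest.raises(ValueError):
            residual_deviance([1], [-1.0])
        with pytest.raises(ValueError):
            residual_deviance([1], [0.0])


def _const_fit_with_deviance(d, n_obs=10):
    base = fit_constant([1] * n_obs, [1.0] * n_obs)
    return replace(base, deviance=float(d))


class TestExplainedVariance:
    def test_extremes(self):
        null = _const_fit_with_deviance(8.0)
        assert explained_variance(replace(null, deviance=0.0, family="monotonic"), null) == 1.0
        assert explained_variance(replace(null, family="monotonic"), null) == 0.0

    def test_arithmetic(self):
        null = _const_fit_with_deviance(8.0)
        alt = replace(null, deviance=2.0, family="monotonic")
        assert explained_variance(alt, null) == pytest.approx(0.75)

    def test_null_must_be_constant(self):
        null = _const_fit_with_deviance(8.0)
        with pytest.raises(ValueError):
            explained_variance(null, replace(null, family="monotonic"))


class TestGeneCni:
    def test_noise_free_dosage_gene(self, rng):
        n = 200
        A, B = dispersed_cn(rng, n)
        g = np.exp(rng.normal(0, 0.3, n))
        g /= g.mean()
        x = np.round(50.0 * (A + B) * g)
        res = gene_cni(x, A, B, g)
        assert res.cni >= 0.95

    def test_constant_cn_gene_has_zero_cni(self, rng):
        n = 100
        x = rng.poisson(12.0, size=n)
        res = gene_cni(x, np.ones(n), np.ones(n), np.ones(n))
        assert res.explained_variance == 0.0
        assert res.cni == 0.0
        assert res.lrt.df == 0 and res.lrt.p == 1.0

    def test_ev_invariant_under_sample_permutation(self, rng):
        n = 80
        A, B = dispersed_cn(rng, n)
        x = rng.poisson(3.0 + 2.0 * (A + B))
        ev1 = gene_cni(x, A, B, np.ones(n)).explained_variance
        perm = rng.permutation(n)
        ev2 = gene_cni(x[perm], A[perm], B[perm], np.ones(n)).explained_variance
        assert ev1 == pytest.approx(ev2, abs=1e-9)

    def test_missing_cn_pairs_excluded(self, rng):
        n = 60
        A, B = dispersed_cn(rng, n)
        x = rng.poisson(3.0 + 2.0 * (A + B))
        A2, B2 = A.copy(), B.copy()
        A2[:10] = np.nan
        B2[:10] = np.nan
        res = gene_cni(x, A2, B2, np.ones(n))
        ref = gene_cni(x[10:], A[10:], B[10:], np.ones(n - 10))
        assert res.explained_variance == pytest.approx(ref.explained_variance, abs=1e-9)


def _gene_result(gene, d_null, d_alt, stat=1.0, df=1):
    return GeneCNI(
        gene_id=gene,
        explained_variance=1 - d_alt / d_null if d_null else 0.0,
        cni=float(np.sqrt(np.clip(1 - d_alt / d_null if d_null else 0.0, 0, 1))),
        lrt=LrtResult(statistic=stat, df=df, p=0.5),
        d_null=d_null,
        d_alt=d_alt,
        converged=True,
    )


class TestPathwayCni:
    def test_single_gene_pooling_identity(self):
        res = {"G1": _gene_result("G1", 8.0, 2.0)}
        pw = pathway_cni(res, ["G1"])
        assert pw.cni == pytest.approx(res["G1"].cni)
        assert pw.contributions == {"G1": 1.0}
        assert pw.perplexity == pytest.approx(1.0)

    def test_two_gene_arithmetic(self):
        res = {"G1": _gene_result("G1", 8.0, 2.0), "G2": _gene_result("G2", 4.0, 4.0)}
        pw = pathway_cni(res, ["G1", "G2"])
        assert pw.pooled_ev == pytest.approx(0.5)
        assert pw.cni == pytest.approx(np.sqrt(0.5))

    def test_all_unexplained_gives_zero(self):
        res = {g: _gene_result(g, 5.0, 5.0) for g in ("G1", "G2", "G3")}
        assert pathway_cni(res, ["G1", "G2", "G3"]).cni == 0.0

    def test_no_usable_members_errors(self):
        with pytest.raises(ValueError):
            pathway_cni({}, ["G1"])

    def test_pooled_ev_matches_concatenated_fit(self, rng):
        # three member genes with identical data: pooling the deviances must
        # equal the EV of one fit on the concatenated observations
        n = 100
        A, B = dispersed_cn(rng, n)
        x = rng.poisson(2.0 + 2.0 * (A + B))
        single = gene_cni(x, A, B, np.ones(n))
        res = {g: single for g in ("G1", "G2", "G3")}
        pooled = pathway_cni(res, ["G1", "G2", "G3"]).pooled_ev
        concat = gene_cni(
            np.tile(x, 3), np.tile(A, 3), np.tile(B, 3), np.ones(3 * n)
        ).explained_variance
        assert pooled == pytest.approx(concat, abs=1e-6)


class TestAdjustPvalues:
    def test_hand_bh(self):
        assert np.allclose(adjust_pvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_identities(self):
        assert adjust_pvalues([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(adjust_pvalues([1.0, 1.0]), 1.0)
        p = np.linspace(0.001, 0.9, 10)
        assert np.all(adjust_pvalues(p) >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])
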