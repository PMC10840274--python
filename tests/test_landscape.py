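"""Contribution shares, perplexity, threshold calibration, quadrants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnimpact.containers import CopyNumberProfile, PathwayCollection
from cnimpact.evaluation import threshold_brute_force
from cnimpact.landscape import (
    LandscapeThresholds,
    build_reference_distributions,
    classify_quadrants,
    gene_contributions,
    group_enrichment,
    mean_cna,
    optimize_threshold,
    perplexity,
)


def _profile(pairs):
    idx = pd.Index([f"G{i}" for i in range(len(pairs))])
    cols = pd.Index([f"S{j}" for j in range(len(pairs[0]))])
    a = pd.DataFrame([[p[0] for p in row] for row in pairs], index=idx, columns=cols)
    b = pd.DataFrame([[p[1] for p in row] for row in pairs], index=idx, columns=cols)
    return CopyNumberProfile(a.astype(float), b.astype(float))


class TestMeanCna:
    def test_diploid_gene(self):
        cn = _profile([[(1, 1), (1, 1)]])
        assert mean_cna(cn, "total").iloc[0] == pytest.approx(2.0)
        assert mean_cna(cn, "deviation").iloc[0] == pytest.approx(0.0)

    def test_total_mode_arithmetic(self):
        cn = _profile([[(2, 1), (4, 3)]])
        assert mean_cna(cn, "total").iloc[0] == pytest.approx(5.0)

    def test_empty_profile_errors(self):
        empty = CopyNumberProfile(pd.DataFrame(), pd.DataFrame())
        with pytest.raises(ValueError):
            mean_cna(empty)


class TestContributions:
    def test_single_gene(self):
        assert np.allclose(gene_contributions([8.0], [2.0]), [1.0])

    def test_identical_members_split_evenly(self):
        assert np.allclose(gene_contributions([8.0, 8.0], [2.0, 2.0]), [0.5, 0.5])

    def test_dominant_gene_takes_all(self):
        # removing G1 collapses the pooled EV; removing the others raises it
        p = gene_contributions([10.0, 5.0, 5.0], [0.0, 2.0, 2.0])
        assert np.allclose(p, [1.0, 0.0, 0.0])

    def test_degenerate_all_zero_uniform(self):
        assert np.allclose(gene_contributions([5.0, 5.0], [5.0, 5.0]), [0.5, 0.5])


class TestPerplexity:
    def test_reference_values(self):
        assert perplexity([0.25] * 4) == pytest.approx(4.0, abs=1e-9)
        assert perplexity([1.0, 0.0, 0.0]) == pytest.approx(1.0, abs=1e-9)
        assert perplexity([0.5, 0.25, 0.25]) == pytest.approx(2 ** 1.5, abs=1e-9)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            perplexity([0.5, 0.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=12))
    def test_bounds_on_random_simplex(self, raw):
        p = np.asarray(raw) / np.sum(raw)
        pi = perplexity(p)
        assert 1.0 - 1e-9 <= pi <= len(p) + 1e-9


class TestOptimizeThreshold:
    def test_separable(self):
        t, acc = optimize_threshold([0.8, 0.9], [0.1, 0.2])
        assert acc == 1.0 and 0.2 < t <= 0.8

    def test_identical_samples(self):
        _, acc = optimize_threshold([0.1, 0.2], [0.1, 0.2])
        assert acc == pytest.approx(0.5)

    def test_brute_force_example(self):
        t, acc = optimize_threshold([0.3, 0.7, 0.9], [0.1, 0.4, 0.5])
        assert acc == pytest.approx(5 / 6)
        assert 0.5 < t <= 0.7

    def test_matches_exhaustive_oracle_on_all_small_pairs(self, rng):
        for n_pos in range(1, 13):
            for n_neg in range(1, 13):
                pos = np.round(rng.uniform(0, 1, n_pos), 2)
                neg = np.round(rng.uniform(0, 1, n_neg), 2)
                _, acc = optimize_threshold(pos, neg)
                assert acc == pytest.approx(threshold_brute_force(pos, neg), abs=1e-12)

    def test_accuracy_at_least_half(self, rng):
        for _ in range(20):
            pos = rng.normal(0, 1, rng.integers(1, 9))
            neg = rng.normal(0.2, 1, rng.integers(1, 9))
            _, acc = optimize_threshold(pos, neg)
            assert acc >= 0.5


def _gene_stats():
    rows = {}
    for i in range(30):
        high = i < 15
        rows[f"G{i}"] = {
            "d_null": 100.0,
            "d_alt": 20.0 if high else 95.0,
            "mean_cna": 4.0 if high else 2.0,
        }
    return pd.DataFrame(rows).T


class TestReferenceDistributions:
    def test_deterministic_for_fixed_seed(self):
        stats = _gene_stats()
        pw = PathwayCollection({"cnp": ("G0", "G1", "G20"), "mutp": ("G20", "G21")})
        args = (pw, stats, ["G0"], ["G20"])
        r1 = build_reference_distributions(*args, n_resamples=5, seed=11)
        r2 = build_reference_distributions(*args, n_resamples=5, seed=11)
        assert np.array_equal(r1.cni_pos, r2.cni_pos)
        assert np.array_equal(r1.cna_neg, r2.cna_neg)

    def test_pathway_without_opposite_drivers_unchanged(self):
        stats = _gene_stats()
        pw = PathwayCollection({"cnp": ("G0", "G1"), "mutp": ("G20", "G21")})
        ref = build_reference_distributions(pw, stats, ["G0"], ["G20"], n_resamples=4, seed=3)
        assert np.allclose(ref.cni_pos, ref.cni_pos[0])

    def test_replacement_pulls_toward_background(self):
        # a CN-driver pathway whose mutation-driver member is replaced by
        # random genome genes must lose some of that member's low signal
        stats = _gene_stats()
        pw = PathwayCollection({"cnp": ("G0", "G1", "G20")})
        orig_cni = np.sqrt(1 - (20 + 20 + 95) / 300)
        ref = build_reference_distributions(
            pw, stats, ["G0"], ["G20"], n_resamples=200, seed=5
        )
        assert ref.cni_pos.mean() != pytest.approx(orig_cni, abs=1e-3)

    def test_empty_driver_list_rejected(self):
        with pytest.raises(ValueError):
            build_reference_distributions(
                PathwayCollection({"p": ("G0",)}), _gene_stats(), [], ["G1"]
            )


class TestQuadrantsAndEnrichment:
    def test_quadrant_rules(self):
        th = LandscapeThresholds(0.5, 3.0, 1.0, 1.0, 10, 0)
        stats = pd.DataFrame(
            {
                "hi_hi": {"cni": 0.8, "mean_cna": 4.0},
                "hi_lo": {"cni": 0.8, "mean_cna": 2.0},
                "lo_hi": {"cni": 0.2, "mean_cna": 4.0},
                "lo_lo": {"cni": 0.2, "mean_cna": 2.0},
            }
        ).T
        q = classify_quadrants(stats, th)
        assert q["hi_hi"] == "cn_driven"
        assert q["hi_lo"] == "conserved"
        assert q["lo_hi"] == "passenger"
        assert q["lo_lo"] == "non_cn_driven"

    def test_group_enrichment_labels(self):
        stacked = pd.DataFrame(
            {
                "direction": ["poor", "good", "poor", "good"],
                "q": [0.01, 0.01, 0.5, 0.5],
            },
            index=["G1", "G2", "G3", "G4"],
        )
        pw = PathwayCollection(
            {
                "only_poor": ("G1", "G3"),
                "both": ("G1", "G2"),
                "nothing": ("G3", "G4"),
            }
        )
        labels = group_enrichment(stacked, pw, q_threshold=0.05)
        assert labels["only_poor"] == "poor"
        assert labels["both"] == "both"
        assert labels["nothing"] == "none"

    def test_enrichment_requires_fits(self):
        with pytest.raises(ValueError):
            group_enrichment(pd.DataFrame(), PathwayCollection({"p": ("G1",)}))
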