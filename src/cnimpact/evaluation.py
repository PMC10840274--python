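"""Calibration and recovery benchmarks.

Each function simulates data from a known truth with an explicit seed,
runs the corresponding part of the package, and returns a scalar summary
(an error, a rate, an accuracy).  The suite doubles as the package's
self-check: closed-form agreement for the constant model, conservatism of
the boundary-constrained likelihood-ratio test, parameter and direction
recovery, transition-point recovery, and landscape classification on a
planted cohort.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import landscape as ls
from .cni import cni_table, gene_cni
from .containers import PathwayCollection
from .models import (
    fit_constant,
    fit_linear,
    fit_monotonic,
    fit_stacked_monotonic,
    lrt,
)
from .simulate import SimulationConfig, simulate_cohort
from .transition import transition_point

__all__ = [
    "constant_closed_form_error",
    "null_lrt_rejection_rate",
    "linear_slope_recovery",
    "cni_dosage_gene",
    "cni_null_fraction_within",
    "monotonic_over_linear_rate",
    "transition_recovery_rate",
    "threshold_brute_force",
    "threshold_oracle_agreement",
    "landscape_recovery_accuracy",
    "stacked_direction_recovery_rate",
]


def _dispersed_cn(rng: np.random.Generator, n: int, probs=None):
    """Dispersed total-CN states with a balanced, occasionally imbalanced
    allele split (the generator's default aberrant-state distribution)."""
    probs = np.asarray(probs if probs is not None else SimulationConfig().dispersed_cn_probs)
    total = rng.choice(np.arange(probs.size), size=n, p=probs)
    b = np.floor(total / 2.0)
    imb = rng.random(n) < 0.3
    b[imb] = rng.integers(0, np.floor(total[imb] / 2.0).astype(int) + 1)
    return total - b, b


def _concentrated_cn(rng: np.random.Generator, n: int):
    """Diploid-concentrated CN states (the generator's independent /
    conserved class distribution)."""
    probs = np.asarray(SimulationConfig().concentrated_cn_probs)
    total = rng.choice(np.arange(probs.size), size=n, p=probs)
    b = np.floor(total / 2.0)
    imb = rng.random(n) < 0.3
    b[imb] = rng.integers(0, np.floor(total[imb] / 2.0).astype(int) + 1)
    return total - b, b


def _scales(rng: np.random.Generator, n: int, sigma: float = 0.3) -> np.ndarray:
    g = np.exp(rng.normal(0.0, sigma, size=n))
    return g / g.mean()


def constant_closed_form_error(n_genes: int = 1000, n_samples: int = 100, seed: int = 0) -> float:
    """Max |b0_hat - sum(x)/sum(g)| over random genes (closed-form oracle)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_genes):
        g = _scales(rng, n_samples)
        b0 = rng.uniform(0.5, 100.0)
        x = rng.poisson(b0 * g)
        fit = fit_constant(x, g)
        worst = max(worst, abs(fit.params["b0"] - x.sum() / g.sum()))
    return worst


def null_lrt_rejection_rate(
    n_genes: int = 1000, n_samples: int = 200, alpha: float = 0.05, seed: int = 0
) -> float:
    """Rejection rate of the constant-vs-monotonic LRT on genes simulated
    from the constant model with dispersed copy number.  The nonnegativity
    constraints make the chi-square reference conservative, so the rate
    should sit at or below the nominal level."""
    rng = np.random.default_rng(seed)
    rejected = 0
    for i in range(n_genes):
        g = _scales(rng, n_samples)
        A, B = _dispersed_cn(rng, n_samples)
        b0 = rng.uniform(5.0, 50.0)
        x = rng.poisson(b0 * g)
        null = fit_constant(x, g)
        alt = fit_monotonic(x, A, B, g, k_max=8, seed=i)
        if lrt(null, alt).p < alpha:
            rejected += 1
    return rejected / n_genes


def linear_slope_recovery(
    n_reps: int = 50, n: int = 500, b0: float = 5.0, a: float = 2.0, seed: int = 0
) -> float:
    """Median relative error of the linear CNA effect a over replicates."""
    rng = np.random.default_rng(seed)
    errors = []
    for i in range(n_reps):
        total = rng.integers(0, 7, size=n)
        B = np.floor(total / 2.0)
        A = total - B
        g = _scales(rng, n)
        x = rng.poisson((b0 + a * (A + B)) * g)
        fit = fit_linear(x, A, B, g, seed=i)
        errors.append(abs(fit.params["a"] - a) / a)
    return float(np.median(errors))


def cni_dosage_gene(n: int = 200, scale: float = 50.0, seed: int = 0) -> float:
    """CNI of a noise-free dosage gene (counts proportional to total CN)."""
    rng = np.random.default_rng(seed)
    A, B = _dispersed_cn(rng, n)
    g = _scales(rng, n)
    x = np.round(scale * (A + B) * g)
    return gene_cni(x, A, B, g, family="monotonic").cni


def cni_null_fraction_within(
    bound: float = 0.15, n_seeds: int = 100, n: int = 200, seed: int = 0
) -> float:
    """Fraction of CN-independent genes whose estimated CNI stays below
    ``bound``.  CN states follow the generator's independent-class
    (diploid-concentrated) distribution."""
    rng = np.random.default_rng(seed)
    ok = 0
    for i in range(n_seeds):
        A, B = _concentrated_cn(rng, n)
        g = _scales(rng, n)
        b0 = rng.uniform(5.0, 50.0)
        x = rng.poisson(b0 * g)
        if gene_cni(x, A, B, g, family="monotonic", seed=i).cni <= bound:
            ok += 1
    return ok / n_seeds


def monotonic_over_linear_rate(
    n_reps: int = 100, n: int = 200, b0: float = 10.0, a: float = 20.0, seed: int = 0
) -> float:
    """Fraction of replicates where the monotonic model out-fits the linear
    one on data with a saturating dose-response (a single early step, flat
    above)."""
    rng = np.random.default_rng(seed)
    wins = 0
    for i in range(n_reps):
        A, B = _dispersed_cn(rng, n)
        g = _scales(rng, n)
        mu = (b0 + a * ((A >= 1).astype(float) + (B >= 1).astype(float))) * g
        x = rng.poisson(mu)
        mono = fit_monotonic(x, A, B, g, k_max=8, seed=i)
        lin = fit_linear(x, A, B, g, seed=i)
        if mono.loglik > lin.loglik:
            wins += 1
    return wins / n_reps


def transition_recovery_rate(
    n_reps: int = 100,
    n: int = 300,
    b0: float = 10.0,
    a: float = 30.0,
    true_t: float = 2.5,
    tol: float = 0.5,
    seed: int = 0,
) -> float:
    """Fraction of replicates recovering a planted expression step between
    total CN 2 and 3 to within ``tol``.  Totals are uniform on 0..5 with a
    balanced allele split; the jump is planted at major-allele level 2."""
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_reps):
        total = rng.integers(0, 6, size=n)
        B = np.floor(total / 2.0)
        A = total - B
        g = _scales(rng, n)
        mu = (b0 + a * ((A >= 2).astype(float) + (B >= 2).astype(float))) * g
        x = rng.poisson(mu)
        fit = fit_monotonic(x, A, B, g, k_max=8, seed=i)
        res = transition_point(fit, x, g)
        if res.transition_point is not None and abs(res.transition_point - true_t) <= tol:
            hits += 1
    return hits / n_reps


def threshold_brute_force(pos, neg) -> float:
    """Exhaustive reference for the separating-threshold accuracy: evaluate
    every cut at each pooled value, every adjacent midpoint and both
    outside cuts, and return the best accuracy."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    pooled = np.sort(np.concatenate([pos, neg]))
    cuts = set(pooled.tolist())
    cuts |= {0.5 * (u + v) for u, v in itertools.pairwise(pooled)}
    cuts |= {pooled[0] - 1.0, pooled[-1] + 1.0}
    n = pos.size + neg.size
    return max(((pos >= t).sum() + (neg < t).sum()) / n for t in cuts)


def threshold_oracle_agreement(max_size: int = 12, draws: int = 3, seed: int = 0) -> float:
    """Fraction of random sample pairs (all sizes up to ``max_size``) on
    which the threshold optimizer attains the brute-force accuracy."""
    rng = np.random.default_rng(seed)
    total = agree = 0
    for n_pos in range(1, max_size + 1):
        for n_neg in range(1, max_size + 1):
            for _ in range(draws):
                pos = np.round(rng.uniform(0, 1, size=n_pos), 2)
                neg = np.round(rng.uniform(0, 1, size=n_neg), 2)
                _, acc = ls.optimize_threshold(pos, neg)
                total += 1
                if abs(acc - threshold_brute_force(pos, neg)) < 1e-12:
                    agree += 1
    return agree / total


def landscape_recovery_accuracy(
    n_pathways: int = 40, n_resamples: int = 1000, seed: int = 17
) -> float:
    """Quadrant classification accuracy on a planted four-quadrant cohort.

    The cohort holds equal numbers of CN-driven, passenger, conserved and
    CN-independent pathways; thresholds are calibrated from the planted
    driver gene lists via the resampling procedure.
    """
    config = SimulationConfig(
        n_genes=520,
        n_samples=150,
        n_pathways=n_pathways,
        pathway_size=(10, 13),
        class_fractions={
            "cn_driven": 0.25,
            "passenger": 0.25,
            "conserved": 0.25,
            "independent": 0.25,
            "group_modulated": 0.0,
        },
        seed=seed,
    )
    expr, cn, pathways, _groups, truth = simulate_cohort(config)
    results = cni_table(expr, cn, family="monotonic", seed=seed)
    gene_mean_cna = ls.mean_cna(cn, mode="total")
    gene_stats = pd.DataFrame(
        {
            "d_null": {g: r.d_null for g, r in results.items()},
            "d_alt": {g: r.d_alt for g, r in results.items()},
            "mean_cna": gene_mean_cna,
        }
    ).dropna()
    cn_drivers = list(truth.genes.index[truth.genes["class"] == "cn_driven"])
    mut_drivers = list(truth.genes.index[truth.genes["class"] == "independent"])
    ref = ls.build_reference_distributions(
        pathways,
        gene_stats,
        cn_drivers,
        mut_drivers,
        n_resamples=n_resamples,
        seed=seed,
    )
    thresholds = ls.calibrate_thresholds(ref, n_resamples=n_resamples, seed=seed)
    stats = pd.DataFrame(
        {
            name: {
                "cni": _pooled(gene_stats, members)[0],
                "mean_cna": _pooled(gene_stats, members)[1],
            }
            for name, members in pathways.items()
        }
    ).T
    pred = ls.classify_quadrants(stats, thresholds)
    truth_q = truth.pathways["quadrant"]
    common = pred.index.intersection(truth_q.index)
    return float((pred.loc[common] == truth_q.loc[common]).mean())


def _pooled(gene_stats: pd.DataFrame, members) -> tuple[float, float]:
    sub = gene_stats.loc[[m for m in members if m in gene_stats.index]]
    tot = sub["d_null"].sum()
    ev = 0.0 if tot == 0 else 1.0 - sub["d_alt"].sum() / tot
    return float(np.sqrt(np.clip(ev, 0, 1))), float(sub["mean_cna"].mean())


def stacked_direction_recovery_rate(
    n_reps: int = 100,
    n: int = 200,
    b0: float = 10.0,
    a: float = 2.0,
    deviation: float = 2.0,
    seed: int = 0,
) -> float:
    """Fraction of replicates where the stacked model places its deviations
    on the group that truly carries the planted extra CNA effect ('poor';
    its step at allele level 2 is larger by ``deviation``)."""
    rng = np.random.default_rng(seed)
    labels = np.array(["good", "poor"] * (n // 2))
    ind = (labels == "poor").astype(float)
    correct = 0
    for i in range(n_reps):
        A, B = _dispersed_cn(rng, n)
        g = _scales(rng, n)
        s2 = (A >= 2).astype(float) + (B >= 2).astype(float)
        mu = (b0 + a * (A + B) + ind * deviation * s2) * g
        x = rng.poisson(mu)
        fit = fit_stacked_monotonic(x, A, B, g, labels, k_max=8, seed=i)
        if fit.direction == "poor":
            correct += 1
    return correct / n_reps
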