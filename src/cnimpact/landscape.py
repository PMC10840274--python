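"""Pathway-level structure: gene contributions, perplexity, and the
CNA-versus-CNI landscape.

Each pathway is placed in a plane spanned by its pooled CNI (how strongly
copy number drives member expression) and its mean absolute copy number
(how aberrant the members are).  Thresholds on the two axes are calibrated
from known driver genes: pathways containing copy-number drivers anchor
the high/high corner and pathways containing mutation drivers the low/low
corner; resampling replaces the opposite driver type with random genome
genes to strip confounded signal.  The resulting quadrants are putative
CN-driven, conserved, passenger and non-CN-driven pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CopyNumberProfile, PathwayCollection

logger = logging.getLogger(__name__)

__all__ = [
    "QUADRANTS",
    "LandscapeThresholds",
    "ReferenceDistributions",
    "mean_cna",
    "gene_contributions",
    "perplexity",
    "build_reference_distributions",
    "optimize_threshold",
    "classify_quadrants",
    "group_enrichment",
    "plot_landscape",
]

QUADRANTS = ("cn_driven", "conserved", "non_cn_driven", "passenger")


@dataclass(frozen=True)
class LandscapeThresholds:
    cni_threshold: float
    cna_threshold: float
    accuracy_cni: float
    accuracy_cna: float
    n_resamples: int
    seed: int


@dataclass(frozen=True)
class ReferenceDistributions:
    """Resampled pathway statistics anchoring the two landscape corners.

    ``*_pos`` come from copy-number-driver pathways (high corner), ``*_neg``
    from mutation-driver pathways (low corner)."""

    cni_pos: np.ndarray
    cni_neg: np.ndarray
    cna_pos: np.ndarray
    cna_neg: np.ndarray


def mean_cna(cn: CopyNumberProfile, mode: str = "total") -> pd.Series:
    """Per-gene average absolute copy number across samples.

    mode ``total`` averages A+B; mode ``deviation`` averages |A+B-2|, which
    makes deletion-driven aberration visible.  Genes missing in every
    sample are excluded with a warning.
    """
    total = cn.total
    if total.size == 0:
        raise ValueError("empty copy-number profile")
    if mode == "total":
        vals = total
    elif mode == "deviation":
        vals = (total - 2.0).abs()
    else:
        raise ValueError(f"unknown mean_cna mode {mode!r}")
    out = vals.mean(axis=1, skipna=True)
    dropped = out.index[out.isna()]
    if len(dropped):
        logger.warning("%d genes without any CN call excluded from mean CNA", len(dropped))
        out = out.dropna()
    if out.empty:
        raise ValueError("no gene has any copy-number call")
    return out


def gene_contributions(d_null, d_alt) -> np.ndarray:
    """Leave-one-out contribution shares of member genes to the pooled EV.

    Delta_i = pooled_EV(all) - pooled_EV(without i), clipped at 0 and
    normalized to sum to 1.  If every delta is 0 (no gene matters) the
    shares are uniform.
    """
    d_null = np.asarray(d_null, dtype=float).ravel()
    d_alt = np.asarray(d_alt, dtype=float).ravel()
    if d_null.shape != d_alt.shape or d_null.size == 0:
        raise ValueError("d_null and d_alt must be equal-length, nonempty")
    k = d_null.size
    if k == 1:
        return np.array([1.0])
    tot_n, tot_a = d_null.sum(), d_alt.sum()
    ev_full = 0.0 if tot_n == 0 else 1.0 - tot_a / tot_n
    loo_n = tot_n - d_null
    loo_a = tot_a - d_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        ev_loo = np.where(loo_n > 0, 1.0 - loo_a / np.where(loo_n > 0, loo_n, 1.0), 0.0)
    delta = np.clip(ev_full - ev_loo, 0.0, None)
    if delta.sum() == 0:
        logger.info("all leave-one-out deltas zero; uniform contributions")
        return np.full(k, 1.0 / k)
    return delta / delta.sum()


def perplexity(p) -> float:
    """Effective number of contributing genes: exp of the entropy of the
    contribution shares, with 0*log(0) = 0.  Lies in [1, k]."""
    p = np.asarray(p, dtype=float).ravel()
    if (p < 0).any():
        raise ValueError("contribution shares must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"contribution shares must sum to 1 (got {p.sum()!r})")
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(p > 0, p * np.log(p), 0.0).sum()
    return float(np.exp(ent))


def _pooled_cni(members, gene_stats: pd.DataFrame) -> tuple[float, float]:
    sub = gene_stats.loc[[m for m in members if m in gene_stats.index]]
    if sub.empty:
        raise ValueError("no member gene with statistics")
    tot_n = sub["d_null"].sum()
    ev = 0.0 if tot_n == 0 else 1.0 - sub["d_alt"].sum() / tot_n
    return float(np.sqrt(np.clip(ev, 0.0, 1.0))), float(sub["mean_cna"].mean())


def build_reference_distributions(
    pathways: PathwayCollection,
    gene_stats: pd.DataFrame,
    cn_driver_genes,
    mutation_driver_genes,
    genome_genes=None,
    n_resamples: int = 1000,
    seed: int = 0,
) -> ReferenceDistributions:
    """Resampled CNI / mean-CNA distributions for threshold calibration.

    ``gene_stats`` is a per-gene table with columns ``d_null``, ``d_alt``
    and ``mean_cna``.  Pathways containing at least one CN driver gene form
    the positive set; in each resample their mutation-driver members are
    replaced with genes drawn uniformly from the genome pool and the
    pathway CNI and mean CNA are recomputed.  Pathways containing mutation
    drivers are treated symmetrically (their CN-driver members are
    replaced).  Fully reproducible for a fixed seed.
    """
    cn_driver_genes = set(cn_driver_genes)
    mutation_driver_genes = set(mutation_driver_genes)
    if not cn_driver_genes or not mutation_driver_genes:
        raise ValueError("both driver gene lists must be nonempty")
    if genome_genes is None:
        genome_genes = list(gene_stats.index)
    pool = [g for g in genome_genes if g in gene_stats.index]
    if not pool:
        raise ValueError("genome gene pool shares no genes with the statistics table")
    rng = np.random.default_rng(seed)

    def resample(members: tuple[str, ...], to_replace: set) -> list[tuple[float, float]]:
        members = [m for m in members if m in gene_stats.index]
        keep = [m for m in members if m not in to_replace]
        n_swap = len(members) - len(keep)
        out = []
        for _ in range(n_resamples):
            if n_swap == 0:
                out.append(_pooled_cni(members, gene_stats))
                continue
            for _attempt in range(100):
                draw = rng.choice(pool, size=n_swap, replace=False)
                new_members = keep + [g for g in draw if g not in keep]
                if new_members:
                    break
                logger.info("resample left pathway empty; redrawing")
            out.append(_pooled_cni(new_members, gene_stats))
        return out

    cni_pos, cna_pos, cni_neg, cna_neg = [], [], [], []
    for name, members in pathways.items():
        present = [m for m in members if m in gene_stats.index]
        if not present:
            continue
        if cn_driver_genes & set(present):
            for c, a in resample(tuple(present), mutation_driver_genes):
                cni_pos.append(c)
                cna_pos.append(a)
        if mutation_driver_genes & set(present):
            for c, a in resample(tuple(present), cn_driver_genes):
                cni_neg.append(c)
                cna_neg.append(a)
    if not cni_pos or not cni_neg:
        raise ValueError("driver lists select no pathways on one side of the landscape")
    return ReferenceDistributions(
        cni_pos=np.array(cni_pos),
        cni_neg=np.array(cni_neg),
        cna_pos=np.array(cna_pos),
        cna_neg=np.array(cna_neg),
    )


def optimize_threshold(pos, neg) -> tuple[float, float]:
    """Cut separating two one-dimensional samples with maximal accuracy.

    Candidates are the midpoints of adjacent order statistics of the pooled
    sample plus cuts below the minimum and above the maximum; positives are
    declared at values >= threshold, accuracy = (TP + TN) / n.  Ties pick
    the smallest threshold.
    """
    pos = np.asarray(pos, dtype=float).ravel()
    neg = np.asarray(neg, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.unique(np.concatenate([pos, neg]))
    candidates = [pooled[0] - 1.0]
    candidates += [0.5 * (u + v) for u, v in zip(pooled, pooled[1:])]
    candidates += [pooled[-1] + 1.0]
    n = pos.size + neg.size
    best_t, best_acc = candidates[0], -1.0
    for t in candidates:
        acc = ((pos >= t).sum() + (neg < t).sum()) / n
        if acc > best_acc + 1e-12:
            best_t, best_acc = t, acc
    return float(best_t), float(best_acc)


def calibrate_thresholds(
    ref: ReferenceDistributions, n_resamples: int, seed: int
) -> LandscapeThresholds:
    """Independent threshold optimization on the CNI and CNA axes."""
    t_cni, acc_cni = optimize_threshold(ref.cni_pos, ref.cni_neg)
    t_cna, acc_cna = optimize_threshold(ref.cna_pos, ref.cna_neg)
    return LandscapeThresholds(
        cni_threshold=t_cni,
        cna_threshold=t_cna,
        accuracy_cni=acc_cni,
        accuracy_cna=acc_cna,
        n_resamples=n_resamples,
        seed=seed,
    )


def classify_quadrants(
    pathway_stats: pd.DataFrame, thresholds: LandscapeThresholds
) -> pd.Series:
    """Assign each pathway a landscape quadrant from its (cni, mean_cna).

    high CNI & high CNA -> cn_driven; high CNI & low CNA -> conserved;
    low CNI & high CNA -> passenger; low & low -> non_cn_driven.
    Pathways with a missing statistic are skipped with a warning.
    """
    required = {"cni", "mean_cna"}
    if not required <= set(pathway_stats.columns):
        raise ValueError("pathway_stats requires columns 'cni' and 'mean_cna'")
    labels = {}
    for name, row in pathway_stats.iterrows():
        if pd.isna(row["cni"]) or pd.isna(row["mean_cna"]):
            logger.warning("pathway %s skipped: missing statistic", name)
            continue
        hi_cni = row["cni"] >= thresholds.cni_threshold
        hi_cna = row["mean_cna"] >= thresholds.cna_threshold
        if hi_cni and hi_cna:
            labels[name] = "cn_driven"
        elif hi_cni:
            labels[name] = "conserved"
        elif hi_cna:
            labels[name] = "passenger"
        else:
            labels[name] = "non_cn_driven"
    return pd.Series(labels, name="quadrant")


def group_enrichment(
    stacked_results: pd.DataFrame,
    pathways: PathwayCollection,
    q_threshold: float = 0.05,
) -> pd.Series:
    """Label pathways by the response group their genes' CNA effects favor.

    ``stacked_results`` is a per-gene table with columns ``direction`` (the
    group carrying the stacked deviations) and ``q`` (BH-adjusted p of the
    stacked-vs-constant LRT).  A pathway is labeled with a group when it
    contains at least one significant gene whose deviations favor that
    group; ``both`` when both directions occur, ``none`` otherwise.
    """
    if not {"direction", "q"} <= set(stacked_results.columns):
        raise ValueError("stacked_results requires columns 'direction' and 'q'")
    if stacked_results.empty:
        raise ValueError("no stacked fits supplied")
    sig = stacked_results[stacked_results["q"] < q_threshold]
    labels = {}
    for name, members in pathways.items():
        hits = sig.loc[sig.index.intersection(list(members)), "direction"]
        dirs = set(hits)
        if len(dirs) >= 2:
            labels[name] = "both"
        elif len(dirs) == 1:
            labels[name] = next(iter(dirs))
        else:
            labels[name] = "none"
    return pd.Series(labels, name="enrichment")


def plot_landscape(
    pathway_stats: pd.DataFrame,
    thresholds: LandscapeThresholds,
    quadrants: pd.Series,
    path,
) -> None:
    """Scatter of pathway CNI vs mean CNA, colored by quadrant."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        "cn_driven": "tab:red",
        "conserved": "tab:blue",
        "non_cn_driven": "tab:orange",
        "passenger": "tab:green",
    }
    fig, ax = plt.subplots(figsize=(6, 5))
    for quad in QUADRANTS:
        idx = quadrants.index[quadrants == quad]
        sub = pathway_stats.loc[pathway_stats.index.intersection(idx)]
        ax.scatter(sub["mean_cna"], sub["cni"], s=18, label=quad, color=colors[quad])
    ax.axhline(thresholds.cni_threshold, ls="--", c="gray", lw=0.8)
    ax.axvline(thresholds.cna_threshold, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("mean absolute CNA")
    ax.set_ylabel("pathway CNI")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
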