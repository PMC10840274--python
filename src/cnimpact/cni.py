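"""Copy-number impact (CNI) at gene and pathway level.

The explained variance of a copy-number model is the deviance-based R²
against the constant model, EV = 1 - D_alt / D_null, where D is the
residual Poisson deviance versus the saturated model.  CNI is the
generalized correlation sqrt(clip(EV, 0, 1)).  Pathway-level CNI pools
the member genes' deviances before forming the ratio, so that genes with
more expression variation weigh more; the pooled likelihood-ratio test
sums the member statistics and degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CopyNumberProfile, ExpressionMatrix, SampleScale
from .models import (
    LrtResult,
    ModelFit,
    fit_constant,
    fit_linear,
    fit_monotonic,
    lrt,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneCNI",
    "PathwayCNI",
    "residual_deviance",
    "explained_variance",
    "gene_cni",
    "cni_table",
    "pathway_cni",
    "adjust_pvalues",
]


@dataclass(frozen=True)
class GeneCNI:
    gene_id: str | None
    explained_variance: float
    cni: float
    lrt: LrtResult
    d_null: float
    d_alt: float
    converged: bool
    q: float | None = None
    null_fit: ModelFit | None = None
    alt_fit: ModelFit | None = None


@dataclass(frozen=True)
class PathwayCNI:
    pathway_id: str | None
    members_used: tuple[str, ...]
    members_unused: tuple[str, ...]
    pooled_ev: float
    cni: float
    lrt_pooled: LrtResult
    mean_cna: float | None = None
    contributions: dict[str, float] | None = None
    perplexity: float | None = None


def residual_deviance(x, mu) -> float:
    """Residual Poisson deviance  D = 2 sum_j [x ln(x/mu) - (x - mu)],
    with the x=0 term taken as 2*mu."""
    x = np.asarray(x, dtype=float).ravel()
    mu = np.asarray(mu, dtype=float).ravel()
    if x.shape != mu.shape:
        raise ValueError("x and mu must have equal length")
    if (mu < 0).any():
        raise ValueError("negative mean in deviance")
    if ((mu == 0) & (x > 0)).any():
        raise ValueError("mu must be positive wherever x > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(x > 0, x * np.log(x / np.maximum(mu, 1e-300)), 0.0)
    return float(2.0 * (term - (x - mu)).sum())


def explained_variance(alt: ModelFit, null: ModelFit) -> float:
    """Deviance-based R² of ``alt`` over the constant model: 1 - D_alt/D_null.
    Defined as 0 when the null deviance is 0.  May be negative; it is
    clipped to [0, 1] only when converted to CNI."""
    if null.family != "constant":
        raise ValueError("null fit must be the constant family")
    if null.n_obs != alt.n_obs:
        raise ValueError("fits compare different data (n_obs mismatch)")
    if null.deviance == 0:
        return 0.0
    return 1.0 - alt.deviance / null.deviance


def _cni_from_ev(ev: float) -> float:
    return float(np.sqrt(np.clip(ev, 0.0, 1.0)))


def gene_cni(
    x,
    A,
    B,
    g,
    family: str = "monotonic",
    k_max: int = 8,
    seed: int = 0,
    gene_id: str | None = None,
    keep_fits: bool = False,
) -> GeneCNI:
    """Fit the constant and the requested alternative model for one gene and
    return its explained variance, CNI and likelihood-ratio test.

    Missing copy-number pairs are excluded from both fits.  If the
    alternative fit does not converge the CNI is reported as NaN with the
    ``converged`` flag cleared.
    """
    A = np.asarray(A, dtype=float).ravel()
    B = np.asarray(B, dtype=float).ravel()
    gv = np.asarray(g.values if isinstance(g, SampleScale) else g, dtype=float).ravel()
    xv = np.asarray(x, dtype=float).ravel()
    mask = ~np.isnan(A) & ~np.isnan(B)
    xv, gv, A, B = xv[mask], gv[mask], A[mask], B[mask]
    null = fit_constant(xv, gv)
    if family == "monotonic":
        alt = fit_monotonic(xv, A, B, gv, k_max=k_max, seed=seed)
    elif family == "linear":
        alt = fit_linear(xv, A, B, gv, with_interaction=False, seed=seed)
    elif family == "interaction":
        alt = fit_linear(xv, A, B, gv, with_interaction=True, seed=seed)
    else:
        raise ValueError(f"unsupported alternative family {family!r}")
    test = lrt(null, alt)
    if not alt.converged:
        logger.warning("gene %s: alternative fit did not converge", gene_id)
        ev, cni_val = float("nan"), float("nan")
    else:
        ev = explained_variance(alt, null)
        cni_val = _cni_from_ev(ev)
    return GeneCNI(
        gene_id=gene_id,
        explained_variance=ev,
        cni=cni_val,
        lrt=test,
        d_null=null.deviance,
        d_alt=alt.deviance,
        converged=alt.converged,
        null_fit=null if keep_fits else None,
        alt_fit=alt if keep_fits else None,
    )


def cni_table(
    expr: ExpressionMatrix,
    cn: CopyNumberProfile,
    g: SampleScale | None = None,
    family: str = "monotonic",
    k_max: int = 8,
    seed: int = 0,
    keep_fits: bool = False,
) -> dict[str, GeneCNI]:
    """Gene-level CNI for every gene of an aligned expression/CN pair, with
    BH-adjusted q-values filled in."""
    from .io import align
    from .models import estimate_sample_scales

    expr, cn = align(expr, cn)
    if g is None:
        g = estimate_sample_scales(expr)
    gvec = g.g.reindex(expr.sample_ids).to_numpy()
    if np.isnan(gvec).any():
        raise ValueError("sample scales missing for some samples")
    results: dict[str, GeneCNI] = {}
    for idx, gene in enumerate(expr.gene_ids):
        results[gene] = gene_cni(
            expr.counts.loc[gene].to_numpy(),
            cn.major.loc[gene].to_numpy(),
            cn.minor.loc[gene].to_numpy(),
            gvec,
            family=family,
            k_max=k_max,
            seed=seed + idx,
            gene_id=gene,
            keep_fits=keep_fits,
        )
    genes = list(results)
    qs = adjust_pvalues([results[gene].lrt.p for gene in genes])
    for gene, q in zip(genes, qs):
        results[gene] = replace(results[gene], q=float(q))
    return results


def pathway_cni(
    results: dict[str, GeneCNI],
    members,
    pathway_id: str | None = None,
    gene_mean_cna: pd.Series | dict | None = None,
    compute_contributions: bool = True,
) -> PathwayCNI:
    """Pool gene-level deviances into a pathway CNI.

    pooled EV = 1 - (sum_i D_alt,i) / (sum_i D_null,i) over the member
    genes with converged fits; the pooled LRT sums statistics and degrees
    of freedom.  Per-gene leave-one-out contributions and their perplexity
    (the effective number of contributing genes) are attached by default.
    """
    members = list(members)
    used = [m for m in members if m in results and results[m].converged]
    unused = [m for m in members if m not in used]
    if not used:
        raise ValueError(f"pathway {pathway_id!r}: no member gene with a converged fit")
    d_null = np.array([results[m].d_null for m in used])
    d_alt = np.array([results[m].d_alt for m in used])
    pooled_ev = 0.0 if d_null.sum() == 0 else 1.0 - d_alt.sum() / d_null.sum()
    stat = float(sum(results[m].lrt.statistic for m in used))
    df = int(sum(results[m].lrt.df for m in used))
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    contributions = perplexity_val = None
    if compute_contributions:
        from .landscape import gene_contributions, perplexity

        shares = gene_contributions(d_null, d_alt)
        contributions = dict(zip(used, map(float, shares)))
        perplexity_val = perplexity(shares)
    mean_cna = None
    if gene_mean_cna is not None:
        vals = [gene_mean_cna[m] for m in used if m in gene_mean_cna]
        if vals:
            mean_cna = float(np.mean(vals))
    return PathwayCNI(
        pathway_id=pathway_id,
        members_used=tuple(used),
        members_unused=tuple(unused),
        pooled_ev=float(pooled_ev),
        cni=_cni_from_ev(pooled_ev),
        lrt_pooled=LrtResult(statistic=stat, df=df, p=p),
        mean_cna=mean_cna,
        contributions=contributions,
        perplexity=perplexity_val,
    )


def adjust_pvalues(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving,
    q >= p elementwise)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
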