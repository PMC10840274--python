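"""Seeded synthetic cohorts with known ground truth.

The generator draws allele-specific integer copy-number states per gene
and sample, then samples expression counts from the same Poisson model
families the package fits, so every planted signal is recoverable in
principle.  Gene classes:

* ``cn_driven``    — dispersed copy number, strong dosage effect;
* ``passenger``    — dispersed copy number, expression independent of CN;
* ``conserved``    — copy number concentrated near diploid, strong dosage
                     effect in the rare aberrant samples;
* ``independent``  — diploid-concentrated CN, constant expression;
* ``group_modulated`` — dosage effect plus nonnegative deviations applied
                     to one of two response groups (stacked model).

Pathways are assembled from genes of a single class, so each carries a
planted landscape quadrant.  All randomness flows through one explicit
seed; identical configurations reproduce byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CopyNumberProfile,
    ExpressionMatrix,
    PathwayCollection,
    SampleGroups,
)

__all__ = [
    "GENE_CLASSES",
    "SimulationConfig",
    "TruthTable",
    "simulate_copy_numbers",
    "simulate_expression",
    "simulate_cohort",
    "write_cohort",
]

GENE_CLASSES = ("cn_driven", "passenger", "conserved", "independent", "group_modulated")

_CLASS_QUADRANT = {
    "cn_driven": "cn_driven",
    "passenger": "passenger",
    "conserved": "conserved",
    "independent": "non_cn_driven",
    "group_modulated": "cn_driven",
}

#: total-CN state probabilities, indices 0..c_max
_DISPERSED = (0.03, 0.07, 0.25, 0.20, 0.15, 0.12, 0.08, 0.06, 0.04)
_CONCENTRATED = (0.0, 0.05, 0.90, 0.05, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    n_samples: int = 200
    n_pathways: int = 50
    pathway_size: tuple[int, int] = (10, 40)
    c_max: int = 8
    class_fractions: dict = field(
        default_factory=lambda: {c: 0.2 for c in GENE_CLASSES}
    )
    dispersed_cn_probs: tuple[float, ...] = _DISPERSED
    concentrated_cn_probs: tuple[float, ...] = _CONCENTRATED
    b0_range: tuple[float, float] = (5.0, 50.0)
    a_range: tuple[float, float] = (2.0, 5.0)
    conserved_effect_multiplier: float = 4.0
    deviation: float = 2.0
    imbalance_prob: float = 0.3
    g_sigma: float = 0.3
    group_labels: tuple[str, str] = ("good", "poor")
    modulated_group: str = "poor"
    seed: int = 17

    def __post_init__(self) -> None:
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        for probs in (self.dispersed_cn_probs, self.concentrated_cn_probs):
            if len(probs) != self.c_max + 1:
                raise ValueError("CN state probabilities must cover 0..c_max")
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError("CN state probabilities must be a distribution")


@dataclass(frozen=True)
class TruthTable:
    """Generating truth: per-gene class and parameters, per-pathway quadrant,
    per-sample group and scale."""

    genes: pd.DataFrame
    pathways: pd.DataFrame
    samples: pd.DataFrame


def _class_probs(config: SimulationConfig, gene_class: str) -> np.ndarray:
    if gene_class in ("cn_driven", "passenger", "group_modulated"):
        return np.asarray(config.dispersed_cn_probs)
    return np.asarray(config.concentrated_cn_probs)


def _draw_gene_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    counts = {c: int(round(f * config.n_genes)) for c, f in config.class_fractions.items()}
    # rounding drift lands on the first class
    first = next(iter(counts))
    counts[first] += config.n_genes - sum(counts.values())
    rows = []
    i = 0
    for gene_class, n in counts.items():
        for _ in range(n):
            b0 = rng.uniform(*config.b0_range)
            a = rng.uniform(*config.a_range)
            if gene_class == "conserved":
                a *= config.conserved_effect_multiplier
            has_effect = gene_class in ("cn_driven", "conserved", "group_modulated")
            steps = tuple([a] * config.c_max) if has_effect else tuple([0.0] * config.c_max)
            dev = [0.0] * config.c_max
            if gene_class == "group_modulated":
                dev[min(1, config.c_max - 1)] = config.deviation  # allele level 2
            rows.append(
                {
                    "gene_id": f"G{i:05d}",
                    "class": gene_class,
                    "b0": b0,
                    "a": a if has_effect else 0.0,
                    "steps": steps,
                    "d0": 0.0,
                    "dev_steps": tuple(dev),
                }
            )
            i += 1
    return pd.DataFrame(rows).set_index("gene_id")


def simulate_copy_numbers(
    config: SimulationConfig,
    seed: int | None = None,
    gene_truth: pd.DataFrame | None = None,
) -> CopyNumberProfile:
    """Draw allele-specific integer CN states per gene and sample.

    Total copy number follows the gene class's state distribution; the
    allele split is balanced (A = ceil(c/2)) except with probability
    ``imbalance_prob`` where the minor count is drawn uniformly from
    0..floor(c/2)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if gene_truth is None:
        gene_truth = _draw_gene_truth(config, rng)
    n_g, n_s = len(gene_truth), config.n_samples
    states = np.arange(config.c_max + 1)
    A = np.empty((n_g, n_s))
    B = np.empty((n_g, n_s))
    for i, (_, row) in enumerate(gene_truth.iterrows()):
        total = rng.choice(states, size=n_s, p=_class_probs(config, row["class"]))
        b = np.floor(total / 2.0)
        imb = rng.random(n_s) < config.imbalance_prob
        b[imb] = rng.integers(0, np.floor(total[imb] / 2.0).astype(int) + 1)
        A[i] = total - b
        B[i] = b
    genes = pd.Index(gene_truth.index, name="gene_id")
    samples = pd.Index([f"S{j:04d}" for j in range(n_s)], name="sample_id")
    return CopyNumberProfile(
        pd.DataFrame(A, index=genes, columns=samples),
        pd.DataFrame(B, index=genes, columns=samples),
    )


def _mean_matrix(
    cn: CopyNumberProfile, truth: TruthTable, c_max: int, modulated_group: str
) -> np.ndarray:
    A = cn.major.to_numpy()
    B = cn.minor.to_numpy()
    g = truth.samples["g"].to_numpy()
    ind = (truth.samples["group"].to_numpy() == modulated_group).astype(float)
    ks = np.arange(1, c_max + 1)
    mu = np.empty_like(A)
    for i, (_, row) in enumerate(truth.genes.iterrows()):
        S = (A[i][:, None] >= ks).astype(float) + (B[i][:, None] >= ks).astype(float)
        steps = np.asarray(row["steps"], dtype=float)
        dev = np.asarray(row["dev_steps"], dtype=float)
        base = row["b0"] + S @ steps
        mu[i] = (base + ind * (row["d0"] + S @ dev)) * g
    if (mu < 0).any():
        raise ValueError("negative Poisson mean generated")
    return mu


def simulate_expression(
    cn: CopyNumberProfile,
    truth: TruthTable,
    config: SimulationConfig,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Draw Poisson counts from each gene's class equation times g_j."""
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    mu = _mean_matrix(cn, truth, config.c_max, config.modulated_group)
    counts = rng.poisson(mu).astype(np.int64)
    return ExpressionMatrix(
        pd.DataFrame(counts, index=cn.gene_ids, columns=cn.sample_ids)
    )


def _assemble_pathways(
    config: SimulationConfig, gene_truth: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    lo, hi = config.pathway_size
    by_class = {c: list(gene_truth.index[gene_truth["class"] == c]) for c in GENE_CLASSES}
    classes = [c for c in GENE_CLASSES if by_class[c]]
    rows = []
    cursor = {c: 0 for c in classes}
    for p in range(config.n_pathways):
        gene_class = classes[p % len(classes)]
        size = int(rng.integers(lo, hi + 1))
        pool = by_class[gene_class]
        start = cursor[gene_class]
        if start + size > len(pool):
            if start + lo > len(pool):
                raise ValueError(
                    f"cannot assemble {config.n_pathways} pathways of size "
                    f">= {lo} from {len(pool)} {gene_class!r} genes"
                )
            size = len(pool) - start
        members = pool[start : start + size]
        cursor[gene_class] = start + size
        rows.append(
            {
                "pathway_id": f"P{p:03d}",
                "class": gene_class,
                "quadrant": _CLASS_QUADRANT[gene_class],
                "members": tuple(members),
            }
        )
    return pd.DataFrame(rows).set_index("pathway_id")


def simulate_cohort(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[ExpressionMatrix, CopyNumberProfile, PathwayCollection, SampleGroups, TruthTable]:
    """Generate a full synthetic cohort with its truth table."""
    config = config or SimulationConfig()
    root_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(root_seed)
    gene_truth = _draw_gene_truth(config, rng)
    cn = simulate_copy_numbers(config, seed=rng.integers(2**31), gene_truth=gene_truth)
    g = np.exp(rng.normal(0.0, config.g_sigma, size=config.n_samples))
    g = g / g.mean()
    groups = np.array(
        [config.group_labels[j % 2] for j in range(config.n_samples)], dtype=object
    )
    samples = pd.DataFrame(
        {"group": groups, "g": g}, index=pd.Index(cn.sample_ids, name="sample_id")
    )
    pathway_truth = _assemble_pathways(config, gene_truth, rng)
    truth = TruthTable(genes=gene_truth, pathways=pathway_truth, samples=samples)
    expr = simulate_expression(cn, truth, config, seed=rng.integers(2**31))
    pathways = PathwayCollection(
        {pid: row["members"] for pid, row in pathway_truth.iterrows()}
    )
    sample_groups = SampleGroups(samples["group"].astype(str))
    return expr, cn, pathways, sample_groups, truth


def write_cohort(
    outdir,
    expr: ExpressionMatrix,
    cn: CopyNumberProfile,
    pathways: PathwayCollection,
    groups: SampleGroups,
    truth: TruthTable,
    header: str | None = None,
) -> dict[str, Path]:
    """Write a simulated cohort in the package's standard text formats."""
    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "gene_cn": outdir / "gene_cn.tsv",
        "pathways": outdir / "pathways.gmt",
        "groups": outdir / "groups.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_pathways": outdir / "truth_pathways.tsv",
        "truth_samples": outdir / "truth_samples.tsv",
    }
    io.write_counts(expr, paths["counts"], header=header)
    io.write_gene_cn(cn, paths["gene_cn"], header=header)
    io.write_gmt(pathways, paths["pathways"])
    io.write_groups(groups, paths["groups"])
    genes_flat = truth.genes.copy()
    genes_flat["steps"] = genes_flat["steps"].map(lambda s: ",".join(map(str, s)))
    genes_flat["dev_steps"] = genes_flat["dev_steps"].map(lambda s: ",".join(map(str, s)))
    genes_flat.to_csv(paths["truth_genes"], sep="\t", lineterminator="\n")
    pw_flat = truth.pathways.copy()
    pw_flat["members"] = pw_flat["members"].map(lambda m: ",".join(m))
    pw_flat.to_csv(paths["truth_pathways"], sep="\t", lineterminator="\n")
    truth.samples.to_csv(paths["truth_samples"], sep="\t", lineterminator="\n")
    return paths
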