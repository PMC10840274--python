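"""Readers and writers for the tabular formats the tool touches.

All files are UTF-8, tab-delimited text.  Lines starting with ``#`` are
treated as comments (writers may emit a provenance header).  Matrices are
written genes-in-rows with a header row of sample ids.  Genomic intervals
are 0-based half-open (BED convention).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    CopyNumberProfile,
    ExpressionMatrix,
    GeneAnnotation,
    PathwayCollection,
    SampleGroups,
    Segment,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "write_counts",
    "read_gene_cn",
    "write_gene_cn",
    "read_gmt",
    "write_gmt",
    "read_segments",
    "write_segments",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_groups",
    "write_groups",
    "align",
]

_CN_LONG_COLUMNS = ("gene_id", "sample_id", "major", "minor")


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def read_counts(path) -> ExpressionMatrix:
    """Read a gene x sample count matrix (first column gene ids, header row
    sample ids).  Cells must be nonnegative integers; integral floats such
    as ``3.0`` are accepted, ``3.5`` is rejected."""
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df)


def write_counts(expr: ExpressionMatrix, path, header: str | None = None) -> None:
    _write_frame(expr.counts, path, header, index_label="gene_id")


def _write_frame(df: pd.DataFrame, path, header: str | None, index_label: str) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label=index_label, lineterminator="\n")


def read_gene_cn(path) -> CopyNumberProfile:
    """Read gene-level allele-specific copy number.

    Two layouts are accepted:

    * long: columns ``gene_id, sample_id, major, minor``; absent
      (gene, sample) rows are treated as missing calls;
    * wide: first column ``gene_id`` and paired columns
      ``<sample>.major`` / ``<sample>.minor``.

    Rows with major < minor are swapped to restore the A >= B convention;
    the number of swaps is logged as a warning.
    """
    head = _read_tsv(path, nrows=0)
    if {"gene_id", "sample_id"} <= set(head.columns):
        df = _read_tsv(path)
        return _cn_from_long(df)
    return _cn_from_wide(_read_tsv(path, index_col=0))


def _enforce_major_minor(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    av, bv = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    ok = ~np.isnan(av)
    if ok.any() and ((av[ok] < 0).any() or (bv[ok] < 0).any()):
        raise ValueError("negative copy number in input")
    swap = ok & (av < bv)
    if swap.any():
        logger.warning("swapped %d gene/sample pairs to enforce major >= minor", swap.sum())
        av2 = np.where(swap, bv, av)
        bv2 = np.where(swap, av, bv)
        a = pd.DataFrame(av2, index=a.index, columns=a.columns)
        b = pd.DataFrame(bv2, index=b.index, columns=b.columns)
    return a, b


def _cn_from_long(df: pd.DataFrame) -> CopyNumberProfile:
    missing = set(_CN_LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s) in gene CN table: {sorted(missing)}")
    df = df.astype({"gene_id": str, "sample_id": str})
    gene_order = df["gene_id"].unique()
    sample_order = df["sample_id"].unique()
    a = df.pivot(index="gene_id", columns="sample_id", values="major")
    b = df.pivot(index="gene_id", columns="sample_id", values="minor")
    a = a.reindex(index=gene_order, columns=sample_order)
    b = b.reindex(index=gene_order, columns=sample_order)
    a, b = _enforce_major_minor(a, b)
    return CopyNumberProfile(a, b)


def _cn_from_wide(df: pd.DataFrame) -> CopyNumberProfile:
    majors = [c for c in df.columns if c.endswith(".major")]
    minors = [c for c in df.columns if c.endswith(".minor")]
    samples = [c[: -len(".major")] for c in majors]
    if not majors or {c[: -len(".minor")] for c in minors} != set(samples):
        raise ValueError(
            "wide gene CN table requires paired '<sample>.major'/'<sample>.minor' columns"
        )
    df.index = df.index.astype(str)
    a = df[[f"{s}.major" for s in samples]].set_axis(samples, axis=1)
    b = df[[f"{s}.minor" for s in samples]].set_axis(samples, axis=1)
    a, b = _enforce_major_minor(a, b)
    return CopyNumberProfile(a, b)


def write_gene_cn(
    cn: CopyNumberProfile, path, layout: str = "long", header: str | None = None
) -> None:
    if layout == "long":
        a = cn.major.stack()
        b = cn.minor.stack()
        long = pd.DataFrame(
            {
                "gene_id": a.index.get_level_values(0),
                "sample_id": a.index.get_level_values(1),
                "major": a.to_numpy().astype(int),
                "minor": b.to_numpy().astype(int),
            }
        )
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            long.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    elif layout == "wide":
        wide = pd.concat(
            {f"{s}.major": cn.major[s] for s in cn.sample_ids}
            | {f"{s}.minor": cn.minor[s] for s in cn.sample_ids},
            axis=1,
        )
        wide = wide[[f"{s}.{k}" for s in cn.sample_ids for k in ("major", "minor")]]
        _write_frame(wide, path, header, index_label="gene_id")
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_gmt(path) -> PathwayCollection:
    """Read gene sets in GMT format (name, description, genes; tab-separated).

    Duplicate genes within one line are dropped with a warning; an empty
    file yields an empty collection with a warning.
    """
    sets: dict[str, tuple[str, ...]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT line needs >= 3 fields")
            name, genes = fields[0], fields[2:]
            seen: list[str] = []
            for gene in genes:
                if gene and gene not in seen:
                    seen.append(gene)
            if len(seen) < len([g for g in genes if g]):
                logger.warning("pathway %s: duplicate genes deduplicated", name)
            sets[name] = tuple(seen)
    if not sets:
        logger.warning("%s: empty GMT file", path)
    return PathwayCollection(sets)


def write_gmt(pathways: PathwayCollection, path, description: str = "na") -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_segments(path) -> list[Segment]:
    """Read a SEG-like TSV: sample, chrom, start, end, major, minor."""
    df = _read_tsv(path)
    required = {"sample", "chrom", "start", "end", "major", "minor"}
    if not required <= set(df.columns):
        raise ValueError(f"segment table missing column(s): {sorted(required - set(df.columns))}")
    return [
        Segment(str(r.sample), str(r.chrom), int(r.start), int(r.end), int(r.major), int(r.minor))
        for r in df.itertuples(index=False)
    ]


def write_segments(segments: Sequence[Segment], path) -> None:
    df = pd.DataFrame(
        [(s.sample_id, s.chrom, s.start, s.end, s.major, s.minor) for s in segments],
        columns=["sample", "chrom", "start", "end", "major", "minor"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gene_annotation(path) -> list[GeneAnnotation]:
    """Read a headerless BED-like table: chrom, start, end, gene_id."""
    df = _read_tsv(path, header=None, names=["chrom", "start", "end", "gene_id"])
    genes = [
        GeneAnnotation(str(r.gene_id), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in annotation")
    return genes


def write_gene_annotation(genes: Sequence[GeneAnnotation], path) -> None:
    df = pd.DataFrame(
        [(g.chrom, g.start, g.end, g.gene_id) for g in genes],
        columns=["chrom", "start", "end", "gene_id"],
    )
    df.to_csv(path, sep="\t", index=False, header=False, lineterminator="\n")


def read_groups(path) -> SampleGroups:
    """Read a two-column TSV: sample_id, group."""
    df = _read_tsv(path)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError("groups table requires columns sample_id, group")
    labels = pd.Series(
        df["group"].astype(str).to_numpy(), index=df["sample_id"].astype(str), name="group"
    )
    return SampleGroups(labels)


def write_groups(groups: SampleGroups, path) -> None:
    df = pd.DataFrame({"sample_id": groups.sample_ids, "group": groups.labels.to_numpy()})
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def align(
    expr: ExpressionMatrix, cn: CopyNumberProfile
) -> tuple[ExpressionMatrix, CopyNumberProfile]:
    """Restrict both matrices to their common genes and samples, in the
    expression matrix's order.  Raises if either intersection is empty."""
    genes = expr.gene_ids.intersection(cn.gene_ids)
    samples = expr.sample_ids.intersection(cn.sample_ids)
    if len(genes) == 0 or len(samples) == 0:
        raise ValueError("no common genes/samples between expression and copy number")
    genes = expr.gene_ids[expr.gene_ids.isin(genes)]
    samples = expr.sample_ids[expr.sample_ids.isin(samples)]
    dropped_g = (len(expr.gene_ids) - len(genes)) + (len(cn.gene_ids) - len(genes))
    dropped_s = (len(expr.sample_ids) - len(samples)) + (len(cn.sample_ids) - len(samples))
    if dropped_g or dropped_s:
        logger.info("align dropped %d gene and %d sample ids", dropped_g, dropped_s)
    expr2 = ExpressionMatrix(expr.counts.loc[genes, samples])
    cn2 = CopyNumberProfile(cn.major.loc[genes, samples], cn.minor.loc[genes, samples])
    return expr2, cn2
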