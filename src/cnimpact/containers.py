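"""Shared data containers.

Conventions used throughout the package:

* Matrices are genes-in-rows, samples-in-columns.
* Genomic coordinates are 0-based, half-open (BED convention).
* Allele-specific copy number is stored as a major/minor pair with
  ``A >= B >= 0``; a missing (gene, sample) copy-number call is ``NaN``
  in both matrices and the pair is excluded from that gene's fit,
  never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CopyNumberProfile",
    "SampleScale",
    "GeneAnnotation",
    "Segment",
    "PathwayCollection",
    "SampleGroups",
]


def _check_unique(ids: Iterable, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValueError(f"duplicate {what} id: {dup!r}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample matrix of nonnegative integer expression counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            fl = values.astype(float)
            if np.isnan(fl).any():
                i, j = np.argwhere(np.isnan(fl))[0]
                raise ValueError(
                    f"NaN count for gene {df.index[i]!r}, sample {df.columns[j]!r}"
                )
            if not np.allclose(fl, np.round(fl), atol=1e-9):
                i, j = np.argwhere(~np.isclose(fl, np.round(fl), atol=1e-9))[0]
                raise ValueError(
                    f"non-integer count {fl[i, j]!r} for gene {df.index[i]!r}, "
                    f"sample {df.columns[j]!r}"
                )
            df = df.round().astype(np.int64)
            object.__setattr__(self, "counts", df)
            values = df.to_numpy()
        if values.size and values.min() < 0:
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count for gene {df.index[i]!r}, sample {df.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)


@dataclass(frozen=True)
class CopyNumberProfile:
    """Allele-specific absolute copy number per gene and sample.

    ``major`` (A) and ``minor`` (B) are float matrices with identical axes;
    ``NaN`` marks a gene/sample pair with no copy-number call.
    """

    major: pd.DataFrame
    minor: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.major.index.equals(self.minor.index) or not self.major.columns.equals(
            self.minor.columns
        ):
            raise ValueError("major and minor matrices must share axes")
        _check_unique(self.major.index, "gene")
        _check_unique(self.major.columns, "sample")
        a = self.major.to_numpy(dtype=float)
        b = self.minor.to_numpy(dtype=float)
        if (np.isnan(a) != np.isnan(b)).any():
            raise ValueError("major/minor missingness must coincide")
        ok = ~np.isnan(a)
        if ok.any():
            if (a[ok] < 0).any() or (b[ok] < 0).any():
                raise ValueError("negative copy number")
            if not np.allclose(a[ok], np.round(a[ok])) or not np.allclose(
                b[ok], np.round(b[ok])
            ):
                raise ValueError("copy numbers must be integral")
            if (a[ok] < b[ok]).any():
                raise ValueError("major copy number must be >= minor (A >= B)")
        object.__setattr__(self, "major", self.major.astype(float))
        object.__setattr__(self, "minor", self.minor.astype(float))

    @property
    def gene_ids(self) -> pd.Index:
        return self.major.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.major.columns

    @property
    def missing(self) -> pd.DataFrame:
        return self.major.isna()

    @property
    def total(self) -> pd.DataFrame:
        """Total copy number A + B (NaN where missing)."""
        return self.major + self.minor

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CopyNumberProfile):
            return NotImplemented
        return self.major.equals(other.major) and self.minor.equals(other.minor)


@dataclass(frozen=True)
class SampleScale:
    """Per-sample global expression scale g_j > 0 (mean 1 by convention)."""

    g: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.g.index, "sample")
        if (self.g.to_numpy(dtype=float) <= 0).any():
            bad = self.g.index[self.g <= 0][0]
            raise ValueError(f"non-positive scale for sample {bad!r}")
        object.__setattr__(self, "g", self.g.astype(float))

    @property
    def sample_ids(self) -> pd.Index:
        return self.g.index

    @property
    def values(self) -> np.ndarray:
        return self.g.to_numpy()


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic location of one gene; 0-based half-open interval."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start must be < end ({self.start}, {self.end})"
            )


@dataclass(frozen=True)
class Segment:
    """One allele-specific copy-number segment; 0-based half-open interval."""

    sample_id: str
    chrom: str
    start: int
    end: int
    major: int
    minor: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"segment start must be < end ({self.start}, {self.end})")
        if self.minor < 0 or self.major < self.minor:
            raise ValueError("segment requires major >= minor >= 0")


@dataclass(frozen=True)
class PathwayCollection:
    """Named gene sets (e.g. curated PID pathways)."""

    sets: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for name, genes in self.sets.items():
            genes = tuple(genes)
            if not genes:
                raise ValueError(f"pathway {name!r} has no genes")
            if len(set(genes)) != len(genes):
                raise ValueError(f"pathway {name!r} contains duplicate genes")
            clean[str(name)] = genes
        object.__setattr__(self, "sets", clean)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass(frozen=True)
class SampleGroups:
    """Binary sample grouping (e.g. poor vs good responders)."""

    labels: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.labels.index, "sample")
        levels = pd.unique(self.labels)
        if len(levels) != 2:
            raise ValueError(
                f"exactly two group labels required, found {list(levels)!r}"
            )
        object.__setattr__(self, "labels", self.labels.astype(str))

    @property
    def sample_ids(self) -> pd.Index:
        return self.labels.index

    @property
    def levels(self) -> tuple[str, str]:
        lv = sorted(map(str, pd.unique(self.labels)))
        return (lv[0], lv[1])

    def indicator(self, level: str) -> np.ndarray:
        """Boolean mask of samples carrying ``level``."""
        if level not in set(self.levels):
            raise ValueError(f"unknown group label {level!r}")
        return (self.labels == level).to_numpy()
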