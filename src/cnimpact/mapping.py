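"""Segment-to-gene copy-number assignment and VAF-based purity.

A gene's copy number is taken from the intersecting segment with the
greatest overlap measured *within the gene body*; ties go to the segment
with the smaller start.  Tumor purity can be approximated from the variant
allele frequency of a truncal homozygous TP53 mutation together with the
total copy number at the locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CopyNumberProfile, GeneAnnotation, Segment

logger = logging.getLogger(__name__)

__all__ = ["PurityEstimate", "assign_gene_cn", "purity_from_tp53"]


@dataclass(frozen=True)
class PurityEstimate:
    purity: float
    cn_used: float
    vaf_used: float
    clamped: bool = False


def purity_from_tp53(cn_total: float, vaf: float) -> PurityEstimate:
    """Approximate tumor purity from the TP53 VAF and total copy number.

    With a homozygous truncal mutation, all tumor copies at the locus carry
    the variant, so  purity = 2 / ((CN / VAF) - (CN - 2)).  The estimate is
    clamped to (0, 1]; ``clamped`` records whether clamping occurred.
    """
    if not cn_total > 0:
        raise ValueError("cn_total must be positive")
    if not (0 < vaf <= 1):
        raise ValueError("vaf must lie in (0, 1]")
    denom = cn_total / vaf - (cn_total - 2.0)
    if denom <= 0:
        raise ValueError(
            f"inconsistent CN/VAF pair (CN={cn_total}, VAF={vaf}): denominator <= 0"
        )
    purity = 2.0 / denom
    clamped = purity > 1.0
    if clamped:
        purity = 1.0
    return PurityEstimate(purity=purity, cn_used=cn_total, vaf_used=vaf, clamped=clamped)


def _check_no_overlap(segments: Sequence[Segment]) -> None:
    by_key: dict[tuple[str, str], list[Segment]] = {}
    for s in segments:
        by_key.setdefault((s.sample_id, s.chrom), []).append(s)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"overlapping segments for sample {sample!r} on {chrom!r}: "
                    f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
                )


def assign_gene_cn(
    segments: Sequence[Segment], genes: Sequence[GeneAnnotation]
) -> CopyNumberProfile:
    """Assign per-gene (major, minor) copy number from allele-specific segments.

    For each gene and sample the segment with the largest overlap with the
    gene body wins; equal overlaps are broken by the smaller segment start.
    Genes with no intersecting segment are marked missing.  Segments of one
    sample must not overlap on a chromosome.
    """
    _check_no_overlap(segments)
    sample_ids = sorted({s.sample_id for s in segments})
    gene_ids = [g.gene_id for g in genes]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene_id in annotation")
    a = np.full((len(genes), len(sample_ids)), np.nan)
    b = np.full_like(a, np.nan)
    sample_pos = {s: j for j, s in enumerate(sample_ids)}
    by_key: dict[tuple[str, str], list[Segment]] = {}
    for s in segments:
        by_key.setdefault((s.sample_id, s.chrom), []).append(s)
    for i, gene in enumerate(genes):
        for sample, j in sample_pos.items():
            best: tuple[int, int] | None = None  # (-overlap, start)
            best_seg: Segment | None = None
            for seg in by_key.get((sample, gene.chrom), ()):
                overlap = min(seg.end, gene.end) - max(seg.start, gene.start)
                if overlap <= 0:
                    continue
                key = (-overlap, seg.start)
                if best is None or key < best:
                    best, best_seg = key, seg
            if best_seg is not None:
                a[i, j] = best_seg.major
                b[i, j] = best_seg.minor
    n_missing = int(np.isnan(a).sum())
    if n_missing:
        logger.info("%d gene/sample pairs without a covering segment", n_missing)
    idx = pd.Index(gene_ids, name="gene_id")
    cols = pd.Index(sample_ids, name="sample_id")
    return CopyNumberProfile(
        pd.DataFrame(a, index=idx, columns=cols),
        pd.DataFrame(b, index=idx, columns=cols),
    )
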