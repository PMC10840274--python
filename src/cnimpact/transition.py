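"""Functional copy-number transition points.

The fitted monotonic model of a gene defines a non-decreasing expression
curve over total copy number (the two alleles are split as evenly as
possible along the curve).  Projecting the cohort's median and quartiles
of scale-normalized expression onto this curve and interpolating the
copy-number axis yields the functional transition point and its
bandwidth: the copy-number range over which expression actually changes.
Transition points are mapped onto a 5-level aberration scheme —
deletion (CNA = 0), loss (CNA = 1), normal (CNA = 2), gain (2 < CNA <= 5)
and amplification (CNA > 5).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .containers import SampleScale
from .models import ModelFit, predict_mean

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "ModelCurve",
    "TransitionResult",
    "model_curve",
    "transition_point",
    "categorize",
    "pathway_transition",
]

CATEGORIES = ("deletion", "loss", "normal", "gain", "amplification")

#: (distance from normal, 1 if on the gain side) — used to break modal ties
#: toward the more extreme category, preferring the gain side
_SEVERITY = {
    "deletion": (2, 0),
    "loss": (1, 0),
    "normal": (0, 0),
    "gain": (1, 1),
    "amplification": (2, 1),
}


@dataclass(frozen=True)
class ModelCurve:
    """Piecewise-linear expression curve over total copy number."""

    cn: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        if (np.diff(self.mu) < -1e-9).any():
            raise ValueError("model curve must be non-decreasing")

    @property
    def is_flat(self) -> bool:
        return bool(self.mu[-1] - self.mu[0] <= 0)


@dataclass(frozen=True)
class TransitionResult:
    gene_id: str | None
    transition_point: float | None
    band_low: float | None
    band_high: float | None
    category: str
    clamped_low: bool = False
    clamped_high: bool = False


def model_curve(fit: ModelFit, split: str = "balanced") -> ModelCurve:
    """Evaluate a monotonic fit along total copy number c = 0..2*k_max.

    ``split`` chooses how total copy number is divided between the alleles:
    ``balanced`` uses A = ceil(c/2), B = floor(c/2); ``major`` puts the
    whole copy number on the major allele (B = 0).
    """
    if fit.family != "monotonic":
        raise ValueError(f"model_curve requires a monotonic fit, got {fit.family!r}")
    if not fit.converged:
        raise ValueError("model_curve requires a converged fit")
    assert fit.k_max is not None
    c = np.arange(0, 2 * fit.k_max + 1, dtype=float)
    if split == "balanced":
        A = np.ceil(c / 2.0)
        B = np.floor(c / 2.0)
    elif split == "major":
        A = c
        B = np.zeros_like(c)
    else:
        raise ValueError(f"unknown allele split {split!r}")
    mu = predict_mean(fit, A, B, np.ones_like(c))
    return ModelCurve(cn=c, mu=mu)


def _invert(curve: ModelCurve, h: float) -> tuple[float, bool, bool]:
    """Copy number at which the curve crosses height ``h``.

    On a flat stretch at exactly ``h`` the midpoint of the stretch is
    returned.  Heights below/above the curve clamp to the grid ends with
    the corresponding flag set.
    """
    cn, mu = curve.cn, curve.mu
    if h < mu[0]:
        return float(cn[0]), True, False
    if h > mu[-1]:
        return float(cn[-1]), False, True
    # leftmost c with mu(c) >= h
    i = int(np.searchsorted(mu, h, side="left"))
    if i == 0:
        c_left = float(cn[0])
    else:
        c_left = float(cn[i - 1] + (h - mu[i - 1]) / (mu[i] - mu[i - 1]))
    # rightmost c with mu(c) <= h
    j = int(np.searchsorted(mu, h, side="right")) - 1
    if j == len(cn) - 1:
        c_right = float(cn[-1])
    else:
        c_right = float(cn[j] + (h - mu[j]) / (mu[j + 1] - mu[j]))
    return (c_left + c_right) / 2.0, False, False


def transition_point(
    fit: ModelFit, x, g, gene_id: str | None = None, split: str = "balanced"
) -> TransitionResult:
    """Project the cohort's expression median and quartiles onto the model
    curve and interpolate the copy-number axis.

    Quantiles of y_j = x_j / g_j use the median-unbiased scheme.  A flat
    curve has no crossing and yields the ``undefined`` category.
    """
    x = np.asarray(x, dtype=float).ravel()
    gv = np.asarray(g.values if isinstance(g, SampleScale) else g, dtype=float).ravel()
    if x.shape != gv.shape:
        raise ValueError("x and g must have equal length")
    if len(x) < 4:
        raise ValueError("transition point requires at least 4 samples")
    curve = model_curve(fit, split=split)
    if curve.is_flat:
        return TransitionResult(gene_id, None, None, None, "undefined")
    y = x / gv
    q1, med, q3 = np.quantile(y, [0.25, 0.5, 0.75], method="median_unbiased")
    t, lo_t, hi_t = _invert(curve, med)
    b_lo, lo_1, hi_1 = _invert(curve, q1)
    b_hi, lo_3, hi_3 = _invert(curve, q3)
    return TransitionResult(
        gene_id=gene_id,
        transition_point=t,
        band_low=b_lo,
        band_high=b_hi,
        category=categorize(t),
        clamped_low=lo_t or lo_1 or lo_3,
        clamped_high=hi_t or hi_1 or hi_3,
    )


def categorize(t: float | None) -> str:
    """Map a transition copy number onto the 5-level aberration scheme.

    The integer anchors are deletion (CNA = 0), loss (CNA = 1), normal
    (CNA = 2), gain (2 < CNA <= 5), amplification (CNA > 5); real-valued
    transition points use the half-way boundaries 0.5 and 1.5 below normal.
    """
    if t is None:
        return "undefined"
    if t < 0:
        raise ValueError("transition point must be nonnegative")
    if t <= 0.5:
        return "deletion"
    if t <= 1.5:
        return "loss"
    if t <= 2.0:
        return "normal"
    if t <= 5.0:
        return "gain"
    return "amplification"


def pathway_transition(categories) -> str:
    """Modal transition category over a pathway's genes.

    Undefined genes are ignored; an all-undefined pathway stays undefined.
    Ties are broken toward the category more extreme relative to normal,
    preferring the gain side (so gain beats loss, amplification beats
    deletion).
    """
    counts = Counter(c for c in categories if c != "undefined")
    if not counts:
        return "undefined"
    for cat in counts:
        if cat not in _SEVERITY:
            raise ValueError(f"unknown category {cat!r}")
    best = max(counts, key=lambda cat: (counts[cat], *_SEVERITY[cat]))
    top = [c for c, n in counts.items() if n == counts[best]]
    if len(top) > 1:
        logger.info("pathway category tie among %s resolved to %s", sorted(top), best)
    return best
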