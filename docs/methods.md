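# Methods

## Model families and fitting

Expression counts are modeled per gene as Poisson with an identity-link
mean that is an affine function of the allele-specific absolute copy
numbers, times a per-sample scale `g_j` (mean-1 column-sum size factors by
default; any scheme can be substituted by constructing a `SampleScale`).
The identity link is deliberate: copy-number dosage acts additively on
transcript output, and the nonnegativity constraints (`b0, a, a_{k-(k-1)},
d >= 0`; only the major-minor interaction coefficient `c` is free) encode
that extra copies cannot reduce expression in this model class.  The
monotonic family assigns each allele a nonnegative increment when its copy
number reaches level `k = 1..k_max`; fitted means are therefore
non-decreasing in each allele by construction.  `k_max` defaults to 8;
higher copy numbers still trigger all indicators up to `k_max` (natural
truncation).

Maximization uses L-BFGS-B with box constraints and the analytic gradient,
initialized at the constant-model MLE `b0 = Σx/Σg` with all other
coefficients at zero, up to three random restarts on failure (the
`converged` flag is honest and never silently dropped).  The mean is
floored at `1e-10` inside the log so the objective stays finite on the
boundary.  The constant model uses its closed form.  When no design column
varies across samples the model space collapses to the constant model and
the closed form is used directly, which makes degenerate cases (a single
CN state, all-zero counts) exact rather than optimizer-dependent.

Design rank is the matrix rank of the columns not structurally fixed at
zero (step levels never observed in the data are excluded).  The
likelihood-ratio test uses `2 Δloglik` with df equal to the rank
difference and a chi-square upper tail.  Because the alternative's
coefficients sit on a boundary under the null, the statistic is a
chi-bar-square mixture dominated by the chi-square reference: **the test
is conservative**, and observed null rejection rates at α = 0.05 are in
the 0.1–0.5% range rather than 5%.  This is a property of applying Wilks'
reference to a constrained fit and is reported as such, not corrected.

## Explained variance and CNI

"R-squared over the constant model" is realized as deviance-based
explained variance `EV = 1 − D_alt/D_null` (residual Poisson deviance
versus the saturated model), the likelihood-consistent choice that reduces
to classical R² in the Gaussian limit.  Raw EV may be slightly negative or
noisy-positive; it is clipped to `[0, 1]` only when converted to
`CNI = sqrt(EV)`.  Because the alternative always gains some deviance by
overfitting, the null distribution of gene CNI at `n` samples is roughly
`sqrt(chibar²_df / D_null)`; at n = 200 with two to three active step
levels its 90th percentile sits near 0.15.  CNI for a null gene is thus
small but not zero, and shrinks as `1/sqrt(n)`.

Pathway CNI pools member deviances (`EV = 1 − ΣD_alt/ΣD_null`), which
weighs genes by their expression variation; the pooled LRT sums statistics
and degrees of freedom.  Leave-one-out contribution shares clip negative
deltas to zero and fall back to uniform shares when every delta is zero.
Gene- and pathway-level p-values are Benjamini–Hochberg adjusted
(separately per level).

## Transition points

The 2-D monotonic fit is reduced to a 1-D curve over total copy number via
the balanced allele split `A = ceil(c/2), B = floor(c/2)` (an all-major
split is available); the curve is piecewise linear between integer grid
points over `c = 0..2·k_max`.  The cohort's median and quartiles of
`x_j/g_j` (median-unbiased quantile scheme) are inverted through the
curve; on a flat stretch at exactly the target height the midpoint of the
stretch is returned, and heights outside the curve's range clamp to the
grid ends with flags.  Categories use the anchors deletion ≤ 0.5 <
loss ≤ 1.5 < normal ≤ 2 < gain ≤ 5 < amplification; the boundaries at 2
and 5 are closed exactly as the integer scheme prints them, and the
half-way boundaries 0.5/1.5 extend the integer anchors to real-valued
transition points.  Pathway categories take the mode over defined member
categories; ties go to the category more extreme relative to normal,
preferring the gain side (gain beats loss, amplification beats deletion).

## Landscape calibration

Per-gene mean CNA defaults to the mean total copy number (`mean(A+B)`);
a `deviation` mode (`mean|A+B−2|`) is provided because deletion-driven
aberration is invisible to the total.  Threshold calibration resamples
pathways containing known CN drivers (replacing their mutation-driver
members with uniform draws from the genome pool, 1,000 times) and
symmetrically for mutation-driver pathways, then scans each axis for the
cut maximizing two-class accuracy.  The scan evaluates midpoints of
adjacent order statistics plus one cut below the minimum and one above the
maximum — exact for the accuracy objective, no grid parameter; ties pick
the smallest threshold, so accuracy is always ≥ 0.5.  Quadrants:
CNI ≥ t and CNA ≥ t → CN-driven; high CNI only → conserved; high CNA
only → passenger; neither → non-CN-driven.

Group enrichment labels a pathway with a response group when it contains
at least one gene whose stacked-vs-constant LRT is significant
(BH q < 0.05 by default) and whose selected deviation direction favors
that group; both directions present → `both`.  This any-hit rule is a
design choice — it is the reading under which a pathway can be common to
both groups.

## Synthetic cohorts

The generator draws total copy number per gene class — dispersed over
0..8 (mean ≈ 3.6) for CN-driven/passenger/group-modulated genes,
concentrated at diploid (90% CN 2, 5% each CN 1/3) for
conserved/independent genes — and splits alleles evenly, with probability
0.3 of a uniformly drawn minor count (LOH-like imbalance).  Expression
follows the fitted model families exactly: basal levels `b0 ~ U(5, 50)`,
dosage steps `a ~ U(2, 5)` (×4 for the conserved class so its sparse
aberrations still carry signal), group deviations of 2.0 at allele level 2
on the modulated group, and log-normal sample scales (σ = 0.3,
renormalized to mean 1).  Default cohort 2,000 genes × 200 samples,
50 single-class pathways of 10–40 genes; benchmark runs use scaled-down
cohorts (e.g. 520 genes × 150 samples for the 40-pathway landscape) that
keep the statistics stable at minute-scale runtimes.

What the generator does *not* emulate: segment-level autocorrelation along
chromosomes, purity/ploidy mixing, batch effects, overdispersion beyond
Poisson, and correlated expression between pathway members.  Passing
recovery benchmarks therefore demonstrates correctness of the estimators
under the model's own assumptions, not robustness to real-data artifacts
such as negative binomial noise or CN-expression confounding by purity.

## Numerical choices and edge cases

* All-zero counts: every coefficient 0, deviance 0, exact.
* Missing CN for a (gene, sample) pair: the pair is excluded from that
  gene's fit; never imputed.
* Major < minor in input: swapped with a logged warning.
* Interaction sign classified with a tolerance band (default 1e-6).
* LRT statistics clamped at 0 (warning beyond 1e-6); df = 0 gives p = 1.
* Purity `2/((CN/VAF) − (CN − 2))` is clamped to (0, 1] with a flag; for
  valid inputs (VAF ≤ 1) the denominator is ≥ 2, so the clamp is a
  safeguard rather than a reachable branch.
* Every stochastic routine takes an explicit seed; there is no hidden
  global random state, and cohort files are byte-identical across runs.

## Known limitations

The chi-square LRT reference is conservative under boundary constraints
(documented above); negative-binomial/zero-inflated variants and
covariates beyond `g_j` are out of scope; transition points carry no
confidence intervals; and the null CNI floor at moderate `n` (see above)
means small CNI values should be interpreted against that floor rather
than against zero.
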