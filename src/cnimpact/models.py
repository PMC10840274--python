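"""Constrained Poisson expression models with identity link.

For gene *i* and sample *j* with expression count ``x_j``, sample scale
``g_j`` and allele-specific copy numbers ``A_j >= B_j >= 0`` the model
families are

* constant:     X_j ~ Poi( b0 * g_j ),                       b0 >= 0
* linear:       X_j ~ Poi( (b0 + a (A_j + B_j)) g_j ),       b0, a >= 0
* interaction:  X_j ~ Poi( (b0 + a (A_j + B_j) + c A_j B_j) g_j ),
                b0, a >= 0, c free in sign
* monotonic:    X_j ~ Poi( (b0 + sum_k a_k (1[A_j>=k] + 1[B_j>=k])) g_j ),
                all coefficients >= 0
* stacked_monotonic: a monotonic base model plus nonnegative group-specific
  deviations (d0, d_k) applied to one of two sample groups; both deviation
  directions are fitted and the better-likelihood variant is kept.

Fitting maximizes the Poisson likelihood under the box constraints with a
bounded quasi-Newton method and analytic gradient, initialized from the
closed-form constant-model MLE.  The mean is floored at a small epsilon
inside the log so the objective stays finite on the boundary.

Nested families are compared with a likelihood-ratio test: statistic
2*(loglik_alt - loglik_null), degrees of freedom equal to the difference of
the design-matrix ranks, p-value from the upper chi-square tail (Wilks).
The nonnegativity constraints make this test conservative under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .containers import ExpressionMatrix, SampleGroups, SampleScale

logger = logging.getLogger(__name__)

__all__ = [
    "ModelFit",
    "LrtResult",
    "MU_EPS",
    "estimate_sample_scales",
    "fit_constant",
    "fit_linear",
    "fit_monotonic",
    "fit_stacked_monotonic",
    "classify_interaction",
    "predict_mean",
    "lrt",
]

#: floor applied to the Poisson mean inside the log-likelihood
MU_EPS = 1e-10

FAMILIES = ("constant", "linear", "interaction", "monotonic", "stacked_monotonic")


@dataclass(frozen=True)
class ModelFit:
    family: str
    params: dict[str, float]
    loglik: float
    rank: int
    deviance: float
    converged: bool
    n_obs: int
    k_max: int | None = None
    direction: str | None = None
    levels: tuple[str, str] | None = None


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    p: float


def estimate_sample_scales(expr: ExpressionMatrix) -> SampleScale:
    """Column-sum size factors normalized to mean 1.

    The global expression level g_j of sample j is its total count divided
    by the mean total count; any other size-factor scheme may be plugged in
    by constructing a :class:`SampleScale` directly.
    """
    totals = expr.counts.sum(axis=0).astype(float)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total count")
    return SampleScale(totals / totals.mean())


# ---------------------------------------------------------------------------
# likelihood machinery


def _poisson_loglik(x: np.ndarray, mu: np.ndarray) -> float:
    mu = np.maximum(mu, MU_EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(x > 0, x * np.log(mu), 0.0)
    return float(term.sum() - mu.sum() - gammaln(x + 1).sum())


def _saturated_loglik(x: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(x > 0, x * np.log(x) - x, 0.0)
    return float(term.sum() - gammaln(x + 1).sum())


def _clean_inputs(x, g, *cn):
    x = np.asarray(x, dtype=float).ravel()
    g = np.asarray(g.values if isinstance(g, SampleScale) else g, dtype=float).ravel()
    arrays = [np.asarray(c, dtype=float).ravel() for c in cn]
    for arr in (g, *arrays):
        if arr.shape != x.shape:
            raise ValueError("x, g and copy-number vectors must have equal length")
    if (g <= 0).any():
        raise ValueError("sample scales must be positive")
    if np.isnan(x).any():
        raise ValueError("counts must not contain NaN")
    mask = np.ones_like(x, dtype=bool)
    for arr in arrays:
        mask &= ~np.isnan(arr)
    return (x[mask], g[mask], *[arr[mask] for arr in arrays])


def _design_rank(Z: np.ndarray) -> int:
    if Z.size == 0:
        return 0
    return int(np.linalg.matrix_rank(Z))


def _maximize(
    x: np.ndarray,
    Z: np.ndarray,
    g: np.ndarray,
    free_cols: tuple[int, ...] = (),
    seed: int = 0,
    max_restarts: int = 3,
):
    """Maximize the Poisson log-likelihood of mu = (Z theta) * g subject to
    theta >= 0 except the columns listed in ``free_cols``.

    Returns (theta, loglik, converged).  Column 0 of Z must be the
    intercept.  If no column beyond the intercept varies across samples the
    model space equals the constant model and the closed-form MLE is used.
    """
    n, p = Z.shape
    if x.sum() == 0:
        return np.zeros(p), 0.0, True
    varying = [j for j in range(1, p) if np.ptp(Z[:, j]) > 0]
    if not varying:
        theta = np.zeros(p)
        theta[0] = x.sum() / g.sum()
        return theta, _poisson_loglik(x, theta[0] * g), True

    bounds = [(0.0, None)] * p
    for j in free_cols:
        bounds[j] = (None, None)

    def objective(theta):
        eta = (Z @ theta) * g
        mu = np.maximum(eta, MU_EPS)
        with np.errstate(divide="ignore"):
            f = mu.sum() - np.where(x > 0, x * np.log(mu), 0.0).sum()
        w = (1.0 - x / mu) * g
        w[eta < MU_EPS] = 0.0
        return f, Z.T @ w

    theta0 = np.zeros(p)
    theta0[0] = max(x.sum() / g.sum(), MU_EPS)
    rng = np.random.default_rng(seed)
    best = None
    converged = False
    start = theta0
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(
            objective,
            start,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            converged = True
            break
        start = theta0 * (1.0 + rng.uniform(0, 1, size=p))
        start[0] = max(start[0], MU_EPS)
    if not converged:
        logger.warning("Poisson fit did not converge after %d restarts", max_restarts)
    theta = np.asarray(best.x, dtype=float)
    mu = np.maximum((Z @ theta) * g, MU_EPS)
    return theta, _poisson_loglik(x, mu), converged


def _finish(family, params, theta_ll, Z, x, g, converged, **extra) -> ModelFit:
    loglik = theta_ll
    deviance = max(0.0, 2.0 * (_saturated_loglik(x) - loglik))
    return ModelFit(
        family=family,
        params=params,
        loglik=loglik,
        rank=_design_rank(Z),
        deviance=deviance,
        converged=converged,
        n_obs=len(x),
        **extra,
    )


# ---------------------------------------------------------------------------
# model families


def fit_constant(x, g) -> ModelFit:
    """Closed-form MLE of the constant model: b0 = sum(x) / sum(g)."""
    x, g = _clean_inputs(x, g)
    b0 = float(x.sum() / g.sum())
    Z = np.ones((len(x), 1))
    ll = _poisson_loglik(x, b0 * g)
    if x.sum() == 0:
        ll = 0.0
    return _finish("constant", {"b0": b0}, ll, Z, x, g, True)


def fit_linear(x, A, B, g, with_interaction: bool = False, seed: int = 0) -> ModelFit:
    """Linear dosage model b0 + a (A+B), optionally with the c*A*B
    interaction term (c unrestricted in sign)."""
    x, g, A, B = _clean_inputs(x, g, A, B)
    cols = [np.ones_like(x), A + B]
    free: tuple[int, ...] = ()
    names = ["b0", "a"]
    if with_interaction:
        cols.append(A * B)
        names.append("c")
        free = (2,)
    Z = np.column_stack(cols)
    theta, ll, converged = _maximize(x, Z, g, free_cols=free, seed=seed)
    params = dict(zip(names, map(float, theta)))
    family = "interaction" if with_interaction else "linear"
    return _finish(family, params, ll, Z, x, g, converged)


def classify_interaction(fit: ModelFit, tol: float = 1e-6) -> str:
    """Sign of the major/minor interaction: synergistic (c > tol),
    antagonistic (c < -tol), else linear."""
    if fit.family != "interaction":
        raise ValueError(f"expected an interaction fit, got {fit.family!r}")
    c = fit.params["c"]
    if c > tol:
        return "synergistic"
    if c < -tol:
        return "antagonistic"
    return "linear"


def _step_name(k: int) -> str:
    return f"a_{k}-{k - 1}"


def _step_design(A: np.ndarray, B: np.ndarray, k_max: int) -> np.ndarray:
    ks = np.arange(1, k_max + 1)
    return ((A[:, None] >= ks) .astype(float) + (B[:, None] >= ks).astype(float))


def fit_monotonic(x, A, B, g, k_max: int = 8, seed: int = 0) -> ModelFit:
    """Monotonic step model: each allele contributes a nonnegative increment
    a_{k-(k-1)} when its copy number reaches level k.  Copy numbers above
    ``k_max`` trigger all indicators up to ``k_max`` (natural truncation).
    Step levels never observed in the data are structurally zero and are
    excluded from the design rank."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    x, g, A, B = _clean_inputs(x, g, A, B)
    S = _step_design(A, B, k_max)
    active = S.any(axis=0)
    Z = np.column_stack([np.ones_like(x), S[:, active]])
    theta, ll, converged = _maximize(x, Z, g, seed=seed)
    params = {"b0": float(theta[0])}
    steps = np.zeros(k_max)
    steps[active] = theta[1:]
    for k in range(1, k_max + 1):
        params[_step_name(k)] = float(steps[k - 1])
    fit = _finish("monotonic", params, ll, Z, x, g, converged, k_max=k_max)
    return fit


def fit_stacked_monotonic(
    x, A, B, g, groups: SampleGroups | np.ndarray, k_max: int = 8, seed: int = 0
) -> ModelFit:
    """Two-group stacked monotonic model.

    One group follows the base model; the other receives additional
    nonnegative deviations (d0 and d_{k-(k-1)}) on every coefficient.  Both
    deviation directions are fitted and the higher-likelihood variant is
    returned, with ``direction`` naming the group that carries the
    deviations.
    """
    if isinstance(groups, SampleGroups):
        labels = groups.labels.to_numpy()
    else:
        labels = np.asarray(groups).astype(str)
    x0 = np.asarray(x, dtype=float).ravel()
    if labels.shape != x0.shape:
        raise ValueError("group labels must align with samples")
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, found {levels!r}")
    x, g, A, B, ind_num = _clean_inputs(x, g, A, B, (labels == levels[1]).astype(float))
    for lv in levels:
        if ((ind_num == 1.0) if lv == levels[1] else (ind_num == 0.0)).sum() < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 usable samples")
    S = _step_design(A, B, k_max)
    active = S.any(axis=0)
    base = np.column_stack([np.ones_like(x), S[:, active]])

    best_fit: ModelFit | None = None
    for direction, ind in ((levels[0], ind_num == 0.0), (levels[1], ind_num == 1.0)):
        dev = base * ind[:, None].astype(float)
        dev_active = dev.any(axis=0)
        Z = np.column_stack([base, dev[:, dev_active]])
        theta, ll, converged = _maximize(x, Z, g, seed=seed)
        p_base = base.shape[1]
        params = {"b0": float(theta[0])}
        steps = np.zeros(k_max)
        steps[active] = theta[1:p_base]
        for k in range(1, k_max + 1):
            params[_step_name(k)] = float(steps[k - 1])
        dev_full = np.zeros(p_base)
        dev_full[dev_active] = theta[p_base:]
        params["d0"] = float(dev_full[0])
        dsteps = np.zeros(k_max)
        dsteps[active] = dev_full[1:]
        for k in range(1, k_max + 1):
            params[f"d_{k}-{k - 1}"] = float(dsteps[k - 1])
        fit = _finish(
            "stacked_monotonic",
            params,
            ll,
            Z,
            x,
            g,
            converged,
            k_max=k_max,
            direction=direction,
            levels=(levels[0], levels[1]),
        )
        if best_fit is None or fit.loglik > best_fit.loglik:
            best_fit = fit
    assert best_fit is not None
    return best_fit


def predict_mean(fit: ModelFit, A=None, B=None, g=1.0, groups=None) -> np.ndarray:
    """Evaluate the fitted mean function mu_j for new (A, B, g).

    ``groups`` (labels aligned with the samples) is required for stacked
    fits and rejected for all others.
    """
    if fit.family not in FAMILIES:
        raise ValueError(f"unknown family {fit.family!r}")
    g = np.atleast_1d(np.asarray(g, dtype=float))
    if fit.family == "constant":
        mu = fit.params["b0"] * g
        return mu
    A = np.atleast_1d(np.asarray(A, dtype=float))
    B = np.atleast_1d(np.asarray(B, dtype=float))
    if g.shape == (1,):
        g = np.full_like(A, g[0])
    p = fit.params
    if fit.family == "linear":
        base = p["b0"] + p["a"] * (A + B)
    elif fit.family == "interaction":
        base = p["b0"] + p["a"] * (A + B) + p["c"] * A * B
    elif fit.family in ("monotonic", "stacked_monotonic"):
        if fit.k_max is None:
            raise ValueError("monotonic fit lacks k_max")
        S = _step_design(A, B, fit.k_max)
        steps = np.array([p[_step_name(k)] for k in range(1, fit.k_max + 1)])
        base = p["b0"] + S @ steps
        if fit.family == "stacked_monotonic":
            if groups is None:
                raise ValueError("stacked fit requires group labels for prediction")
            labels = (
                groups.labels.to_numpy() if isinstance(groups, SampleGroups) else np.asarray(groups).astype(str)
            )
            ind = (labels == fit.direction).astype(float)
            dsteps = np.array([p[f"d_{k}-{k - 1}"] for k in range(1, fit.k_max + 1)])
            base = base + ind * (p["d0"] + S @ dsteps)
    mu = base * g
    if (mu < -1e-9).any():
        raise ValueError("negative predicted mean")
    return np.maximum(mu, 0.0)


def lrt(null_fit: ModelFit, alt_fit: ModelFit) -> LrtResult:
    """Likelihood-ratio test of nested fits on the same data.

    statistic = max(0, 2 * (loglik_alt - loglik_null)); df = rank_alt -
    rank_null; p from the chi-square upper tail (p = 1 when df = 0).
    """
    if null_fit.n_obs != alt_fit.n_obs:
        raise ValueError("fits compare different data (n_obs mismatch)")
    df = alt_fit.rank - null_fit.rank
    if df < 0:
        raise ValueError("alternative fit has lower rank than null")
    statistic = 2.0 * (alt_fit.loglik - null_fit.loglik)
    if statistic < 0:
        if statistic < -1e-6:
            logger.warning("LRT statistic %.3g < 0 clamped to 0", statistic)
        statistic = 0.0
    p = 1.0 if df == 0 else float(stats.chi2.sf(statistic, df))
    return LrtResult(statistic=float(statistic), df=int(df), p=p)
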