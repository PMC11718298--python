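"""Fitting Pitman-Yor parameters to anonymity-set data, plus samplers.

The size multiset of anonymity sets is exactly a partition of the gallery, so
the natural likelihood for ``(d, alpha)`` is the exchangeable partition
probability function (EPPF) of the Pitman-Yor process:

    log P = sum_{i=1}^{K-1} log(alpha + i d)
          - [lgamma(alpha + n) - lgamma(alpha + 1)]
          + sum_sets [lgamma(s - d) - lgamma(1 - d)]

Maximum a-posteriori estimation (:func:`fit_map`) maximizes this plus a
configurable log-prior over ``(d, log alpha)`` by derivative-free simplex
search with deterministic multi-starts; the default prior is flat within
bounds, i.e. bounded maximum likelihood.  The fitted point is reported in the
entropy / tail-complexity parameterization.

Two samplers serve as simulation oracles and power posterior-predictive
checks: the sequential Chinese-restaurant construction (:func:`sample_crp`)
and the stick-breaking representation (:func:`sample_stick_breaking`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .galleries import AnonymitySetCounts
from .metrics import FrequencyVector
from .params import LN2, InfoParams, PYParams, info_from_py

__all__ = [
    "FitConfig",
    "FitDiagnostics",
    "eppf_log_likelihood",
    "fit_map",
    "sample_crp",
    "sample_stick_breaking",
    "posterior_predictive_bands",
    "kl_ranksize",
]

_BIG = 1e300


def eppf_log_likelihood(counts: AnonymitySetCounts, params: PYParams) -> float:
    """Log exchangeable-partition probability of the observed size multiset
    under ``PY(d, alpha)``.

    Finite for all valid inputs in the standard regime; boundary poles
    (``d -> 1`` with any set of size >= 2) return ``-inf`` rather than raise.
    """
    d, alpha = params.d, params.alpha
    if not (0.0 <= d < 1.0):
        raise ValueError(f"eppf_log_likelihood: fitting regime requires 0 <= d < 1, got d={d}")
    n = counts.n_records
    K = counts.n_sets
    s, mult = counts.size_arrays()
    if K > 1:
        term_new = float(np.sum(np.log(alpha + d * np.arange(1, K, dtype=float))))
    else:
        term_new = 0.0
    term_seq = float(gammaln(alpha + n) - gammaln(alpha + 1.0))
    term_sets = float(np.sum(mult * (gammaln(s - d) - gammaln(1.0 - d))))
    return term_new - term_seq + term_sets


@dataclass(frozen=True)
class FitConfig:
    """Search configuration for :func:`fit_map`.

    Bounds are expressed in ``(d, log alpha)`` space, where the likelihood
    ridge is easiest to bracket; the flat default prior makes the fit a
    bounded maximum-likelihood estimate.  ``log_prior`` may be any callable
    ``(d, alpha) -> float`` added to the log-likelihood.
    """

    d_bounds: tuple[float, float] = (0.0, 0.999)
    log_alpha_bounds: tuple[float, float] = (-6.0, 30.0)
    starts: tuple[tuple[float, float], ...] = (
        (0.05, 0.0),
        (0.3, 2.0),
        (0.5, 5.0),
        (0.7, 8.0),
        (0.95, 2.0),
    )
    ftol: float = 1e-8
    xtol: float = 1e-8
    max_iter: int = 2000
    log_prior: Callable[[float, float], float] | None = None
    #: distance to a bound (in the search coordinates) below which the fit is
    #: flagged as boundary / non-identifiable
    boundary_margin: float = 1e-3


@dataclass
class FitDiagnostics:
    """Diagnostics attached to a Pitman-Yor MAP fit."""

    log_likelihood: float
    converged: bool
    n_restarts: int
    n_evals: int
    boundary: bool
    d: float
    alpha: float
    kl_bits: float | None = None
    trace: list = field(default_factory=list)


def fit_map(
    counts: AnonymitySetCounts, config: FitConfig | None = None
) -> tuple[InfoParams, FitDiagnostics]:
    """MAP estimate of ``(h, gamma)`` from an anonymity-set size multiset.

    Maximizes the EPPF plus the configured log-prior over ``(d, log alpha)``
    with Nelder-Mead simplex search from deterministic multi-starts, then
    converts the best point to the information parameterization.  The result
    is deterministic given ``config``.
    """
    config = config or FitConfig()
    if counts.n_records < 2:
        raise ValueError("fit_map: need at least 2 records to fit")
    (d_lo, d_hi) = config.d_bounds
    (la_lo, la_hi) = config.log_alpha_bounds
    n_evals = 0

    def neg_objective(x):
        nonlocal n_evals
        n_evals += 1
        d, la = float(x[0]), float(x[1])
        if not (d_lo <= d <= d_hi and la_lo <= la <= la_hi):
            return _BIG
        alpha = math.exp(la)
        ll = eppf_log_likelihood(counts, PYParams(d, alpha))
        if config.log_prior is not None:
            ll += config.log_prior(d, alpha)
        if not math.isfinite(ll):
            return _BIG
        return -ll

    results = []
    trace = []
    for start in config.starts:
        res = minimize(
            neg_objective,
            x0=np.asarray(start, dtype=float),
            method="Nelder-Mead",
            options={
                "fatol": config.ftol,
                "xatol": config.xtol,
                "maxiter": config.max_iter,
            },
        )
        results.append(res)
        trace.append(
            {"start": tuple(start), "x": tuple(res.x), "fun": float(res.fun), "success": bool(res.success)}
        )
    usable = [r for r in results if np.isfinite(r.fun) and r.fun < _BIG]
    if not usable:
        raise RuntimeError(f"fit_map: all {len(results)} starts failed to converge: {trace}")
    best = min(usable, key=lambda r: r.fun)
    d_hat = float(np.clip(best.x[0], d_lo, d_hi))
    la_hat = float(np.clip(best.x[1], la_lo, la_hi))
    alpha_hat = math.exp(la_hat)
    # d at its lower bound is the regular Dirichlet-process case, not a
    # pathology; non-identifiability shows as d -> 1 or log(alpha) at a bound
    boundary = (
        d_hi - d_hat < config.boundary_margin
        or min(la_hat - la_lo, la_hi - la_hat) < config.boundary_margin
    )
    params = PYParams(d_hat, alpha_hat)
    diag = FitDiagnostics(
        log_likelihood=eppf_log_likelihood(counts, params),
        converged=any(r.success for r in usable),
        n_restarts=len(config.starts),
        n_evals=n_evals,
        boundary=boundary,
        d=d_hat,
        alpha=alpha_hat,
        trace=trace,
    )
    return info_from_py(params), diag


def sample_crp(n: int, params: PYParams, seed) -> AnonymitySetCounts:
    """Sample an anonymity-set partition of ``n`` records by the sequential
    Chinese-restaurant construction of ``PY(d, alpha)``.

    Record ``i`` (0-based, ``i`` already seated) opens a new set with
    probability ``(alpha + K d)/(alpha + i)`` and otherwise joins an existing
    set with probability proportional to its size minus ``d`` (implemented by
    uniform-record proposal with rejection, exact and O(1) expected per
    record).  Reproducible given ``seed``.
    """
    n = int(n)
    if n < 1:
        raise ValueError("sample_crp: n must be >= 1")
    if params.d < 0:
        raise ValueError("sample_crp: sampling requires the standard regime d >= 0")
    d, alpha = params.d, params.alpha
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=np.int64)
    sizes: list[int] = []
    branch_u = rng.random(n)
    K = 0
    for i in range(n):
        if i == 0 or branch_u[i] * (alpha + i) < alpha + K * d:
            assign[i] = K
            sizes.append(1)
            K += 1
        else:
            while True:
                t = int(assign[rng.integers(i)])
                if d == 0.0 or rng.random() * sizes[t] >= d:
                    break
            assign[i] = t
            sizes[t] += 1
    return AnonymitySetCounts.from_sizes(sizes)


def sample_stick_breaking(
    params: PYParams,
    tail_mass_tol: float = 1e-8,
    max_atoms: int = 100_000,
    seed=None,
) -> FrequencyVector:
    """Draw a frequency vector from ``PY(d, alpha)`` by stick breaking.

    ``V_i ~ Beta(1 - d, alpha + i d)`` and ``pi_i = V_i prod_{j<i}(1 - V_j)``,
    truncated once the remaining stick mass drops below ``tail_mass_tol`` and
    renormalized.  If ``max_atoms`` is reached first, the result is returned
    renormalized with its ``truncated`` flag set.
    """
    if params.d < 0:
        raise ValueError("sample_stick_breaking: requires the standard regime d >= 0")
    d, alpha = params.d, params.alpha
    rng = np.random.default_rng(seed)
    chunks = []
    remaining = 1.0
    i = 0
    block = 1024
    truncated = True
    while i < max_atoms:
        idx = np.arange(i + 1, min(i + block, max_atoms) + 1, dtype=float)
        v = rng.beta(1.0 - d, alpha + d * idx)
        stick = remaining * v * np.cumprod(np.concatenate([[1.0], 1.0 - v[:-1]]))
        chunks.append(stick)
        remaining *= float(np.prod(1.0 - v))
        i += idx.size
        if remaining < tail_mass_tol:
            truncated = False
            break
    p = np.concatenate(chunks)
    p = p[p > 0]
    return FrequencyVector(p / p.sum(), truncated=truncated)


def _ranked_sizes(gallery_counts: np.ndarray, max_rank: int) -> np.ndarray:
    sizes = np.sort(gallery_counts[gallery_counts > 0])[::-1]
    out = np.zeros(max_rank, dtype=float)
    out[: min(max_rank, sizes.size)] = sizes[:max_rank]
    return out


def posterior_predictive_bands(
    params: PYParams,
    n: int,
    reps: int = 200,
    quantiles: tuple[float, ...] = (0.025, 0.5, 0.975),
    seed=None,
    tail_mass_tol: float | None = None,
    max_atoms: int = 100_000,
):
    """Rank-size envelope of anonymity-set sizes predicted by ``PY(d, alpha)``.

    Each replicate draws frequencies by stick breaking, then an ``n``-record
    gallery from them, and records the sorted (rank-size) set sizes.  Returns
    a dict with ``ranks`` (1-based), ``quantiles`` (requested levels) and
    ``bands`` of shape ``(len(quantiles), max_rank)``; absent ranks count as
    size 0.
    """
    n = int(n)
    reps = int(reps)
    if reps < 1:
        raise ValueError("posterior_predictive_bands: reps must be >= 1")
    rng = np.random.default_rng(seed)
    tol = tail_mass_tol if tail_mass_tol is not None else min(1e-6, 0.1 / n)
    draws = []
    max_rank = 1
    for _ in range(reps):
        freqs = sample_stick_breaking(params, tail_mass_tol=tol, max_atoms=max_atoms, seed=rng)
        gallery = rng.multinomial(n, freqs.p)
        draws.append(gallery)
        max_rank = max(max_rank, int(np.sum(gallery > 0)))
    mat = np.stack([_ranked_sizes(g, max_rank) for g in draws])
    bands = np.quantile(mat, quantiles, axis=0)
    return {"ranks": np.arange(1, max_rank + 1), "quantiles": tuple(quantiles), "bands": bands}


def kl_ranksize(
    empirical: AnonymitySetCounts,
    fitted: PYParams,
    n: int | None = None,
    reps: int = 50,
    seed=None,
    max_atoms: int = 100_000,
) -> float:
    """KL divergence (bits) between the empirical anonymity-set size
    distribution and the mean predictive size distribution of the fitted
    process, simulated at gallery size ``n`` (defaults to the empirical N).

    Both distributions are expressed over ranks: the empirical distribution
    assigns rank ``r`` the relative size of the r-th largest anonymity set,
    and the predictive distribution averages the rank-r set size over
    replicates (absent ranks count 0).  Returns ``+inf`` (no support overlap
    at some observed rank) when every replicate produces fewer sets than
    observed at a rank the empirical data occupies.
    """
    n = int(n) if n is not None else empirical.n_records
    rng = np.random.default_rng(seed)
    tol = min(1e-6, 0.1 / n)
    emp_sizes = np.sort(empirical.expand_sizes())[::-1].astype(float)
    p_emp = emp_sizes / emp_sizes.sum()
    rank_draws = []
    max_rank = p_emp.size
    for _ in range(int(reps)):
        freqs = sample_stick_breaking(fitted, tail_mass_tol=tol, max_atoms=max_atoms, seed=rng)
        gallery = rng.multinomial(n, freqs.p)
        rank_draws.append(np.sort(gallery[gallery > 0])[::-1].astype(float))
        max_rank = max(max_rank, rank_draws[-1].size)
    mat = np.zeros((len(rank_draws), max_rank))
    for i, draw in enumerate(rank_draws):
        mat[i, : draw.size] = draw
    q = mat.mean(axis=0)
    q = q / q.sum()
    p = np.zeros(max_rank)
    p[: p_emp.size] = p_emp
    if np.any((p > 0) & (q == 0)):
        return float("inf")
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])) / LN2)
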