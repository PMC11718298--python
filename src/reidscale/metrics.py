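"""Closed-form privacy metrics: correctness, uniqueness, k-anonymity violations.

Two families of formulas live here.

*Finite-distribution forms* take an explicit frequency vector ``pi`` over
anonymity sets and give the exact expectation of each metric for a gallery of
``n`` i.i.d. records:

- correctness  ``kappa(n) = (1/n) * sum_i [1 - (1 - pi_i)^n]``
  (expected number of occupied anonymity sets over ``n``);
- uniqueness   ``Xi(n) = sum_i pi_i (1 - pi_i)^(n-1)``;
- k-violations ``V_k(n) = sum_i pi_i * P[Binomial(n-1, pi_i) <= k-2]``,
  the per-record probability that fewer than ``k`` records share its set.

*Prior-expectation forms* integrate those quantities over a Pitman-Yor prior
``PY(d, alpha)`` on the frequencies, yielding gamma-function ratios evaluated
in log-gamma space so they remain stable up to populations of billions.  The
``d -> 0`` Dirichlet-process limits are handled analytically (switchover at
``|d| < 1e-8``) to avoid the catastrophic cancellation in ``1/(n d)``.

The expected number of k-anonymity violations uses the finite occupancy sum

    E[V_k(n)] = sum_{j=1}^{k-1} (j/n) C(n, j) * C_{d,alpha} * B(j - d, n - j + alpha + d)

with ``C_{d,alpha} = Gamma(1+alpha) / (Gamma(1-d) Gamma(alpha+d))`` the mean
intensity constant of the process -- an exact rewriting of the generalized
hypergeometric (3F2) form that avoids fragile special-function edge cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, betainc

from .params import PYParams, digamma

__all__ = [
    "FrequencyVector",
    "expected_correctness",
    "expected_uniqueness",
    "expected_kanon_violations",
    "correctness_from_frequencies",
    "uniqueness_from_frequencies",
    "kanon_from_frequencies",
]

#: below this discount the analytic Dirichlet-process limit is used
DP_LIMIT_THRESHOLD = 1e-8
#: tolerance on sum(pi) for a frequency vector to count as normalized
FREQ_NORM_TOL = 1e-8


@dataclass(frozen=True)
class FrequencyVector:
    """A finite vector of anonymity-set probabilities.

    Entries must be strictly positive and sum to one (within tolerance).
    Semantics are exchangeable: the order of entries never matters.
    ``truncated`` marks vectors produced by a truncated stick-breaking
    construction that hit its atom cap before reaching its mass tolerance.
    """

    p: np.ndarray
    truncated: bool = field(default=False, compare=False)

    def __post_init__(self):
        arr = np.asarray(self.p, dtype=float).ravel()
        if arr.size == 0:
            raise ValueError("FrequencyVector: empty frequency vector")
        if np.any(arr <= 0):
            raise ValueError("FrequencyVector: all frequencies must be strictly positive")
        total = arr.sum()
        if abs(total - 1.0) > FREQ_NORM_TOL:
            raise ValueError(
                f"FrequencyVector: frequencies sum to {total!r}, not 1 (tol {FREQ_NORM_TOL})"
            )
        object.__setattr__(self, "p", arr)

    def __len__(self):
        return self.p.size

    def entropy(self) -> float:
        """Shannon entropy of the vector, in nats."""
        return float(-np.sum(self.p * np.log(self.p)))


#: above this argument, log-gamma/digamma differences switch to asymptotic
#: series (direct subtraction loses all precision for huge nearly-equal args)
_SERIES_SWITCH = 1e4


def _c2(a: float) -> float:
    # z^-2 coefficient of log[Gamma(z+a)/Gamma(z)] - a log z - a(a-1)/(2z)
    return a * (a - 1.0) * (a - 2.0) * (3.0 * a - 1.0) / 24.0 - (a * (a - 1.0)) ** 2 / 8.0


def _lgamma_diff(x, a: float):
    """lgamma(x + a) - lgamma(x) for 0 < |a| < 2, stable for huge x."""
    x = np.asarray(x, dtype=float)
    small = x <= _SERIES_SWITCH
    out = np.empty_like(x)
    if np.any(small):
        xs = x[small]
        out[small] = gammaln(xs + a) - gammaln(xs)
    if np.any(~small):
        xl = x[~small]
        out[~small] = a * np.log(xl) + a * (a - 1.0) / (2.0 * xl) + _c2(a) / xl**2
    return out


def _lgamma_ratio_shift(alpha: float, n, d: float):
    """[lgamma(n+alpha+d) - lgamma(n+alpha)] - [lgamma(alpha+d) - lgamma(alpha)].

    Equals ``log[ Gamma(n+alpha+d) Gamma(alpha) / (Gamma(n+alpha) Gamma(alpha+d)) ]``,
    which tends to ``d * n / alpha`` as ``alpha -> inf``; the joint series keeps
    full relative accuracy there where separate log-gamma calls lose everything.
    """
    n = np.asarray(n, dtype=float)
    if alpha <= _SERIES_SWITCH:
        return _lgamma_diff(n + alpha, d) - (gammaln(alpha + d) - gammaln(alpha))
    u = 1.0 / alpha
    w = 1.0 / (n + alpha)
    return (
        d * np.log1p(n * u)
        - 0.5 * d * (d - 1.0) * n * u * w
        + _c2(d) * (w * w - u * u)
    )


def _digamma_diff(alpha: float, n):
    """psi0(alpha + n) - psi0(alpha), stable for huge alpha."""
    n = np.asarray(n, dtype=float)
    if alpha <= _SERIES_SWITCH:
        return digamma(alpha + n) - digamma(alpha)
    u = 1.0 / alpha
    w = 1.0 / (alpha + n)
    return np.log1p(n * u) + 0.5 * n * u * w + (u * u - w * w) / 12.0


def _check_n(n) -> np.ndarray:
    arr = np.asarray(n, dtype=float)
    if np.any(arr < 1):
        raise ValueError(f"population size n must be >= 1, got {n!r}")
    return arr


def _maybe_scalar(out, n):
    if np.isscalar(n) or np.asarray(n).ndim == 0:
        return float(out)
    return out


def expected_correctness(n, params: PYParams):
    """Expected correctness ``E[kappa(n) | d, alpha]`` under a Pitman-Yor prior.

    The expected fraction of records correctly matched from their auxiliary
    information in a gallery of ``n`` i.i.d. records:

        (1/(n d)) * (Gamma(1+alpha) Gamma(n+d+alpha) / (Gamma(d+alpha) Gamma(n+alpha)) - alpha)

    with the Dirichlet-process limit ``(alpha/n) * (psi0(alpha+n) - psi0(alpha))``
    as ``d -> 0``.  Accepts a scalar or array ``n``; values lie in ``(0, 1]``
    and are non-increasing in ``n``.
    """
    narr = _check_n(n)
    d, alpha = params.d, params.alpha
    if abs(d) < DP_LIMIT_THRESHOLD:
        out = (alpha / narr) * _digamma_diff(alpha, narr)
    elif alpha > 0:
        # (ratio - alpha)/(n d) with ratio = alpha * exp(shift); the expm1 form
        # stays accurate when ratio ~ alpha (huge alpha, kappa ~ 1)
        shift = _lgamma_ratio_shift(alpha, narr, d)
        out = alpha * np.expm1(shift) / (narr * d)
    else:
        # alpha = 0 (heaviest tail): Gamma(n+d)/(Gamma(d) Gamma(n)) / (n d)
        log_ratio = _lgamma_diff(narr, d) - gammaln(d)
        out = np.exp(log_ratio) / (narr * d)
    out = np.clip(out, 0.0, 1.0)
    return _maybe_scalar(out, n)


def expected_uniqueness(n, params: PYParams):
    """Expected uniqueness ``E[Xi(n) | d, alpha]``: the fraction of records
    whose auxiliary information is unique in a gallery of ``n`` records.

        Gamma(alpha+1) Gamma(n+d+alpha-1) / (Gamma(d+alpha) Gamma(n+alpha))

    with the Dirichlet-process limit ``alpha / (n + alpha - 1)``.
    """
    narr = _check_n(n)
    d, alpha = params.d, params.alpha
    if abs(d) < DP_LIMIT_THRESHOLD:
        out = alpha / (narr + alpha - 1.0)
    elif alpha > 0:
        # alpha * exp(shift at n-1) / (n + alpha - 1)
        shift = _lgamma_ratio_shift(alpha, narr - 1.0, d)
        out = alpha * np.exp(shift) / (narr + alpha - 1.0)
    else:
        log_val = np.where(
            narr > 1.0, _lgamma_diff(narr, d - 1.0) - gammaln(d), 0.0
        )
        out = np.exp(log_val)
    out = np.clip(out, 0.0, 1.0)
    return _maybe_scalar(out, n)


def expected_kanon_violations(n, k: int, params: PYParams):
    """Expected fraction of k-anonymity violations ``E[V_k(n) | d, alpha]``.

    A record violates k-anonymity when its anonymity set holds fewer than
    ``k`` records.  Evaluated as the exact occupancy sum over set sizes
    ``j = 1 .. k-1`` (see module docstring); ``k = 1`` is identically 0 and
    ``k = 2`` reduces to the expected uniqueness.
    """
    narr = _check_n(n)
    k = int(k)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if np.any(k > narr):
        raise ValueError(f"k={k} exceeds population size n={n!r}")
    if k == 1:
        return _maybe_scalar(np.zeros_like(narr), n)
    d, alpha = params.d, params.alpha
    j = np.arange(1, k, dtype=float)  # set sizes counted as violations
    narr_b = narr[..., None]
    # log of (j/n) * C(n, j) * Gamma(1+alpha)/(Gamma(1-d)Gamma(alpha+d)) * B(j-d, n-j+alpha+d)
    log_terms = (
        np.log(j)
        - np.log(narr_b)
        + gammaln(narr_b + 1.0)
        - gammaln(j + 1.0)
        - gammaln(narr_b - j + 1.0)
        + gammaln(1.0 + alpha)
        - gammaln(1.0 - d)
        - gammaln(alpha + d)
        + gammaln(j - d)
        + gammaln(narr_b - j + alpha + d)
        - gammaln(narr_b + alpha)
    )
    out = np.clip(np.exp(log_terms).sum(axis=-1), 0.0, 1.0)
    return _maybe_scalar(out, n)


def correctness_from_frequencies(freqs: FrequencyVector, n):
    """Exact expected correctness for an explicit frequency vector.

    ``kappa(n) = (1/n) sum_i [1 - (1 - pi_i)^n]`` -- the expected number of
    occupied anonymity sets divided by the gallery size.
    """
    narr = _check_n(n)
    p = freqs.p
    # 1 - (1-p)^n computed as -expm1(n * log1p(-p)) for accuracy at small p;
    # p = 1 gives log1p(-1) = -inf, which expm1 maps to the correct limit 1
    with np.errstate(divide="ignore"):
        log1mp = np.log1p(-p)
    occupied = -np.expm1(narr[..., None] * log1mp)
    out = occupied.sum(axis=-1) / narr
    return _maybe_scalar(np.clip(out, 0.0, 1.0), n)


def uniqueness_from_frequencies(freqs: FrequencyVector, n):
    """Exact expected uniqueness ``Xi(n) = sum_i pi_i (1 - pi_i)^(n-1)``."""
    narr = _check_n(n)
    p = freqs.p
    with np.errstate(divide="ignore", invalid="ignore"):
        log1mp = np.log1p(-p)
        terms = p * np.exp((narr[..., None] - 1.0) * log1mp)
    # p = 1 contributes (1-1)^(n-1): 1 at n=1, 0 for n > 1
    terms = np.where(np.isnan(terms), np.where(narr[..., None] == 1.0, p, 0.0), terms)
    out = terms.sum(axis=-1)
    return _maybe_scalar(np.clip(out, 0.0, 1.0), n)


def kanon_from_frequencies(freqs: FrequencyVector, n, k: int):
    """Exact expected fraction of k-anonymity violations for explicit
    frequencies: ``V_k(n) = sum_i pi_i * I_{1-pi_i}(n-k+1, k-1)``, where the
    regularized incomplete beta term is the probability that at most ``k-2``
    of the other ``n-1`` records fall in set ``i``.
    """
    narr = _check_n(n)
    k = int(k)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if np.any(k > narr):
        raise ValueError(f"k={k} exceeds population size n={n!r}")
    if k == 1:
        return _maybe_scalar(np.zeros_like(narr), n)
    if k == 2:
        return uniqueness_from_frequencies(freqs, n)
    p = freqs.p
    # I_{1-p}(n-k+1, k-1) = P[Binomial(n-1, p) <= k-2]
    tail = betainc(narr[..., None] - k + 1.0, k - 1.0, np.clip(1.0 - p, 0.0, 1.0))
    out = (p * tail).sum(axis=-1)
    return _maybe_scalar(np.clip(out, 0.0, 1.0), n)
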