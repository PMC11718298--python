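"""Measurement-based extrapolation of identification accuracy.

Given ``t >= 2`` measurements of the correctness ``kappa`` at gallery sizes
``n_1 < ... < n_t``, fit the two information parameters ``(h, gamma)`` by
minimizing the log-weighted quadratic loss

    R(h, gamma) = sum_i log(n_i) * [kappa_hat(n_i) - E[kappa(n_i) | h, gamma]]^2

with derivative-free simplex search, then forecast ``E[kappa(n') | h, gamma]``
at any larger population ``n'``.  The log weight places more trust in larger
galleries, whose correctness measurements are more precise.

Baseline comparators fitted under the *identical* loss:

- ENT — the same model restricted to ``gamma = 0`` (entropy only, one free
  parameter), the analytic form of the classical "bits of entropy" rule of
  thumb;
- EXP — exponential decay ``kappa(n) = min(1, a * exp(-b n))``;
- POL — power law ``kappa(n) = min(1, a * n^-b)``;
- RND — a seeded uniform draw on ``[0, kappa_hat(n_t)]``, the no-information
  reference.

:func:`evaluate_extrapolation` runs the standard benchmark: for each
collection with known full-population correctness, build a training curve of
up to ``t = 50`` points evenly spaced in log population up to a sampling
fraction ``mu`` of the full size, fit every model, forecast at the full size
and aggregate RMSE / bias per model and fraction (keeping only collections
with ``0.01 < kappa(n_t) < 0.99``, where extrapolation is non-trivial).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .galleries import (
    AnonymitySetCounts,
    CorrectnessCurve,
    empirical_correctness,
    subsampled_correctness_curve,
)
from .metrics import expected_correctness
from .params import InfoParams, py_from_info

__all__ = [
    "MODEL_KINDS",
    "CurveFitConfig",
    "FitResult",
    "pyc_mb_loss",
    "fit_pyc_mb",
    "fit_baseline",
    "forecast",
    "training_sizes",
    "measure_training_curve",
    "evaluate_extrapolation",
]

MODEL_KINDS = ("PYC", "ENT", "EXP", "POL", "RND")

_BIG = 1e300
#: losses within this of the optimum count as ties (broken by smallest h,
#: then smallest gamma, for deterministic output)
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class CurveFitConfig:
    """Search configuration for curve fitting.

    ``h`` bounds are in nats and cover every regime from a handful of
    distinguishable profiles to far beyond cryptographic identifiers;
    the 4x4 multi-start lattice spans the (h, gamma) box.
    """

    h_bounds: tuple[float, float] = (1e-3, 120.0)
    gamma_bounds: tuple[float, float] = (0.0, 1.0)
    h_starts: tuple[float, ...] = (1.0, 10.0, 40.0, 90.0)
    gamma_starts: tuple[float, ...] = (0.05, 0.35, 0.65, 0.95)
    ftol: float = 1e-10
    xtol: float = 1e-8
    max_iter: int = 1000
    seed: int = 0


@dataclass
class FitResult:
    """A fitted scaling-law model.

    ``params`` holds the model's free parameters (``h``/``gamma`` for
    PYC and ENT, ``a``/``b`` for EXP and POL, ``kappa_max``/``seed`` for
    RND); ``loss`` is the final log-weighted quadratic loss; ``train_range``
    records the span of population sizes used.
    """

    kind: str
    params: dict
    loss: float
    converged: bool
    train_range: tuple[float, float]
    boundary: bool = False
    notes: list = field(default_factory=list)

    def info(self) -> InfoParams:
        if self.kind not in ("PYC", "ENT"):
            raise ValueError(f"FitResult.info: model {self.kind} has no (h, gamma)")
        return InfoParams(self.params["h"], self.params["gamma"])


def _usable_points(curve: CorrectnessCurve) -> tuple[np.ndarray, np.ndarray]:
    n, kappa = curve.n, curve.kappa
    keep = n >= 2
    if not np.all(keep):
        warnings.warn(
            "pyc_mb_loss: dropping training points at n=1 (zero log-weight and kappa(1)=1)",
            stacklevel=3,
        )
    return n[keep], kappa[keep]


def _model_kappa(info: InfoParams, n: np.ndarray) -> np.ndarray:
    return np.asarray(expected_correctness(n, py_from_info(info)), dtype=float)


def pyc_mb_loss(info: InfoParams, curve: CorrectnessCurve) -> float:
    """Log-weighted quadratic loss of an ``(h, gamma)`` candidate on a curve."""
    n, kappa = _usable_points(curve)
    if n.size < 2:
        raise ValueError("pyc_mb_loss: need at least 2 usable points with n >= 2")
    model = _model_kappa(info, n)
    return float(np.sum(np.log(n) * (kappa - model) ** 2))


def _simplex_minimize(fun, x0, config):
    return minimize(
        fun,
        x0=np.asarray(x0, dtype=float),
        method="Nelder-Mead",
        options={"fatol": config.ftol, "xatol": config.xtol, "maxiter": config.max_iter},
    )


def _select_best(cands):
    """Pick min-loss candidate; ties broken by smallest h then smallest gamma
    (or smallest parameter tuple for the ad-hoc baselines)."""
    best_loss = min(c[0] for c in cands)
    tied = [c for c in cands if c[0] <= best_loss + _TIE_TOL]
    return min(tied, key=lambda c: (c[1], c[2]))


def fit_pyc_mb(curve: CorrectnessCurve, config: CurveFitConfig | None = None) -> FitResult:
    """Fit ``(h, gamma)`` to a correctness curve under the log-weighted loss.

    Deterministic multi-start Nelder-Mead over the bounded ``(h, gamma)``
    box.  A curve that is identically 1 pins ``h`` at its upper bound and is
    flagged as a boundary fit.
    """
    config = config or CurveFitConfig()
    n, kappa = _usable_points(curve)
    if n.size < 2:
        raise ValueError("fit_pyc_mb: need at least 2 usable points with n >= 2")
    (h_lo, h_hi) = config.h_bounds
    (g_lo, g_hi) = config.gamma_bounds
    if np.all(kappa >= 1.0):
        # degenerate: everyone identified at every measured size; any
        # sufficiently large entropy interpolates, report the bound flagged
        return FitResult(
            kind="PYC",
            params={"h": h_hi, "gamma": g_lo},
            loss=0.0,
            converged=True,
            train_range=(float(n[0]), float(n[-1])),
            boundary=True,
            notes=["degenerate all-ones curve: entropy pinned at its upper bound"],
        )
    logn = np.log(n)

    def neg(x):
        h, g = float(x[0]), float(x[1])
        if not (h_lo <= h <= h_hi and g_lo <= g <= g_hi):
            return _BIG
        model = _model_kappa(InfoParams(h, g), n)
        return float(np.sum(logn * (kappa - model) ** 2))

    # seeding with the entropy-only (gamma = 0) optimum guarantees the nested
    # model can never beat the full fit
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # already warned above
            ent_h = _fit_ent(curve, config).params["h"]
        extra_starts = [(ent_h, g_lo)]
    except RuntimeError:
        extra_starts = []
    cands = []
    any_success = False
    start_grid = [(h0, g0) for h0 in config.h_starts for g0 in config.gamma_starts]
    for h0, g0 in start_grid + extra_starts:
        res = _simplex_minimize(neg, (h0, g0), config)
        if not np.isfinite(res.fun) or res.fun >= _BIG:
            continue
        h, g = float(np.clip(res.x[0], h_lo, h_hi)), float(np.clip(res.x[1], g_lo, g_hi))
        cands.append((float(res.fun), h, g, bool(res.success)))
        any_success = any_success or res.success
    if not cands:
        raise RuntimeError("fit_pyc_mb: no start converged to a finite loss")
    loss, h, g, _ = _select_best(cands)
    boundary = min(h - h_lo, h_hi - h) < 1e-6 * (h_hi - h_lo) or np.all(kappa >= 1.0)
    return FitResult(
        kind="PYC",
        params={"h": h, "gamma": g},
        loss=loss,
        converged=any_success,
        train_range=(float(n[0]), float(n[-1])),
        boundary=bool(boundary),
    )


def _fit_ent(curve, config):
    n, kappa = _usable_points(curve)
    if n.size < 2:
        raise ValueError("fit_baseline: ENT needs at least 2 usable points")
    (h_lo, h_hi) = config.h_bounds
    logn = np.log(n)

    def neg(x):
        h = float(x[0])
        if not (h_lo <= h <= h_hi):
            return _BIG
        model = _model_kappa(InfoParams(h, 0.0), n)
        return float(np.sum(logn * (kappa - model) ** 2))

    cands = []
    any_success = False
    for h0 in config.h_starts:
        res = _simplex_minimize(neg, (h0,), config)
        if not np.isfinite(res.fun) or res.fun >= _BIG:
            continue
        h = float(np.clip(res.x[0], h_lo, h_hi))
        cands.append((float(res.fun), h, 0.0, bool(res.success)))
        any_success = any_success or res.success
    if not cands:
        raise RuntimeError("fit_baseline: no ENT start converged")
    loss, h, _, _ = _select_best(cands)
    boundary = min(h - h_lo, h_hi - h) < 1e-6 * (h_hi - h_lo)
    return FitResult(
        kind="ENT",
        params={"h": h, "gamma": 0.0},
        loss=loss,
        converged=any_success,
        train_range=(float(n[0]), float(n[-1])),
        boundary=bool(boundary),
    )


def _decay_model(kind: str, a: float, b: float, n: np.ndarray) -> np.ndarray:
    if kind == "EXP":
        with np.errstate(under="ignore"):
            vals = a * np.exp(-b * n)
    else:  # POL
        vals = a * n ** (-b)
    return np.minimum(1.0, vals)


def _fit_decay(curve, kind, config):
    n, kappa = _usable_points(curve)
    if n.size < 2:
        raise ValueError(f"fit_baseline: {kind} needs at least 2 usable points")
    logn = np.log(n)

    def neg(x):
        la, lb = float(x[0]), float(x[1])
        if abs(la) > 200 or lb < -300 or lb > 200:
            return _BIG
        model = _decay_model(kind, math.exp(la), math.exp(lb), n)
        return float(np.sum(logn * (kappa - model) ** 2))

    # seed from a log-linear regression on the decaying part of the curve
    pos = kappa > 1e-12
    starts = [(0.0, -math.log(n[-1])), (0.0, math.log(1.0 / n[-1]) / 2), (1.0, -5.0)]
    if pos.sum() >= 2:
        x_reg = n[pos] if kind == "EXP" else np.log(n[pos])
        slope, intercept = np.polyfit(x_reg, np.log(kappa[pos]), 1)
        if slope < 0:
            starts.insert(0, (float(intercept), float(math.log(-slope))))
    cands = []
    any_success = False
    for x0 in starts:
        res = _simplex_minimize(neg, x0, config)
        if not np.isfinite(res.fun) or res.fun >= _BIG:
            continue
        a, b = math.exp(float(res.x[0])), math.exp(float(res.x[1]))
        cands.append((float(res.fun), a, b, bool(res.success)))
        any_success = any_success or res.success
    if not cands:
        raise RuntimeError(f"fit_baseline: no {kind} start converged")
    loss, a, b, _ = _select_best(cands)
    return FitResult(
        kind=kind,
        params={"a": a, "b": b},
        loss=loss,
        converged=any_success,
        train_range=(float(n[0]), float(n[-1])),
    )


def fit_baseline(
    curve: CorrectnessCurve, kind: str, config: CurveFitConfig | None = None
) -> FitResult:
    """Fit one of the baseline comparators (ENT / EXP / POL / RND) to a curve
    under the same log-weighted loss as the main model."""
    config = config or CurveFitConfig()
    kind = kind.upper()
    if kind == "PYC":
        return fit_pyc_mb(curve, config)
    if kind == "ENT":
        return _fit_ent(curve, config)
    if kind in ("EXP", "POL"):
        return _fit_decay(curve, kind, config)
    if kind == "RND":
        kappa_max = float(curve.kappa[-1])
        return FitResult(
            kind="RND",
            params={"kappa_max": kappa_max, "seed": int(config.seed)},
            loss=float("nan"),
            converged=True,
            train_range=(float(curve.n[0]), float(curve.n[-1])),
        )
    raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")


def forecast(fit: FitResult, n_prime) -> float:
    """Evaluate a fitted model at population size ``n_prime``."""
    n_prime = float(n_prime)
    if n_prime < 1:
        raise ValueError("forecast: n_prime must be >= 1")
    if fit.kind in ("PYC", "ENT"):
        if n_prime == 1.0:
            return 1.0
        return float(expected_correctness(n_prime, py_from_info(fit.info())))
    if fit.kind in ("EXP", "POL"):
        return float(_decay_model(fit.kind, fit.params["a"], fit.params["b"], np.array([n_prime]))[0])
    if fit.kind == "RND":
        rng = np.random.default_rng([fit.params["seed"], int(n_prime) & 0x7FFFFFFF])
        return float(rng.uniform(0.0, fit.params["kappa_max"]))
    raise ValueError(f"unknown model kind {fit.kind!r}")


def training_sizes(n_max: int, t: int = 50) -> np.ndarray:
    """Up to ``t`` integer population sizes evenly spaced in log from 1 to
    ``n_max`` (deduplicated after rounding)."""
    n_max = int(n_max)
    if n_max < 1:
        raise ValueError("training_sizes: n_max must be >= 1")
    grid = np.exp(np.linspace(0.0, math.log(n_max), t))
    return np.unique(np.round(grid).astype(np.int64))


def measure_training_curve(
    counts: AnonymitySetCounts, mu: float, t: int = 50
) -> CorrectnessCurve:
    """Exact expected correctness curve of a gallery, measured at up to ``t``
    log-spaced subsample sizes reaching a fraction ``mu`` of the gallery."""
    if not (0 < mu <= 1):
        raise ValueError("measure_training_curve: mu must be in (0, 1]")
    n_t = int(round(mu * counts.n_records))
    if n_t < 2:
        raise ValueError(f"measure_training_curve: mu*N = {n_t} < 2 records")
    return subsampled_correctness_curve(counts, training_sizes(n_t, t))


def evaluate_extrapolation(
    collections: Sequence[tuple[str, AnonymitySetCounts]],
    fractions: Sequence[float] = (0.01, 0.05, 0.10),
    models: Sequence[str] = MODEL_KINDS,
    seed: int = 0,
    t: int = 50,
    config: CurveFitConfig | None = None,
    keep_errors: bool = False,
):
    """Benchmark extrapolation models on collections with known ground truth.

    For each named collection and sampling fraction ``mu``, the training
    curve is the exact subsampled correctness at up to ``t`` log-spaced sizes
    reaching ``mu * N``; each model is fitted on it and its forecast at the
    full size ``N`` is compared with the empirical correctness ``K/N``.
    Collections whose training endpoint has ``kappa <= 0.01`` or ``>= 0.99``
    are excluded (nothing left to extrapolate).  Returns a DataFrame with one
    row per (model, mu): RMSE, mean bias and the number of collections used;
    with ``keep_errors=True`` also a per-collection error table.
    """
    config = config or CurveFitConfig(seed=seed)
    rows = []
    per_coll = []
    for mu in fractions:
        for kind in models:
            kind = kind.upper()
            errors = []
            for name, counts in collections:
                N = counts.n_records
                truth = empirical_correctness(counts)
                n_t = int(round(mu * N))
                if n_t < 2:
                    continue
                curve = subsampled_correctness_curve(counts, training_sizes(n_t, t))
                kappa_end = float(curve.kappa[-1])
                if not (0.01 < kappa_end < 0.99):
                    continue
                with warnings.catch_warnings():
                    # the n=1 anchor point carries zero log-weight by design
                    warnings.simplefilter("ignore", UserWarning)
                    fit = fit_baseline(curve, kind, config)
                err = forecast(fit, N) - truth
                errors.append(err)
                per_coll.append(
                    {"collection": name, "mu": mu, "model": kind, "error": err, "truth": truth}
                )
            if errors:
                arr = np.asarray(errors)
                rows.append(
                    {
                        "model": kind,
                        "mu": mu,
                        "rmse": float(np.sqrt(np.mean(arr**2))),
                        "bias": float(np.mean(arr)),
                        "n_collections": arr.size,
                    }
                )
    table = pd.DataFrame(rows)
    if keep_errors:
        return table, pd.DataFrame(per_coll)
    return table
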