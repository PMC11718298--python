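"""Pitman-Yor parameterizations and the entropy/tail-complexity bijection.

A Pitman-Yor process ``PY(d, alpha)`` is described either by its natural
parameters -- the discount ``d`` and concentration ``alpha`` -- or by an
information-theoretic pair: the expected Shannon entropy ``h`` of the random
frequency vector it generates and the tail complexity ``gamma``::

    h     = psi0(alpha + 1) - psi0(1 - d)
    gamma = (psi0(1) - psi0(1 - d)) / h

with ``psi0`` the digamma function.  ``gamma = 0`` corresponds to a geometric
tail (the Dirichlet-process case ``d = 0``), ``gamma = 1`` to the heaviest
tail the process supports (``alpha = 0``), and ``gamma < 0`` to finite,
near-uniform supports (the analytically-continued ``d < 0`` regime, used for
forward evaluation only).

``h`` is stored internally in natural-log units (nats); conversion helpers to
and from bits are provided because both conventions are common in the
disclosure-control literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma as _scipy_digamma, polygamma as _polygamma

__all__ = [
    "LN2",
    "PYParams",
    "InfoParams",
    "digamma",
    "inverse_digamma",
    "info_from_py",
    "py_from_info",
    "bits_to_nats",
    "nats_to_bits",
]

LN2 = math.log(2.0)

#: absolute tolerance for special-function evaluation
SPECIAL_TOL = 1e-12
#: absolute tolerance for root finding (inverse digamma)
ROOT_TOL = 1e-10
#: iteration cap for Newton refinement of the inverse digamma
_MAX_NEWTON_ITER = 200

# psi0(1) = -EulerGamma
PSI0_1 = float(_scipy_digamma(1.0))


def bits_to_nats(h_bits: float) -> float:
    """Convert an entropy from bits to natural-log units."""
    return float(h_bits) * LN2


def nats_to_bits(h_nats: float) -> float:
    """Convert an entropy from natural-log units to bits."""
    return float(h_nats) / LN2


def digamma(x):
    """Digamma function ``psi0(x)``.

    Accepts scalars or arrays.  Non-positive integers are poles and raise a
    ``ValueError``; other negative arguments are permitted (needed when the
    discount is analytically continued below zero).
    """
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("digamma: argument must be finite")
    at_pole = (arr <= 0) & (arr == np.floor(arr))
    if np.any(at_pole):
        raise ValueError(f"digamma: pole at non-positive integer argument {arr[at_pole]}")
    out = _scipy_digamma(arr)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def inverse_digamma(y: float) -> float:
    """Inverse of the digamma function restricted to the positive half-line.

    ``psi0`` is strictly increasing on ``(0, inf)``, mapping onto all of R,
    so the inverse is well defined for any finite ``y``.  Uses the standard
    asymptotic initial guess (``exp(y) + 1/2`` for large ``y``, ``-1/(y +
    EulerGamma)`` near the pole) followed by Newton iterations on
    ``psi0(x) - y`` with the trigamma derivative.
    """
    y = float(y)
    if not math.isfinite(y):
        raise ValueError("inverse_digamma: argument must be finite")
    if y >= -2.22:
        x = math.exp(y) + 0.5
    else:
        x = -1.0 / (y - PSI0_1)
    for _ in range(_MAX_NEWTON_ITER):
        f = float(_scipy_digamma(x)) - y
        if abs(f) < ROOT_TOL:
            return x
        step = f / float(_polygamma(1, x))
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0  # damped step: stay on the positive half-line
        x = x_new
    raise ArithmeticError(
        f"inverse_digamma: Newton iteration did not reach |psi0(x)-y| < {ROOT_TOL} "
        f"for y={y!r} (last x={x!r}, residual={f!r})"
    )


@dataclass(frozen=True)
class PYParams:
    """Natural parameters of a Pitman-Yor process.

    Standard regime: ``0 <= d < 1`` and ``alpha > -d`` (with ``alpha > 0``
    when ``d = 0``, the Dirichlet-process case).  The extended regime
    ``d < 0`` is accepted for forward evaluation of the closed-form metrics
    and is flagged by :attr:`extended`; fitting never searches it.
    """

    d: float
    alpha: float

    def __post_init__(self):
        d, alpha = float(self.d), float(self.alpha)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "alpha", alpha)
        if not (math.isfinite(d) and math.isfinite(alpha)):
            raise ValueError("PYParams: d and alpha must be finite")
        if d >= 1.0:
            raise ValueError(f"PYParams: discount d={d} violates d < 1")
        if alpha <= -d:
            raise ValueError(f"PYParams: concentration alpha={alpha} violates alpha > -d (d={d})")
        if d == 0.0 and alpha <= 0.0:
            raise ValueError("PYParams: the Dirichlet-process case d=0 requires alpha > 0")

    @property
    def extended(self) -> bool:
        """True in the analytically-continued regime ``d < 0``."""
        return self.d < 0.0


@dataclass(frozen=True)
class InfoParams:
    """Entropy / tail-complexity parameterization.

    ``h`` is the expected Shannon entropy of the anonymity-set frequencies in
    nats (``h > 0``); ``gamma`` is the tail complexity (``gamma <= 1``, with
    ``gamma in [0, 1]`` in the standard regime and ``gamma < 0`` only in the
    extended finite-support regime).
    """

    h: float
    gamma: float

    def __post_init__(self):
        h, g = float(self.h), float(self.gamma)
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "gamma", g)
        if not (math.isfinite(h) and math.isfinite(g)):
            raise ValueError("InfoParams: h and gamma must be finite")
        if h <= 0:
            raise ValueError(f"InfoParams: entropy h={h} must be positive")
        if g > 1.0:
            raise ValueError(f"InfoParams: tail complexity gamma={g} violates gamma <= 1")

    @classmethod
    def from_bits(cls, h_bits: float, gamma: float) -> "InfoParams":
        """Build from an entropy stated in bits."""
        return cls(bits_to_nats(h_bits), gamma)

    @property
    def h_bits(self) -> float:
        """The entropy in bits."""
        return nats_to_bits(self.h)

    @property
    def extended(self) -> bool:
        return self.gamma < 0.0


def info_from_py(params: PYParams) -> InfoParams:
    """Map natural parameters ``(d, alpha)`` to ``(h, gamma)``.

    ``h = psi0(alpha+1) - psi0(1-d)`` and
    ``gamma = (psi0(1) - psi0(1-d)) / h``.
    """
    d, alpha = params.d, params.alpha
    h = digamma(alpha + 1.0) - digamma(1.0 - d)
    if h <= 0:
        raise ValueError(
            f"info_from_py: expected entropy h={h} is non-positive for (d={d}, alpha={alpha})"
        )
    gamma = (PSI0_1 - digamma(1.0 - d)) / h
    return InfoParams(h, gamma)


def py_from_info(info: InfoParams) -> PYParams:
    """Map ``(h, gamma)`` back to natural parameters ``(d, alpha)``.

    Inverts the digamma relations: with ``u = 1-d`` and ``v = alpha+1``,
    ``u = psi0^{-1}(psi0(1) - h*gamma)`` and
    ``v = psi0^{-1}(psi0(1) + h*(1-gamma))``.  Exact endpoint cases are
    pinned: ``gamma = 0`` gives ``d = 0`` and ``gamma = 1`` gives
    ``alpha = 0``.
    """
    h, gamma = info.h, info.gamma
    if gamma == 0.0:
        d = 0.0
    else:
        u = inverse_digamma(PSI0_1 - h * gamma)
        d = 1.0 - u
    if gamma == 1.0:
        alpha = 0.0
    else:
        v = inverse_digamma(PSI0_1 + h * (1.0 - gamma))
        alpha = v - 1.0
    try:
        return PYParams(d, alpha)
    except ValueError as exc:
        raise ValueError(
            f"py_from_info: (h={h}, gamma={gamma}) maps outside the supported "
            f"Pitman-Yor domain: {exc}"
        ) from exc
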