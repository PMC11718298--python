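"""Synthetic frequency families and galleries (geometric / Poisson / Zipf).

These three classical count families span the entropy / tail-complexity
plane that real quasi-identifier data occupies: geometric tails fit near
``gamma = 0``, low-exponent Zipf laws approach ``gamma = 1``, and Poisson
distributions sit in between with tightly concentrated set sizes.  A corpus
of such collections lets every fitting and extrapolation routine be
exercised end to end with known ground truth and no external data.

Frequency vectors are truncated by *mass tolerance* (discard < ``mass_tol``)
rather than at a fixed support, so heavy tails keep their shape; a hard
``max_support`` cap guards Zipf exponents near 1 whose mass-based truncation
point would be astronomically large (the cap is recorded via the
truncation actually applied and the vector is renormalized).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import poisson as _poisson

from .galleries import AnonymitySetCounts
from .metrics import FrequencyVector

__all__ = ["ScenarioConfig", "make_frequencies", "sample_gallery", "make_corpus"]

FAMILIES = ("geometric", "poisson", "zipf")

#: default parameter ranges for corpus generation (drawn log-uniformly)
DEFAULT_RANGES = {
    "geometric": (0.001, 0.5),  # success probability p
    "poisson": (1.0, 1000.0),  # rate lambda
    "zipf": (1.01, 3.0),  # exponent s
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One synthetic collection: a frequency family, its parameter, the
    gallery size and the seed that reproduces it."""

    family: str
    param: float
    n: int = 100_000
    seed: int = 0
    mass_tol: float = 1e-9
    max_support: int = 1_000_000

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.family == "geometric" and not (0.0 < self.param < 1.0):
            raise ValueError(f"geometric success probability must be in (0,1), got {self.param}")
        if self.family == "poisson" and self.param <= 0:
            raise ValueError(f"poisson rate must be positive, got {self.param}")
        if self.family == "zipf" and self.param <= 1.0:
            raise ValueError(f"zipf exponent must exceed 1, got {self.param}")
        if self.n < 1:
            raise ValueError("gallery size n must be >= 1")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "param": self.param,
            "n": self.n,
            "seed": self.seed,
            "mass_tol": self.mass_tol,
            "max_support": self.max_support,
        }


def make_frequencies(config: ScenarioConfig) -> FrequencyVector:
    """Build the (truncated, renormalized) frequency vector of a family.

    geometric: ``pi_i ∝ (1-p)^(i-1) p`` over ``i >= 1``;
    poisson:   ``pi_i ∝ lambda^i e^-lambda / i!`` shifted to 1-based support;
    zipf:      ``pi_i ∝ i^-s``.
    """
    if config.family == "geometric":
        p = config.param
        # support so that discarded mass (1-p)^M < mass_tol
        M = min(config.max_support, max(1, math.ceil(math.log(config.mass_tol) / math.log1p(-p))))
        i = np.arange(M, dtype=float)
        w = np.exp(i * math.log1p(-p)) * p
    elif config.family == "poisson":
        lam = config.param
        lo = int(_poisson.ppf(config.mass_tol / 2, lam))
        hi = int(_poisson.isf(config.mass_tol / 2, lam))
        hi = min(hi, lo + config.max_support - 1)
        support = np.arange(lo, hi + 1)
        w = _poisson.pmf(support, lam)
    else:  # zipf
        s = config.param
        # tail mass beyond M is ~ M^(1-s)/(s-1); cap at max_support
        if s > 1.05:
            M = math.ceil(((s - 1.0) * config.mass_tol) ** (1.0 / (1.0 - s)))
        else:
            M = config.max_support
        M = int(min(max(M, 1), config.max_support))
        i = np.arange(1, M + 1, dtype=float)
        w = i ** (-s)
    w = w[w > 0]
    if w.size == 0:
        raise ValueError(f"make_frequencies: degenerate support for {config}")
    return FrequencyVector(w / w.sum())


def sample_gallery(freqs: FrequencyVector, n: int, seed) -> AnonymitySetCounts:
    """Draw ``n`` i.i.d. records from explicit set frequencies and return the
    occupancy multiset of anonymity-set sizes."""
    n = int(n)
    if n < 1:
        raise ValueError("sample_gallery: n must be >= 1")
    rng = np.random.default_rng(seed)
    occ = rng.multinomial(n, freqs.p)
    return AnonymitySetCounts.from_sizes(occ[occ > 0])


@dataclass(frozen=True)
class CorpusCollection:
    """One generated collection and the configuration that produced it."""

    config: ScenarioConfig
    counts: AnonymitySetCounts


def make_corpus(
    n_collections: int,
    families: Sequence[str] = FAMILIES,
    ranges: dict | None = None,
    n: int = 100_000,
    master_seed: int = 0,
) -> list[CorpusCollection]:
    """Generate a corpus of synthetic collections with per-collection seeds
    derived deterministically from ``master_seed``.

    Family parameters are drawn log-uniformly within ``ranges`` (defaults in
    :data:`DEFAULT_RANGES`); collections cycle through ``families``.  The same
    ``master_seed`` always yields the identical corpus.
    """
    if n_collections < 0:
        raise ValueError("n_collections must be >= 0")
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    seed_seq = np.random.SeedSequence(master_seed)
    children = seed_seq.spawn(max(n_collections, 1))
    out: list[CorpusCollection] = []
    for idx in range(n_collections):
        family = families[idx % len(families)]
        child = children[idx]
        rng = np.random.default_rng(child)
        lo, hi = ranges[family]
        param = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        draw_seed = int(rng.integers(2**31))
        config = ScenarioConfig(family=family, param=param, n=n, seed=draw_seed)
        freqs = make_frequencies(config)
        counts = sample_gallery(freqs, n, seed=draw_seed)
        out.append(CorpusCollection(config=config, counts=counts))
    return out
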