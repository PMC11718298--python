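"""Anonymity-set accounting for tabular galleries.

A gallery is a table of records; an attacker matching on a chosen set of
quasi-identifier columns partitions it into *anonymity sets* — equivalence
classes of records agreeing on all quasi-identifier values.  The multiset of
anonymity-set sizes (:class:`AnonymitySetCounts`) is a sufficient statistic
for every empirical privacy metric here:

- correctness ``kappa = K/N`` (number of sets over number of records, equal
  to the mean of ``1/|set|`` over records),
- uniqueness ``Xi = m_1/N`` (fraction of records in singleton sets),
- k-anonymity violations ``V_k`` (fraction of records in sets smaller than k),

plus exact expected curves of each metric under uniform subsampling without
replacement, computed from hypergeometric inclusion probabilities (so the
"empirical dots" of a correctness-versus-population-size plot need no Monte
Carlo, though a seeded Monte Carlo mode is provided as an oracle).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "AnonymitySetCounts",
    "CorrectnessCurve",
    "partition_gallery",
    "empirical_correctness",
    "empirical_uniqueness",
    "empirical_kanon_violations",
    "subsampled_correctness_curve",
    "subsampled_uniqueness_curve",
    "subsampled_kanon_curve",
]


@dataclass(frozen=True)
class AnonymitySetCounts:
    """Multiset of anonymity-set sizes: ``{size: multiplicity}``.

    ``n_records`` is ``N = sum(s * m_s)`` and ``n_sets`` is ``K = sum(m_s)``.
    """

    sizes: Mapping[int, int]

    def __post_init__(self):
        clean = {}
        for s, m in dict(self.sizes).items():
            s, m = int(s), int(m)
            if s < 1 or m < 1:
                raise ValueError(f"AnonymitySetCounts: invalid entry size={s}, count={m}")
            clean[s] = clean.get(s, 0) + m
        if not clean:
            raise ValueError("AnonymitySetCounts: empty partition")
        object.__setattr__(self, "sizes", dict(sorted(clean.items())))

    @classmethod
    def from_sizes(cls, sizes: Iterable[int]) -> "AnonymitySetCounts":
        """Build from a flat list of set sizes (one entry per set)."""
        vals, counts = np.unique(np.asarray(list(sizes), dtype=np.int64), return_counts=True)
        return cls(dict(zip(vals.tolist(), counts.tolist())))

    @property
    def n_records(self) -> int:
        return int(sum(s * m for s, m in self.sizes.items()))

    @property
    def n_sets(self) -> int:
        return int(sum(self.sizes.values()))

    def size_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Distinct sizes and their multiplicities, as aligned arrays."""
        s = np.array(sorted(self.sizes), dtype=np.int64)
        m = np.array([self.sizes[int(v)] for v in s], dtype=np.int64)
        return s, m

    def expand_sizes(self) -> np.ndarray:
        """One entry per set (size repeated by multiplicity)."""
        s, m = self.size_arrays()
        return np.repeat(s, m)


@dataclass(frozen=True)
class CorrectnessCurve:
    """Ordered identification-accuracy measurements ``(n_i, kappa_i)``.

    ``n`` must be strictly increasing and ``kappa`` must lie in [0, 1].
    ``reps`` optionally records how many replicates each point averages.
    """

    n: np.ndarray
    kappa: np.ndarray
    reps: np.ndarray | None = None

    def __post_init__(self):
        n = np.asarray(self.n, dtype=float).ravel()
        kappa = np.asarray(self.kappa, dtype=float).ravel()
        if n.size != kappa.size or n.size == 0:
            raise ValueError("CorrectnessCurve: n and kappa must be non-empty and aligned")
        if np.any(np.diff(n) <= 0):
            raise ValueError("CorrectnessCurve: n must be strictly increasing")
        if np.any(n < 1):
            raise ValueError("CorrectnessCurve: population sizes must be >= 1")
        if np.any((kappa < 0) | (kappa > 1)):
            raise ValueError("CorrectnessCurve: kappa values must lie in [0, 1]")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "kappa", kappa)
        if self.reps is not None:
            reps = np.asarray(self.reps, dtype=np.int64).ravel()
            if reps.size != n.size:
                raise ValueError("CorrectnessCurve: reps must align with n")
            object.__setattr__(self, "reps", reps)

    def __len__(self):
        return self.n.size


def partition_gallery(
    table: pd.DataFrame,
    qid_columns: Sequence[str],
    bins: Mapping[str, int | Sequence[float]] | None = None,
) -> AnonymitySetCounts:
    """Partition a gallery into anonymity sets by exact quasi-identifier match.

    Records are grouped by equality on the tuple of values in ``qid_columns``;
    missing values form their own level rather than being dropped (dropping
    would silently change the gallery size).  Float-valued columns are
    refused unless a discretization is supplied in ``bins`` (``{column:
    n_bins or bin edges}``), because exact matching is only defined on
    discrete values.
    """
    if not list(qid_columns):
        raise ValueError("partition_gallery: qid_columns must be non-empty")
    missing = [c for c in qid_columns if c not in table.columns]
    if missing:
        raise KeyError(
            f"partition_gallery: unknown column(s) {missing}; available: {list(table.columns)}"
        )
    if len(table) < 1:
        raise ValueError("partition_gallery: gallery must contain at least one record")
    bins = dict(bins or {})
    work = {}
    for col in qid_columns:
        series = table[col]
        if pd.api.types.is_float_dtype(series):
            if col not in bins:
                raise ValueError(
                    f"partition_gallery: column {col!r} is continuous; supply a binning "
                    "via bins={column: n_bins or edges} to discretize it first"
                )
            work[col] = pd.cut(series, bins[col])
        else:
            work[col] = series
    grouped = pd.DataFrame(work).groupby(list(qid_columns), dropna=False, observed=True)
    return AnonymitySetCounts.from_sizes(grouped.size().to_numpy())


def empirical_correctness(counts: AnonymitySetCounts) -> float:
    """Per-record correctness of exact matching: ``K/N``.

    Algebraically identical to the mean of ``1/|set|`` over records (each set
    contributes ``s * (1/s) = 1``).
    """
    return counts.n_sets / counts.n_records


def empirical_uniqueness(counts: AnonymitySetCounts) -> float:
    """Fraction of records in singleton anonymity sets."""
    return counts.sizes.get(1, 0) / counts.n_records


def empirical_kanon_violations(counts: AnonymitySetCounts, k: int) -> float:
    """Fraction of records whose anonymity set holds fewer than ``k`` records."""
    k = int(k)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return sum(s * m for s, m in counts.sizes.items() if s < k) / counts.n_records


def _check_sizes(counts: AnonymitySetCounts, sample_sizes) -> np.ndarray:
    m = np.asarray(sample_sizes, dtype=np.int64).ravel()
    if np.any(m < 1) or np.any(m > counts.n_records):
        raise ValueError(
            f"subsample sizes must lie in [1, N={counts.n_records}], got {sample_sizes!r}"
        )
    return m


def _montecarlo_curve(counts, sample_sizes, reps, seed, per_sample_stat):
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(counts.n_sets), counts.expand_sizes())
    n_rec = counts.n_records
    out = np.empty(len(sample_sizes), dtype=float)
    for i, m in enumerate(sample_sizes):
        acc = 0.0
        for _ in range(reps):
            take = rng.choice(n_rec, size=int(m), replace=False)
            sub_sizes = np.bincount(labels[take])
            acc += per_sample_stat(sub_sizes[sub_sizes > 0], int(m))
        out[i] = acc / reps
    return out


def subsampled_correctness_curve(
    counts: AnonymitySetCounts,
    sample_sizes: Sequence[int],
    method: str = "exact",
    reps: int = 200,
    seed: int | None = None,
) -> CorrectnessCurve:
    """Expected correctness when ``m`` records are drawn uniformly without
    replacement from the gallery, for each ``m`` in ``sample_sizes``.

    Exact mode sums set-occupancy probabilities: ``E[kappa(m)] = (1/m) *
    sum_sets P[set intersects the sample]`` with hypergeometric inclusion
    probabilities.  Monte-Carlo mode averages ``K_sub/m`` over ``reps``
    seeded subsamples.  At ``m = N`` both modes equal ``K/N``.
    """
    msizes = _check_sizes(counts, sample_sizes)
    s, mult = counts.size_arrays()
    N = counts.n_records
    if method == "exact":
        vals = np.empty(msizes.size, dtype=float)
        for i, m in enumerate(msizes):
            occupied = float(np.sum(mult * hypergeom.sf(0, N, s, int(m))))
            vals[i] = occupied / m
    elif method == "montecarlo":
        if reps < 1:
            raise ValueError("montecarlo mode requires reps >= 1")
        vals = _montecarlo_curve(
            counts, msizes, reps, seed, lambda sub, m: sub.size / m
        )
    else:
        raise ValueError(f"unknown method {method!r}; use 'exact' or 'montecarlo'")
    order = np.argsort(msizes)
    return CorrectnessCurve(msizes[order], np.clip(vals[order], 0.0, 1.0))


def subsampled_uniqueness_curve(
    counts: AnonymitySetCounts,
    sample_sizes: Sequence[int],
    method: str = "exact",
    reps: int = 200,
    seed: int | None = None,
) -> CorrectnessCurve:
    """Expected fraction of sampled records that are unique within the sample.

    Exact mode: a sampled record from a set of size ``s`` is unique in the
    sample iff none of its ``s - 1`` set-mates is among the other ``m - 1``
    draws, a hypergeometric zero-count event.
    """
    msizes = _check_sizes(counts, sample_sizes)
    s, mult = counts.size_arrays()
    N = counts.n_records
    if method == "exact":
        vals = np.empty(msizes.size, dtype=float)
        for i, m in enumerate(msizes):
            vals[i] = float(
                np.sum(mult * s * hypergeom.pmf(0, N - 1, s - 1, int(m) - 1)) / N
            )
    elif method == "montecarlo":
        vals = _montecarlo_curve(
            counts, msizes, reps, seed, lambda sub, m: np.sum(sub == 1) / m
        )
    else:
        raise ValueError(f"unknown method {method!r}; use 'exact' or 'montecarlo'")
    order = np.argsort(msizes)
    return CorrectnessCurve(msizes[order], np.clip(vals[order], 0.0, 1.0))


def subsampled_kanon_curve(
    counts: AnonymitySetCounts,
    sample_sizes: Sequence[int],
    k: int,
    method: str = "exact",
    reps: int = 200,
    seed: int | None = None,
) -> CorrectnessCurve:
    """Expected fraction of sampled records violating k-anonymity within the
    sample (their within-sample set holds fewer than ``k`` records)."""
    k = int(k)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    msizes = _check_sizes(counts, sample_sizes)
    s, mult = counts.size_arrays()
    N = counts.n_records
    if method == "exact":
        vals = np.empty(msizes.size, dtype=float)
        for i, m in enumerate(msizes):
            if k == 1:
                vals[i] = 0.0
            else:
                # companions of a sampled record ~ Hypergeom(N-1, s-1, m-1)
                cdf = hypergeom.cdf(k - 2, N - 1, s - 1, int(m) - 1)
                vals[i] = float(np.sum(mult * s * cdf) / N)
    elif method == "montecarlo":
        vals = _montecarlo_curve(
            counts, msizes, reps, seed, lambda sub, m: np.sum(sub[sub < k]) / m
        )
    else:
        raise ValueError(f"unknown method {method!r}; use 'exact' or 'montecarlo'")
    order = np.argsort(msizes)
    return CorrectnessCurve(msizes[order], np.clip(vals[order], 0.0, 1.0))
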