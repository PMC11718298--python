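import itertools

import numpy as np
import pytest

from reidscale import AnonymitySetCounts, FrequencyVector


@pytest.fixture(scope="session")
def small_counts():
    """A four-record gallery with one pair and two singletons."""
    return AnonymitySetCounts({2: 1, 1: 2})


@pytest.fixture(scope="session")
def pair_counts():
    """Two anonymity sets of two records each."""
    return AnonymitySetCounts({2: 2})


def enumerate_outcomes(freqs: FrequencyVector, n: int):
    """Yield (probability, occupancy vector) over all M^n assignments of n
    records to the M anonymity sets -- the brute-force oracle for every
    finite-distribution metric."""
    p = freqs.p
    M = p.size
    for assign in itertools.product(range(M), repeat=n):
        prob = float(np.prod([p[i] for i in assign]))
        occ = np.bincount(np.asarray(assign), minlength=M)
        yield prob, occ


def brute_force_metric(freqs: FrequencyVector, n: int, stat):
    """Expectation of ``stat(occupancy)`` under iid sampling, by enumeration."""
    return sum(prob * stat(occ) for prob, occ in enumerate_outcomes(freqs, n))
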