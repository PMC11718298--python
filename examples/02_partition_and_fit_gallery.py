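"""Partition a tabular gallery, fit the Pitman-Yor model, check the fit.

A small demographic-style gallery is simulated, partitioned into anonymity
sets on its quasi-identifier columns, and the (h, gamma) parameters are
fitted to the anonymity-set size multiset by maximum a-posteriori
estimation on the exchangeable-partition likelihood.
"""

import numpy as np
import pandas as pd

from reidscale import (
    PYParams,
    empirical_correctness,
    empirical_kanon_violations,
    empirical_uniqueness,
    fit_map,
    kl_ranksize,
    partition_gallery,
    py_from_info,
)

rng = np.random.default_rng(0)
n = 20_000
gallery = pd.DataFrame(
    {
        "zip3": rng.zipf(1.6, n) % 900,  # skewed region codes
        "sex": rng.choice(["F", "M"], n),
        "birth_year": rng.integers(1930, 2005, n),
    }
)

counts = partition_gallery(gallery, ["zip3", "sex", "birth_year"])
print(f"{counts.n_records} records fall into {counts.n_sets} anonymity sets")
print(f"  correctness  kappa = {empirical_correctness(counts):.3f}")
print(f"  uniqueness   Xi    = {empirical_uniqueness(counts):.3f}")
print(f"  5-anon violations  = {empirical_kanon_violations(counts, 5):.3f}")

info, diag = fit_map(counts)
fitted = py_from_info(info)
print(f"\nfitted entropy h = {info.h_bits:.2f} bits, tail complexity gamma = {info.gamma:.3f}")
print(f"  (d = {fitted.d:.3f}, alpha = {fitted.alpha:.1f}; converged = {diag.converged})")

kl = kl_ranksize(counts, PYParams(diag.d, diag.alpha), reps=30, seed=1)
print(f"  rank-size KL divergence of fit vs data: {kl:.2f} bits (small = good fit)")
print(
    "\nReading: the fitted (h, gamma) summarize how identifiable these\n"
    "quasi-identifiers are, and the KL diagnostic checks the two-parameter\n"
    "model reproduces the observed anonymity-set size distribution."
)
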