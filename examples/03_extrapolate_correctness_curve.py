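"""Measurement-based extrapolation: forecast a 10x larger population.

A synthetic Zipf gallery plays the role of a real identification study.
The correctness is "measured" (exactly, by hypergeometric subsampling) only
up to 10% of the gallery; the scaling law and two curve-fitting baselines
are fitted on those measurements and asked to forecast the full-population
correctness, which here we can check against the truth.
"""

import warnings

from reidscale import (
    ScenarioConfig,
    empirical_correctness,
    fit_baseline,
    fit_pyc_mb,
    forecast,
    make_frequencies,
    measure_training_curve,
    sample_gallery,
)

counts = sample_gallery(make_frequencies(ScenarioConfig("zipf", 1.4)), 100_000, seed=3)
truth = empirical_correctness(counts)

curve = measure_training_curve(counts, mu=0.10)  # 50 log-spaced points to 10% of N
print(f"training on {len(curve)} measurement points up to n = {int(curve.n[-1])}")

# the n=1 anchor point carries zero log-weight; silence the routine notice
with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    pyc = fit_pyc_mb(curve)
    baselines = {kind: fit_baseline(curve, kind) for kind in ("EXP", "POL")}
print(
    f"fitted scaling law: h = {pyc.params['h']:.2f} nats, gamma = {pyc.params['gamma']:.3f}"
)
print(f"\nforecast of kappa at N = {counts.n_records}:")
print(f"  scaling law (PYC-MB): {forecast(pyc, counts.n_records):.4f}")
for kind, fit in baselines.items():
    print(f"  {kind} baseline:         {forecast(fit, counts.n_records):.4f}")
print(f"  empirical truth:      {truth:.4f}")
print(
    "\nReading: the two-parameter scaling law lands within a few tenths of a\n"
    "percentage point of the truth from a 10% sample, while exponential and\n"
    "power-law fits over- or under-shoot."
)
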