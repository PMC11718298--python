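"""Closed-form forecasts of identification accuracy at world scale.

The expected correctness (rank-1 identification rate) of an exact-matching
attack depends on just two numbers: the entropy h of the auxiliary
information and the tail complexity gamma of its distribution.  This script
evaluates the closed form at a few classic operating points.
"""

from reidscale import InfoParams, expected_correctness, expected_uniqueness, py_from_info

WORLD = 7.53e9

print("entropy 40 bits, world population of 7.53B people:")
for gamma, label in [(0.0, "geometric tail (gamma=0)"), (1.0, "heavy tail  (gamma=1)")]:
    params = py_from_info(InfoParams.from_bits(40.0, gamma))
    kappa = expected_correctness(WORLD, params)
    print(f"  {label}: correctness = {kappa:.1%}")

# fitted browser-fingerprint parameters over the global device population
params = py_from_info(InfoParams(41.54, 0.68))
kappa = expected_correctness(4e9, params)
xi = expected_uniqueness(4e9, params)
print("\nbrowser fingerprints (h=41.54 nats, gamma=0.68), 4B devices:")
print(f"  correctness = {kappa:.1%}   uniqueness = {xi:.1%}")

print(
    "\nReading: with the same 40 bits of entropy, tail shape alone moves the\n"
    "identifiable fraction of the world from ~99% down to ~45%; heavy-tailed\n"
    "high-entropy fingerprints keep ~3 in 4 devices identifiable at 4B scale."
)
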