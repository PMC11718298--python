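# reidscale

Forecasting how identification and re-identification accuracy scales with
population size.

Identification techniques — exact matching on quasi-identifiers, sparse
matching on set-valued traces, machine-learning ("robust") matching on faces,
text or mobility — are usually benchmarked on small galleries. Accuracy
always decays as the gallery grows, but the *shape* of that decay varies
enormously between techniques, so small-scale numbers say little about
deployment at the scale of a country or the Internet. `reidscale` gives
privacy researchers, biometrics evaluators and disclosure-control
practitioners a principled two-parameter scaling law for that decay, plus the
tooling to fit it from either raw tabular data or published accuracy
measurements.

## The model

A gallery of *n* records partitions into *anonymity sets* — equivalence
classes of records sharing the same auxiliary information φ(x). For exact
matching, the correctness (rank-1 identification rate) is

    κ = (1/n) Σ_l |S(x_l)|⁻¹  =  (number of anonymity sets) / n.

Modelling the random anonymity-set frequencies π with a two-parameter
Pitman-Yor prior PY(d, α) and reparameterizing by the expected Shannon
entropy *h* and the tail complexity *γ*,

    h = ψ₀(α+1) − ψ₀(1−d),      γ = (ψ₀(1) − ψ₀(1−d)) / h,

yields closed forms for the expected correctness κ(n), the population
uniqueness Ξ(n) (fraction of records unique in the gallery) and the fraction
of k-anonymity violations V_k(n), valid to populations of billions. γ = 0 is
a geometric tail (Dirichlet-process case), γ = 1 the heaviest tail the
process supports, γ < 0 a finite near-uniform support.

Two fitting routes are provided:

- **from frequency data** — MAP estimation of (h, γ) from the anonymity-set
  size multiset via the exchangeable partition probability function (EPPF);
- **from measurements (PYC-MB)** — given t ≥ 2 observed points (nᵢ, κ̂ᵢ) of
  any identification technique's accuracy, minimize the log-weighted loss
  R(h, γ) = Σᵢ log nᵢ · [κ̂(nᵢ) − E[κ(nᵢ)|h, γ]]² and forecast κ at any
  larger n′. Entropy-only (ENT), exponential-decay (EXP), power-law (POL)
  and random (RND) baselines are fitted under the identical loss for
  comparison.

## Worked example

```python
from reidscale import InfoParams, expected_correctness, py_from_info

for gamma in (0.0, 1.0):
    params = py_from_info(InfoParams.from_bits(40.0, gamma))
    print(f"gamma={gamma}: {expected_correctness(7.53e9, params):.1%}")
```

prints

```
gamma=0.0: 99.4%
gamma=1.0: 44.8%
```

— at a fixed 40 bits of entropy, tail shape alone decides whether nearly the
whole world population is identifiable (geometric tail) or fewer than half
(heavy tail). The same closed form with the fitted browser-fingerprint
parameters (h = 41.54 nats, γ = 0.68) gives 74.4% expected correctness
across 4 billion Internet devices.

Extrapolation from measurements (`examples/04_benchmark_baselines.py`, 15
synthetic collections of 50 000 records, models trained on 10% samples):

```
model     mu   rmse    bias  n_collections
  PYC 0.1000 0.0080  0.0040              8
  ENT 0.1000 0.0917 -0.0402              8
  EXP 0.1000 0.1080 -0.0539              8
  POL 0.1000 0.0302  0.0219              8
  RND 0.1000 0.0313  0.0128              8
```

The scaling law forecasts the full-population correctness with 0.8
percentage points RMSE, an order of magnitude below the entropy-only and
exponential baselines.

Each script in `examples/` is a short, self-contained walkthrough of one
capability (closed-form forecasts, gallery partitioning and fitting,
curve extrapolation, baseline benchmarking). A thin CLI mirrors the
pipeline: `reidscale partition | fit-frequencies | fit-curve | forecast |
simulate | evaluate`.

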