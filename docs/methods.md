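# Methods

## Model

Records are drawn i.i.d. from a discrete distribution over auxiliary
information; the gallery of *n* records partitions into anonymity sets with
random frequencies π = {π_i}. Conditional on π, the exact expectations of
the three privacy metrics are

- correctness κ(n) = (1/n) Σ_i [1 − (1 − π_i)ⁿ] — the expected number of
  occupied anonymity sets over n (each occupied set contributes exactly one
  correct match on average under exact matching);
- uniqueness Ξ(n) = Σ_i π_i (1 − π_i)ⁿ⁻¹;
- k-anonymity violations V_k(n) = Σ_i π_i · P[Binomial(n−1, π_i) ≤ k−2],
  the per-record probability that fewer than k records share its set
  (equivalently the regularized incomplete beta I_{1−π}(n−k+1, k−1)).

Placing a Pitman-Yor prior π ~ PY(d, α) — discount d ∈ [0, 1), concentration
α > −d — and integrating gives gamma-function closed forms, e.g.

    E[κ(n)|d,α] = (1/(n d)) [ Γ(1+α) Γ(n+d+α) / (Γ(d+α) Γ(n+α)) − α ],
    E[Ξ(n)|d,α] = Γ(α+1) Γ(n+d+α−1) / (Γ(d+α) Γ(n+α)),

and, for V_k, the finite occupancy sum

    E[V_k(n)] = Σ_{j=1}^{k−1} (j/n) C(n,j) · Γ(1+α)/(Γ(1−d)Γ(α+d)) · B(j−d, n−j+α+d),

obtained from the mean intensity of the process; it is an exact algebraic
rewriting of the generalized hypergeometric (₃F₂) expression of the same
quantity and reduces to E[Ξ] at k = 2. We prefer it because it needs only
log-gamma evaluations and has no special-function convergence edge cases;
tests cross-check it against a high-precision ₃F₂ evaluation and against
seating-process simulation.

The prior is reparameterized by the expected Shannon entropy h (nats) and
the tail complexity γ:

    h = ψ₀(α+1) − ψ₀(1−d),   γ = (ψ₀(1) − ψ₀(1−d)) / h,

a bijection inverted with a Newton-refined inverse digamma (tolerance 1e-10).
γ = 0 ⇔ d = 0 (geometric tail), γ = 1 ⇔ α = 0 (heaviest tail). The
analytically-continued regime d < 0 (γ < 0, finite near-uniform supports) is
supported for forward evaluation of the closed forms only and is flagged;
fitting never searches it, because real anonymity-set data in this domain is
fitted well inside d ∈ [0, 1) and the continuation is only needed to reason
about finite uniform scenarios.

### Units

All internal entropies are in natural-log units, where the digamma
identities are exact; public interfaces accept and report bits via ln 2
conversion with an explicit units flag, since both conventions circulate in
the disclosure-control literature. The package treats quoted entropies of
round numbers ("40 bits") as bits and fitted decimal values carried through
its own pipelines as nats; callers must check which convention a number they
import was stated in.

## Numerical choices

- All gamma-ratio forms are evaluated in log-gamma space. Above argument
  1e4, log-gamma and digamma *differences* switch to joint asymptotic series
  (through the z⁻² term) because direct subtraction of nearly equal
  log-gammas loses every significant digit when α is huge (high entropy at
  low γ maps to α ~ 1e30). Verified to ≤ 1e-11 relative error against a
  150-digit arbitrary-precision oracle across regimes up to n = 7.53e9.
- E[κ] uses the expm1 form α·expm1(Δ)/(n d) so that κ → 1 is represented
  accurately when the gamma ratio and α nearly cancel.
- The d → 0 Dirichlet-process limits, (α/n)(ψ₀(α+n) − ψ₀(α)) and
  α/(n+α−1), are used analytically below |d| < 1e-8; no ε-perturbation, which
  would be destroyed by the 1/(n d) factor.
- Frequency-vector forms use log1p/expm1 throughout and tolerate π_i = 1.

## Empirical metrics and subsampled curves

Gallery partitioning groups records by exact equality on the chosen
quasi-identifier tuple; missing values form their own level (dropping rows
would silently change n), and float columns are refused unless an explicit
binning is supplied, because exact matching is defined on discrete equality.

Correctness at smaller population sizes is measured by uniform subsampling
*without replacement* from the finite gallery. The default is the exact
hypergeometric expectation (occupied-set inclusion probabilities), which is
deterministic and replicate-free; a seeded Monte-Carlo mode exists and is
used as its oracle in tests. The same construction gives exact subsampled
uniqueness and k-anonymity-violation curves via the hypergeometric law of a
record's within-sample set size.

## Fitting from frequency data

The anonymity-set size multiset is a partition of n, so its likelihood under
PY(d, α) is the exchangeable partition probability function

    log P = Σ_{i=1}^{K−1} log(α + i d) − [lnΓ(α+n) − lnΓ(α+1)]
          + Σ_sets [lnΓ(s − d) − lnΓ(1 − d)].

MAP estimation maximizes this plus a configurable log-prior over
(d, log α) by Nelder-Mead simplex search from five deterministic starts on a
coarse lattice (objective tolerance 1e-8), then transforms to (h, γ). The
default prior is flat on d ∈ [0, 0.999], log α ∈ [−6, 30] — bounded maximum
likelihood; a weak informative prior can be supplied as a callable but none
is imposed. Degenerate inputs (all singletons, a single set) push the
optimum to a bound and are flagged non-identifiable rather than rejected.
Fits are invariant to how the multiset is represented and deterministic
given the configuration.

Two samplers serve as oracles and power the posterior-predictive
diagnostics: the sequential Chinese-restaurant construction (exact O(1)
expected work per record via uniform-record proposal with rejection) and
stick breaking V_i ~ Beta(1−d, α+i·d), truncated by tail mass with
renormalization and a flagged atom cap. Goodness of fit is summarized by the
KL divergence (bits) between the empirical rank-size distribution of set
sizes and the mean simulated predictive rank-size distribution; +inf with no
support overlap at observed ranks.

## Fitting from correctness measurements

Given measurements (nᵢ, κ̂ᵢ), (h, γ) minimizes R(h, γ) = Σ log nᵢ ·
(κ̂ᵢ − E[κ(nᵢ)|h,γ])². The log weight trusts larger galleries, whose
accuracy estimates average more trials. Points at n = 1 carry zero weight
(and κ(1) ≡ 1) and are skipped with a warning. Search: Nelder-Mead over the
box h ∈ [1e-3, 120] nats, γ ∈ [0, 1], from a 4×4 multi-start lattice plus
the entropy-only optimum as an extra start — the latter guarantees the
nested-model property loss(PYC) ≤ loss(ENT) holds for the returned fits, not
just in theory. Equal-loss optima are tie-broken toward smallest h, then
smallest γ, for deterministic output. An identically-1 curve is degenerate
(any large h interpolates); it returns the upper entropy bound, flagged.

Baselines are fitted under the identical loss for comparability: ENT is the
γ = 0 slice (one parameter); EXP is κ(n) = min(1, a·e^{−bn}) and POL is
κ(n) = min(1, a·n^{−b}), both searched in (log a, log b) with a log-linear
regression seed; RND forecasts a seeded uniform draw on [0, κ̂(n_t)]
(a correctness is a probability, so the draw is bounded by the last
training value). EXP and POL are plain two-parameter decay laws — the
standard ad-hoc extrapolation choices in this literature — clipped to [0, 1].

The evaluation harness builds, for each collection and sampling fraction μ,
a training curve of up to t = 50 points at n = round(exp(linspace(0,
ln(μN), 50))), deduplicated (fewer points are accepted as-is, as happens
with published measurement curves); fits every model; forecasts at the full
size N; and aggregates RMSE and mean bias per (model, μ). Collections whose
training endpoint has κ ≤ 0.01 or ≥ 0.99 are excluded — there is nothing
left to extrapolate at the top and no signal at the bottom. External
measurement curves enter the same pipeline as CSV (n, kappa) files.

## Synthetic corpus

The generator emulates galleries whose anonymity-set frequencies follow
geometric (success probability p ∈ [0.001, 0.5]), Poisson (rate λ ∈ [1,
1000]) or Zipf (exponent s ∈ [1.01, 3]) laws, parameters drawn log-uniformly,
n = 1e5 records per collection by default, per-collection seeds spawned
deterministically from a master seed. These ranges were chosen once to span
the (h, γ) plane — geometric tails fit near γ = 0, low-exponent Zipf near
γ = 1, Poisson in between — which is exactly the variety the fitting and
extrapolation routines must handle. Frequency vectors are truncated by mass
tolerance (default discarded mass < 1e-9) rather than fixed support so heavy
tails keep their shape; a hard cap of 1e6 atoms bounds Zipf exponents near 1,
whose mass-based truncation point is astronomically large — for those the
truncated law is itself the ground truth the pipeline is tested against.

What the synthetic corpus does *not* emulate: correlated quasi-identifier
columns, attribute-subset sampling from real microdata, temporal drift, or
measurement noise in published accuracy scores. Passing tests therefore
demonstrate correctness of the estimators and the forecasting machinery
under the i.i.d. discrete model, not robustness to real-data deviations from
it; fitting real corpora remains the user's validation burden.

## Problem sizes used in the test suite

Simulation-backed checks run at gallery sizes 2 000 – 100 000 with 300–500
replicates, parameter-recovery at n = 1e5 over 20 seeds, and the benchmark
ordering on 50 synthetic collections of 1e5 records at μ = 10% — sizes at
which Monte-Carlo error bars are tight enough for 3-standard-error
equivalence tests while the whole suite stays desk-scale.

## Known limitations

- Point estimates only: no posterior distributions over (d, α) and no
  confidence intervals on forecasts.
- Per-record (individual) risk is out of scope; all metrics are population
  averages, and a low average correctness does not certify that no record is
  identifiable.
- The EPPF route assumes exchangeability of anonymity sets; ordered or
  hierarchically grouped galleries are not modelled.
- Extrapolation quality for sparse/robust matching rests on the empirical
  adequacy of the two-parameter decay family, not on a theoretical
  guarantee; the model is exact only for fixed discrete auxiliary
  information.
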