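# Methods

## Scope and model

`circart` implements six two-sample tests for circular observations and a
Monte-Carlo framework for measuring their operating characteristics. All
internal angle arithmetic is in radians on the half-open interval [0, 2π)
(exact multiples of 2π wrap to 0); degrees exist only at the I/O boundary,
where they are the default input unit because field data are usually
compass bearings.

### The angular randomisation test

The ART statistic is the sum of geodesic distances over all cross-sample
pairs, G = Σᵢ Σⱼ D(φᵢ, ψⱼ) with D(a, b) = min(Δ, 2π − Δ), Δ = |a − b| mod
2π. D is computed from the absolute difference so that it is exactly
symmetric in floating point; it is invariant under common rotation and
reflection, which makes every statistic here origin-free. No scalar
multiplier is applied to G — it would cancel in permutation inference.

Inference is upper-tail only: a large G means the samples sit farther apart
around the circle than a random relabelling would put them. The test
therefore has no power against alternatives that leave the expected
cross-pair distance unchanged (see Limitations), and no two-sided variant
is offered — the low-power regimes are a property of the published test and
are reproduced, not patched.

### Permutation engine

All permutation tests share one engine. N relabellings of the pooled m + n
values into groups of sizes m and n are drawn as independent uniform
permutations of the pooled index vector, from a single generator seeded per
invocation. The p-value is (Q + 1)/(N + 1) where Q counts relabellings with
statistic **weakly** greater than the observed value; the weak inequality
is the conservative convention, identical to strict counting for continuous
data but safer with duplicated angles. Because mathematical ties (the
complement relabelling of a symmetric statistic, coinciding rank patterns
of U²) can land a hair below the observed value in floating point, the
comparison uses a relative tolerance of 1e−9 — far below any genuine gap in
these statistics, far above accumulated rounding error.

Relabellings are applied in pooled-index space, not sorted-order space, so
a common rotation of both samples leaves every relabelled grouping — and
hence the p-value at a fixed seed — unchanged.

The default permutation budget is N = 10,000, overridable everywhere for
speed.

### Comparator statistics

* **Watson U²** uses the classical pooled-ordering form: scanning the
  pooled circular sort, d_k is the difference between the fractions of each
  sample seen so far and U² = (mn/T²) Σ(d_k − d̄)²; the centring on d̄ makes
  it origin-invariant. Exact cross-sample ties are broken deterministically
  by placing sample-1 values first (equivalent to an infinitesimal positive
  offset on sample 2). The asymptotic p-value is the alternating series
  2 Σ (−1)^{k−1} exp(−2k²π²U²), truncated when terms drop below 1e−10;
  below U² = 0.05, where that series converges too slowly, the Jacobi theta
  transformation of the same function is summed instead
  (p = 1 − √(2/(πU²)) Σ exp(−(2j+1)²/(8U²))), and the result is clamped to
  (0, 1]. No small-sample correction is applied.
* **Watson–Wheeler** maps pooled circular ranks r to uniform scores
  β = 2πr/T and uses W = 2(R₁²/m + R₂²/n) = 2TR₁²/(mn) (the scores sum to
  zero, so both group resultants coincide), asymptotically χ² with 2
  degrees of freedom. Exact cross-sample ties raise an error by default
  because silent tie-breaking changes the rank statistic invisibly; an
  opt-in seeded jitter of 1e−9 rad is available.
* **Rao spacing frequencies (Rsf)**: sample 1's m sorted angles cut the
  circle into m arcs; f_i counts sample-2 points in arc i and the statistic
  is Σ|f_i − n/m|, with permutation inference. The literature describes
  this test only through external code; this discrepancy form is the
  canonical spacing-frequencies choice, and numerical agreement with other
  implementations is not guaranteed.

## Generative families

Three samplers drive the simulations, all deterministic given a numpy
`Generator` or integer seed and location-equivariant (shifting μ or ξ by c
equals rotating the sample by c under the same stream):

* **von Mises VM(μ, K)** — numpy's Best–Fisher rejection sampler; K = 0
  short-circuits to the exact circular uniform.
* **axial von Mises** — an equal 50/50 mixture of VM(μ, K) and VM(μ+π, K):
  two antipodal modes with one concentration. Its correctness oracle is the
  angle-doubling identity: the raw resultant vanishes while the doubled
  angles 2θ have mean resultant length I₂(K)/I₀(K) (the doubled variable is
  not itself von Mises; its resultant is E[cos 2θ]).
* **wrapped skew-normal WSN(ξ, ρ, α)** — (ξ + ρZ) mod 2π with Z standard
  skew-normal of shape α drawn via the Azzalini convolution representation
  (scipy). α = 0 is a wrapped normal; positive α skews left. ρ is read as
  the skew-normal scale; whether other software reparameterises the
  dispersion is unknown, so dispersion sweeps are comparable within this
  package but not guaranteed to match external parameterisations
  numerically.

These samplers emulate clean, continuous, independent draws. Real field
data are often rounded to 5° or 10° bins, serially dependent, or
contaminated; none of that is modelled, so passing simulations demonstrate
calibration and relative power for ideal data only. Grouped-data behaviour
in particular is untested.

## Simulation design

A `Scenario` fixes two distributions, sample sizes (m, n), the tests, the
replicate count R, the permutation count N, the significance level and a
seed. Each replicate draws fresh samples and runs every requested test;
the rejection fraction is reported with its binomial Monte-Carlo standard
error √(r(1−r)/R). With R = 10,000 a 5% rate carries a 95% CI half-width
of 1.96·√(0.05·0.95/10,000) ≈ 0.0043.

Key reproducibility choices:

* Per-replicate RNG substreams are derived from (seed, CRC-32 of the
  scenario id, replicate index), so results are independent of execution
  order and resumable by scenario id.
* Within a replicate, the four permutation tests share one relabelling
  matrix (fresh each replicate); asymptotic tests reuse the same observed
  statistics. This keeps a six-test replicate at one permutation-matrix
  cost without coupling replicates.
* The significance level defaults to 0.05.

Grids are declarative: a sweep is `null` (identical distributions, type-I
error), `sweep2` (sample 1 fixed, one parameter of sample 2 swept — a
dispersion/concentration contrast) or `shift` (identical shapes, sample 2's
location rotated by 0°–180°). Default sweep grids are K ∈ {0, 1, 2, 4, 8},
ρ ∈ {1, 1.5, 2, 3, 4}, shift ∈ {0°, 30°, …, 180°}, and the default
sample-size pairs are (10,10), (20,20), (50,50), (10,50), (50,10) — sizes
of 10 and 50 being the named small/medium anchors. Desk-scale defaults are
R = 1,000 and N = 999, which resolve every claim tested here while keeping
a full grid to minutes on one CPU; `--paper-scale` restores
R = N = 10,000 (hours of CPU). The test suite and the acceptance script
use the desk-scale budget with tolerances widened to 3 binomial standard
errors at the actual R.

## Numerical choices and degenerate inputs

* Non-finite angles are rejected on input; empty samples are rejected;
  Rsf requires m ≥ 2 anchors; U²/W require a pooled size of at least 3.
* Pooled sorting is stable with sample-1 values first on exact ties (the
  documented U² tie-break); under permutation, ties fall back to original
  pooled position.
* Permutation p-values live on the lattice {k/(N+1)} and never reach 0.
* The asymptotic p-value clamp keeps outputs in (0, 1].

## Limitations

* **ART blind spots** (reproduced by design): axially symmetric
  alternatives shift no mass in the cross-pair distance distribution's
  mean, so ART's rejection rate stays at the null level even for a 90°
  rotation of the modes; and for a small concentrated sample paired with a
  large dispersed one, ART's power collapses to near zero while Watson's
  U² retains power.
* **Rsf discreteness**: Σ|f_i − n/m| is integer-valued, so at m = n = 10
  its permutation null has only a handful of atoms near the 5% tail; with
  the conservative weak-inequality p-value the attained size is ~0.02–0.03,
  and with strict counting it would be ~0.13. No attainable size sits near
  0.05 at that sample size — an inherent property of exact inference on a
  heavily tied statistic, left visible rather than patched with mid-p
  adjustments.
* Asymptotic WU2/WW p-values are used without small-sample corrections;
  at m = n = 10 they are mildly liberal (observed type-I up to ~0.06).
* No k-sample (>2) extension, no confidence intervals on effect size, no
  grouped/rounded-data handling.
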