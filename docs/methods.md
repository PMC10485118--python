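# Methods

This note documents the statistical models and algorithms implemented in
`allema`, the parameter choices behind the defaults, the numerical
decisions, and what the synthetic-data generators do and do not emulate.

## Sampling algorithms (`allema.sampling`)

**Capped PPS inclusion.** `solve_capped_inclusion` solves
`sum_i min(C * s_i, 1) = target` by iterative saturation: units whose
provisional probability reaches 1 are fixed ("always selected") and the
constant is re-solved exactly on the remainder by division; iteration
stops when no new unit saturates. The fixed point is unique because the
left-hand side is continuous and non-decreasing in `C`; the unit tests
cross-check against an independent Brent root-finder to 1e-9. Tolerance on
the achieved sum: 1e-9.

**Cube method.** The flight phase uses the fast one-pass variant: a
sliding buffer of `p + 1` units (`p` = number of balancing columns), a
null-space direction of the restricted constraint matrix from an SVD, and
the two martingale step lengths chosen with probabilities `λ2/(λ1+λ2)` and
`λ1/(λ1+λ2)`, which preserves the expectation of every entry and conserves
the Horvitz–Thompson equations of all balancing columns exactly at every
step. Unit visiting order is randomized by the seeded generator to avoid
order artefacts. Degenerate entries (0 or 1) are frozen before any step;
entries within 1e-8 of an integer are snapped.

**Landing.** Sequential suppression of balancing variables: the last
column is dropped first and the flight re-run on the unresolved units,
down to the leading column; any unit still fractional afterwards is
rounded by an independent Bernoulli trial, which preserves its marginal
expectation. By convention the inclusion-probability column is placed
*first*, so it is suppressed last; when `sum(pi)` is an integer this makes
the realized sample size exact in every draw (at the single-column stage
at most one unit can be fractional, and an integer total forces it to an
integer). We deliberately round the tail by Bernoulli rather than by
enumerating candidate samples: the enumeration only redistributes the
(already bounded) balance error of at most one unit per suppressed
variable, and the Monte Carlo suite confirms both the inclusion
probabilities and the fixed-size contract without it.

**Local pivotal method.** LPM1 behaviour: repeatedly pick a random
unresolved unit, find its nearest unresolved neighbour under standardized
Euclidean distance (each coordinate divided by its population standard
deviation), and apply the pivotal probability transfer only when the two
are mutually nearest. Coordinate ties are broken by unit index, so
duplicate coordinates are legal. Mutually-nearest pairs always exist in a
finite point set, so the loop terminates with probability one. LPM1 was
chosen over LPM2 as the variant with the strongest spreading; the choice
is a package decision, not dictated by the design being emulated.

**Doubly balanced (local cube) sampling.** Flight steps are applied to
clusters formed by a random unresolved unit and its `p` nearest
unresolved neighbours, which yields samples simultaneously balanced on the
auxiliary columns and spatially spread; the remainder is resolved by the
standard landing. Spatial spread is scored by the Voronoi statistic
`B = (1/n) Σ_selected (Σ_cell π − 1)²` (each population unit assigned to
its nearest selected unit); the tests require `B` to be stochastically
smaller than under a multinomial design with the same probabilities.

**Stratified balancing.** The local flight phase runs separately within
each group; unresolved units are pooled and a second flight runs with the
balancing matrix augmented by group-wise `pi` columns placed first. The
landing then suppresses the original balancing variables before the group
columns, and finishes with a per-group single-column flight, so any group
whose probability sum is an integer realizes that size in every draw.
This is what guarantees annual panels of exactly `m/r` squares.

**Randomness.** Every sampler accepts either an integer seed or a NumPy
`Generator`; all draws flow from that single source, and the returned
`SampleDraw` records the seed and an algorithm identifier.

## Allocation and calibration (`allema.calibration`)

Power allocation assigns stratum sample shares proportional to
`area^alpha`; `alpha = 0.5` (the default) compromises between equal
stratum samples (`alpha = 0`) and proportional-to-size allocation
(`alpha = 1`).

The index of interest solves the double-stratification constraints by
calibration with the bounded logistic function
`F(u) = (L(U−1) + U(1−L)e^{Au}) / ((U−1) + (1−L)e^{Au})`,
`A = (U−L)/((1−L)(U−1))`, which satisfies `F(0) = 1`, `F′(0) = 1` and maps
onto `(L, U)`; bounds `(0, ∞)` recover raking (`F = exp`). The dual
variables are found by damped Newton iteration (residual Jacobian
`Z' diag(d F′) Z`, least-squares step because one constraint is redundant,
backtracking halving on non-decreasing residual norm; at most 200
iterations, convergence tolerance 1e-8). A necessary per-constraint
feasibility check (`target ∈ [L, U] × stratum weight`) runs first and
failures name the violated constraint. If Newton stalls with all residuals
below 1e-3 the closest bounded solution is returned with a warning — with
a finite frame exact feasibility is not always attainable and small
deviations must be accepted; larger gaps raise an error, never a silent
partial fit. Stratum membership is by square centre (no fractional
membership). The default bounds `(0.61, 3)` limit the dispersion of the
first-stage weights.

## The three-stage design (`allema.design`)

Defaults (`DesignConfig`): `m = 170` squares, `r = 5` rotation groups,
`v0 = 19` vegetation plots per square, `alpha = 0.5`, bounds
`(0.61, 3)`, square side 950 m, grid spacing 50 m, plot areas 10 and
200 m². These are the operational constants of the monitoring design the
package implements.

* The 19 × 19 plot grid is centred in the square (symmetric 25-m margins),
  which keeps the 200 m² circles (radius ≈ 7.98 m) inside the square.
* The per-square vegetation quota is adjusted as `v_i = min(v0, n_i)` —
  the simplest rule consistent with taking small squares exhaustively. The
  rule is a package decision; alternatives (e.g. tapering before `n_i`
  reaches `v0`) would change only squares near the threshold.
* Terrain covariates: slope from central differences on the 25-m
  elevation raster; aspect measured in degrees clockwise from north,
  pointing downslope; the orientation covariates are **east = cos(aspect),
  north = sin(aspect)** — the convention used by the design being
  emulated, although common GIS practice swaps the two. A config switch
  (`gis_aspect_convention`) selects the GIS convention; either way
  `east² + north² = 1` wherever aspect is defined, and flat cells get 0/0
  with a flag. The topographic-position covariate is elevation minus the
  mean elevation within 100 m, rescaled to an 8-level ordinal ladder
  (8 = exposed ridge … 1 = distinct ditch) by equal-frequency binning; the
  source design describes the ladder but gives no formula, so this is a
  package decision.
* Probability products (`pi_H = pi1 · pi2|S1`, `pi_V = pi1 · pi2|S1 ·
  pi3|S2`) are computed in one place and tested to 1e-12.
* Polygon-targeted (EFA-style) second/third stages are not constructed by
  this package; the estimator path accepts externally supplied conditional
  probabilities and area-mismatch weights `w_j` instead.

## Estimators (`allema.estimators`)

Hájek means and area shares; the simplified Hansen–Hurwitz variance with
drawing probabilities `p_i = π₁,ᵢ/m`. Selected squares without sampled
plots keep `Ŷᵢ = 0` so the between-square sum runs over all `m` draws.
Domain estimation zeroes the response outside the domain while keeping the
full denominator structure. The with-replacement assumption ignores the
finite-population correction and the balancing gains, so the estimator is
slightly conservative; the tests assert the direction (empirical variance
≤ 1.15 × mean estimated variance on balanced synthetic populations) rather
than a sharp calibration.

## Synthetic data (`allema.simulate`)

The frame generator emulates the *structure* of the national frame: 455
squares on a systematic 12 km × 8 km lattice (jitter ±500 m), elevation
rising smoothly south→north with 180-m local noise, production zones as
elevation quantile bands and biogeographic regions as longitude bands (so
the stratifications cross-cut), accessible area `A_i` Beta(2, 1.3)-shaped
and shrinking with elevation, `n_i = round(361 A_i / 0.9025)`, the dense
grid in the two easternmost regions, rotation groups interleaved
systematically across the lattice. The raw-frame variant adds 35
fully-inaccessible and 19 no-agricultural-land squares (509 total)
concentrated at high elevation. What it does **not** emulate: the true
spatial autocorrelation of Swiss habitats, real stratum geometries, or
within-stratum habitat gradients — so passing tests demonstrate the
design's algebraic and design-based properties, not field-realistic
efficiency gains.

The habitat population model is double Poisson:
`n_il = ½ · Poisson(2) · Poisson(p_lg · n_i)` independently per square and
habitat, giving `E[n_il] = p_lg n_i` and variance
`0.5 λ² + 1.5 λ > λ` (over-dispersed). `Pois(a, b)` is read as a Poisson
with mean `a·b`, the only reading that makes `p_lg` the expected
proportion; the halving is applied after the integer draws and values are
kept unrounded. Because the real expert table of `p_lg` values is not
public, a seedable generator produces a sparse stratum-structured matrix
(67 habitats in 1–2 host strata each, decaying frequency, per-stratum
totals ≤ 0.95); consequently the published efficiency percentages of the
original study are **not** reproduction targets — the Monte Carlo
comparison asserts the directional result (stratified balancing lowers the
mean CV versus pure UPS over 300 draws, one-sided α = 0.05).

The cost model (`cost_neutral_scaling`) holds
`m·travel_to + total_plots·(record + travel_between)` constant and returns
the affordable plot effort as floats, so the budget identity is exact.

## Power analysis (`allema.power`)

Minimum squares for detecting a relative change `delta` on re-measured
squares:
`m_min = ceil(s²(2−2ρ)(Z₁₋α/₂+Z₁₋β)² / (δ Ȳ)²)` in the default
`squared` mode. An `as_printed` mode with the Z-term unsquared is provided
for literal reproduction of designs computed that way; the two coincide
only when the Z-term equals 1 (e.g. near α = 0.32, power = 0.5, where the
sum is ≈ 0.994). The default grids are δ ∈ {0.1, 0.2, 0.3},
ρ ∈ {0.8, 0.9, 0.95}, power ∈ {0.5, 0.7, 0.9} at α = 0.32 (68%
confidence — "significant standard errors", a deliberately low threshold
for early change detection). `s²` is recovered from a design-based
variance as `var̂·m`; the paired correlation estimator accepts survey
weights (use `1/π₁` per square). The empirical check simulates paired
square proportions as bivariate normal with the specified `(s², ρ)` and
verifies the achieved power of the two-sided paired z-test at `m_min` is
within ±0.07 of the nominal 0.5.

## Problem sizes used in the tests

Monte Carlo sizes were chosen to make binomial/3-SE criteria sharp at
desk scale: 10 000 replicates for per-unit inclusion-frequency recovery on
20-unit fixtures (4 binomial SE), 10 000 draws for the double-Poisson
moments, 300 draws for the design comparison on a 200-square frame
(m = 50), 500 replicates for first-stage π recovery on a 60-square frame,
100 replicates for the exact-size contracts on the full 455-square frame,
2 000 replicates for estimator unbiasedness and achieved power. The
third-stage exact-quota check runs on a band of squares with
n_i ∈ {7, 19, 60, 150, 300}, which brackets the quota threshold.

## Known limitations

* The landing phase's Bernoulli tail can break *approximate* balance by at
  most the suppressed variables' contribution of one unit; exact
  fixed-size contracts are unaffected.
* Calibration accepts residuals up to 1e-3 when exact feasibility fails;
  the returned diagnostics expose the residuals, and anything larger is an
  error.
* The self-weighting diagnostic reports dispersion; perfect constancy of
  `pi_V` holds only in the idealized configuration (no capping, constant
  plot index, full quota everywhere).
* `run_design_comparison` compares first-stage designs only; second/third
  stage contributions to the CV are outside its scope.
* Polygon layers are assumed planar metric; no CRS transformation is
  performed.
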