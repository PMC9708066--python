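# Methods

This note documents the models implemented in `thermotraits`, the choices
made where conventions were genuinely open, and what the synthetic-data
generator does and does not emulate.

## Trait derivation from raw assays

The derivation chain converts one replicate's raw measurements into
physiological traits.

*Biomass.* Cells are treated as spheres (`V = πd³/6`) because only
diameters are measured; callers with better shape information can supply
volumes directly. Carbon per cell follows the allometry
`fgC = 133.754 · V^0.438`, and culture biomass is carbon per cell times
the cell count. When several per-cell diameters are supplied, the mean of
the per-cell *volumes* is used (volume is convex in diameter, so this
differs from the volume of the mean diameter).

*Growth.* `µ = ln(C_tot/C_0)/t` assumes the culture is in exponential
growth for the whole assay (the protocol primes cells to skip lag phase).
Natural log, per the exponential-growth convention. Negative µ (shrinking
cultures) is allowed and propagates unchanged.

*Respiration.* `R = µ·R_tot/(C_0 e^{µt} − C_0)` divides cumulative
respired carbon by time-integrated biomass. The denominator vanishes as
µ→0; below `|µt| < 1e−8` the analytic limit `R_tot/(C_0 t)` is used
(relative switch error at that threshold is ≲ 5e−9, far below measurement
precision). `R_tot` must be in the same mass unit as biomass (fgC).

*ATP.* The luminescence reaction develops over minutes, so the peak RLU
across the timepoints is used, inverted through
`log10(nM) = 1.21·log10(RLU) − 4.69`. Base 10 on both sides — the
calibration-curve convention; the source relation does not state a base.
ATP per biomass is reported as nM per fgC; only additive constants after
the log transform depend on this unit choice.

## Sharpe–Schoolfield fitting

The model is parameterised with an explicit peak temperature `Tpk`;
`Tref` defaults to 273.15 K and is never fitted (it only rescales `B0`,
never `Topt`, `E` or `ED`). Fitting minimises squared residuals on the
linear rate scale (a log-scale option exists but is off by default, since
multiplicative-error fitting changes the estimator). Internals work in
Kelvin; all I/O is Celsius.

Optimisation details:

- free parameters `(log B0, E, ED−E, Tpk)`; optimising `log B0` keeps the
  rate positive and the gap parameterisation enforces `ED > E` within box
  bounds: `E ∈ [0.01, 10] eV`, `ED − E ∈ [0.01, 30] eV`,
  `Tpk ∈ [min obs − 5 K, max obs + 10 K]`;
- multi-start over `E ∈ {0.2, 0.65, 1.2} eV` with `ED = 4E`, `Tpk` at the
  argmax observed rate and `B0` backed out from the observation nearest
  `Tref` through the Arrhenius rise; the lowest-RSS start wins, ties
  broken toward smaller `E`;
- non-positive rates are dropped before fitting (the model is strictly
  positive) and logged;
- fewer than five distinct temperatures cannot support a four-parameter
  fit: the temperature of the highest observed rate is returned as a
  fallback `Topt` with `method="fallback"`;
- monotonically rising data (no decline within the measured range) fit
  with `Tpk` at or past the warmest observation; a diagnostic warning is
  attached rather than refusing the fit.

The peak rate is evaluated in closed form at `T = Tpk`. The operational
niche width solves `B(T) = B(Tpk)/2` below the peak by Brent root finding
on `[floor, Tpk]`; the floor defaults to −10 °C (it bounds the search
without asserting biology) and a curve still above half-max at the floor
returns an undefined width rather than an error. Arrhenius correction
`rate · e^{(E/k)(1/T_obs − 1/T_target)}` uses `E = 0.61 eV` by default,
the conventional value for normalising metabolic rates across studies.

## Phylogenetic signal and ancestral states

Traits are aligned to tree tips strictly (mismatches are errors; a
permissive mode drops unmatched entries with a warning). `Topt` is
log-transformed (natural log of the Celsius value — all observed optima
are far above 0 °C) before signal estimation because its distribution is
right-skewed; the transform is a flag, and using Kelvin instead changes λ
only marginally.

*Pagel's λ* multiplies the off-diagonal of the Brownian covariance matrix
(shared root-to-MRCA path lengths). The mean and rate are profiled out by
GLS, leaving a 1-D likelihood maximised on [0, 1] by bounded scalar
search (tolerance 1e−8); λ > 1 is not searched. The p-value compares
`2(ℓ(λ̂) − ℓ(0))` to χ²₁ with no boundary correction — a plain χ² test,
documented as such; when the LRT statistic is 0 the p-value is exactly 1.

*Blomberg's K* is the observed MSE₀/MSE ratio divided by its Brownian
expectation `(tr(V) − n/Σ(V⁻¹))/(n−1)`. The permutation test shuffles
trait values across tips (default 999 permutations + the observed
arrangement, upper tail) with a recorded seed; passing
`n_permutations=None` skips the test, which is useful in calibration
loops.

*Ancestral states* use the GLS construction: each internal node is an
extra zero-length tip of the multivariate normal, giving
`â_u = µ̂ + c_u' V⁻¹ (x − µ̂)` with prediction variance including the
uncertainty of µ̂. This is exact and O(n³) — fine for trees up to a few
hundred tips; a pruning fast path would be an optimisation, not a
behavioural change. Implementation verified against R's
`phytools::phylosig` and `fastAnc` (agreement to ≥5 decimals on seeded
fixtures, frozen in the test suite) and against an independent
joint-likelihood linear-system oracle. Polytomies and zero-length
internal branches are supported; branch-length rescaling leaves λ, K, p
and states unchanged (the rate rescales inversely).

## Community statistics

- Sorting regression: quadratic vs. straight line by the nested F-test
  `F = (RSS₁ − RSS₂)/(RSS₂/(n−3))` on (1, n−3) df; fitted in °C with one
  row per isolate, restricted to sorting-mode isolates. Standard-
  temperature isolates are described by the simple linear model only.
- PCA: SVD of the column-standardised matrix; eigenvector signs are
  arbitrary, so the largest-magnitude loading of each component is made
  positive for determinism. Row filters let callers include or exclude
  phyla from the fit.
- Power-law scaling: OLS of `log10 y` on `log10 x`; pooled over all
  replicate measurements per phylum rather than per-isolate means.
- Rank-sum tests: exact enumeration when the pooled sample is ≤ 12 with
  no ties, otherwise the normal approximation with tie and continuity
  corrections. The two branches typically agree to ~0.01 in p at 6+6
  (worst case ~0.015). Two-sided by default; significance stars at
  0.05/0.01/0.001. No multiple-testing correction is applied; the number
  of tests run is recorded on the result.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of their integer seed (identical seeds give
bitwise-identical outputs).

- *Rate noise* is multiplicative lognormal with mean 1 and coefficient of
  variation `noise_cv` (default 0.05): rates are positive and skewed, and
  no per-replicate error magnitude is reported for the original assays,
  so 5% is a realistic placeholder for plate-reader-scale noise, chosen
  once.
- *Assay records* invert the derivation chain exactly; optional Poisson
  count noise is off by default so round trips are exact to machine
  precision.
- *Trees* are pure-birth (Yule) with depth rescaled to 1; recovery
  studies need any ultrametric topology, not the empirical tree.
- *The community scenario* (defaults: sorting temperatures 4, 10, 21, 30,
  40, 50 °C; six isolates per temperature; +8 °C cold offset decaying
  linearly to zero at 21 °C; mesophile standard-temperature isolates)
  reproduces the qualitative structure of a sorting experiment: optima on
  the 1:1 line with upward cold-end deviation (hence the quadratic
  preference), warm-adapted isolates labelled Firmicutes, r/K trait
  contrast between phyla, and trait-ordered tip assignment so `Topt`
  carries strong phylogenetic signal. The cold offset is a smooth
  additive bias — it reproduces the curvature without asserting a
  mechanism.

What passing tests on these data show: the estimators recover known
generating parameters under the stated noise. What they do not show:
robustness to real-data pathologies — non-exponential growth phases,
flow-cytometry gating error, phylogenetic uncertainty, model
misspecification of the TPC shape — none of which the generator
simulates.

## Problem sizes

The default validation runs use 100 simulated curves (7 temperatures × 4
replicates) for fit recovery, 100 replicate Brownian simulations on
200-tip trees for λ/K calibration, 50 random parameter sets or 10-tip
trees for the grid and GLS oracles, and a 72-isolate community scenario —
sizes at which Monte-Carlo error is well below the acceptance margins
while a full run stays interactive (~10 s).

## Known limitations

- No alternative TPC forms (Brière, quadratic) or model selection; no
  replicate-variance weighting.
- λ is not searched above 1; traits with stronger-than-Brownian
  similarity hit the boundary.
- The ancestral-state solver is dense O(n³); thousands of tips would need
  a pruning implementation.
- The CLI pipeline feeds the phylogenetic stage with fitted `Topt` from
  the synthetic scenario's own tree; consuming an external time tree is
  supported by placing `tree.nwk` in the run directory.
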