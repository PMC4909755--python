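# Methods

## The fragmentation process

A parcellation is grown from a single root region of volume 1 (units are
arbitrary; every statistic uses natural logarithms, so the choice cannot
matter).  At each step:

1. a current leaf region is drawn with probability `p_i = v_i^mu / Z`,
   with `Z` normalising over all current leaves.  The weights are
   recomputed over the full leaf set at every step, in log space with
   max-subtraction, so extreme `mu * ln v` cannot overflow;
2. the chosen region is replaced by two daughters.  One multiplier
   `r ~ Normal(1, noise_sd)` is drawn and the daughters get `v*r/2` and
   `v*(2-r)/2`.  A single multiplier applied complementarily is the only
   way to give each daughter the stated multiplicative dispersion while
   conserving the parent volume exactly; the second daughter's volume is
   computed as `v - v*r/2`, so conservation is exact in floating point
   as well.  `r` is redrawn outside (0.02, 1.98) to keep both daughters
   positive — a ~1e-22 event at the default `noise_sd = 0.10`, relevant
   only for pathological noise settings (`noise_sd` is capped below
   0.5).

The process stops at `n_target` leaves.  Since each step adds one
region, the leaf count is also the evolutionary time.  At `mu = 0` and
zero noise the process is a Yule process and leaf volumes are exact
powers of 1/2; the test suite checks the simulator's leaf-depth
distribution against an independent brute-force implementation, and its
dispersion statistic against a second, stdlib-random implementation.

Two equivalent engines exist.  `run_fragmentation` builds the full
binary history (a `ParcellationTree`) with a single `numpy` generator
consumed in a fixed order (one uniform for leaf selection, then the
noise draw), so a seed reproduces the tree bit for bit.
`simulate_log_volumes` advances many replicate runs in lockstep, storing
only log leaf volumes; envelope inference needs ~10^5 runs and this
vectorised path makes that a few seconds of work.  The two paths consume
randomness differently and are therefore only statistically, not
bitwise, identical; a two-sample KS test in the suite enforces the
statistical equivalence.

## Size-distribution statistics

`fit_log_gaussian` reports the sample mean and the unbiased (n−1)
standard deviation of `ln v`; at realistic sample sizes the denominator
choice is negligible, n−1 is simply the package-wide convention.
`sigma(ln v)` from a simulated run uses the same n−1 convention.

`ks_lognormality` runs a one-sample KS test of `ln v` against a normal
with the *fitted* parameters and reports the classical p-value by
default.  Because the parameters are estimated from the same sample this
p-value is anti-conservative (the Lilliefors situation); a parametric
bootstrap (`lilliefors=True`, default 1000 resamples, seeded) is
provided for calibrated inference.  The anti-conservative default is
deliberate: it is the convention against which published parcellation
p-values are comparable.

QQ points use plotting positions `(i - 0.5)/n` against the fitted
normal.  Zero-volume records (atlas leaves without a volume annotation)
are removed by `filter_volumes` before any statistic, with a warning
counting the dropped rows.

## Envelope inference of mu

`sigma_envelope(n_pu, mu_grid, n_sims, ...)` runs `n_sims` independent
fragmentations per grid value of `mu` and records each run's
`sigma(ln v)`; the 5th/95th empirical percentiles form a 90% band
(quantile levels are parameters).  Each grid point receives an
independent child stream spawned from the seed, so refining the grid
never perturbs existing points.  Defaults: grid −0.8…0.8 in steps of
0.02, 1000 simulations per point, 10% split noise.

`infer_mu_interval` treats the two bands as piecewise linear and, on
every grid segment, solves the linear constraints
`lower(mu) <= sigma_obs <= upper(mu)` in closed form.  The union of the
feasible sub-intervals gives the reported endpoints.  Scanning every
segment (rather than assuming the bands decrease) means Monte-Carlo
roughness in the bands can widen but never silently truncate the
interval; isotonic smoothing was considered and rejected as a default
because it would move the endpoints by an amount that depends on a
smoothing choice the user never sees.  If the observation never enters
the band, both endpoints are `None`.

Coverage of the interval was measured by simulation: with a true
`mu* ∈ {0, 0.2}` at 91 PUs, the 90% interval contains `mu*` in ≈ 89–92%
of replicate observations (the acceptance suite estimates the rate from
400 replicates per `mu*` so the binomial error of the estimate, ~1.5%,
is small against the margin being tested).

The package ships one named PU count, `MACAQUE_N_PU = 91` (the cortical
area count of the standard macaque retrograde-tracing parcellation);
counts for other species are user inputs taken from the user's atlas
table.

## Connectivity

`outer_product_connectome` builds `C_ij = f * rho^2 * v_i * v_j / 2`
(`f` the ancestral pairwise connection probability, `rho` the uniform
neuron density).  The diagonal is zeroed by default, matching how tracer
studies report extrinsic connections only; `include_diagonal=True`
restores the self-blocks and with them the exact total-count identity
`sum(C) = f N^2 / 2` with `N = rho * sum(v)`.

`normalize_fln` divides each row by its sum (all-zero rows are left zero
and flagged).  Fits are ordinary least squares of `ln strength` on
`ln volume` over strictly positive strengths — zeros are excluded, not
floored, because any floor biases the slope, and absent connections are
a separate regime of the model (the Hebbian rule has `C = 0` as an
equilibrium).  A fit refuses to run with fewer than 3 positive points or
with a volume spread below 1.001 (max/min), where the slope is not
identifiable.  Pooled incoming fits weight each point, not each target,
equally.  Natural logs are used throughout; the slope is base-invariant
and the intercept is documented as a natural-log intercept.

## Hebbian dynamics

`dC_ij/dt = eps1 f_i^alpha C_ij^beta f_j^gamma - eps2 C_ij` with
activities `f_i = v_i` by default (the proportionality constant is
absorbed by `eps1` and cannot affect exponents).  For `beta < 1` the
closed-form fixed point
`C* = (eps1/eps2)^(1/(1-beta)) f_i^(alpha/(1-beta)) f_j^(gamma/(1-beta))`
is attracting from positive initial conditions and `C = 0` is repelling;
for `beta >= 1` the roles reverse, so the module refuses `beta >= 1`
instead of integrating toward divergence.  Integration uses LSODA on the
entrywise-decoupled system (entries starting at exactly zero are held at
zero), in chunks of roughly ten relaxation times
`1/((1-beta) eps2)`, stopping when `max |dC/dt| / max C` falls below the
tolerance (default 1e-9).  Only the equilibrium is contractual; the
trajectory is not.

## Synthetic data

The generators produce every input the analyses consume, so the full
suite runs without any external data:

- `make_lognormal_volumes` — lognormal region volumes; the default
  dispersion 1.24 natural-log units matches the scale observed in real
  cortical parcellations.
- `make_hierarchy_fixture` — an atlas-style parent–child table from a
  fragmentation run (default bias `mu = 0.14`, the midpoint of the range
  consistent with real brains), with a chosen fraction of zero-volume
  leaves to exercise filtering.
- `make_power_law_fln` — FLN matrices with a planted exponent,
  multiplicative lognormal scatter and missing-at-random zeros.  With
  `noise_sigma = 2.6` and 90 sources the fitted `r^2` lands near 0.6,
  the regime of the best-measured real target areas; recovery tests run
  at that noise level.

What the generators do *not* emulate: spatial embedding and distance-
dependent connectivity, region growth or shrinkage between splits,
non-binary splits, structured (non-random) zero patterns, and
injection-count-dependent measurement noise.  Passing tests therefore
show that the procedures are correct and well calibrated under the
model's own assumptions, not that real atlas or tracer data satisfy
those assumptions.

## Problem sizes

Ensemble statements in the tests and the results script use 200–400
replicate runs (dispersion means, coverage, exponent recovery), 1000
simulations per envelope grid point, 100-seed recovery experiments, and
10–12-area systems for ODE integration — sizes at which the Monte-Carlo
error of each asserted quantity is small against its tolerance.

## Known limitations

- The classical KS p-value is anti-conservative by construction (see
  above); use the bootstrap flag when calibration matters.
- The envelope method inherits the grid: intervals are resolved to the
  grid step (default 0.02) plus linear interpolation error.
- Ensemble means of `sigma(ln v)` at small PU counts have run-to-run
  spreads of ±0.3; a single simulated parcellation is a noisy estimate
  of the ensemble value.
- For strongly negative `mu` the smallest region dominates the split
  probabilities and the size distribution develops a heavy left tail;
  dispersion summaries remain well defined but lognormality degrades.
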