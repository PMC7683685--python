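# Methods

`dynforce` models and analyzes the constant-pulling optical-trap assay used
to probe the strength of the dynein–microtubule bond, and classifies the
stalk coiled-coil registries (alpha/beta/gamma) that set that strength. All
stages run on synthetic data from the built-in simulator, so every estimator
can be checked against a known ground truth.

## The assay and its model

A polystyrene bead carrying a single motor domain sits in a harmonic optical
trap (stiffness `k_trap`, default 0.036 pN/nm) while the microscope stage
sweeps back and forth parallel to a surface-bound microtubule as a triangle
wave (speed `v_stage`, default 156 nm/s; half peak-to-peak amplitude
`sweep_amplitude`, default 250 nm). When the motor binds, the moving stage
loads the bond at the *apparent* loading rate `k_trap * v_stage` (5.6 pN/s
at the defaults). The motor and bead linkage is compliant, so the force on
the bond actually grows at the smaller *effective* rate

    r(F) = v_stage * (1/k_trap + 1/k_motor)^-1 ,

the series-spring result. We model the linkage as a linear spring,
`motor_stiffness` = 0.2 pN/nm by default — an order of magnitude typical of
single motor/bead linkages; no measured value is available for this
construct, so the parameter is configurable and `inf` recovers the
apparent-rate (rigid) limit. For a linear spring r is force-independent; a
callable `k_motor(F)` is accepted for nonlinear linkages.

Sign convention, used everywhere: positive force = backward (hindering)
load toward the microtubule plus end; negative = forward (assisting) load.
Analyses treat forces as magnitudes per direction.

### Bond models

The unbinding rate k(F) is piecewise Bell: within each force segment
`k(F) = k0_eff * exp((F - F_lo)/F_scale)`, with `F_scale = inf` giving a
force-independent (ideal) segment and `F_scale < 0` a catch segment.
Segment prefactors are chained so k is continuous. Factories cover the
phenotypes relevant here: `slip`, `ideal`, `catch`, `slip_ideal`,
`slip_ideal_slip`.

### Rupture statistics

Under a ramp, rupture is a first-passage problem with the closed-form
density

    p(F) = k(F)/r(F) * exp(-∫_0^F k(f)/r(f) df).

`analytic_force_pdf` evaluates this by trapezoid quadrature on a 0.002-pN
grid; `sample_unbinding_forces` inverts the survival on the same grid
(inverse-CDF sampling). These two functions are the oracles that every
downstream estimator is tested against. Note that a catch bond whose rate
decays too fast has a *defective* rupture distribution (the survival
plateaus above zero); the sampler refuses such configurations rather than
silently truncating.

### Trace simulation

`simulate_pull_trace` is event-driven: binding times are geometric draws at
`k_on` (default 1 s^-1) per sample; while bound, the true force follows the
deterministic ramp set by the stage and the series stiffness, and the
rupture sample is found by comparing an exponential deviate against the
cumulative per-sample hazard `k(|F|)/sample_rate` — equivalent to per-step
survival `exp(-k dt)` but O(1) passes over the trace. White Gaussian noise
(`noise_sd`, default 0.05 pN) is added to the observed force only.
Defaults: 2 kHz sampling, so `k dt << 1` for all bonds considered; the
simulator refuses sample rates that resolve fewer than 10 samples per pN at
the apparent rate.

After rupture the force relaxes to baseline instantly by default. Passing
`relax_time > 0` (seconds) makes the relaxation exponential, and a rebind
during the decay starts a new episode under pre-load (`F_start > 0`) — a
*secondary* event. Bead relaxation in the real assay is millisecond-fast,
so secondaries require rapid rebinding; the simulator logs ground-truth
episodes (times, forces, pre-load, primary flag) on `Trace.truth`.

What the generator does *not* emulate: full Langevin bead dynamics (the
bead relaxation is assumed instantaneous relative to the loading),
processive stepping against the trap, 3-D bead geometry, drift, and
low-frequency instrument noise. Passing tests therefore demonstrate
estimator correctness under idealized trap physics, not robustness to every
instrumental artifact of real recordings.

## Event detection

Real analyses only use *primary* events — episodes whose force history
starts from zero — because the rupture-force law depends on the load
history. `detect_events` works on the force magnitude with a 2-ms boxcar
for onset tracking:

- onset: a crossing of `bind_threshold` (default 0.3 pN, the assay's
  detection floor); the binding point is the nearest noise-tolerant local
  minimum of the smoothed magnitude (searched both backward — loaded from
  baseline — and forward — rebind on a decaying force); `F_start` is the
  raw magnitude there;
- rupture: an abrupt collapse losing at least `drop_fraction` (default
  0.8) of the just-before level within ~2 samples. A collapse that settles
  at baseline closes the episode; one that settles above `bind_threshold`
  is a rupture followed by an immediate rebind and opens a secondary
  episode. A *slow* return to baseline (unloading across a stage reversal)
  closes the episode without an event;
- events shorter than `min_bound_time` (default 10 ms) or never exceeding
  the threshold are discarded. The reported `rupture_force` is the running
  maximum of the episode, and direction comes from the force sign just
  before the collapse.

On simulated traces at the default noise, ≥99% of ruptures with peak force
above `bind_threshold + 3*noise_sd` are recovered within 2 samples and
with force errors within 3 noise SD; with `noise_sd = 0` recovery is exact
to machine precision (these are test assertions, not aspirations).

## From forces to rates

Pooled primary rupture-force magnitudes (per condition and direction) are
summarized as 1-pN normalized histograms (bin value = count/N) and as a
kernel density. The force-dependent unbinding rate then follows from the
model-free identity

    k(F) = r(F) * p(F) / S(F),   S(F) = 1 - ∫_0^F p,

with r(F) the effective loading rate above. `kde_pdf` uses a Gaussian
kernel reflected at F = 0 with Silverman's rule
(`0.9 min(sd, IQR/1.34) n^-1/5`). Two numerical caveats are inherent to
this estimator:

- within one bandwidth of F = 0 the reflection forces a zero derivative, so
  densities with nonzero boundary slope (e.g. exponential) carry an O(h)
  boundary bias (~5% of the peak at typical n);
- the hazard transform divides by the survival, so a *fixed* bandwidth
  leaves the high-force tail of k(F) noisy. `rate_curve` therefore defaults
  to an adaptive bandwidth (Abramson's square-root law over a Silverman
  pilot), which equalizes relative error across the force range;
  `adaptive=False` restores the plain estimator.

Rates are reported only for F ≥ 0.5 pN (detection-limit convention) and
while S(F) ≥ `survival_floor` (default 0.05): beyond that point the
denominator rests on a handful of events and the transform is unreliable.
The grid spacing is 0.05 pN. `n_effective = N*S(F)` is attached so plots
can show how much data supports each force.

As an independent cross-check (tests only), `empirical_rate_oracle`
differences the Nelson–Aalen cumulative hazard (jumps `1/(N-i+1)` at the
i-th order statistic) over blocks of ~sqrt(N) order statistics — a
KDE-free step-function estimate. The two routes agree to a median relative
discrepancy well under 15% at n = 5000.

## Uncertainty

Rupture-force distributions under a ramp are skewed, so inference is by
bootstrap throughout:

- `boot_ci_mean`: percentile bootstrap of the mean, B = 4000, 95% level
  (BCa available via `method="bca"`). Measured coverage at n = 200 over 500
  replications: ~0.95.
- `boot_mean_diff_test`: the shifted-null two-tailed test. B = 1e5
  replicate means per sample, differenced pairwise; the difference
  distribution is recentered to zero (the null), and p_m is the fraction of
  recentered differences at least as large in magnitude as the observed
  mean difference, floored at 1/B. Pairing is B paired draws; a full
  cross-product is available behind `pairing="cross"`. Measured type-I
  error at the 5% level: ~0.04-0.06.
- `boot_rate_ci`: resample forces, recompute the whole KDE-to-rate
  transform, take pointwise percentile bands on the point estimate's grid;
  resamples whose reported range misses a grid point are excluded pointwise
  with a logged count. The bands capture sampling variance, not the
  smoothing bias of the point estimate, so single-dataset pointwise
  coverage can dip locally; on average over datasets the true curve sits
  inside the 95% band at ≥90% of grid points (tested).

Motility summaries follow the field's reporting conventions: velocities are
summarized by a least-squares Gaussian fit to the binned histogram
(mean ± SEM, SEM = SD/sqrt(N)), construct comparisons use unpaired Welch's
t tests, and stall forces are reported as mean ± SD.

## Registry and phenotype classification

Reference profiles for the three stalk registries come from constructs
disulfide-crosslinked into each registry: mean unbinding forces 0.7 pN
(beta, both directions), 1.6 pN (gamma, both directions), 2.7 pN (alpha,
backward load only — no forward alpha reference exists, so forward calls
choose among beta/gamma or return "unassigned"). The packaged references
store the published means and 95% CIs; users can substitute raw reference
samples.

`classify_registry` works per direction. With raw reference samples it
runs the shifted-null bootstrap test against each reference and assigns the
largest p_m above `alpha_level`. With mean-only references it computes the
condition's bootstrap CI and accepts references whose stored CI overlaps it
(nearest mean breaks ties). CI *overlap* — rather than requiring the
reference mean to fall inside the condition CI — is a deliberate choice:
the stricter rule fails at its own nominal rate per direction (~5%), which
compounds to ~10% two-direction error at realistic event counts and would
misclassify conditions that are in fact at the reference mean;
`compat="mean_in_ci"` restores it. Self-classification accuracy at the
reference means (n = 300/direction) is ≥95% per scenario (tested over 100
replications).

`classify_bond_phenotype` segments log k(F) into up to three linear pieces
(breakpoint scan on a 0.25-pN grid, BIC over segment counts, minimum
segment span 0.75 pN). A segment is called rising/falling only if its
slope exceeds `slope_tol` (default 0.12 pN^-1) *and* is significant at
`slope_alpha` — with the OLS standard error deflated to roughly one
independent observation per bandwidth, since neighboring grid points of a
smoothed curve share data. Adjacent same-sign segments merge, and the sign
pattern maps to slip / ideal / catch / slip-ideal / slip-ideal-slip /
other. Known edge artifact: near the survival floor the rate estimate can
curl upward on some datasets, which the classifier may read as a final slip
segment; phenotype calls within ~one bandwidth of the truncation point
should be read together with the bootstrap bands.

## Problem sizes and numerical choices

Recovery tests run at the event counts of the real experiments
(~300 events per direction and condition; n = 5000 for estimator-recovery
checks; 500 replications for CI coverage; 1000 for test calibration — sizes
chosen to keep every check's Monte-Carlo error well below the tolerance it
asserts). All randomness flows through `numpy.random.Generator` seeds;
every stochastic API takes a seed, simulations are bit-reproducible, and
pipeline reruns with identical config and seeds are byte-identical
(asserted). Quadrature grids: 0.002 pN (first-passage integrals), 0.05 pN
(reported curves). Degenerate inputs (zero loading rate, zero-variance
Welch input, empty samples, defective catch bonds) raise informative
errors rather than returning NaN.

## Limitations

- The compliance correction assumes a linear series spring; if the real
  linkage stiffens under load, r(F) is force-dependent — supported via a
  callable stiffness but not fitted from data.
- Detection parameters are exposed, not learned; on real traces with drift
  or colored noise they would need tuning that the simulator cannot
  justify.
- The registry classifier's mean-only mode is weaker than a
  distribution-level comparison; with raw reference data the bootstrap
  test mode should be preferred.
- Phenotype segmentation assumes at most three segments (the piecewise
  patterns discussed for this system) and piecewise-log-linear shape.
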