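# Methods

## The model

The package simulates the early gravitropic bending of a growing shoot
(the calibration targets wheat coleoptiles) as a chain of three processes,
each with its own time scale:

1. **Statolith avalanche (sensing).** In each gravity-sensing cell the
   dense statolith pile flows toward the horizontal when the cell is
   inclined. Because the flow is overdamped (Reynolds number of order
   10⁻⁶ for the measured cytoplasm viscosity, statolith speed and pile
   size), the pile angle `A_stato` relaxes viscously,

       dA_stato/dt = -(1/tau_aval) * sin(A_stato - A_stem),

   with no repose angle: the free surface returns exactly to the
   horizontal. The relaxation time follows from the balance of the
   buoyancy-reduced pile weight against viscous drag and is inversely
   proportional to gravity, `tau_aval = tau_aval_ref / g_eff`. Separating
   variables gives the closed form `tan(psi/2) = tan(psi0/2) exp(-t/tau)`
   for the free-surface angle `psi = A_stem - A_stato`, used as the test
   oracle for the numerical solver.

2. **Memory integration (signalling).** The growth signal `G_s` is not an
   instantaneous readout of the statolith position but an exponentially
   weighted integral of `sin(A_stato)` over a memory time `tau_memory`,
   applied after a pure delay `tau_reaction`:

       dG_s/dt = (1/tau_memory) * (beta * sin(A_stato(t - tau_reaction)) - G_s).

   The equivalent explicit kernel integral is implemented separately
   (adaptive quadrature of the exponential kernel) and the two routes are
   required to agree to 10⁻⁶ in the tests.

3. **Growth-driven curvature (actuation).** Differential elongation
   converts the signal into curvature change along the organ,

       R * dC/dt = -(1/tau_growth) * G_s,
       A_stem(s, t) = A_stem(0, t) + integral_0^s C ds',

   with the local inclination recovered by cumulative integration of the
   curvature from the imposed base angle. Proprioception (curvature
   sensing) is deliberately omitted: the package addresses the early
   bending phase where curvatures are small, and no hook is left for a
   proprioceptive term. The organ length is held fixed within a
   simulation window because bending (~1 h) is fast compared to
   elongation (`tau_growth` ~ 20 h); elongation enters only through
   `tau_growth` and the mean elongation velocity `epsilon_dot * L`.

The loop is negatively fed back: a permanently inclined organ bends until
its tip realigns with effective gravity. A dedicated test guards the sign
conventions by asserting exactly this behavior.

## Parameters

| parameter      | meaning                                | default (wheat) |
|----------------|----------------------------------------|-----------------|
| `R`            | organ radius                           | 0.8 mm          |
| `L`            | organ length                           | 20 mm           |
| `tau_growth`   | growth time, `1/epsilon_dot`           | 1200 min        |
| `beta`         | gravitropic gain                       | 0.8             |
| `tau_memory`   | memory-integration time                | 13 min          |
| `tau_reaction` | reaction delay                         | 13 min          |
| `tau_aval_ref` | avalanche time at 1 g                  | 1.04 min        |
| `g_eff`        | effective gravity (multiples of Earth) | 1               |

Times are minutes, lengths millimetres, angles degrees at every public
interface (radians internally), gravity a dimensionless multiple of Earth
gravity. `epsilon_dot` defaults to `1/tau_growth` so the identity
`tau_growth * epsilon_dot = 1` underlying the sensitivity normalization
holds exactly; an explicitly supplied elongation rate is used verbatim.
The organ length is not part of the published calibration table; 20 mm is
a realistic coleoptile length and makes the modified growth time
`tau*_growth = tau_growth * R / (beta * L)` equal to 60 min, the value the
derived quantities here are built around. Where the memory time is
reported inconsistently elsewhere (13/15/20 min), the calibration value of
13 min is canonical in this package.

## Response metrics

The gravitropic sensitivity is

    beta_tilde = R * max(d theta_tip / dt) / (sin(theta_incl) * epsilon_dot * L),

with the maximum tip-angle slope taken over the first rising phase of the
counter-bending response (centered finite differences, windowed to times
before the response's first maximum; an optional Savitzky-Golay filter is
applied first for noisy input). Dose-response curves evaluate
`beta_tilde` over a list of stimulation durations; "permanent" stimuli
are represented as at least 100 memory times and `inf` is accepted.

Four asymptotic regimes partition the (avalanche time, stimulation
duration) plane:

- **memory-limited dose** (`tau_aval < tau_memory`, `dt < tau_memory`):
  `beta_tilde ~ beta * dt / tau_memory`, gravity-independent;
- **saturated sine law** (long stimulus, avalanche faster than bending):
  `beta_tilde ~ beta`;
- **avalanche-limited dose** (`tau_aval > tau_memory`, `dt < tau_aval`):
  `beta_tilde ~ beta * dt / tau_aval`, gravity-dependent;
- **growth-limited** (`tau_aval > tau*_growth`,
  `dt > sqrt(tau*_growth * tau_aval)`):
  `beta_tilde ~ beta * sqrt(tau*_growth / tau_aval)`.

The growth-limited plateau expression is typeset ambiguously in print; it
was resolved here numerically from the full model and from the sinusoidal
solution of the tip-angle reduction, both of which give the square-root
form. Regime labels use factor-of-1 inequalities with ties broken toward
the dose regimes, and a boundary flag marks cells within a factor of 2 of
any bounding inequality of their regime, where no single asymptotic
formula is accurate. The crossover gravities `g = tau_aval_ref/tau_memory`
(= 0.08 for the defaults) and `tau_aval_ref/tau_growth` (= 8.7e-4) mark
where lowering gravity hands control of the dose-response to the
avalanche and to growth respectively.

### Accuracy of the asymptotic formulas at the calibrated point

Two quantitative caveats, both measured with this package and worth
knowing before comparing the full model against the asymptotes:

- The memory-dose slope `beta/tau_memory` is approached only when
  `tau_aval << dt`. At the calibrated `tau_aval = 1.04 min` the avalanche
  tail spreads the delivered dose over roughly `2 * tau_aval`, lowering
  the filtered signal peak; the small-`dt` slope of the dose curve then
  sits ~16% below `beta/tau_memory`. Two decades of separation
  (`tau_aval_ref ~ 0.02 min`) bring the agreement to ~2%.
- For the same reason the 1g and 3g dose curves differ by up to ~6% at
  the shortest stimulations (3 min) under the calibrated parameters; with
  `tau_aval` two decades below `tau_memory` they coincide within 2%.
- The permanent-inclination plateau evaluates to `beta_tilde = 0.729` for
  the calibrated set rather than `beta = 0.8` exactly: the memory lag
  (13 min) is not negligible against the bending time (60 min), so the
  signal peaks only after the tip has already realigned part-way. The
  identity `beta_tilde -> beta` is recovered as `tau_memory -> 0`.

## The tip-angle reduction

Assuming homogeneous curvature (`C ~ theta_tip / L`) collapses the
spatial fields to three scalars at the tip (`simulate_tip_reduced`); this
is the reduction behind all four asymptotic formulas. In the
growth-limited limit with fast memory it yields the oscillation
`theta_tip = theta_incl * cos(t / sqrt(tau*_growth * tau_aval))`. Two of
its error terms matter and are covered by tests:

- the reduction itself carries damping `exp(-t/(2*tau_aval))` that the
  undamped cosine ignores; at `tau_aval = 100 * tau*_growth` this alone
  is ~14% by the half-period, so the 5% cosine check is run at
  `tau_aval = 1000 * tau*_growth`;
- the full spatial model departs from the reduction once bending is
  large, because the restoring signal follows the organ's mean
  inclination, which lags the tip (the full model overshoots). Agreement
  with the cosine is therefore asserted for the full model only over the
  first quarter-period (10%), and the sensitivity — which is read off
  during the first rising phase — still lands within a factor 2 of the
  asymptote deep inside every regime (verified cell by cell).

## Numerics

- Fixed-step classical RK4 for all initial-value problems; the default
  step is `min(tau_aval, tau_memory)/20`, shortened so an integer number
  of steps spans the reaction delay (this puts the delay on the output
  grid and makes the detected onset exact for noiseless data).
- The delay term is handled by a ring buffer of past pile-angle fields
  with linear interpolation at `t - tau_reaction`; history before t = 0
  is the settled vertical equilibrium (all fields zero). Stage times of
  the RK4 scheme read the buffer at their own delayed times.
- Spatial discretization: 64 nodes on [0, L] by default (32 in some
  fitting loops), curvature-to-angle by cumulative trapezoid. Refinement
  (dt/2, 2x nodes) moves the calibrated transient trajectory by < 1% in
  sup norm.
- Base-angle changes are instantaneous steps evaluated at RK4 stage
  times; a step falling inside an integration step is resolved to within
  one step (default 0.052 min).
- Field blow-up (non-finite values or runaway angles) raises a
  `NumericalStabilityError` naming the offending step size.
- Simulation horizons for response metrics are chosen from the time
  scales (`10*tau_memory + pi*sqrt(tau*_growth*tau_aval) + 5*min(tau_aval,
  tau*_growth) + 2*tau*_growth` past the stimulus) so the first response
  maximum is always inside the window; stimulations longer than 100
  memory times beyond that horizon are truncated, which cannot affect the
  first rising phase.

## Calibration procedures

- **Avalanche time**: nonlinear least squares of the saturating
  exponential `A_stato = A_stem * (1 - exp(-t/tau))` (log-scale
  parameter, initial guess from a log-linear regression on `psi(t)`).
  The exponential is a surrogate for the sine relaxation: fitted to
  sine-ODE data at 45 degrees it is biased by about +4%, a model mismatch
  the tests quantify rather than hide. Flat traces are flagged
  non-converged.
- **Reaction delay**: first time the absolute bending rate exceeds a
  threshold persistently (two consecutive samples by default). On
  noiseless model output with a vanishing threshold this is exact,
  because the response is identically zero before the delay. The default
  threshold, 5% of the peak rate, assumes the rate estimate's noise floor
  is below that; for noisy cohorts the caller should pass a threshold
  above the floor (`noise_sd * sqrt(2) / (2 * sampling_interval)` per the
  centered-difference propagation), and detected onsets are then biased
  late by the time the true rate needs to reach the threshold.
- **Dose-response refit**: least squares on (log beta, log tau_memory),
  re-simulating the full model over the curve's durations at every
  residual evaluation; three starts with log-spaced memory times,
  parameter tolerance 1e-8. Curves whose shortest duration already sits
  on the plateau leave the memory time unconstrained; this degeneracy is
  flagged, not silently absorbed.

## Synthetic data

The generator emulates the two experimental assays: cohorts of tip-angle
trajectories under transient inclination (default 12 plants, in the 9-27
range of the experiments, sampled every 5 min) and cohorts of statolith
pile-angle relaxations (default ~10 cells). Plant-to-plant variability is
multiplicative log-normal jitter (unit mean, default CV 10%) on the gain
and the three physiological time scales — log-normal so all time scales
stay positive. Measurement error is additive i.i.d. Gaussian noise on the
extracted angles, default sd 2 degrees, typical of skeleton-based angle
extraction; the source experiments do not quantify either spread, so
these are conventions recorded in every dataset's metadata. Identical
seeds give bitwise-identical datasets.

What the generator does not emulate: the slow logarithmic creep of the
pile surface after the initial avalanche (only the viscous relaxation law
is modelled), image-level artifacts, circumnutation, temporally
correlated tracking errors, and any gravity dependence of the biochemical
time scales. Passing recovery tests therefore demonstrate estimator
correctness under the model's own assumptions, not robustness to those
unmodelled features.

## Known limitations

- No proprioception: the slow return-to-vertical phase of real
  coleoptiles is faster than the model's, as expected when curvature
  sensing is omitted; only the first rising phase is quantitative.
- The exponential avalanche fit inherits the ~4% surrogate bias above.
- Onset detection from noisy, coarsely sampled cohorts is
  threshold-limited. At 2 degrees of noise and 5-min sampling the rate
  estimate's noise floor (~0.28 deg/min) is comparable to the peak rate
  (~0.5 deg/min for a 20-min stimulus), so any false-alarm-safe
  threshold crosses late: detected onsets lag the true delay by up to
  about one memory time, and even the cohort minimum lands near 20-25
  min for a 13-min delay. Recovering the delay to within one sampling
  interval at this SNR requires either lower noise, denser sampling, or
  model-based fitting rather than threshold detection.
- Elongation is frozen within a window; protocols much longer than a few
  hours leave the model's domain of validity.
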