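# Methods

## Model and assumptions

Titratable acidity `N` (% lactic acid, w/w) is treated as the ripening
index of packaged kimchi.  Its growth follows a Baranyi–Roberts system in
which the physiological state `Q` gates growth through the adjustment
factor `α(t) = Q/(1+Q)`:

    dN/dt = α(t) · μmax(T) · (1 − N/Nmax) · N
    dQ/dt = μmax(T) · Q

The model assumes (i) a single pooled acidification process (no explicit
microbial community dynamics), (ii) temperature affects only `μmax` and
`Nmax`, (iii) at constant temperature `Nmax` is constant in time, and
(iv) acidity never falls — de-acidification is outside the model.

**Units.** All rates are per day, all times in days, temperatures in °C.
This convention is load-bearing: the reference constants are only
meaningful on the day scale.

**Reference constants** (packaged as `reference_parameters()`, calibrated
for commercial napa-cabbage kimchi on 0–20 °C):

| constant | value | meaning |
|---|---|---|
| a0 | 7.09e-2 | μmax at 0 °C (1/day) |
| a1 | 1.52e-2 | linear μmax coefficient (1/(day·°C)) |
| a2 | 2.33e-3 | quadratic μmax coefficient (1/(day·°C²)) |
| Q0 | 3.70e-7 | initial physiological state (dimensionless) |
| Nmax_intercept | 8.78e-1 | plateau at 0 °C (%) |
| Nmax_slope | 1.60e-2 | plateau slope (%/°C) |

With these values the implied lag `ln(1/Q0)/μmax` is ≈11 d at 20 °C and
≈209 d at 0 °C.  That is a property of the constants themselves, not of the
implementation; consumers of the reference parameter set should be aware
that day-scale lags dominate short fluctuating-storage horizons (see
*Limitations*).

## Numerics

**Constant-temperature solution.**  With `μ` and `Nmax` fixed, `Q(t) =
Q0·e^{μt}` and the system collapses to logistic growth in the transformed
time `τ(t) = ln((1+Q0·e^{μt})/(1+Q0))/μ`:

    N(t) = Nmax / (1 + (Nmax/N0 − 1)·e^{−μ·τ(t)})

`τ` is evaluated with `logaddexp`, so `e^{μt}` never overflows and the
asymptote `τ → t − ln((1+Q0)/Q0)/μ` is reached exactly.  This closed form
is both the test oracle for the integrators and the fast path of the MKT
inversion and the fitting objective.  `N0 > Nmax` is admitted (the solution
relaxes down toward the plateau), which the dynamic simulators rely on.

**ODE integration** (constant-T and instantaneous-Nmax simulators) uses
adaptive explicit Runge–Kutta (`solve_ivp`, RK45) with rtol 1e-8 and atol
1e-10 — tight enough that the 1e-6 % oracle-agreement bound is a statement
about correctness, not solver noise.  `Q` is integrated as `log Q` (its ODE
is then trivially linear), avoiding overflow; where trajectories export
`Q = exp(log Q)`, saturation to `inf` deep in the stationary phase is
accepted as the honest limit.  Piecewise-constant profiles are integrated
segment by segment with state carried across breakpoints, and the output
grid is the union of the requested grid and the breakpoints.

**MKT estimation** inverts the monotone map `T ↦ N(t; T)` with Brent root
bracketing (tolerance 0.005 °C, reported to ±0.01 °C) over the profile's
[min, max] temperature; monotonicity is asserted on a 5-point grid at each
call.  Targets outside the achievable interval clamp to the nearer bracket
end with a warning.  While the acidity is within 1e-6 % of `N0` the
inversion is degenerate; the MKT is then defined as the running
time-average of the profile temperature, which equals the initial
temperature at t = 0 and hands over continuously once acidity moves.  A
small discontinuity at handover is possible and accepted.

**MKT dynamic stepping.**  The MKT is refreshed at every grid point
(default step 1 h; the grid also includes every profile breakpoint) and
held within the step, together with `Nmax(T_MKT)`.  Within a step all
coefficients are constant, so the update is the *exact*
constant-coefficient solution (Q advances analytically; N is logistic in
the step's transformed time) — the only discretisation error is the MKT
refresh interval.  Halving the step changes the final acidity by <1e-4 %.

**μmax source in the MKT model.**  Only the plateau needs the MKT to stay
monotone; the growth rate may follow either the instantaneous temperature
(default, `mu_source="instantaneous"`) or the MKT
(`mu_source="mkt"`).  Both variants are monotone; they differ by ~1e-3 %
on square-wave runs.  The default follows the view that the rate is a local
property of the current temperature while the plateau reflects the
integrated history.

## Calibration

All six constants plus one initial acidity per experiment are estimated
jointly by minimising the unweighted sum of squared acidity residuals
against the constant-temperature closed form, pooled over temperatures and
experiments.  `q0` is optimised as `log10 q0` in [−10, −2] because its
likelihood surface spans orders of magnitude.  Bounds: a0, a1, a2 ∈ [0, 5];
Nmax_intercept ∈ [0.1, 3] %; Nmax_slope ∈ [0, 0.2] %/°C; N0 ∈ [0.05, 0.6] %.

The optimiser is two-stage: seeded differential evolution (population 60,
up to 200 generations, convergence tolerance 1e-8, no internal polish)
followed by bounded trust-region least squares started from the **five
best population members**, keeping the lowest-RSS refinement.  The
multi-start polish matters: from a single start roughly one seeded
replicate in twenty lands in a local minimum (RSS ~10 instead of ~0.1)
where the plateau parameters degenerate.  Identical data and seed give
bit-identical results.

95 % confidence intervals are linearised by default
(`cov = s²(JᵀJ)⁻¹`, Student-t quantiles, `q0` handled in log10 space so
its interval is asymmetric and wide — spanning an order of magnitude under
realistic noise, reflecting genuine weak identifiability of the lag), with
a seeded residual-resampling bootstrap as option and as automatic fallback
when `JᵀJ` is ill-conditioned.  Fewer than two constant temperatures raises
an identifiability error: the secondary models cannot be separated from the
primary ones.

## Synthetic data

The generator emulates the calibration study's design: three seasonal
experiments with initial acidities drawn uniformly from [0.20, 0.30] %
(anchored to the reported ≈0.24 % starting acidity), constant storage at
0/5/10/20 °C, square-wave fluctuating profiles (0↔10 °C for 20 d and
5↔15 °C for 14 d, switching every 24 h — `interval_h` is the dwell per
level, so one full cycle is two segments), and additive Gaussian noise on
acidity with sd 0.03 % truncated at a 0.01 % floor.  The noise magnitude is
a stand-in — the titration assay's true error is unreported — chosen to
match typical replicate scatter in published acidity curves.

**Sampling horizons** per constant temperature default to the time at which
the *generating model* covers 99 % of the span `N0 → Nmax(T)`
(≈288/100/46/16 d at 0/5/10/20 °C with the reference constants), so every
series spans lag, exponential and stationary phases and all six constants
are identifiable.  Real studies use shorter horizons; the defaults here are
a property of the generating constants, whose long lags would otherwise
leave the cold series flat and the recovery exercise meaningless.

What the generator does *not* emulate: seasonal differences beyond `N0`,
correlated (drifting) titration error, temperature-logger noise in the
constant-temperature conditions, package CO₂ effects, or any
de-acidification.  Passing recovery tests therefore show that the
calibration machinery is correct and well-conditioned under the stated
design, not that the model captures every feature of real storage data.

## Design choices that were genuinely open

* **Interpolation for validation:** predictions are interpolated linearly
  from the trajectory's own grid onto observation times; no pairing rule is
  standard.
* **MKT refresh cadence:** refreshed every grid step (hourly by default)
  rather than only at observation times; continuous refresh is the natural
  limit of the definition and is what the grid-convergence test probes.
* **Extrapolation policy:** secondary models evaluated outside 0–20 °C warn
  and compute rather than raise, because logger data wander outside the
  calibrated range in practice.
* **`interval_h` naming:** square waves are parameterised by dwell per
  level (24 h), matching how alternating storage regimes are described in
  validation studies.

## Limitations

* With the reference constants, short fluctuating-storage horizons
  (≤20 d) sit inside the lag phase: acidity barely moves, the
  instantaneous-Nmax artefact cannot yet manifest, and the MKT is mostly
  the degenerate time-average.  The behavioural contrast between the
  dynamic schemes is therefore demonstrated on longer runs (≈160 d) where
  the system actually passes its plateau.
* The MKT inversion assumes `N(t; T)` is increasing in `T`, which holds
  when both secondary models increase with temperature (true on 0–20 °C
  for the reference constants); profiles spanning a non-monotone region
  would make the MKT ill-posed, and the startup check raises in that case.
* `Af`/`Bf` summarise multiplicative error only; no RMSE/R² are provided.
* No pH, colour, texture, microbial-count or sensory modelling; acidity is
  the single quality index.
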