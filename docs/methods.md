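# Methods

## Model representation

Each model is a declarative `ModelSpec` holding three synchronized views
of the same dynamics: per-variable signed drift terms (used by the ODE and
Euler backends), a stochastic event decomposition (used by the Gillespie
backend), and human-readable formula strings (used by `describe` and as
the source for the compiled stochastic kernel). The logistic growth term
g·B·(1−B/Bmax) is split into two events — a birth at propensity g·B and a
density-dependent death at g·B²/Bmax — so both propensities remain
nonnegative even when B exceeds the carrying capacity; no single-event
decomposition of a logistic term has that property. The test suite
enforces the consistency invariant that, at any nonnegative state, the
propensity-weighted sum of state changes equals the drift to 10⁻¹²
relative tolerance.

Initial conditions (B, I), rate parameters, and time settings (tstart,
tfinal, dt) share one flat, validated namespace, mirroring the simulator
call signatures users of this kind of teaching software expect. Validation
rejects negative values, nonpositive dt or Bmax, and tfinal ≤ tstart, and
names the offending field.

The two shipped models differ only in the immune activation term (r·B·I
vs r·B·I/(s+B)) and in the defaults of r and s. The saturated form changes
the units of r from 1/(abundance·time) to 1/time; the default r jumps from
10⁻³ to 10³ accordingly so the immune response is still triggered at a
comparable strength. The package documents this unit change but makes no
attempt to reconcile the two parameterizations.

## Backends and numerical choices

**ODE.** `scipy.integrate.solve_ivp` with RK45 at rtol 10⁻⁸ / atol 10⁻¹⁰,
evaluated on the fixed output grid. At these tolerances the solver
over-resolves the dynamics, so dt is purely an output grid, not an
accuracy knob. Values driven below zero by solver round-off are clamped to
zero; anything below −10⁻⁶ raises an error rather than being masked.

**Discrete.** Plain forward Euler with the dt setting as the update step.
A step that overshoots below zero is clamped to zero and logged with the
step index: deterministic, visible, and it avoids silent blow-up of a
method deliberately kept simple enough to hand-check (the first default
step is B = 10 + 0.05·8.99899 = 10.4499495, I = 1 + 0.05·(−0.99) =
0.9505).

**Stochastic.** Exact SSA (Gillespie direct method) rather than
tau-leaping: exactness keeps the backend-consistency argument simple and
makes the trajectory a deterministic function of the seed. The inner loop
is compiled with numba; the propensity kernel is generated from the
events' formula strings and verified against the propensity callables on
random states at build time, so the compiled path cannot drift from the
declarative model. Non-integer initial conditions are rounded with a
warning. Sampling onto the output grid is last-event-carried-forward, and
if the total propensity hits zero the remaining grid is filled with the
absorbing state. Default-parameter runs from the printed initial state
take well under a second; the large-population regime (B=1000, I=100) is
heavy — the immune compartment grows to ~10⁶–10⁷ individuals, so a single
replicate to t=5 fires on the order of 10⁷ events.

**Grid.** The output grid is tstart, tstart+dt, …; the final point is
exactly tfinal when (tfinal−tstart)/dt is integral and otherwise the last
multiple below tfinal, avoiding a ragged final step.

## Exploration workflows

Outcome metrics are the maximum of a variable's series over the reported
grid (`peak`, the headline quantity) and the last reported value
(`final_value`, plumbing for equilibrium checks). Sweeps substitute one
grid value at a time into an otherwise fixed parameter set; runs share no
mutable state, so outcome order always matches value order and repeated
sweeps are bit-identical. Stochastic sweeps require exactly one seed per
grid point; replicate-averaged sweeps are out of scope. The two standard
experiments are the 20-point log-grid sweep of r over [10⁻⁵, 10⁻²]
(peak of B, non-increasing response) and of s over [10⁻³, 10³] on the
saturated model (peak of I, declining response; at s = 10¹² the activation
term vanishes and the peak equals the initial immune level to within
10⁻³).

## Reference computations (oracles)

Independent checks are implemented without calling the engine they test:
the closed-form logistic solution Bmax/(1+(Bmax/B0−1)e^(−g·t)) (the B
equation with dB = k = 0); the interior equilibrium B\* = dI/r,
I\* = (g(1−B\*/Bmax)−dB)/k derived once by hand and hard-coded (no root
finding), which is (1000, 890000) at the printed defaults and flagged
infeasible when I\* would be negative or r·k = 0; and a from-scratch
fixed-step classical RK4 integrator used to cross-check the adaptive
solver (agreement below 10⁻⁶ relative on the default model at a 10⁻³
substep).

**Convergence diagnostic.** The empirical order of the Euler backend is
measured on the error of the peak bacterial load relative to the ODE
backend across dt ∈ {0.05, 0.025, 0.0125}, giving successive orders of
about 1.01 and 1.02 on the default model. A whole-trajectory sup-norm is
deliberately not used at these step sizes: the default dynamics include a
sharp immune spike (I reaches ~1.6·10⁷, independently confirmed with an
R deSolve integration of the same equations), during which forward Euler
at dt = 0.05 leaves its stability region and triggers the negative-state
clamp, so a trajectory-wide norm there measures the clamping artifact
rather than asymptotic convergence. The peak outcome — the quantity the
exploration workflows actually report — remains in the asymptotic regime
at the customary step sizes (sup-norm convergence is likewise clean, order
≈ 0.95, on any window ending before the spike, or at finer steps).

## Interfaces

Trajectories serialize to CSV with header `time,<variables>` at 17
significant digits (lossless for doubles); sweeps to a two-column CSV with
a `#` metadata line. Config files are YAML (JSON is accepted by the same
loader, being a YAML subset); precedence is flags > file > model defaults.
Plots (PNG, log-scaled) are side outputs and never required for success;
matplotlib runs on the Agg backend so everything is headless-safe.
Parameters used in a run are echoed to stderr at INFO level, suppressed by
`--quiet`. The app registry holds the two models whose equations are fully
specified here; adding a model requires one `ModelSpec` and one
`AppEntry`, with no engine changes.

## What the tests do and do not show

All checks run on the two shipped models: closed-form limits, dual-oracle
agreement, mean-field agreement of the SSA (100 replicates at B=1000,
I=100, mean B within 3 Monte-Carlo standard errors of the ODE at t = 1, 2,
5), sweep shapes, and reproducibility. These validate the numerics and the
contracts, not biological realism: the models are deliberately minimal
teaching abstractions (no explicit immune cell types, no delays, no
spatial structure), and parameters are in arbitrary abundance/time units.
Stiff systems, delay equations, tau-leaping, two-parameter sweeps, and
model fitting to data are out of scope.
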