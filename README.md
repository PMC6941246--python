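# withinhost

A scriptable toolkit for simulating within-host bacterial infection and
immune response dynamics. It is aimed at immunologists and modellers who
want to explore compartmental infection models — run them, change
parameters, and sweep a parameter over a grid while recording an outcome
such as peak bacterial load — without writing simulation code themselves.

## The models

The toolkit ships two predator–prey-type compartmental models tracking a
bacterial load *B* and an immune response level *I* (both in arbitrary
abundance units; the time unit is set by the units chosen for the rate
parameters).

**Basic bacteria model**

dB/dt = g·B·(1 − B/B<sub>max</sub>) − d<sub>B</sub>·B − k·B·I
dI/dt = r·B·I − d<sub>I</sub>·I

Bacteria grow logistically at rate *g* toward carrying capacity
*B*<sub>max</sub>, die naturally at rate *d*<sub>B</sub>, and are killed by
the immune response at rate constant *k*. The immune response is activated
in proportion to both populations (rate constant *r*) and decays at rate
*d*<sub>I</sub>. Defaults: B=10, I=1, g=1, B<sub>max</sub>=10⁵,
d<sub>B</sub>=0.1, k=10⁻⁶, r=0.001, d<sub>I</sub>=1, simulated over
t ∈ [0, 30] with output step dt=0.05.

**Saturating immune activation variant**

dI/dt = r·B·I/(s + B) − d<sub>I</sub>·I

Immune activation grows proportionally to the bacterial load while
*B* ≪ *s*, and saturates at the fixed maximum per-capita rate *r* once
*B* ≫ *s*. Defaults change to r=10³ and s=10³ (note *r* switches units
from 1/(abundance·time) to 1/time between the two models).

Each model is declared once — variables, signed drift terms, and a
stochastic event decomposition — and can be run through three
interchangeable backends:

* `ode` — adaptive Runge–Kutta integration (rtol 10⁻⁸, atol 10⁻¹⁰), with
  dt acting purely as the output grid;
* `discrete` — forward Euler, x(t+dt) = x(t) + dt·f(x(t));
* `stochastic` — exact Gillespie stochastic simulation over the event
  decomposition, sampled onto the dt grid.

## Worked example

```python
from withinhost import (
    make_basic_bacteria_model, resolve_parameters, simulate,
    peak, sweep, log_grid,
)

model = make_basic_bacteria_model()
params = resolve_parameters(model, {"g": 0.5, "r": 0.002})
traj = simulate(model, params, backend="ode")
print(f"peak bacterial load: {peak(traj, 'B'):.1f}")
print(f"final immune level:  {traj['I'][-1]:.3f}")

result = sweep(model, resolve_parameters(model), "r",
               log_grid(-5, -2, 20), metric="peak", variable="B")
print(f"Bpeak at r=1e-5: {result.outcomes[0]:.0f}")
print(f"Bpeak at r=1e-2: {result.outcomes[-1]:.0f}")
```

prints

```
peak bacterial load: 5364.2
final immune level:  15.058
Bpeak at r=1e-5: 90000
Bpeak at r=1e-2: 1648
```

Halving the growth rate and doubling the activation rate caps the outbreak
at a peak load of ~5·10³ instead of ~1.7·10⁴ under the defaults. The sweep
reproduces the classic response curve: the weaker the immune activation
rate, the closer the peak load gets to the ~9·10⁴ level set by growth and
death alone, while strong activation suppresses the peak by almost two
orders of magnitude.

The same workflows are available from the shell:

```sh
withinhost list                             # show the registered models
withinhost describe basicbacteria          # equations, events, defaults
withinhost run -s g=0.5 -s r=0.002 -o run.csv --plot run.png
withinhost run -b stochastic --seed 1 -o ssa.csv
withinhost sweep -p r --lo -5 --hi -2 --n 20 --variable B -o rsweep.csv
```

`run` writes a `time,B,I` CSV (601 rows under the defaults); `sweep`
writes a two-column CSV of parameter value vs outcome. Settings can also
come from a YAML/JSON config file (`-c config.yaml`), with command-line
flags taking precedence.

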