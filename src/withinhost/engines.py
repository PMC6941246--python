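"""Simulation backends: continuous (ODE), discrete-time (Euler), stochastic (SSA).

All three share one call signature ``(spec, params[, seed])`` and return a
:class:`Trajectory` reported on the same fixed output grid
``tstart, tstart+dt, ...`` capped at ``tfinal``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .models import ModelSpec, ParameterSet

__all__ = [
    "Trajectory",
    "SimulationError",
    "time_grid",
    "simulate_ode",
    "simulate_discrete",
    "simulate_stochastic",
    "simulate",
    "BACKENDS",
]

logger = logging.getLogger(__name__)

# Deterministic trajectories may carry solver round-off slightly below zero;
# anything above this magnitude is clamped, anything below it is an error.
_NEG_TOL = 1e-6


class SimulationError(RuntimeError):
    """Raised when a backend produces a non-finite or invalid state."""


@dataclass(frozen=True)
class Trajectory:
    """Simulation output: a time grid plus one series per model variable."""

    times: np.ndarray
    series: Mapping[str, np.ndarray]
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, values in self.series.items():
            if len(values) != len(self.times):
                raise ValueError(
                    f"series {name} has {len(values)} points, "
                    f"expected {len(self.times)}"
                )

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.series)

    def __getitem__(self, variable: str) -> np.ndarray:
        try:
            return self.series[variable]
        except KeyError:
            raise KeyError(
                f"unknown variable {variable!r} (have: {', '.join(self.series)})"
            ) from None


def time_grid(params: Mapping[str, float]) -> np.ndarray:
    """Fixed output grid tstart, tstart+dt, ... capped at tfinal.

    The final point is exactly tfinal when (tfinal-tstart)/dt is integral;
    otherwise the grid stops at the last multiple below tfinal.
    """
    tstart, tfinal, dt = params["tstart"], params["tfinal"], params["dt"]
    n = int(math.floor((tfinal - tstart) / dt + 1e-9))
    return tstart + dt * np.arange(n + 1)


def _initial_state(spec: ModelSpec, params: Mapping[str, float]) -> np.ndarray:
    return np.array([params[v] for v in spec.variables], dtype=float)


def _clamp_deterministic(values: np.ndarray, backend: str) -> np.ndarray:
    low = values.min()
    if low < -_NEG_TOL:
        raise SimulationError(
            f"{backend} backend produced a negative state ({low:g}) beyond "
            "round-off tolerance"
        )
    return np.maximum(values, 0.0)


def simulate_ode(spec: ModelSpec, params: ParameterSet) -> Trajectory:
    """Integrate the drift equations with an adaptive Runge-Kutta solver.

    The solver runs at tolerances (rtol=1e-8, atol=1e-10) that over-resolve
    these dynamics, so ``dt`` acts purely as an output grid.
    """
    grid = time_grid(params)
    names = spec.variables
    p = dict(params)

    def rhs(t: float, y: np.ndarray) -> list[float]:
        state = dict(zip(names, y))
        d = spec.drift(state, p)
        return [d[v] for v in names]

    sol = solve_ivp(
        rhs,
        (grid[0], grid[-1]),
        _initial_state(spec, params),
        method="RK45",
        t_eval=grid,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        t_fail = sol.t[-1] if sol.t.size else grid[0]
        raise SimulationError(f"ODE solver failed near t = {t_fail:g}: {sol.message}")
    series = {
        v: _clamp_deterministic(sol.y[i], "ode") for i, v in enumerate(names)
    }
    return Trajectory(grid, series, {"backend": "ode", "params": dict(params)})


def simulate_discrete(spec: ModelSpec, params: ParameterSet) -> Trajectory:
    """Forward-Euler update x(t+dt) = x(t) + dt*drift(x(t)) on the dt grid.

    Negative intermediate results are clamped to zero and logged with the
    step index; this keeps the map deterministic and avoids silent blow-up.
    """
    grid = time_grid(params)
    names = spec.variables
    p = dict(params)
    dt = p["dt"]
    y = _initial_state(spec, params)
    out = np.empty((len(grid), len(names)))
    out[0] = y
    for step in range(1, len(grid)):
        state = dict(zip(names, y))
        d = spec.drift(state, p)
        y = y + dt * np.array([d[v] for v in names])
        if not np.all(np.isfinite(y)):
            raise SimulationError(
                f"discrete backend produced a non-finite state at step {step}"
            )
        if (y < 0).any():
            logger.warning(
                "discrete backend clamped negative state to 0 at step %d (t=%g)",
                step,
                grid[step],
            )
            y = np.maximum(y, 0.0)
        out[step] = y
    series = {v: out[:, i].copy() for i, v in enumerate(names)}
    return Trajectory(grid, series, {"backend": "discrete", "params": dict(params)})


def _compile_propensities(spec: ModelSpec):
    """Compile the event propensities into a numba kernel.

    The kernel source is generated from the events' declarative formula
    strings (plain Python arithmetic over the model's variable and
    parameter names) and is verified against the propensity callables on a
    handful of random nonnegative states before use, so the two
    representations cannot silently drift apart.
    """
    import numba

    names = spec.variables
    pnames = tuple(
        n for n in spec.defaults if n not in names and n not in ("tstart", "tfinal", "dt")
    )
    lines = ["def _props(y, c, a):"]
    for i, v in enumerate(names):
        lines.append(f"    {v} = y[{i}]")
    for i, n in enumerate(pnames):
        lines.append(f"    {n} = c[{i}]")
    for j, ev in enumerate(spec.events):
        lines.append(f"    a[{j}] = {ev.formula}")
    namespace: dict[str, object] = {}
    exec("\n".join(lines), namespace)  # noqa: S102 - source built from own formulas
    kernel = numba.njit(cache=False)(namespace["_props"])

    # cross-check against the callables before trusting the kernel
    rng = np.random.default_rng(12345)
    c = np.array([spec.defaults[n] for n in pnames])
    a = np.empty(len(spec.events))
    for _ in range(5):
        y = rng.uniform(0, 1e4, size=len(names))
        kernel(y, c, a)
        state = dict(zip(names, y))
        p = dict(zip(pnames, c))
        for j, ev in enumerate(spec.events):
            expected = ev.propensity(state, p)
            if not math.isclose(a[j], expected, rel_tol=1e-12, abs_tol=1e-12):
                raise SimulationError(
                    f"compiled propensity for event {ev.name!r} disagrees "
                    f"with its formula ({a[j]!r} vs {expected!r})"
                )
    stoich = np.zeros((len(spec.events), len(names)), dtype=np.int64)
    for j, ev in enumerate(spec.events):
        for v, delta in ev.changes.items():
            stoich[j, names.index(v)] = delta
    return kernel, pnames, stoich


_KERNEL_CACHE: dict[tuple, tuple] = {}


def _kernel_for(spec: ModelSpec):
    key = (spec.id, tuple(ev.formula for ev in spec.events))
    if key not in _KERNEL_CACHE:
        _KERNEL_CACHE[key] = _compile_propensities(spec)
    return _KERNEL_CACHE[key]


_SSA_DRIVER = None


def _ssa_driver():
    """Gillespie direct-method inner loop, jitted once per propensity kernel."""
    global _SSA_DRIVER
    if _SSA_DRIVER is not None:
        return _SSA_DRIVER
    import numba

    @numba.njit(cache=False)
    def driver(props, stoich, y, c, grid, seed):  # pragma: no cover - jitted
        np.random.seed(seed)
        n_grid = grid.shape[0]
        n_var = y.shape[0]
        n_ev = stoich.shape[0]
        out = np.empty((n_grid, n_var))
        a = np.empty(n_ev)
        t = grid[0]
        tfinal = grid[-1]
        idx = 0
        while t < tfinal:
            props(y, c, a)
            total = 0.0
            for j in range(n_ev):
                if a[j] < 0.0:
                    raise ValueError("negative propensity in stochastic simulation")
                total += a[j]
            if total == 0.0:
                break  # absorbing state; remaining grid filled below
            t_next = t - np.log(1.0 - np.random.random()) / total
            cap = t_next if t_next < tfinal else tfinal
            while idx < n_grid and grid[idx] <= cap:
                for v in range(n_var):
                    out[idx, v] = y[v]
                idx += 1
            if t_next > tfinal:
                t = t_next
                break
            target = np.random.random() * total
            acc = 0.0
            fired = n_ev - 1
            for j in range(n_ev):
                acc += a[j]
                if target < acc:
                    fired = j
                    break
            for v in range(n_var):
                y[v] += stoich[fired, v]
            t = t_next
        while idx < n_grid:
            for v in range(n_var):
                out[idx, v] = y[v]
            idx += 1
        return out

    _SSA_DRIVER = driver
    return driver


def simulate_stochastic(
    spec: ModelSpec, params: ParameterSet, seed: int
) -> Trajectory:
    """Exact stochastic simulation (Gillespie direct method).

    Events fire one at a time with exponential waiting times; the state is
    sampled onto the dt grid with last-event-carried-forward.  If the total
    propensity reaches zero the remaining grid is filled with the absorbing
    state.  Identical seed and parameters give identical trajectories.
    """
    grid = time_grid(params)
    names = spec.variables
    y0 = _initial_state(spec, params)
    rounded = np.rint(y0)
    if not np.array_equal(rounded, y0):
        warnings.warn(
            "stochastic backend rounded non-integer initial conditions "
            f"{dict(zip(names, y0))} to integers",
            stacklevel=2,
        )
    kernel, pnames, stoich = _kernel_for(spec)
    c = np.array([params[n] for n in pnames])
    driver = _ssa_driver()
    try:
        out = driver(kernel, stoich, rounded.copy(), c, grid, int(seed) % 2**32)
    except ValueError as exc:
        raise SimulationError(str(exc)) from exc
    series = {v: out[:, i].copy() for i, v in enumerate(names)}
    return Trajectory(
        grid,
        series,
        {"backend": "stochastic", "seed": int(seed), "params": dict(params)},
    )


BACKENDS = {
    "ode": simulate_ode,
    "discrete": simulate_discrete,
    "stochastic": simulate_stochastic,
}


def simulate(
    spec: ModelSpec,
    params: ParameterSet,
    backend: str = "ode",
    seed: int | None = None,
) -> Trajectory:
    """Dispatch to a backend by id (``ode``, ``discrete``, ``stochastic``)."""
    if backend not in BACKENDS:
        raise ValueError(
            f"unknown backend {backend!r} (known: {', '.join(BACKENDS)})"
        )
    if backend == "stochastic":
        if seed is None:
            raise ValueError("the stochastic backend requires a seed")
        return simulate_stochastic(spec, params, seed)
    return BACKENDS[backend](spec, params)
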