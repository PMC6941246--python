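"""Outcome metrics and one-parameter sweeps.

The headline workflow: pick a parameter, lay a logarithmic grid over it,
run one simulation per grid value with everything else fixed, and record a
scalar outcome (the peak of a variable's time series, or its final value)
for each run — e.g. peak bacterial load as a function of the immune
activation rate, or peak immune response as a function of the saturation
constant.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .engines import Trajectory, simulate
from .models import ModelSpec, ParameterSet

__all__ = ["SweepResult", "peak", "final_value", "log_grid", "sweep", "METRICS"]


def peak(traj: Trajectory, variable: str) -> float:
    """Maximum of a variable's series over the reported grid."""
    return float(np.max(traj[variable]))


def final_value(traj: Trajectory, variable: str) -> float:
    """Last reported value of a variable (steady-state companion to peak)."""
    return float(traj[variable][-1])


METRICS = {"peak": peak, "final_value": final_value}


def log_grid(lo_exponent: float, hi_exponent: float, n: int) -> np.ndarray:
    """``n`` values ``10**e`` with ``e`` equally spaced over the exponent range."""
    if n < 1:
        raise ValueError("log_grid needs at least one point (empty grid)")
    if lo_exponent > hi_exponent:
        raise ValueError("lo_exponent must not exceed hi_exponent")
    return np.power(10.0, np.linspace(lo_exponent, hi_exponent, n))


@dataclass(frozen=True)
class SweepResult:
    """A swept parameter's grid paired with one outcome metric per value."""

    parameter: str
    values: np.ndarray
    metric: str
    variable: str
    outcomes: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.outcomes) != len(self.values):
            raise ValueError("outcomes and values must have equal length")
        if len(self.values) > 1 and not np.all(np.diff(self.values) > 0):
            raise ValueError("sweep values must be strictly increasing")


def sweep(
    spec: ModelSpec,
    base: ParameterSet,
    parameter: str,
    values: Sequence[float],
    metric: str = "peak",
    variable: str | None = None,
    backend: str = "ode",
    seeds: Sequence[int] | None = None,
) -> SweepResult:
    """Run one simulation per grid value and record the chosen metric.

    Each run substitutes a single grid value for ``parameter`` into
    ``base``; all other inputs stay fixed.  Runs are independent (no shared
    mutable state), so outcome order always matches value order.  For the
    stochastic backend, ``seeds`` must supply one seed per grid point to
    keep the result reproducible.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r} (known: {', '.join(METRICS)})")
    if variable is None:
        variable = spec.variables[0]
    if variable not in spec.variables:
        raise ValueError(
            f"unknown variable {variable!r} (model has: {', '.join(spec.variables)})"
        )
    values = np.asarray(values, dtype=float)
    if backend == "stochastic":
        if seeds is None or len(seeds) != len(values):
            raise ValueError(
                "stochastic sweeps need exactly one seed per grid value"
            )
    metric_fn = METRICS[metric]
    outcomes = np.empty(len(values))
    for i, v in enumerate(values):
        try:
            params = base.replace(**{parameter: float(v)})
            seed = int(seeds[i]) if backend == "stochastic" else None
            traj = simulate(spec, params, backend=backend, seed=seed)
            outcomes[i] = metric_fn(traj, variable)
        except Exception as exc:
            raise RuntimeError(
                f"sweep failed at {parameter} = {v:g}: {exc}"
            ) from exc
    meta: dict[str, object] = {
        "model": spec.id,
        "backend": backend,
        "base": dict(base),
    }
    if seeds is not None:
        meta["seeds"] = [int(s) for s in seeds]
    return SweepResult(parameter, values, metric, variable, outcomes, meta)
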