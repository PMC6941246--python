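"""Tabular output, configuration files, and plotting.

Trajectories and sweep results are written as plain CSV at full double
precision; run configurations are YAML (JSON, being a YAML subset, is
accepted by the same loader).  Plots are side outputs and headless-safe.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .engines import Trajectory
from .explore import SweepResult

__all__ = [
    "RunConfig",
    "load_config",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_sweep_csv",
    "plot_trajectory",
    "plot_sweep",
]

# shortest decimal representation that round-trips a double
_FMT = "{:.17g}"


def _fnum(x: float) -> str:
    return _FMT.format(float(x))


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV: header ``time`` then the variables."""
    if not traj.series:
        raise ValueError("trajectory has no variables; at least one required")
    path = Path(path)
    names = list(traj.series)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", *names])
        columns = [traj.series[v] for v in names]
        for i, t in enumerate(traj.times):
            writer.writerow([_fnum(t), *(_fnum(col[i]) for col in columns)])


def read_trajectory_csv(path: str | Path) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory_csv`.

    Malformed rows raise ValueError carrying the 1-based line number.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: line 1: empty file") from None
        if not header or header[0] != "time" or len(header) < 2:
            raise ValueError(
                f"{path}: line 1: expected header 'time,<variables>', got {header!r}"
            )
        names = header[1:]
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(row)}"
                )
            try:
                rows.append([float(x) for x in row])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric value in {row!r}"
                ) from None
    data = np.asarray(rows, dtype=float).reshape(len(rows), len(header))
    series = {v: data[:, i + 1].copy() for i, v in enumerate(names)}
    return Trajectory(data[:, 0].copy(), series, {"source": str(path)})


def write_sweep_csv(result: SweepResult, path: str | Path) -> None:
    """Write a sweep as a two-column CSV with a ``#``-prefixed metadata header."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(
            f"# model={result.meta.get('model', '?')} "
            f"backend={result.meta.get('backend', '?')} "
            f"metric={result.metric} variable={result.variable}\n"
        )
        writer = csv.writer(fh)
        writer.writerow([result.parameter, f"{result.metric}_{result.variable}"])
        for v, y in zip(result.values, result.outcomes):
            writer.writerow([_fnum(v), _fnum(y)])


@dataclass(frozen=True)
class SweepBlock:
    """Sweep settings: parameter plus a log grid given by exponents."""

    parameter: str
    lo: float
    hi: float
    n: int
    metric: str = "peak"
    variable: str | None = None


@dataclass(frozen=True)
class RunConfig:
    """One run or sweep: model, backend, overrides, and output paths."""

    model: str = "basicbacteria"
    backend: str = "ode"
    overrides: Mapping[str, float] = field(default_factory=dict)
    seed: int | None = None
    sweep: SweepBlock | None = None
    out: str | None = None
    plot: str | None = None

    def merged(self, **updates: object) -> "RunConfig":
        """New config with non-None ``updates`` taking precedence."""
        current = {
            "model": self.model,
            "backend": self.backend,
            "overrides": dict(self.overrides),
            "seed": self.seed,
            "sweep": self.sweep,
            "out": self.out,
            "plot": self.plot,
        }
        for key, value in updates.items():
            if value is None:
                continue
            if key == "overrides":
                current["overrides"] = {**current["overrides"], **value}  # type: ignore[dict-item]
            else:
                current[key] = value
        return RunConfig(**current)  # type: ignore[arg-type]


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON) file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(raw).__name__}")
    known = {"model", "backend", "overrides", "seed", "sweep", "out", "plot"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config field {', '.join(sorted(unknown))}")
    sweep_block = None
    if raw.get("sweep") is not None:
        sb = raw["sweep"]
        if not isinstance(sb, dict):
            raise ValueError(f"{path}: sweep block must be a mapping")
        sweep_known = {"parameter", "lo", "hi", "n", "metric", "variable"}
        extra = set(sb) - sweep_known
        if extra:
            raise ValueError(
                f"{path}: unknown sweep field {', '.join(sorted(extra))}"
            )
        try:
            sweep_block = SweepBlock(
                parameter=sb["parameter"],
                lo=float(sb["lo"]),
                hi=float(sb["hi"]),
                n=int(sb["n"]),
                metric=sb.get("metric", "peak"),
                variable=sb.get("variable"),
            )
        except KeyError as exc:
            raise ValueError(f"{path}: sweep block missing field {exc}") from None
    overrides = raw.get("overrides") or {}
    if not isinstance(overrides, dict):
        raise ValueError(f"{path}: overrides must be a mapping")
    return RunConfig(
        model=raw.get("model", "basicbacteria"),
        backend=raw.get("backend", "ode"),
        overrides={k: float(v) for k, v in overrides.items()},
        seed=None if raw.get("seed") is None else int(raw["seed"]),
        sweep=sweep_block,
        out=raw.get("out"),
        plot=raw.get("plot"),
    )


def _agg():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Time-series plot of all variables on a log y-axis."""
    plt = _agg()
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, values in traj.series.items():
        ax.plot(traj.times, values, label=name)
    ax.set_xlabel("Time")
    ax.set_ylabel("Abundance")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sweep(result: SweepResult, path: str | Path) -> None:
    """Log-log scatter of outcome vs swept parameter value."""
    plt = _agg()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(result.values, result.outcomes, "o")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(result.parameter)
    ax.set_ylabel(f"{result.metric} of {result.variable}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
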