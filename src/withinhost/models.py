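"""Declarative compartmental model specifications.

A :class:`ModelSpec` describes a within-host model three ways at once:

* *drift terms* — signed rate expressions per variable, used by the
  continuous (ODE) and discrete-time (Euler) backends;
* *events* — a stochastic reaction decomposition (state-change vector plus
  propensity), used by the Gillespie backend;
* *string forms* — human-readable equations for ``describe`` output.

The two views must agree: for every variable, the signed sum of event
propensities times state changes equals the drift at any nonnegative state.
This backend-consistency invariant is enforced by the test suite.

Two concrete models are provided.  The basic bacteria model tracks a
bacterial load ``B`` growing logistically (rate ``g``, carrying capacity
``Bmax``), dying naturally (``dB``) and being killed by an immune response
``I`` (rate constant ``k``); the immune response is activated
proportionally to both populations (``r*B*I``) and decays (``dI``).  The
saturated variant replaces the activation term by ``r*B*I/(s+B)``: for
``B`` well below the saturation constant ``s`` the immune response grows at
a per-capita rate proportional to the bacterial load, while for ``B >> s``
it grows at the fixed maximum per-capita rate ``r``, independent of
bacterial load.  Note the units of ``r`` differ between the two models
(1/(abundance*time) vs 1/time), which is why the saturated variant ships a
much larger default ``r``; the package documents but does not reconcile
this.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from typing import Callable

__all__ = [
    "RateTerm",
    "Event",
    "ModelSpec",
    "ParameterSet",
    "ParameterError",
    "make_basic_bacteria_model",
    "make_saturated_immunity_model",
    "resolve_parameters",
]

State = Mapping[str, float]
Params = Mapping[str, float]
RateFn = Callable[[State, Params], float]

#: names that configure the time grid rather than the dynamics
TIME_SETTINGS = ("tstart", "tfinal", "dt")


class ParameterError(ValueError):
    """Raised for unknown parameter names or invariant violations."""


@dataclass(frozen=True)
class RateTerm:
    """One signed term of a drift equation.

    ``rate`` evaluates the term (sign included) given a state mapping and a
    parameter mapping; ``formula`` is the matching human-readable form.
    """

    formula: str
    rate: RateFn

    def __call__(self, state: State, params: Params) -> float:
        return self.rate(state, params)


@dataclass(frozen=True)
class Event:
    """A stochastic reaction: state-change vector plus propensity.

    ``changes`` maps variable names to integer increments; ``propensity``
    must be nonnegative for any componentwise-nonnegative state and
    nonnegative parameters.
    """

    name: str
    changes: Mapping[str, int]
    formula: str
    propensity: RateFn

    def __call__(self, state: State, params: Params) -> float:
        return self.propensity(state, params)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a compartmental dynamical model."""

    id: str
    variables: tuple[str, ...]
    defaults: Mapping[str, float]
    drift_terms: Mapping[str, tuple[RateTerm, ...]]
    events: tuple[Event, ...]
    title: str = ""

    @property
    def names(self) -> tuple[str, ...]:
        """All legal parameter-set names (flat namespace)."""
        return tuple(self.defaults)

    def drift(self, state: State, params: Params) -> dict[str, float]:
        """Evaluate the full drift (sum of signed terms) per variable."""
        return {
            var: sum(term(state, params) for term in self.drift_terms[var])
            for var in self.variables
        }

    def event_drift(self, state: State, params: Params) -> dict[str, float]:
        """Drift implied by the event decomposition (consistency check)."""
        out = dict.fromkeys(self.variables, 0.0)
        for ev in self.events:
            a = ev(state, params)
            for var, delta in ev.changes.items():
                out[var] += delta * a
        return out

    def describe(self) -> str:
        """Human-readable equations, defaults, and event table."""
        lines = [f"model {self.id}: {self.title}", "", "drift equations:"]
        for var in self.variables:
            rhs = " ".join(
                t.formula if i == 0 or t.formula.startswith("-") else f"+ {t.formula}"
                for i, t in enumerate(self.drift_terms[var])
            )
            lines.append(f"  d{var}/dt = {rhs}")
        lines.append("")
        lines.append("stochastic events (change : propensity):")
        for ev in self.events:
            change = ", ".join(f"{v}{d:+d}" for v, d in ev.changes.items())
            lines.append(f"  {ev.name:24s} {change:8s} : {ev.formula}")
        lines.append("")
        lines.append("defaults:")
        lines.append(
            "  " + ", ".join(f"{k} = {v:g}" for k, v in self.defaults.items())
        )
        return "\n".join(lines)


class ParameterSet(Mapping):
    """Validated flat mapping of initial conditions, rates and time settings.

    Mirrors the simulator call signatures where initial conditions (``B``,
    ``I``), rate parameters and time settings are peer arguments.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        self._values = dict(values)
        self._validate()

    def _validate(self) -> None:
        v = self._values
        for name, value in v.items():
            if not (value == value) or value in (float("inf"), float("-inf")):
                raise ParameterError(f"parameter {name} must be finite, got {value}")
            if value < 0:
                raise ParameterError(f"parameter {name} must be >= 0, got {value}")
        if "Bmax" in v and v["Bmax"] <= 0:
            raise ParameterError("Bmax must be > 0")
        if "dt" in v and v["dt"] <= 0:
            raise ParameterError("dt must be > 0")
        if "tstart" in v and "tfinal" in v and v["tfinal"] <= v["tstart"]:
            raise ParameterError(
                f"tfinal ({v['tfinal']}) must exceed tstart ({v['tstart']})"
            )

    # Mapping protocol -------------------------------------------------
    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        inner = ", ".join(f"{k}={v:g}" for k, v in self._values.items())
        return f"ParameterSet({inner})"

    def replace(self, **overrides: float) -> "ParameterSet":
        """Return a new set with ``overrides`` applied (names must exist)."""
        unknown = set(overrides) - set(self._values)
        if unknown:
            raise ParameterError(
                f"unknown parameter {', '.join(sorted(unknown))}"
            )
        return ParameterSet({**self._values, **overrides})


def resolve_parameters(
    spec: ModelSpec, overrides: Mapping[str, float] | None = None
) -> ParameterSet:
    """Merge ``overrides`` into ``spec`` defaults and validate.

    Raises :class:`ParameterError` for names not declared by the model or
    for values violating the invariants (negative values, ``dt <= 0``,
    ``tfinal <= tstart``).
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - set(spec.defaults)
    if unknown:
        raise ParameterError(
            f"unknown parameter {', '.join(sorted(unknown))} "
            f"(known: {', '.join(spec.defaults)})"
        )
    return ParameterSet({**spec.defaults, **overrides})


def _basic_drift_terms() -> dict[str, tuple[RateTerm, ...]]:
    return {
        "B": (
            RateTerm("g*B*(1-B/Bmax)", lambda x, p: p["g"] * x["B"] * (1 - x["B"] / p["Bmax"])),
            RateTerm("- dB*B", lambda x, p: -p["dB"] * x["B"]),
            RateTerm("- k*B*I", lambda x, p: -p["k"] * x["B"] * x["I"]),
        ),
        "I": (
            RateTerm("r*B*I", lambda x, p: p["r"] * x["B"] * x["I"]),
            RateTerm("- dI*I", lambda x, p: -p["dI"] * x["I"]),
        ),
    }


def _basic_events() -> tuple[Event, ...]:
    # Logistic growth is split into a birth and a density-dependent death
    # event so both propensities stay nonnegative even when B > Bmax.
    return (
        Event("bacteria birth", {"B": +1}, "g*B", lambda x, p: p["g"] * x["B"]),
        Event(
            "bacteria crowding death",
            {"B": -1},
            "g*B**2/Bmax",
            lambda x, p: p["g"] * x["B"] * x["B"] / p["Bmax"],
        ),
        Event("bacteria natural death", {"B": -1}, "dB*B", lambda x, p: p["dB"] * x["B"]),
        Event(
            "bacteria killed by immunity",
            {"B": -1},
            "k*B*I",
            lambda x, p: p["k"] * x["B"] * x["I"],
        ),
        Event("immune activation", {"I": +1}, "r*B*I", lambda x, p: p["r"] * x["B"] * x["I"]),
        Event("immune decay", {"I": -1}, "dI*I", lambda x, p: p["dI"] * x["I"]),
    )


def make_basic_bacteria_model() -> ModelSpec:
    """Basic bacteria / immune-response model.

    dB/dt = g*B*(1 - B/Bmax) - dB*B - k*B*I
    dI/dt = r*B*I - dI*I
    """
    return ModelSpec(
        id="basicbacteria",
        title="Basic bacteria and immune response model",
        variables=("B", "I"),
        defaults={
            "B": 10.0,
            "I": 1.0,
            "g": 1.0,
            "Bmax": 1e5,
            "dB": 0.1,
            "k": 1e-6,
            "r": 0.001,
            "dI": 1.0,
            "tstart": 0.0,
            "tfinal": 30.0,
            "dt": 0.05,
        },
        drift_terms=_basic_drift_terms(),
        events=_basic_events(),
    )


def make_saturated_immunity_model() -> ModelSpec:
    """Variant with saturating immune activation.

    dB/dt = g*B*(1 - B/Bmax) - dB*B - k*B*I
    dI/dt = r*B*I/(s + B) - dI*I

    The activation term saturates at per-capita rate ``r`` once the
    bacterial load exceeds the saturation constant ``s``; ``r`` here has
    units 1/time (vs 1/(abundance*time) in the basic model), hence the
    much larger default.
    """
    terms = _basic_drift_terms()
    terms["I"] = (
        RateTerm(
            "r*B*I/(s+B)", lambda x, p: p["r"] * x["B"] * x["I"] / (p["s"] + x["B"])
        ),
        terms["I"][1],
    )
    events = list(_basic_events())
    events[4] = Event(
        "immune activation",
        {"I": +1},
        "r*B*I/(s+B)",
        lambda x, p: p["r"] * x["B"] * x["I"] / (p["s"] + x["B"]),
    )
    return ModelSpec(
        id="basicbacteria_saturated",
        title="Bacteria model with saturating immune activation",
        variables=("B", "I"),
        defaults={
            "B": 10.0,
            "I": 1.0,
            "g": 1.0,
            "Bmax": 1e5,
            "dB": 0.1,
            "k": 1e-6,
            "r": 1e3,
            "dI": 1.0,
            "tstart": 0.0,
            "tfinal": 30.0,
            "dt": 0.05,
            "s": 1e3,
        },
        drift_terms=terms,
        events=tuple(events),
    )
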