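"""App registry: the package's menu of runnable models.

Adding a model means writing one :class:`~withinhost.models.ModelSpec`
factory and one :class:`AppEntry`; the engines need no changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .models import ModelSpec, make_basic_bacteria_model, make_saturated_immunity_model

__all__ = ["AppEntry", "get_app", "list_apps"]


@dataclass(frozen=True)
class AppEntry:
    """Registry record tying a model spec to descriptive text and backends."""

    id: str
    title: str
    overview: str
    make_spec: Callable[[], ModelSpec]
    backends: tuple[str, ...] = ("ode", "discrete", "stochastic")
    references: tuple[str, ...] = ()

    def spec(self) -> ModelSpec:
        return self.make_spec()


_APPS: tuple[AppEntry, ...] = (
    AppEntry(
        id="basicbacteria",
        title="Basic Bacteria Model",
        overview=(
            "Bacteria growing logistically, controlled by an immune response "
            "activated in proportion to bacterial load."
        ),
        make_spec=make_basic_bacteria_model,
        references=(
            "Predator-prey-type within-host dynamics; logistic pathogen growth.",
        ),
    ),
    AppEntry(
        id="basicbacteria_saturated",
        title="Bacteria Model with Saturating Immune Activation",
        overview=(
            "Same bacterial dynamics, but immune activation saturates at a "
            "maximum per-capita rate r once the load exceeds the constant s."
        ),
        make_spec=make_saturated_immunity_model,
        references=(
            "Michaelis-Menten-like saturation of immune activation.",
        ),
    ),
)

_BY_ID = {app.id: app for app in _APPS}


def list_apps() -> tuple[AppEntry, ...]:
    """All registered apps, in stable menu order."""
    return _APPS


def get_app(app_id: str) -> AppEntry:
    """Look up one app by id; raises KeyError listing known ids."""
    try:
        return _BY_ID[app_id]
    except KeyError:
        raise KeyError(
            f"unknown app {app_id!r} (known: {', '.join(_BY_ID)})"
        ) from None
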