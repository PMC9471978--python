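"""Fixed model parameters: transition probabilities, utilities, penalties.

The decision model compares elective repair of a symptomatic abdominal
hernia against nonoperative management in patients with cirrhosis, in
180-day Markov cycles.  All fixed per-cycle transition probabilities and
the utility structure live in :class:`ModelParameters`.

Utilities follow a two-level construction:

* base states accrue a per-cycle utility (``u_resolved`` for a resolved
  hernia; the symptomatic state takes a configurable fractional decrement
  from it; death accrues 0);
* transition states (incarceration, flood syndrome, elective surgery,
  emergent surgery, complicated recovery) each incur a one-time penalty
  expressed as a fraction of the best-health-state yearly utility
  ``u_best_yearly``.

Storing penalties as (anchor, fraction) pairs rather than raw decrements
lets sensitivity analyses vary the fractions directly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "PENALTY_EVENTS",
    "ModelParameters",
    "load_parameters",
    "symptomatic_utility",
    "transition_penalty",
]

#: Transition states that carry a one-time utility penalty.
PENALTY_EVENTS = (
    "incarceration",
    "flood",
    "elective_surgery",
    "emergent_surgery",
    "complicated_recovery",
)


def _default_penalty_fractions() -> dict[str, float]:
    # Fractional decrements from the best health state, one per
    # penalised transition state.
    return {
        "incarceration": 0.228,
        "flood": 0.429,
        "elective_surgery": 0.088,
        "emergent_surgery": 0.218,
        "complicated_recovery": 0.208,
    }


@dataclass
class ModelParameters:
    """All fixed inputs of the Markov cohort model.

    Defaults are the base-case values of the published decision model:
    per-cycle incarceration probability 0.071, successful reduction of an
    incarcerated hernia 0.333, flood syndrome (spontaneous rupture) 0.008,
    hernia recurrence after repair 0.01, resolved-hernia per-cycle utility
    0.324 with a 10% symptomatic decrement, 180-day cycles over a 10-cycle
    (~5 year) horizon, and MELD-Na drift of 0.75 points per cycle.

    ``u_best_yearly`` anchors the transition-state penalties; 0.65 is
    inferred from the ratio of each published penalty to its published
    fraction (see docs/methods.md) and may be overridden.
    """

    p_incarceration: float = 0.071
    p_reduction_success: float = 0.333
    p_flood: float = 0.008
    p_recurrence: float = 0.01
    u_resolved: float = 0.324
    symptomatic_decrement: float = 0.10
    u_best_yearly: float = 0.65
    penalty_fractions: dict[str, float] = field(
        default_factory=_default_penalty_fractions
    )
    cycle_days: float = 180.0
    n_cycles: int = 10
    meld_drift_per_cycle: float = 0.75
    meld_floor: float = 6.0
    meld_cap: float = 40.0

    def __post_init__(self) -> None:
        for name in (
            "p_incarceration",
            "p_reduction_success",
            "p_flood",
            "p_recurrence",
            "u_resolved",
            "symptomatic_decrement",
            "u_best_yearly",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        if set(self.penalty_fractions) != set(PENALTY_EVENTS):
            raise ValueError(
                "penalty_fractions must have exactly the keys "
                f"{sorted(PENALTY_EVENTS)}, got {sorted(self.penalty_fractions)}"
            )
        for event, frac in self.penalty_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"penalty_fractions[{event!r}]={frac!r} outside [0, 1]"
                )
        if self.p_incarceration + self.p_flood > 1.0:
            raise ValueError(
                "p_incarceration + p_flood exceeds 1; the within-cycle event "
                "split is multinomial"
            )
        if self.cycle_days <= 0:
            raise ValueError(f"cycle_days={self.cycle_days!r} must be positive")
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles={self.n_cycles!r} must be >= 1")
        if self.meld_floor > self.meld_cap:
            raise ValueError("meld_floor exceeds meld_cap")

    # -- derived quantities -------------------------------------------------

    @property
    def u_symptomatic(self) -> float:
        """Per-cycle utility of the symptomatic-hernia base state."""
        return symptomatic_utility(self.u_resolved, self.symptomatic_decrement)

    def penalty(self, event: str) -> float:
        """Signed one-time utility decrement for a transition state."""
        return transition_penalty(self.u_best_yearly, self.penalty_fractions[event])

    def yearly_utility(self, state: str) -> float:
        """Yearly utility of a live base state, used for the terminal payoff.

        Per-cycle utilities are rescaled by (365.25 / cycle_days); death has
        yearly utility 0.
        """
        factor = 365.25 / self.cycle_days
        if state == "resolved":
            return self.u_resolved * factor
        if state == "symptomatic":
            return self.u_symptomatic * factor
        if state == "dead":
            return 0.0
        raise KeyError(f"unknown base state {state!r}")

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **changes: Any) -> "ModelParameters":
        """Return a validated copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


def symptomatic_utility(u_resolved: float, decrement: float) -> float:
    """Per-cycle utility of the symptomatic state: u_resolved x (1 - decrement)."""
    if not 0.0 <= u_resolved <= 1.0:
        raise ValueError(f"u_resolved={u_resolved!r} outside [0, 1]")
    if not 0.0 <= decrement <= 1.0:
        raise ValueError(f"decrement={decrement!r} outside [0, 1]")
    return u_resolved * (1.0 - decrement)


def transition_penalty(u_best_yearly: float, fraction: float) -> float:
    """Signed penalty for traversing a transition state: -(fraction x anchor)."""
    if not 0.0 <= u_best_yearly <= 1.0:
        raise ValueError(f"u_best_yearly={u_best_yearly!r} outside [0, 1]")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction={fraction!r} outside [0, 1]")
    return -(fraction * u_best_yearly)


def load_parameters(
    config: str | Path | Mapping[str, Any] | None = None,
) -> ModelParameters:
    """Build :class:`ModelParameters` from a YAML/JSON file or mapping.

    Absent keys keep their defaults; unknown keys are rejected.  YAML is a
    superset of JSON, so a ``.json`` file parses through the same reader.
    """
    if config is None:
        data: dict[str, Any] = {}
    elif isinstance(config, Mapping):
        data = dict(config)
    else:
        path = Path(config)
        try:
            text = path.read_text()
        except OSError as exc:
            raise ValueError(f"cannot read config {path}: {exc}") from exc
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed config {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must contain a mapping")
        data = loaded

    known = {f.name for f in dataclasses.fields(ModelParameters)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return ModelParameters(**data)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write parameters as JSON (round-trips through :func:`load_parameters`)."""
    Path(path).write_text(json.dumps(params.to_dict(), indent=2, sort_keys=True))
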