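"""Three-state Markov cohort engine with half-cycle correction.

Base states: symptomatic hernia, resolved hernia, death.  Within each
180-day cycle a patient may traverse transition states (incarceration,
flood syndrome, elective or emergent surgery, complicated recovery),
each charging a one-time utility penalty, before coming to rest in a
base state that accrues its per-cycle utility.

Event tree for one cycle (probabilities evaluated at the cycle's
MELD-Na):

* surgical strategy, cycle 1 only: all symptomatic mass undergoes
  elective surgery (penalty), dies with p_elective, survivors incur a
  complicated recovery (penalty) with p_comp and rest resolved;
* otherwise symptomatic mass splits multinomially into incarceration
  (p_incarceration), flood syndrome (p_flood) or neither;

  - incarcerated mass (penalty) is reduced successfully with
    p_reduction_success and stays symptomatic, else proceeds to
    emergent surgery;
  - flood mass (penalty) proceeds to emergent surgery;
  - emergent surgery (penalty) kills with p_emergent; survivors incur
    a complicated recovery (penalty) with p_ecomp and rest resolved;
  - mass with no surgical event dies of liver disease with p_nonop,
    else rests in its base state;

* resolved mass dies with p_nonop; survivors recur to the symptomatic
  state with p_recurrence (no penalty; a recurrence is a return of
  symptoms, not an acute event).

Liver-disease mortality applies only to mass with no surgical event in
the cycle: operative mortality already embeds liver-related risk, so
stacking both would double-count death.

QALY accounting uses a half-cycle correction on base-state utilities:
occupancy is valued at every cycle boundary, the entry and exit
boundaries at half weight.  Penalties are instantaneous events and are
never halved.  A terminal payoff adds projected median life expectancy
at the exit MELD-Na times the yearly utility of the final base state,
occupancy-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

from .params import ModelParameters
from .risk_models import MortalityModels

__all__ = [
    "BASE_STATES",
    "StateVector",
    "CycleOutcome",
    "StrategyResult",
    "cycle_transition",
    "terminal_payoff",
    "run_cohort",
]

BASE_STATES = ("symptomatic", "resolved", "dead")

Strategy = Literal["surgical", "nonoperative"]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class StateVector:
    """Occupancy fractions over the three base states (sums to 1)."""

    symptomatic: float = 1.0
    resolved: float = 0.0
    dead: float = 0.0

    def __post_init__(self) -> None:
        total = self.symptomatic + self.resolved + self.dead
        if min(self.symptomatic, self.resolved, self.dead) < 0:
            raise ValueError("negative occupancy fraction")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"occupancy sums to {total!r}, not 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "symptomatic": self.symptomatic,
            "resolved": self.resolved,
            "dead": self.dead,
        }


@dataclass(frozen=True)
class CycleOutcome:
    new_state: StateVector
    #: occupancy-weighted utility of the resting base states plus penalties
    cycle_utility: float
    #: expectation-weighted penalty total (<= 0), excluded from half-cycling
    penalty_utility: float
    event_flow: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class StrategyResult:
    strategy: Strategy
    initial_meld: float
    expected_qaly: float
    trace: tuple[StateVector, ...]
    exit_meld: float
    terminal_payoff: float
    final_state_distribution: dict[str, float]


def _check_prob(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value!r} outside [0, 1]")
    return value


def state_utility(state: StateVector, params: ModelParameters) -> float:
    """Occupancy-weighted per-cycle base-state utility (death contributes 0)."""
    return state.symptomatic * params.u_symptomatic + state.resolved * params.u_resolved


def cycle_transition(
    state: StateVector,
    meld: float,
    params: ModelParameters,
    models: MortalityModels,
    *,
    first_cycle_surgical: bool = False,
) -> CycleOutcome:
    """Advance the cohort one cycle through the event tree."""
    total = state.symptomatic + state.resolved + state.dead
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"occupancy sums to {total!r}, not 1")
    p_em = _check_prob("p_emergent", models.p_emergent(meld))
    p_ec = _check_prob("p_ecomp", models.p_ecomp(meld))
    p_n = _check_prob("p_nonop", models.p_nonop(meld))

    S, R, D = state.symptomatic, state.resolved, state.dead
    pen = 0.0
    flow: dict[str, float] = {
        "incarceration": 0.0,
        "reduction_success": 0.0,
        "flood": 0.0,
        "elective_surgery": 0.0,
        "emergent_surgery": 0.0,
        "complicated_recovery": 0.0,
        "death_operative": 0.0,
        "death_liver": 0.0,
    }

    new_s = 0.0
    new_r = 0.0
    new_d = D

    if first_cycle_surgical:
        p_el = _check_prob("p_elective", models.p_elective(meld))
        p_c = _check_prob("p_comp", models.p_comp(meld))
        flow["elective_surgery"] = S
        pen += S * params.penalty("elective_surgery")
        died = S * p_el
        survivors = S - died
        comp = survivors * p_c
        flow["complicated_recovery"] += comp
        pen += comp * params.penalty("complicated_recovery")
        flow["death_operative"] += died
        new_d += died
        new_r += survivors
    else:
        inc = S * params.p_incarceration
        fld = S * params.p_flood
        quiet = S - inc - fld

        flow["incarceration"] = inc
        pen += inc * params.penalty("incarceration")
        reduced = inc * params.p_reduction_success
        flow["reduction_success"] = reduced

        flow["flood"] = fld
        pen += fld * params.penalty("flood")

        emergent = (inc - reduced) + fld
        flow["emergent_surgery"] = emergent
        pen += emergent * params.penalty("emergent_surgery")
        em_died = emergent * p_em
        em_surv = emergent - em_died
        em_comp = em_surv * p_ec
        flow["complicated_recovery"] += em_comp
        pen += em_comp * params.penalty("complicated_recovery")
        flow["death_operative"] += em_died

        # no surgical event this cycle -> baseline liver-disease mortality
        nonsurgical = reduced + quiet
        liver_died = nonsurgical * p_n
        flow["death_liver"] += liver_died

        new_s += nonsurgical - liver_died
        new_r += em_surv
        new_d += em_died + liver_died

    # resolved mass: liver mortality, then possible recurrence
    r_died = R * p_n
    flow["death_liver"] += r_died
    r_surv = R - r_died
    recurred = r_surv * params.p_recurrence
    new_s += recurred
    new_r += r_surv - recurred
    new_d += r_died

    new_state = StateVector(new_s, new_r, new_d)
    utility = state_utility(new_state, params) + pen
    return CycleOutcome(
        new_state=new_state,
        cycle_utility=utility,
        penalty_utility=pen,
        event_flow=flow,
    )


def terminal_payoff(
    exit_meld: float,
    final_state: StateVector | str,
    life_model,
    yearly_utilities: Mapping[str, float],
) -> float:
    """Projected median life expectancy at exit MELD-Na, utility-weighted.

    For a single base state: 0 if dead, else life expectancy times the
    state's yearly utility.  For an occupancy vector: the expectation over
    live states.
    """
    if not 6.0 <= exit_meld <= 40.0:
        raise ValueError(f"exit_meld={exit_meld!r} outside [6, 40]")
    years = life_model(exit_meld)
    if isinstance(final_state, str):
        if final_state == "dead":
            return 0.0
        if final_state not in yearly_utilities:
            raise KeyError(f"no yearly utility for live state {final_state!r}")
        return years * yearly_utilities[final_state]
    payoff = 0.0
    for name in ("symptomatic", "resolved"):
        occ = getattr(final_state, name)
        if occ > 0 and name not in yearly_utilities:
            raise KeyError(f"no yearly utility for live state {name!r}")
        payoff += occ * years * yearly_utilities.get(name, 0.0)
    return payoff


def meld_at_cycle(initial_meld: float, cycle_index: int, params: ModelParameters) -> float:
    """MELD-Na at the start of 1-based ``cycle_index`` (drifted, clamped)."""
    m = initial_meld + (cycle_index - 1) * params.meld_drift_per_cycle
    return min(max(m, params.meld_floor), params.meld_cap)


def run_cohort(
    strategy: Strategy,
    initial_meld: float,
    params: ModelParameters,
    models: MortalityModels,
    *,
    include_terminal: bool = True,
) -> StrategyResult:
    """Run one strategy from a given initial MELD-Na over the full horizon."""
    if strategy not in ("surgical", "nonoperative"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if not params.meld_floor <= initial_meld <= params.meld_cap:
        raise ValueError(
            f"initial_meld={initial_meld!r} outside "
            f"[{params.meld_floor}, {params.meld_cap}]"
        )

    state = StateVector()
    trace: list[StateVector] = [state]
    penalties = 0.0
    # half-cycle correction: occupancy valued at each cycle boundary,
    # entry and exit boundaries at half weight
    qaly = 0.5 * state_utility(state, params)
    for t in range(1, params.n_cycles + 1):
        meld = meld_at_cycle(initial_meld, t, params)
        outcome = cycle_transition(
            state,
            meld,
            params,
            models,
            first_cycle_surgical=(strategy == "surgical" and t == 1),
        )
        state = outcome.new_state
        trace.append(state)
        penalties += outcome.penalty_utility
        weight = 0.5 if t == params.n_cycles else 1.0
        qaly += weight * state_utility(state, params)
    qaly += penalties

    exit_meld = min(
        max(
            initial_meld + params.n_cycles * params.meld_drift_per_cycle,
            params.meld_floor,
        ),
        params.meld_cap,
    )
    if include_terminal:
        yearly = {s: params.yearly_utility(s) for s in ("symptomatic", "resolved")}
        payoff = terminal_payoff(exit_meld, state, models.life_expectancy, yearly)
    else:
        payoff = 0.0

    return StrategyResult(
        strategy=strategy,
        initial_meld=initial_meld,
        expected_qaly=qaly + payoff,
        trace=tuple(trace),
        exit_meld=exit_meld,
        terminal_payoff=payoff,
        final_state_distribution=state.as_dict(),
    )
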