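"""Uncertainty analyses: microsimulation, PSA, tornado, grid sweeps.

Four complementary views of model uncertainty:

* first-order Monte Carlo **microsimulation** sends individual patients
  through the same per-cycle event tree as the cohort engine, with
  common random numbers pairing the two strategies within each trial;
* **probabilistic sensitivity analysis** (second-order) redraws the
  uncertain transition probabilities and the symptomatic utility
  decrement from beta distributions whose central 95% mass covers each
  parameter's plausible range, and records how often elective repair
  wins on cohort expectations;
* **tornado** one-way sweeps rank parameters by the QALY-difference
  range they induce;
* deterministic **two-way / three-way sweeps** re-run the full threshold
  search while scaling the complicated-recovery channels or varying the
  recurrence probability and symptomatic decrement jointly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .decision_analysis import QalyCurves, find_threshold
from .markov_engine import meld_at_cycle, run_cohort
from .params import ModelParameters
from .risk_models import MortalityModels, scale_complications

__all__ = [
    "BetaSpec",
    "MicrosimResult",
    "PSAResult",
    "TornadoEntry",
    "PSA_PARAMETERS",
    "default_range_spec",
    "fit_beta_from_range",
    "microsimulate",
    "run_psa",
    "tornado",
    "two_way_sensitivity",
    "three_way_sensitivity",
]

#: Parameters varied in PSA/tornado: the four fixed transition
#: probabilities plus the symptomatic utility decrement fraction.
PSA_PARAMETERS = (
    "p_incarceration",
    "p_reduction_success",
    "p_flood",
    "p_recurrence",
    "symptomatic_decrement",
)


def default_range_spec(params: ModelParameters) -> dict[str, tuple[float, float]]:
    """Default low/high range per varied parameter: [0.75x, 2x] of base.

    The high side is capped so probabilities stay below 1.
    """
    spec = {}
    for name in PSA_PARAMETERS:
        base = getattr(params, name)
        spec[name] = (0.75 * base, min(2.0 * base, 0.999))
    return spec


# ---------------------------------------------------------------------------
# beta distributions matched to a coverage interval


@dataclass(frozen=True)
class BetaSpec:
    """Beta(alpha, beta) whose central ``coverage`` mass spans a target range."""

    alpha: float
    beta: float
    target_low: float
    target_high: float
    coverage: float = 0.95

    def sample(self, rng: np.random.Generator, size=None):
        return rng.beta(self.alpha, self.beta, size=size)


def fit_beta_from_range(
    target_low: float, target_high: float, coverage: float = 0.95
) -> BetaSpec:
    """Solve for (alpha, beta) whose central quantiles hit the target range.

    The (1-coverage)/2 and 1-(1-coverage)/2 quantiles of the fitted beta
    reproduce ``target_low`` and ``target_high`` to within 1e-6.
    """
    if not 0.0 < target_low < target_high < 1.0:
        raise ValueError(
            f"need 0 < target_low < target_high < 1, got ({target_low}, {target_high})"
        )
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    tail = 0.5 * (1.0 - coverage)
    z = stats.norm.ppf(1.0 - tail)

    # moment-matched start: normal approximation of the interval
    mean = 0.5 * (target_low + target_high)
    sd = (target_high - target_low) / (2.0 * z)
    var = min(sd * sd, 0.9 * mean * (1.0 - mean))
    nu = mean * (1.0 - mean) / var - 1.0
    x0 = np.log([max(mean * nu, 1e-3), max((1.0 - mean) * nu, 1e-3)])

    def residual(logab: np.ndarray) -> np.ndarray:
        a, b = np.exp(logab)
        q = stats.beta.ppf([tail, 1.0 - tail], a, b)
        return q - [target_low, target_high]

    sol = optimize.root(residual, x0, method="hybr", tol=1e-12)
    a, b = np.exp(sol.x)
    err = np.abs(residual(sol.x)).max()
    if not sol.success or err > 1e-6:
        raise ValueError(
            f"beta fit failed for range ({target_low}, {target_high}): "
            f"max quantile error {err:.2e}"
        )
    return BetaSpec(float(a), float(b), target_low, target_high, coverage)


# ---------------------------------------------------------------------------
# first-order Monte Carlo microsimulation

_SYMPT, _RESOLVED, _DEAD = 0, 1, 2


@dataclass(frozen=True)
class MicrosimResult:
    n_trials: int
    qaly_diff_sample: np.ndarray
    proportion_surgery_favored: float
    proportion_ci: tuple[float, float]
    mean_qaly_by_strategy: dict[str, float]


def _binomial_ci(
    p: float, n: int, method: Literal["wald", "wilson"] = "wald"
) -> tuple[float, float]:
    z = 1.959963984540054
    if method == "wald":
        half = z * np.sqrt(max(p * (1.0 - p), 0.0) / n)
        return (max(0.0, p - half), min(1.0, p + half))
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1.0 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def _simulate_individuals(
    strategy: str,
    uniforms: np.ndarray,
    initial_meld: float,
    params: ModelParameters,
    models: MortalityModels,
) -> np.ndarray:
    """Vectorised patient-level pass through the cycle event tree.

    ``uniforms`` has shape (n_cycles, 5, n_trials); the five streams are
    event split, reduction, death, complication, recurrence.  Returns
    per-patient QALYs (half-cycle corrected, penalties, terminal payoff).
    """
    n_cycles = params.n_cycles
    n = uniforms.shape[2]
    state = np.full(n, _SYMPT, dtype=np.int8)
    penalties = np.zeros(n)
    base_util = np.array([params.u_symptomatic, params.u_resolved, 0.0])

    qaly = np.full(n, 0.5 * base_util[_SYMPT])  # entry boundary, half weight
    pen = {e: params.penalty(e) for e in (
        "incarceration", "flood", "elective_surgery",
        "emergent_surgery", "complicated_recovery",
    )}

    for t in range(1, n_cycles + 1):
        meld = meld_at_cycle(initial_meld, t, params)
        u_event, u_reduce, u_death, u_comp, u_recur = uniforms[t - 1]
        p_em, p_ec, p_n = models.p_emergent(meld), models.p_ecomp(meld), models.p_nonop(meld)

        sympt = state == _SYMPT
        resolved = state == _RESOLVED
        new_state = state.copy()

        if t == 1 and strategy == "surgical":
            died = sympt & (u_death < models.p_elective(meld))
            surv = sympt & ~died
            comp = surv & (u_comp < models.p_comp(meld))
            penalties[sympt] += pen["elective_surgery"]
            penalties[comp] += pen["complicated_recovery"]
            new_state[died] = _DEAD
            new_state[surv] = _RESOLVED
        else:
            inc = sympt & (u_event < params.p_incarceration)
            fld = sympt & ~inc & (
                u_event < params.p_incarceration + params.p_flood
            )
            quiet = sympt & ~inc & ~fld
            reduced = inc & (u_reduce < params.p_reduction_success)
            emergent = (inc & ~reduced) | fld

            penalties[inc] += pen["incarceration"]
            penalties[fld] += pen["flood"]
            penalties[emergent] += pen["emergent_surgery"]
            em_died = emergent & (u_death < p_em)
            em_surv = emergent & ~em_died
            em_comp = em_surv & (u_comp < p_ec)
            penalties[em_comp] += pen["complicated_recovery"]

            nonsurgical = reduced | quiet
            liver_died = nonsurgical & (u_death < p_n)

            new_state[em_died | liver_died] = _DEAD
            new_state[em_surv] = _RESOLVED
            # reduced/quiet survivors stay symptomatic (already _SYMPT)

        r_died = resolved & (u_death < p_n)
        r_surv = resolved & ~r_died
        recurred = r_surv & (u_recur < params.p_recurrence)
        new_state[r_died] = _DEAD
        new_state[recurred] = _SYMPT

        state = new_state
        weight = 0.5 if t == n_cycles else 1.0
        qaly += weight * base_util[state]

    exit_meld = min(
        max(initial_meld + n_cycles * params.meld_drift_per_cycle, params.meld_floor),
        params.meld_cap,
    )
    years = models.life_expectancy(exit_meld)
    yearly = np.array(
        [params.yearly_utility("symptomatic"), params.yearly_utility("resolved"), 0.0]
    )
    return qaly + penalties + years * yearly[state]


def microsimulate(
    initial_meld: float,
    n_trials: int,
    seed: int,
    params: ModelParameters,
    models: MortalityModels,
    *,
    paired: bool = True,
    ci_method: Literal["wald", "wilson"] = "wald",
) -> MicrosimResult:
    """Monte Carlo trials of individual patients under both strategies.

    With ``paired=True`` (default) each trial re-uses the same underlying
    uniform draws for both strategies (common random numbers), so the
    per-trial QALY difference isolates the effect of the initial decision.
    Exact ties count half toward the proportion favouring surgery.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    u_surg = rng.uniform(size=(params.n_cycles, 5, n_trials))
    u_non = u_surg if paired else rng.uniform(size=(params.n_cycles, 5, n_trials))

    q_surg = _simulate_individuals("surgical", u_surg, initial_meld, params, models)
    q_non = _simulate_individuals("nonoperative", u_non, initial_meld, params, models)
    diff = q_surg - q_non
    prop = float(np.mean(diff > 0) + 0.5 * np.mean(diff == 0))
    return MicrosimResult(
        n_trials=n_trials,
        qaly_diff_sample=diff,
        proportion_surgery_favored=prop,
        proportion_ci=_binomial_ci(prop, n_trials, ci_method),
        mean_qaly_by_strategy={
            "surgical": float(q_surg.mean()),
            "nonoperative": float(q_non.mean()),
        },
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis (second-order)


@dataclass(frozen=True)
class PSAResult:
    initial_meld: float
    n_trials: int
    proportion_surgery_favored: float
    proportion_ci: tuple[float, float]


def run_psa(
    initial_meld: float,
    n_trials: int,
    seed: int,
    params: ModelParameters,
    models: MortalityModels,
    range_spec: Mapping[str, tuple[float, float]] | None = None,
    *,
    coverage: float = 0.95,
    ci_method: Literal["wald", "wilson"] = "wald",
) -> PSAResult:
    """Joint resampling of uncertain inputs; decisions on cohort expectations.

    Each trial draws every varied parameter from its matched beta
    distribution, re-runs the cohort model for both strategies, and
    records which maximises expected QALYs (exact ties count half).  Only
    input uncertainty is sampled; patient-level chance is integrated out
    by the cohort expectation.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ranges = dict(range_spec) if range_spec is not None else default_range_spec(params)
    unknown = set(ranges) - set(PSA_PARAMETERS)
    if unknown:
        raise ValueError(f"unknown PSA parameters: {sorted(unknown)}")
    betas = {
        name: fit_beta_from_range(lo, hi, coverage) for name, (lo, hi) in ranges.items()
    }
    rng = np.random.default_rng(seed)
    draws = {name: spec.sample(rng, n_trials) for name, spec in betas.items()}

    favored = 0.0
    for i in range(n_trials):
        trial_params = params.replace(
            **{name: float(draws[name][i]) for name in draws}
        )
        qs = run_cohort("surgical", initial_meld, trial_params, models).expected_qaly
        qn = run_cohort("nonoperative", initial_meld, trial_params, models).expected_qaly
        if qs > qn:
            favored += 1.0
        elif qs == qn:
            favored += 0.5
    prop = favored / n_trials
    return PSAResult(
        initial_meld=initial_meld,
        n_trials=n_trials,
        proportion_surgery_favored=prop,
        proportion_ci=_binomial_ci(prop, n_trials, ci_method),
    )


# ---------------------------------------------------------------------------
# deterministic sweeps


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    outcome_at_low: float
    outcome_at_high: float

    @property
    def bar_width(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def _qaly_difference(
    initial_meld: float, params: ModelParameters, models: MortalityModels
) -> float:
    return (
        run_cohort("surgical", initial_meld, params, models).expected_qaly
        - run_cohort("nonoperative", initial_meld, params, models).expected_qaly
    )


def tornado(
    initial_meld: float,
    params: ModelParameters,
    models: MortalityModels,
    range_spec: Mapping[str, tuple[float, float]] | None = None,
) -> list[TornadoEntry]:
    """One-way sweeps of each varied parameter, sorted by bar width."""
    ranges = dict(range_spec) if range_spec is not None else default_range_spec(params)
    entries = []
    for name, (lo, hi) in ranges.items():
        out_lo = _qaly_difference(initial_meld, params.replace(**{name: lo}), models)
        out_hi = _qaly_difference(initial_meld, params.replace(**{name: hi}), models)
        entries.append(TornadoEntry(name, lo, hi, out_lo, out_hi))
    return sorted(entries, key=lambda e: e.bar_width, reverse=True)


def _threshold_over_grid(
    meld_grid: Sequence[float], params: ModelParameters, models: MortalityModels
) -> float | None:
    grid = tuple(float(m) for m in meld_grid)
    qs = tuple(run_cohort("surgical", m, params, models).expected_qaly for m in grid)
    qn = tuple(
        run_cohort("nonoperative", m, params, models).expected_qaly for m in grid
    )
    return find_threshold(QalyCurves(grid, qs, qn)).threshold_meld


def two_way_sensitivity(
    complication_factor_grid: Sequence[float],
    meld_grid: Sequence[float],
    params: ModelParameters,
    models: MortalityModels,
) -> pd.DataFrame:
    """Decision threshold as the complicated-recovery channels are scaled.

    Both the elective and emergent complication probabilities are
    multiplied by each factor together.
    """
    rows = []
    for factor in complication_factor_grid:
        if factor <= 0:
            raise ValueError("complication factors must be positive")
        scaled = scale_complications(models, float(factor))
        rows.append(
            {
                "complication_factor": float(factor),
                "threshold_meld": _threshold_over_grid(meld_grid, params, scaled),
            }
        )
    return pd.DataFrame(rows)


def three_way_sensitivity(
    recurrence_grid: Sequence[float],
    decrement_grid: Sequence[float],
    params: ModelParameters,
    models: MortalityModels,
    *,
    meld_min: float = 6.0,
    meld_max: float = 25.0,
    step: float = 1.0,
) -> pd.DataFrame:
    """Threshold surface over (recurrence probability, symptomatic decrement).

    Returns a frame indexed by recurrence with one column per decrement;
    cells hold the decision threshold (NaN when one strategy dominates
    the whole grid).
    """
    if len(recurrence_grid) == 0 or len(decrement_grid) == 0:
        raise ValueError("grids must be nonempty")
    n = int(round((meld_max - meld_min) / step)) + 1
    meld_grid = [meld_min + i * step for i in range(n)]
    surface = {}
    for dec in decrement_grid:
        col = []
        for rec in recurrence_grid:
            trial = params.replace(p_recurrence=float(rec), symptomatic_decrement=float(dec))
            t = _threshold_over_grid(meld_grid, trial, models)
            col.append(np.nan if t is None else t)
        surface[float(dec)] = col
    frame = pd.DataFrame(surface, index=[float(r) for r in recurrence_grid])
    frame.index.name = "p_recurrence"
    frame.columns.name = "symptomatic_decrement"
    return frame
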