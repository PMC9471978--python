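"""MELD-Na-indexed mortality/complication models driving the Markov engine.

Five per-cycle probability channels are needed, all functions of the
current MELD-Na score:

* ``p_elective`` / ``p_emergent`` -- 180-day postoperative mortality in
  the elective and emergent settings (probability-scale lines fitted to
  stratum means of an external surgical-risk score's predictions);
* ``p_comp`` / ``p_ecomp`` -- complicated postoperative recovery in the
  same two settings (same construction);
* ``p_nonop`` -- 180-day mortality attributable to liver disease alone,
  a logistic regression of observed 180-day death on MELD-Na among
  nonoperative patients.

A sixth model projects median life expectancy in years from ln(MELD-Na)
and prices the terminal payoff after the modelled horizon.

The engine only requires callables ``m -> probability``; both the fitted
model classes here and a tabulated per-MELD lookup satisfy that
interface, so users holding an exact per-MELD probability table can feed
it in unchanged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter

__all__ = [
    "LogisticMortalityModel",
    "LinearMortalityModel",
    "TabulatedProbability",
    "LifeExpectancyModel",
    "MortalityModels",
    "fit_nonoperative_mortality",
    "fit_operative_mortality_line",
    "excess_operative_mortality",
    "fit_life_expectancy",
    "estimate_meld_drift",
    "fit_all_models",
    "export_mortality_table",
    "load_mortality_table",
    "scale_complications",
]

OperativeChannel = Literal["elective", "emergent", "comp", "ecomp"]

_CHANNEL_COLUMNS: dict[str, str] = {
    "elective": "predicted_p_elective",
    "emergent": "predicted_p_emergent",
    "comp": "predicted_p_comp",
    "ecomp": "predicted_p_ecomp",
}


@dataclass(frozen=True)
class LogisticMortalityModel:
    """p(m) = expit(intercept + slope * m); strictly inside (0, 1)."""

    intercept: float
    slope: float

    def __call__(self, meld: float) -> float:
        return 1.0 / (1.0 + math.exp(-(self.intercept + self.slope * meld)))


@dataclass(frozen=True)
class LinearMortalityModel:
    """p(m) = clip(intercept + slope * m, 0, 1)."""

    intercept: float
    slope: float

    def __call__(self, meld: float) -> float:
        return min(1.0, max(0.0, self.intercept + self.slope * meld))


@dataclass(frozen=True)
class TabulatedProbability:
    """Per-integer-MELD probability lookup with linear interpolation.

    Queries outside the tabulated span evaluate at the nearest endpoint.
    """

    meld: tuple[float, ...]
    prob: tuple[float, ...]

    def __call__(self, meld: float) -> float:
        return float(np.clip(np.interp(meld, self.meld, self.prob), 0.0, 1.0))


@dataclass(frozen=True)
class LifeExpectancyModel:
    """Median life expectancy (years) = max(a + b * ln(m), floor)."""

    a: float
    b: float
    floor: float = 0.25

    def __call__(self, meld: float) -> float:
        return max(self.a + self.b * math.log(meld), self.floor)


ProbabilityFn = Callable[[float], float]


@dataclass(frozen=True)
class MortalityModels:
    """Bundle of the five probability channels plus life expectancy."""

    p_elective: ProbabilityFn
    p_emergent: ProbabilityFn
    p_comp: ProbabilityFn
    p_ecomp: ProbabilityFn
    p_nonop: ProbabilityFn
    life_expectancy: LifeExpectancyModel

    def __post_init__(self) -> None:
        grid = np.arange(6.0, 41.0)
        if any(self.p_emergent(m) < self.p_elective(m) for m in grid):
            warnings.warn(
                "emergent mortality falls below elective mortality for some "
                "MELD-Na in [6, 40]",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# fitting


def fit_nonoperative_mortality(cohort: pd.DataFrame) -> LogisticMortalityModel:
    """Maximum-likelihood logistic fit of 180-day death on MELD-Na.

    Expects the cohort restricted to nonoperative patients (an ``operative``
    column, if present, is used to restrict automatically).
    """
    frame = cohort
    if "operative" in frame.columns:
        frame = frame[~frame["operative"].astype(bool)]
    y = frame["dead_180d"].astype(float).to_numpy()
    m = frame["meld_na"].astype(float).to_numpy()
    if np.unique(m).size < 2:
        raise ValueError("need >= 2 distinct MELD-Na values for a logistic fit")
    if y.min() == y.max():
        raise ValueError(
            "single-class outcome: all dead_180d are "
            f"{bool(y[0])}; logistic fit is undefined"
        )
    X = sm.add_constant(m)
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            res = sm.Logit(y, X).fit(disp=0)
        except Exception as exc:  # separation surfaces as warning or error
            raise ValueError(
                f"logistic fit failed (possible complete separation): {exc}"
            ) from exc
    if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 1e3:
        raise ValueError("logistic fit diverged: complete separation suspected")
    return LogisticMortalityModel(float(res.params[0]), float(res.params[1]))


def fit_operative_mortality_line(
    cohort: pd.DataFrame, which: OperativeChannel
) -> LinearMortalityModel:
    """OLS of stratum-mean predicted probability on integer MELD-Na.

    Patients are grouped by integer MELD-Na stratum, the chosen channel's
    predictions are averaged per stratum, and a line is fitted through the
    stratum means (each stratum weighted equally).
    """
    col = _CHANNEL_COLUMNS[which]
    strata = (
        cohort.assign(_m=cohort["meld_na"].round().astype(int))
        .groupby("_m")[col]
        .mean()
    )
    if len(strata) < 2:
        raise ValueError("need >= 2 MELD-Na strata to fit a line")
    slope, intercept = np.polyfit(strata.index.to_numpy(float), strata.to_numpy(), 1)
    return LinearMortalityModel(float(intercept), float(slope))


def excess_operative_mortality(
    models: MortalityModels, which: Literal["elective", "emergent"], meld: float
) -> float:
    """Operative-channel probability minus nonoperative probability at ``meld``."""
    if not 6.0 <= meld <= 40.0:
        raise ValueError(f"meld={meld!r} outside [6, 40]")
    channel = models.p_elective if which == "elective" else models.p_emergent
    return channel(meld) - models.p_nonop(meld)


def _stratum_median_survival(group: pd.DataFrame) -> float:
    """Median survival in years; Kaplan-Meier when any record is censored."""
    if bool(group["event_observed"].all()):
        return float(group["survival_years"].median())
    km = KaplanMeierFitter()
    km.fit(group["survival_years"], event_observed=group["event_observed"])
    return float(km.median_survival_time_)


def fit_life_expectancy(
    cohort: pd.DataFrame, floor: float = 0.25
) -> LifeExpectancyModel:
    """OLS of per-stratum median survival on ln(MELD-Na).

    Strata whose median is not estimable (Kaplan-Meier median never
    reached) are dropped; at least two estimable strata are required.
    """
    frame = cohort
    if "operative" in frame.columns:
        frame = frame[~frame["operative"].astype(bool)]
    medians: dict[int, float] = {}
    for m, group in frame.groupby(frame["meld_na"].round().astype(int)):
        med = _stratum_median_survival(group)
        if np.isfinite(med):
            medians[int(m)] = med
    if len(medians) < 2:
        raise ValueError("fewer than 2 strata with an estimable median survival")
    x = np.log(np.array(sorted(medians), dtype=float))
    y = np.array([medians[k] for k in sorted(medians)])
    b, a = np.polyfit(x, y, 1)
    return LifeExpectancyModel(float(a), float(b), floor=floor)


def estimate_meld_drift(cohort: pd.DataFrame, cycle_days: float = 180.0) -> float:
    """Mean annual MELD-Na change converted to points per cycle."""
    drift = cohort["annual_meld_change"].to_numpy(float)
    if drift.size == 0:
        raise ValueError("no annual_meld_change values")
    return float(drift.mean() * cycle_days / 365.25)


def fit_all_models(cohort: pd.DataFrame, life_floor: float = 0.25) -> MortalityModels:
    """Fit every channel from one cohort frame."""
    return MortalityModels(
        p_elective=fit_operative_mortality_line(cohort, "elective"),
        p_emergent=fit_operative_mortality_line(cohort, "emergent"),
        p_comp=fit_operative_mortality_line(cohort, "comp"),
        p_ecomp=fit_operative_mortality_line(cohort, "ecomp"),
        p_nonop=fit_nonoperative_mortality(cohort),
        life_expectancy=fit_life_expectancy(cohort, floor=life_floor),
    )


# ---------------------------------------------------------------------------
# tabulated input / output

_TABLE_COLUMNS = ("meld", "p_elective", "p_emergent", "p_comp", "p_ecomp", "p_nonop")


def export_mortality_table(
    models: MortalityModels, path: str | Path, meld_min: int = 6, meld_max: int = 40
) -> None:
    """Evaluate all five channels on an integer grid and write them as CSV."""
    grid = np.arange(meld_min, meld_max + 1)
    frame = pd.DataFrame(
        {
            "meld": grid,
            "p_elective": [models.p_elective(m) for m in grid],
            "p_emergent": [models.p_emergent(m) for m in grid],
            "p_comp": [models.p_comp(m) for m in grid],
            "p_ecomp": [models.p_ecomp(m) for m in grid],
            "p_nonop": [models.p_nonop(m) for m in grid],
        }
    )
    frame.to_csv(path, index=False)


def load_mortality_table(
    path: str | Path, life_expectancy: LifeExpectancyModel | None = None
) -> MortalityModels:
    """Read a per-MELD probability table (CSV) into :class:`MortalityModels`.

    The table must cover every integer MELD-Na row within its own span and
    within [6, 40]; non-integer queries interpolate linearly and queries
    beyond the span evaluate at the nearest tabulated score.
    """
    frame = pd.read_csv(path)
    missing = set(_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"mortality table missing columns: {sorted(missing)}")
    frame = frame.sort_values("meld")
    meld = frame["meld"].to_numpy(float)
    expected = np.arange(max(6.0, meld.min()), min(40.0, meld.max()) + 1)
    if not np.array_equal(np.intersect1d(meld, expected), expected):
        raise ValueError(
            "mortality table has missing integer MELD-Na rows inside [6, 40]"
        )
    for col in _TABLE_COLUMNS[1:]:
        vals = frame[col].to_numpy(float)
        if np.any((vals < 0.0) | (vals > 1.0)):
            raise ValueError(f"{col} contains probabilities outside [0, 1]")
    meld_t = tuple(meld)

    def table(col: str) -> TabulatedProbability:
        return TabulatedProbability(meld_t, tuple(frame[col].to_numpy(float)))

    return MortalityModels(
        p_elective=table("p_elective"),
        p_emergent=table("p_emergent"),
        p_comp=table("p_comp"),
        p_ecomp=table("p_ecomp"),
        p_nonop=table("p_nonop"),
        life_expectancy=life_expectancy or LifeExpectancyModel(12.0, -3.0),
    )


@dataclass(frozen=True)
class _Scaled:
    base: ProbabilityFn
    factor: float

    def __call__(self, meld: float) -> float:
        return min(1.0, max(0.0, self.factor * self.base(meld)))


def scale_complications(models: MortalityModels, factor: float) -> MortalityModels:
    """Scale both complicated-recovery channels by ``factor`` (clipped to [0,1])."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return replace(
        models,
        p_comp=_Scaled(models.p_comp, factor),
        p_ecomp=_Scaled(models.p_ecomp, factor),
    )
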