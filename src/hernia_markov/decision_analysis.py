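"""Strategy comparison across initial MELD-Na and the decision threshold.

The base analysis runs the cohort engine for both strategies at every
initial MELD-Na on a grid (default 6..25 in 1-point steps) and locates
the equivalence threshold where expected QALYs cross: below it elective
repair maximises QALYs, above it nonoperative management does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov_engine import StrategyResult, run_cohort
from .params import ModelParameters
from .risk_models import MortalityModels

__all__ = [
    "QalyCurves",
    "ThresholdResult",
    "qaly_curves",
    "find_threshold",
    "refine_threshold",
    "final_state_distribution",
]


@dataclass(frozen=True)
class QalyCurves:
    meld_grid: tuple[float, ...]
    qaly_surgical: tuple[float, ...]
    qaly_nonoperative: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "meld_na": self.meld_grid,
                "qaly_surgical": self.qaly_surgical,
                "qaly_nonoperative": self.qaly_nonoperative,
            }
        )


@dataclass(frozen=True)
class ThresholdResult:
    """Equivalence point of the two QALY curves, if any.

    ``threshold_meld`` is None when one strategy dominates over the whole
    grid; ``favored_below``/``favored_above`` name the QALY-maximising
    strategy on each side (equal when there is no crossing).
    """

    threshold_meld: float | None
    bracketing_grid_points: tuple[float, float] | None
    favored_below: str
    favored_above: str


def qaly_curves(
    meld_min: float,
    meld_max: float,
    step: float,
    params: ModelParameters,
    models: MortalityModels,
) -> QalyCurves:
    """Expected QALYs for both strategies on a regular initial-MELD grid."""
    if not meld_min < meld_max:
        raise ValueError("meld_min must be < meld_max")
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((meld_max - meld_min) / step)) + 1
    grid = tuple(float(meld_min + i * step) for i in range(n))
    qs = tuple(
        run_cohort("surgical", m, params, models).expected_qaly for m in grid
    )
    qn = tuple(
        run_cohort("nonoperative", m, params, models).expected_qaly for m in grid
    )
    return QalyCurves(grid, qs, qn)


def _favored(diff: float) -> str:
    return "surgical" if diff >= 0 else "nonoperative"


def find_threshold(curves: QalyCurves) -> ThresholdResult:
    """Locate the sign change of (surgical - nonoperative) along the grid.

    A fractional threshold is obtained by linear interpolation between the
    bracketing grid points; an exact zero at a grid point is reported as
    the threshold itself.  Multiple sign changes raise, flagging a
    non-monotone model rather than silently picking one crossing.
    """
    grid = np.asarray(curves.meld_grid, float)
    diff = np.asarray(curves.qaly_surgical, float) - np.asarray(
        curves.qaly_nonoperative, float
    )
    if grid.size != diff.size or grid.size < 2:
        raise ValueError("curves must be aligned with >= 2 grid points")

    crossings: list[tuple[float, tuple[float, float]]] = []
    for i in range(diff.size - 1):
        a, b = diff[i], diff[i + 1]
        if a == 0.0:
            if i == 0 or diff[i - 1] != 0.0:
                crossings.append((float(grid[i]), (float(grid[i]), float(grid[i]))))
        elif a * b < 0:
            frac = a / (a - b)
            t = grid[i] + frac * (grid[i + 1] - grid[i])
            crossings.append((float(t), (float(grid[i]), float(grid[i + 1]))))
    if diff[-1] == 0.0 and diff[-2] != 0.0:
        crossings.append((float(grid[-1]), (float(grid[-1]), float(grid[-1]))))

    if len(crossings) > 1:
        raise ValueError(
            "multiple QALY-curve crossings at MELD-Na "
            f"{[round(c[0], 4) for c in crossings]}; model is non-monotone"
        )
    if not crossings:
        side = _favored(float(diff[0]))
        return ThresholdResult(None, None, side, _favored(float(diff[-1])))
    t, bracket = crossings[0]
    return ThresholdResult(t, bracket, _favored(float(diff[0])), _favored(float(diff[-1])))


def refine_threshold(
    curves: QalyCurves,
    params: ModelParameters,
    models: MortalityModels,
    tol: float = 1e-3,
    max_iter: int = 60,
) -> ThresholdResult:
    """Bisect the QALY difference with real model runs inside the bracket.

    Sharpens the interpolated threshold when the difference is visibly
    curved between grid points.
    """
    coarse = find_threshold(curves)
    if coarse.threshold_meld is None or coarse.bracketing_grid_points is None:
        return coarse
    lo, hi = coarse.bracketing_grid_points
    if lo == hi:
        return coarse

    def diff(m: float) -> float:
        return (
            run_cohort("surgical", m, params, models).expected_qaly
            - run_cohort("nonoperative", m, params, models).expected_qaly
        )

    f_lo = diff(lo)
    for _ in range(max_iter):
        if hi - lo <= tol:
            break
        mid = 0.5 * (lo + hi)
        f_mid = diff(mid)
        if f_mid == 0.0:
            lo = hi = mid
            break
        if (f_lo > 0) == (f_mid > 0):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return ThresholdResult(
        0.5 * (lo + hi),
        coarse.bracketing_grid_points,
        coarse.favored_below,
        coarse.favored_above,
    )


def final_state_distribution(result: StrategyResult) -> dict[str, float]:
    """Occupancy over base states at the end of the modelled horizon."""
    return dict(result.final_state_distribution)
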