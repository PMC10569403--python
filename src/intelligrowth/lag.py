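"""Developmental lag: the horizontal distance between percentile curves.

For a percentile level p and each age a on a grid, the lag d(a) solves

    case_quantile(a + d, p) = ref_quantile(a, p),

i.e. how many months later the case group's p-th percentile reaches the
level the reference group shows at age a.  Positive lag means the case
group is delayed.  The headline statistic is the mean of d(a) over the
grid ages where a root exists inside both models' fitted ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .betareg import BetaGrowthModel, model_quantile

logger = logging.getLogger(__name__)

MAX_LAG = 36.0   # months searched either side
ROOT_TOL = 1e-3  # months
DEFAULT_GRID = np.arange(36, 91)  # monthly, interior so a + d stays in range


@dataclass(frozen=True)
class LagEstimate:
    """Horizontal-gap summary for one percentile level."""

    percentile: float
    mean_lag: float
    per_age_lags: dict[float, float]
    age_grid: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        ages = sorted(self.per_age_lags)
        return pd.DataFrame(
            {"age_months": ages, "lag_months": [self.per_age_lags[a] for a in ages]}
        )


def _solve_lag(
    case_model: BetaGrowthModel, target: float, age: float, p: float
) -> float | None:
    """Smallest-magnitude root of case_quantile(age + d, p) - target."""
    lo_m, hi_m = case_model.age_range
    d_lo = max(-MAX_LAG, lo_m - age)
    d_hi = min(MAX_LAG, hi_m - age)
    if d_hi - d_lo < ROOT_TOL:
        return None

    def g(d: float) -> float:
        return model_quantile(case_model, age + d, p) - target

    # scan for sign changes; fitted splines can be locally non-monotone
    grid = np.linspace(d_lo, d_hi, 73)
    vals = np.array([g(d) for d in grid])
    roots: list[float] = []
    exact = np.flatnonzero(vals == 0.0)
    roots.extend(float(grid[i]) for i in exact)
    sign_change = np.flatnonzero(vals[:-1] * vals[1:] < 0.0)
    for i in sign_change:
        roots.append(float(optimize.brentq(g, grid[i], grid[i + 1], xtol=ROOT_TOL)))
    if not roots:
        return None
    if len(roots) > 1:
        logger.info(
            "non-monotone percentile curve at age %.0f (p=%.2f): %d roots, "
            "taking the smallest-magnitude one", age, p, len(roots),
        )
    return min(roots, key=abs)


def horizontal_lag(
    ref_model: BetaGrowthModel,
    case_model: BetaGrowthModel,
    p: float,
    age_grid=DEFAULT_GRID,
) -> LagEstimate:
    """Months of delay of the case group's p-th percentile curve.

    Grid ages where no bracketed root exists inside both models' ranges
    are omitted; fewer than 3 solvable ages refuses the estimate.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly inside (0, 1)")
    grid = np.asarray(age_grid, dtype=float)
    lo_r, hi_r = ref_model.age_range
    per_age: dict[float, float] = {}
    for age in grid:
        if not (lo_r <= age <= hi_r):
            continue
        target = model_quantile(ref_model, age, p)
        d = _solve_lag(case_model, target, float(age), p)
        if d is not None:
            per_age[float(age)] = d
    if len(per_age) < 3:
        raise ValueError(
            f"lag estimate refused: only {len(per_age)} solvable grid ages"
        )
    return LagEstimate(
        percentile=p,
        mean_lag=float(np.mean(list(per_age.values()))),
        per_age_lags=per_age,
        age_grid=grid,
    )


def vertical_gap(
    ref_model: BetaGrowthModel,
    case_model: BetaGrowthModel,
    p: float,
    age_grid=DEFAULT_GRID,
) -> pd.DataFrame:
    """Percentage-point gap between the two p-th percentile curves by age
    (descriptive helper, not a headline statistic)."""
    grid = np.asarray(age_grid, dtype=float)
    ref_q = np.array([model_quantile(ref_model, a, p) for a in grid])
    case_q = np.array([model_quantile(case_model, a, p) for a in grid])
    return pd.DataFrame(
        {"age_months": grid, "gap_points": (ref_q - case_q) * 100.0}
    )


def write_lag(est: LagEstimate, path: str | Path) -> None:
    """Export per-age lags as delimited text."""
    est.to_frame().to_csv(path, index=False, float_format="%.6g")
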