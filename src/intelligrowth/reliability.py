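"""Listener transcription reliability.

Each child-visit is scored independently by two listeners; the analysed
intelligibility value is their average.  Reliability of that average is
the one-way random-effects, average-measures, consistency intraclass
correlation from the one-way ANOVA decomposition over units (child-visits):

    ICC = (MSB - MSW) / MSB

with MSB the between-unit and MSW the within-unit mean square over the
k = 2 ratings per unit.  A negative estimate (MSW > MSB) is returned as
computed rather than floored at zero.  The companion descriptive is the
mean absolute within-pair difference in percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import Cohort


@dataclass(frozen=True)
class ListenerPairSet:
    """Paired listener scores, one pair per child-visit unit."""

    scores: np.ndarray  # shape (n_units, 2)

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("scores must have shape (n_units, 2)")
        if arr.shape[0] < 2:
            raise ValueError("need at least 2 units")
        if not np.all(np.isfinite(arr)):
            raise ValueError("scores must be finite")
        if np.any(arr < 0.0) or np.any(arr > 1.0):
            raise ValueError("scores must lie in [0, 1]")
        object.__setattr__(self, "scores", arr)

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "ListenerPairSet":
        df = cohort.data.dropna(subset=["listener_a", "listener_b"])
        if df.empty:
            raise ValueError("cohort carries no listener scores")
        return cls(df[["listener_a", "listener_b"]].to_numpy(dtype=float))


def _anova_mean_squares(pairs: ListenerPairSet) -> tuple[float, float, int, int]:
    x = pairs.scores
    n, k = x.shape
    unit_means = x.mean(axis=1)
    grand = x.mean()
    ssb = k * np.sum((unit_means - grand) ** 2)
    ssw = np.sum((x - unit_means[:, None]) ** 2)
    df_b, df_w = n - 1, n * (k - 1)
    return ssb / df_b, ssw / df_w, df_b, df_w


def icc_oneway_average(pairs: ListenerPairSet) -> float:
    """One-way random-effects, average-measures ICC for the two-listener
    mean score: (MSB - MSW) / MSB."""
    msb, msw, _, _ = _anova_mean_squares(pairs)
    if msb == 0.0:
        raise ValueError("ICC undefined: no between-unit variance (MSB = 0)")
    return float((msb - msw) / msb)


def icc_confidence_interval(
    pairs: ListenerPairSet, level: float = 0.95
) -> tuple[float, float]:
    """F-distribution interval for the one-way average-measures ICC.

    With F = MSB/MSW on (n-1, n(k-1)) df, the bounds are
    1 - 1/F_L and 1 - 1/F_U where F_L = F / F_upper and
    F_U = F * F'_upper for the matching tail quantiles.
    """
    msb, msw, df_b, df_w = _anova_mean_squares(pairs)
    if msw == 0.0:
        return 1.0, 1.0
    f_obs = msb / msw
    alpha = 1.0 - level
    f_l = f_obs / stats.f.ppf(1.0 - alpha / 2.0, df_b, df_w)
    f_u = f_obs * stats.f.ppf(1.0 - alpha / 2.0, df_w, df_b)
    return float(1.0 - 1.0 / f_l), float(1.0 - 1.0 / f_u)


def mean_pair_difference(pairs: ListenerPairSet) -> tuple[float, float]:
    """Mean and SD of |listener_a - listener_b| in percentage points."""
    diffs = np.abs(pairs.scores[:, 0] - pairs.scores[:, 1]) * 100.0
    return float(diffs.mean()), float(diffs.std(ddof=1))
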