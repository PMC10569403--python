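"""Bootstrap uncertainty for derived statistics.

Two resampling schemes respect the two study designs:

* **stratified** (cross-sectional reference sample) — children are
  resampled with replacement independently within five age strata
  (30-41, 42-53, 54-65, 66-77, 78-96 months), preserving each stratum's
  count exactly, so the age composition of every replicate matches the
  original sample.
* **cluster** (longitudinal clinical sample) — whole children are
  resampled with replacement, each drawn child contributing all of
  their visits, which respects within-child correlation.

``bootstrap_ci`` reruns the entire derivation chain (model refits and
all downstream statistics) on each replicate and reports a percentile
confidence interval.  Replicates whose refit fails to converge are
excluded with a logged count; more than 10% failures aborts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .betareg import FitError
from .cohort import Cohort

logger = logging.getLogger(__name__)

STRATA_MONTHS = ((30, 41), (42, 53), (54, 65), (66, 77), (78, 96))
DEFAULT_B = 2000
MAX_FAILURE_FRACTION = 0.10


@dataclass(frozen=True)
class BootstrapResult:
    """Replicates and the percentile interval for one statistic."""

    statistic_name: str
    replicates: np.ndarray
    point_estimate: float
    ci_low: float
    ci_high: float
    level: float
    B: int
    seed: int
    n_failed: int = 0


def stratified_resample(td_cohort: Cohort, seed) -> Cohort:
    """Resample a cross-sectional cohort within fixed age strata.

    ``seed`` may be an int or a numpy Generator.  Per-stratum counts are
    preserved exactly.
    """
    if td_cohort.design != "cross_sectional":
        raise ValueError("stratified resampling expects a cross-sectional cohort")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = td_cohort.data
    ages = df["age_months"].to_numpy()
    take: list[np.ndarray] = []
    for lo, hi in STRATA_MONTHS:
        rows = np.flatnonzero((ages >= lo) & (ages <= hi))
        if rows.size == 0:
            raise ValueError(f"empty age stratum {lo}-{hi} months")
        take.append(rng.choice(rows, size=rows.size, replace=True))
    out = df.take(np.concatenate(take)).reset_index(drop=True)
    # resampling duplicates children; relabel so the cohort invariant holds
    out["child_id"] = [f"b{i:05d}" for i in range(len(out))]
    return Cohort(out, design="cross_sectional")


def cluster_resample(cp_cohort: Cohort, seed) -> Cohort:
    """Resample whole children (with all their visits) with replacement."""
    if len(cp_cohort) == 0:
        raise ValueError("cannot resample an empty cohort")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = cp_cohort.data
    groups = df.groupby("child_id", sort=False).indices
    children = list(groups)
    drawn = rng.choice(len(children), size=len(children), replace=True)
    rows = np.concatenate([groups[children[i]] for i in drawn])
    out = df.take(rows).reset_index(drop=True)
    # duplicates get distinct synthetic ids
    labels = np.repeat(
        [f"{children[i]}#{k}" for k, i in enumerate(drawn)],
        [len(groups[children[i]]) for i in drawn],
    )
    out["child_id"] = labels
    return Cohort(out, design=cp_cohort.design)


def resample(cohort: Cohort, seed) -> Cohort:
    """Design-appropriate resample: stratified if cross-sectional,
    cluster (whole-child) if longitudinal."""
    if cohort.design == "cross_sectional":
        return stratified_resample(cohort, seed)
    return cluster_resample(cohort, seed)


def bootstrap_ci(
    statistic: Callable[..., float],
    cohorts: Cohort | Sequence[Cohort],
    B: int = DEFAULT_B,
    level: float = 0.95,
    seed: int = 0,
    statistic_name: str = "statistic",
) -> BootstrapResult:
    """Percentile bootstrap interval for ``statistic(*cohorts)``.

    Each replicate resamples every cohort with its design-appropriate
    scheme and recomputes the statistic from scratch.  Replicate random
    streams are spawned deterministically from ``(seed, replicate)``, so
    results do not depend on execution order.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if isinstance(cohorts, Cohort):
        cohorts = [cohorts]
    point = float(statistic(*cohorts))

    root = np.random.SeedSequence([int(seed), 0xB5])
    streams = root.spawn(B)
    reps: list[float] = []
    n_failed = 0
    for b in range(B):
        child_streams = streams[b].spawn(len(cohorts))
        try:
            boot = [
                resample(c, np.random.default_rng(s))
                for c, s in zip(cohorts, child_streams)
            ]
            reps.append(float(statistic(*boot)))
        except (FitError, ValueError) as err:
            n_failed += 1
            logger.warning("bootstrap replicate %d failed: %s", b, err)
    if n_failed > MAX_FAILURE_FRACTION * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed (> "
            f"{MAX_FAILURE_FRACTION:.0%}); aborting"
        )
    arr = np.asarray(reps, dtype=float)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(arr, [alpha, 1.0 - alpha])
    return BootstrapResult(
        statistic_name=statistic_name,
        replicates=arr,
        point_estimate=point,
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        B=B,
        seed=int(seed),
        n_failed=n_failed,
    )
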