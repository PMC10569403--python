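"""Clinical cut-points: fixed-specificity / fixed-sensitivity thresholds,
operating characteristics and positive predictive values by age.

Two screening rules are supported, matching the two clinical questions:

* **fix_specificity** — the threshold is the *reference* group's
  (1 - specificity)-quantile (e.g. the TD 10th percentile for
  specificity .90); the case model then supplies the achieved
  sensitivity.  Used for flagging possible delay against norms.
* **fix_sensitivity** — the threshold is the *case* group's
  sensitivity-quantile (e.g. the SMI 90th percentile for sensitivity
  .90); the reference model supplies the achieved specificity.  Used for
  casting a wide net for speech motor involvement within the clinical
  population, where the positive predictive value
  PPV = Se pi / (Se pi + (1 - Sp)(1 - pi)) with prevalence pi is the
  quantity of clinical interest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .betareg import BetaGrowthModel, model_cdf, model_quantile

MONTHS_PER_YEAR = 12
DEFAULT_REPORT_YEARS = (3, 4, 5, 6, 7, 8)


def threshold_at_specificity(
    ref_model: BetaGrowthModel, age: float, spec: float = 0.90
) -> float:
    """The intelligibility cut-point achieving the given specificity.

    This is the reference model's (1 - spec)-quantile: by construction
    a fraction ``spec`` of reference children score above it.
    """
    if not (0.0 < spec < 1.0):
        raise ValueError("spec must lie strictly inside (0, 1)")
    return float(model_quantile(ref_model, age, 1.0 - spec))


def threshold_at_sensitivity(
    case_model: BetaGrowthModel, age: float, sens: float = 0.90
) -> float:
    """The cut-point achieving the given sensitivity: the case model's
    sens-quantile, below which that fraction of affected children score."""
    if not (0.0 < sens < 1.0):
        raise ValueError("sens must lie strictly inside (0, 1)")
    return float(model_quantile(case_model, age, sens))


def sensitivity_at_threshold(
    case_model: BetaGrowthModel, age: float, t: float
) -> float:
    """Fraction of affected children scoring below t: F_case(t)."""
    if not (0.0 < t < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    return float(model_cdf(case_model, age, t))


def specificity_at_threshold(
    ref_model: BetaGrowthModel, age: float, t: float
) -> float:
    """Fraction of reference children scoring above t: 1 - F_ref(t)."""
    if not (0.0 < t < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    return float(1.0 - model_cdf(ref_model, age, t))


def ppv(sens: float, spec: float, prevalence: float) -> float:
    """Positive predictive value by Bayes' rule.

    PPV = Se pi / (Se pi + (1 - Sp) (1 - pi)).
    """
    for name, v in (("sens", sens), ("spec", spec), ("prevalence", prevalence)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    denom = sens * prevalence + (1.0 - spec) * (1.0 - prevalence)
    if denom == 0.0:
        raise ZeroDivisionError("PPV undefined: no positive calls in either group")
    return sens * prevalence / denom


def prevalence_from_counts(n_case: int, n_control: int) -> float:
    """Case prevalence from child counts (children, not observations)."""
    if n_case < 0 or n_control < 0:
        raise ValueError("counts must be non-negative")
    total = n_case + n_control
    if total == 0:
        raise ZeroDivisionError("prevalence undefined for an empty sample")
    return n_case / total


def round_half_point(x: float) -> float:
    """Round a proportion to the nearest 0.5 percentage point (the
    printed-table dialect for thresholds)."""
    return round(x * 200.0) / 200.0


@dataclass(frozen=True)
class ThresholdRow:
    """One age's row of a cut-point table.

    ``threshold`` keeps full precision; ``threshold_rounded`` is the
    half-percentage-point presentation value.
    """

    age_years: int
    threshold: float
    sensitivity: float
    specificity: float
    prevalence: float | None = None
    ppv: float | None = None

    @property
    def threshold_rounded(self) -> float:
        return round_half_point(self.threshold)


def build_threshold_table(
    ref_model: BetaGrowthModel,
    case_model: BetaGrowthModel,
    ages_years=DEFAULT_REPORT_YEARS,
    mode: str = "fix_specificity",
    level: float = 0.90,
    prevalence: float | None = None,
) -> list[ThresholdRow]:
    """Build the per-age cut-point table for one screening rule.

    Ages are given in years and evaluated at exact year marks
    (36, 48, ... months).  With ``fix_specificity`` the threshold is the
    reference quantile and sensitivity is derived; with
    ``fix_sensitivity`` the threshold is the case quantile and
    specificity is derived.  PPV is filled in when a prevalence is given.
    """
    if mode not in ("fix_specificity", "fix_sensitivity"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for year in ages_years:
        age = year * MONTHS_PER_YEAR
        if mode == "fix_specificity":
            t = threshold_at_specificity(ref_model, age, level)
            sens = sensitivity_at_threshold(case_model, age, t)
            spec = level
        else:
            t = threshold_at_sensitivity(case_model, age, level)
            sens = level
            spec = specificity_at_threshold(ref_model, age, t)
        row_ppv = ppv(sens, spec, prevalence) if prevalence is not None else None
        rows.append(
            ThresholdRow(
                age_years=int(year), threshold=t, sensitivity=sens,
                specificity=spec, prevalence=prevalence, ppv=row_ppv,
            )
        )
    return rows


def table_to_frame(rows: list[ThresholdRow]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "age_years": [r.age_years for r in rows],
            "threshold": [r.threshold for r in rows],
            "threshold_rounded": [r.threshold_rounded for r in rows],
            "sensitivity": [r.sensitivity for r in rows],
            "specificity": [r.specificity for r in rows],
        }
    )
    if rows and rows[0].prevalence is not None:
        df["prevalence"] = [r.prevalence for r in rows]
        df["ppv"] = [r.ppv for r in rows]
    return df


def write_table(rows: list[ThresholdRow], path: str | Path) -> None:
    """Write a cut-point table as delimited text."""
    table_to_frame(rows).to_csv(path, index=False, float_format="%.6g")
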