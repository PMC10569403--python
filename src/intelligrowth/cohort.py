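"""Child-level intelligibility records and cohort containers.

A cohort is a table of child-visit observations: an opaque child id, a
group label (``TD``, ``NSMI`` or ``SMI``), an age in months, a speech
intelligibility score expressed as a proportion in (0, 1), and optionally
the two individual listener scores whose mean the intelligibility score is.

Cohorts come in two designs:

* ``cross_sectional`` — each child contributes exactly one observation
  (the typically-developing normative sample);
* ``longitudinal`` — each child contributes 2-11 visits at roughly
  6-month intervals (the cerebral-palsy sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("TD", "NSMI", "SMI")
AGE_MIN = 30
AGE_MAX = 96

COLUMNS = ["child_id", "group", "age_months", "intelligibility", "listener_a", "listener_b"]


class CohortError(ValueError):
    """Raised when a cohort violates its structural invariants."""


@dataclass(frozen=True)
class IntelligibilityRecord:
    """One child-visit observation."""

    child_id: str
    group: str
    age_months: int
    intelligibility: float
    listener_a: float | None = None
    listener_b: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortError(f"unknown group {self.group!r}")
        if not (AGE_MIN <= self.age_months <= AGE_MAX):
            raise CohortError(
                f"age_months={self.age_months} outside [{AGE_MIN}, {AGE_MAX}]"
            )
        if not (0.0 < self.intelligibility < 1.0):
            raise CohortError(
                f"intelligibility={self.intelligibility} not strictly inside (0, 1)"
            )
        has_a, has_b = self.listener_a is not None, self.listener_b is not None
        if has_a != has_b:
            raise CohortError("listener scores must be given as a pair or not at all")
        if has_a:
            if not (0.0 <= self.listener_a <= 1.0 and 0.0 <= self.listener_b <= 1.0):
                raise CohortError("listener scores must lie in [0, 1]")
            if abs((self.listener_a + self.listener_b) / 2.0 - self.intelligibility) > 1e-9:
                raise CohortError("intelligibility must equal the listener-pair mean")


@dataclass
class Cohort:
    """An ordered collection of intelligibility records with a study design.

    ``data`` is a pandas DataFrame with columns
    ``child_id, group, age_months, intelligibility, listener_a, listener_b``
    (the listener columns may be all-NaN).
    """

    data: pd.DataFrame
    design: str = "cross_sectional"
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.design not in ("cross_sectional", "longitudinal"):
            raise CohortError(f"unknown design {self.design!r}")
        df = self.data
        missing = [c for c in COLUMNS[:4] if c not in df.columns]
        if missing:
            raise CohortError(f"missing columns: {missing}")
        for col in ("listener_a", "listener_b"):
            if col not in df.columns:
                df[col] = np.nan
        self.data = df.loc[:, COLUMNS].reset_index(drop=True)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        bad_group = ~df["group"].isin(GROUPS)
        if bad_group.any():
            row = int(df.index[bad_group][0])
            raise CohortError(f"row {row}: unknown group {df.loc[row, 'group']!r}")
        bad_age = (df["age_months"] < AGE_MIN) | (df["age_months"] > AGE_MAX)
        if bad_age.any():
            row = int(df.index[bad_age][0])
            raise CohortError(
                f"row {row}: age_months={df.loc[row, 'age_months']} outside "
                f"[{AGE_MIN}, {AGE_MAX}]"
            )
        bad_y = (df["intelligibility"] <= 0.0) | (df["intelligibility"] >= 1.0)
        if bad_y.any():
            row = int(df.index[bad_y][0])
            raise CohortError(
                f"row {row}: intelligibility={df.loc[row, 'intelligibility']} "
                "not strictly inside (0, 1)"
            )
        counts = df.groupby("child_id", sort=False).size()
        if self.design == "cross_sectional":
            if (counts > 1).any():
                cid = counts.index[counts > 1][0]
                raise CohortError(
                    f"cross-sectional cohort has repeated child_id {cid!r}"
                )
        else:
            if (counts < 2).any() or (counts > 11).any():
                cid = counts.index[(counts < 2) | (counts > 11)][0]
                raise CohortError(
                    f"longitudinal child {cid!r} has {counts[cid]} visits "
                    "(expected 2-11)"
                )
            for cid, sub in df.groupby("child_id", sort=False):
                ages = np.sort(sub["age_months"].to_numpy())
                if np.any(np.diff(ages) < 5):
                    raise CohortError(
                        f"longitudinal child {cid!r} has visits closer than 5 months"
                    )
        self._validated = True

    # -- conveniences ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_children(self) -> int:
        return self.data["child_id"].nunique()

    @property
    def ages(self) -> np.ndarray:
        return self.data["age_months"].to_numpy(dtype=float)

    @property
    def scores(self) -> np.ndarray:
        return self.data["intelligibility"].to_numpy(dtype=float)

    def subset(self, group: str) -> "Cohort":
        """Return the records of one group as a new cohort (same design)."""
        if group not in GROUPS:
            raise CohortError(f"unknown group {group!r}")
        sub = self.data[self.data["group"] == group].reset_index(drop=True)
        if sub.empty:
            raise CohortError(f"no records for group {group!r}")
        return Cohort(sub, design=self.design)

    def records(self) -> list[IntelligibilityRecord]:
        out = []
        for row in self.data.itertuples(index=False):
            la = None if pd.isna(row.listener_a) else float(row.listener_a)
            lb = None if pd.isna(row.listener_b) else float(row.listener_b)
            out.append(
                IntelligibilityRecord(
                    str(row.child_id), str(row.group), int(row.age_months),
                    float(row.intelligibility), la, lb,
                )
            )
        return out


def concat(*cohorts: Cohort, design: str | None = None) -> Cohort:
    """Stack cohorts sharing a design into one."""
    designs = {c.design for c in cohorts}
    if design is None:
        if len(designs) != 1:
            raise CohortError("cohorts mix designs; pass design= explicitly")
        design = designs.pop()
    return Cohort(pd.concat([c.data for c in cohorts], ignore_index=True), design=design)


def read_cohort(path: str | Path, design: str = "cross_sectional") -> Cohort:
    """Read a cohort from delimited text (CSV with the canonical header).

    Schema violations are reported with 1-based data line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS[:4] if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing columns {missing}")
    for col in ("listener_a", "listener_b"):
        if col not in df.columns:
            df[col] = np.nan
    try:
        return Cohort(df, design=design)
    except CohortError as err:
        # re-raise with file context; Cohort errors carry the row index
        msg = str(err)
        if msg.startswith("row "):
            row = int(msg.split()[1].rstrip(":"))
            msg = f"{path}, line {row + 2}: " + msg.split(": ", 1)[1]
        else:
            msg = f"{path}: {msg}"
        raise CohortError(msg) from None


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV with the canonical column order."""
    cohort.data.to_csv(path, index=False, float_format="%.10g")
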