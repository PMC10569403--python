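"""Synthetic intelligibility cohorts with known ground truth.

The study's raw child data are not public, so this module generates
cohorts with the same statistical structure: a large cross-sectional
typically-developing (TD) sample with rising mean and shrinking variance,
and a smaller longitudinal cerebral-palsy sample split into NSMI (no
speech motor involvement; tracks TD with a lag) and SMI (speech motor
involvement; lower mean, variance *widening* with age).

Ground truth per group is a four-parameter logistic mean curve

    mu*(a) = floor + (asymptote - floor) / (1 + exp(-(a - midpoint)/scale))

with a log-linear precision curve

    phi*(a) = precision_intercept * exp(precision_slope * (a - 30)),

and scores drawn from Beta(mu* phi*, (1 - mu*) phi*).  Longitudinal
children additionally receive child-level random effects: a normal shift
of the midpoint age and a normal perturbation of the asymptote on the
logit scale.  The latter is what widens the SMI group's cross-child
spread at older ages.  Closed-form quantiles of the generating
distribution are exposed as oracles for parameter-recovery testing.

The default truth parameters are fixtures chosen to mimic the
qualitative shapes of the study groups (medians ordered TD > NSMI > SMI
through the preschool years, NSMI lagging TD by roughly half a year);
they are not estimates of any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from .cohort import AGE_MAX, AGE_MIN, Cohort


@dataclass(frozen=True)
class GroupTruth:
    """Generating parameters for one group."""

    asymptote: float
    midpoint_age: float
    scale: float
    floor: float = 0.0
    precision_intercept: float = 5.0
    precision_slope: float = 0.0
    child_sd_shift: float = 0.0   # months; SD of per-child midpoint shift
    child_sd_asym: float = 0.0    # logit units; SD of per-child asymptote wobble

    def __post_init__(self) -> None:
        if not (0.0 < self.asymptote <= 1.0):
            raise ValueError("asymptote must lie in (0, 1]")
        if not (0.0 <= self.floor < self.asymptote):
            raise ValueError("floor must lie in [0, asymptote)")
        if self.scale <= 0.0:
            raise ValueError("scale must be positive")
        if self.precision_intercept <= 0.0:
            raise ValueError("precision_intercept must be positive")
        if self.child_sd_shift < 0.0 or self.child_sd_asym < 0.0:
            raise ValueError("random-effect SDs must be non-negative")

    def mean(self, age) -> np.ndarray | float:
        """True mean curve mu*(a); strictly increasing in age."""
        a = np.asarray(age, dtype=float)
        out = self.floor + (self.asymptote - self.floor) * special.expit(
            (a - self.midpoint_age) / self.scale
        )
        return float(out) if out.ndim == 0 else out

    def precision(self, age) -> np.ndarray | float:
        """True precision curve phi*(a) = phi0 exp(slope (a - 30))."""
        a = np.asarray(age, dtype=float)
        out = self.precision_intercept * np.exp(self.precision_slope * (a - AGE_MIN))
        return float(out) if out.ndim == 0 else out


# Default truths: plumbing fixtures emulating the study's group shapes.
TD_TRUTH = GroupTruth(
    asymptote=0.97, midpoint_age=32.0, scale=12.0, floor=0.10,
    precision_intercept=6.0, precision_slope=0.035,
)
NSMI_TRUTH = GroupTruth(
    asymptote=0.965, midpoint_age=39.0, scale=12.0, floor=0.10,
    precision_intercept=6.0, precision_slope=0.035,
    child_sd_shift=4.0, child_sd_asym=0.25,
)
SMI_TRUTH = GroupTruth(
    asymptote=0.80, midpoint_age=50.0, scale=16.0, floor=0.05,
    precision_intercept=8.0, precision_slope=-0.025,
    child_sd_shift=6.0, child_sd_asym=1.0,
)

# Mean absolute within-pair listener difference, as proportions.
LISTENER_DIFF_TD = 0.037
LISTENER_DIFF_CP = 0.050

_EDGE = 1e-6  # keep generated scores strictly inside (0, 1)


def true_quantile(truth: GroupTruth, age: float, p: float) -> float:
    """The p-quantile of the generating beta distribution at one age.

    This is the oracle against which fitted percentile curves are judged.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly inside (0, 1)")
    mu = truth.mean(age)
    phi = truth.precision(age)
    return float(stats.beta.ppf(p, mu * phi, (1.0 - mu) * phi))


def _attach_listeners(
    rng: np.random.Generator, y: np.ndarray, mean_abs_diff: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split each score into a listener pair whose mean is the score.

    The half-gap is normal with SD chosen so E|a - b| = mean_abs_diff
    (folded-normal identity E|Z| = sigma sqrt(2/pi)), shrunk where needed
    to keep both listener scores inside [0, 1].
    """
    sd = mean_abs_diff * np.sqrt(np.pi / 2.0)
    half = rng.normal(0.0, sd / 2.0, size=len(y))
    room = np.minimum(y, 1.0 - y)
    half = np.clip(half, -room, room)
    return y + half, y - half


def _draw_scores(rng, mu, phi) -> np.ndarray:
    y = rng.beta(mu * phi, (1.0 - mu) * phi)
    return np.clip(y, _EDGE, 1.0 - _EDGE)


def generate_td_cohort(
    n: int,
    truth: GroupTruth = TD_TRUTH,
    seed: int = 0,
    *,
    listeners: bool = True,
) -> Cohort:
    """Generate a cross-sectional TD cohort of ``n`` children.

    Ages are uniform over the 30-96 month range (integer months); each
    child's score is one beta draw from the group truth at their age.
    The same ``(n, truth, seed)`` always produces the identical cohort.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7D]))
    ages = rng.integers(AGE_MIN, AGE_MAX + 1, size=n)
    mu = truth.mean(ages)
    phi = truth.precision(ages)
    y = _draw_scores(rng, mu, phi)
    data = pd.DataFrame(
        {
            "child_id": [f"td{i:05d}" for i in range(n)],
            "group": "TD",
            "age_months": ages,
            "intelligibility": y,
        }
    )
    if listeners:
        a, b = _attach_listeners(rng, y, LISTENER_DIFF_TD)
        data["listener_a"], data["listener_b"] = a, b
    return Cohort(data, design="cross_sectional")


def _child_truth(rng: np.random.Generator, truth: GroupTruth) -> GroupTruth:
    """Perturb a group truth into one child's latent trajectory."""
    shift = rng.normal(0.0, truth.child_sd_shift) if truth.child_sd_shift else 0.0
    wobble = rng.normal(0.0, truth.child_sd_asym) if truth.child_sd_asym else 0.0
    asym = float(special.expit(special.logit(truth.asymptote) + wobble))
    asym = max(asym, truth.floor + 1e-3)
    return replace(
        truth,
        midpoint_age=truth.midpoint_age + shift,
        asymptote=asym,
        child_sd_shift=0.0,
        child_sd_asym=0.0,
    )


def _longitudinal_children(
    rng_master: np.random.SeedSequence,
    n: int,
    truth: GroupTruth,
    group: str,
    prefix: str,
    listeners: bool,
) -> pd.DataFrame:
    frames = []
    for i, child_seq in enumerate(rng_master.spawn(n)):
        rng = np.random.default_rng(child_seq)
        child = _child_truth(rng, truth)
        # visits sit on the study's 6-month grid anchored at 30 months
        start = AGE_MIN + 6 * int(rng.integers(0, 6))
        n_visits = int(rng.integers(2, 12))
        # the study cohorts span the full design range (visits through
        # age 8); guarantee that here so fits cover [30, 96] months
        if n >= 2 and i == 0:
            start = AGE_MIN
        elif n >= 2 and i == 1:
            start, n_visits = 60, 7
        ages = np.arange(start, AGE_MAX + 1, 6)[:n_visits]
        mu = np.clip(child.mean(ages), _EDGE, 1.0 - _EDGE)
        phi = child.precision(ages)
        y = _draw_scores(rng, mu, phi)
        frame = pd.DataFrame(
            {
                "child_id": f"{prefix}{i:04d}",
                "group": group,
                "age_months": ages,
                "intelligibility": y,
            }
        )
        if listeners:
            a, b = _attach_listeners(rng, y, LISTENER_DIFF_CP)
            frame["listener_a"], frame["listener_b"] = a, b
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def generate_cp_cohort(
    n_nsmi: int = 21,
    n_smi: int = 44,
    truth_nsmi: GroupTruth = NSMI_TRUTH,
    truth_smi: GroupTruth = SMI_TRUTH,
    seed: int = 0,
    *,
    listeners: bool = True,
) -> Cohort:
    """Generate a longitudinal cerebral-palsy cohort (NSMI + SMI groups).

    Each child gets a uniform start age in [30, 60] months, a uniform
    visit count in {2..11} (capped by the 96-month ceiling), visits at
    6-month spacing, and child-level random effects drawn from the group
    truth.  Per-child substreams are spawned deterministically from the
    single seed, so any child's trajectory is reproducible.
    """
    if n_nsmi < 1 or n_smi < 1:
        raise ValueError("group sizes must be >= 1")
    root = np.random.SeedSequence([seed, 0xCB])
    seq_nsmi, seq_smi = root.spawn(2)
    data = pd.concat(
        [
            _longitudinal_children(seq_nsmi, n_nsmi, truth_nsmi, "NSMI", "nsmi", listeners),
            _longitudinal_children(seq_smi, n_smi, truth_smi, "SMI", "smi", listeners),
        ],
        ignore_index=True,
    )
    return Cohort(data, design="longitudinal")
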