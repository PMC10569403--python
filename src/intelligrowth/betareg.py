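"""Flexible beta regression for intelligibility growth.

The model: each child-visit intelligibility score y in (0, 1) at age a is
beta distributed,

    y | a  ~  Beta(mu(a) * phi(a), (1 - mu(a)) * phi(a)),

with the mean mu modelled on the logit scale by a 3-df natural cubic
spline in age and the precision phi on the log scale by a 2-df natural
cubic spline.  Higher phi means lower variance at a fixed mean
(Var = mu (1 - mu) / (1 + phi)), so the model captures both a growing
average and an age-varying spread — together these give the full set of
age-specific percentile curves.

This is the mean-precision (mu, phi) parameterization of distributional
beta regression; a mean-sigma parameterization (as in GAMLSS BE) is the
same family with phi = (1 - sigma^2) / sigma^2.

Observations are treated as independent at the point-estimation stage;
within-child correlation in longitudinal cohorts is handled by the
cluster bootstrap (see :mod:`intelligrowth.bootstrap`), not by random
effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize, special, stats

from .cohort import Cohort
from .splines import NaturalSplineBasis, build_basis

DEFAULT_DF_MEAN = 3
DEFAULT_DF_PRECISION = 2
_GRAD_TOL = 1e-6
_REL_TOL = 1e-8


class FitError(RuntimeError):
    """Raised when the likelihood maximization fails to converge."""


@dataclass(frozen=True)
class AgeDistribution:
    """The fitted beta distribution at one age."""

    mu: float
    phi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.mu < 1.0):
            raise ValueError(f"mu={self.mu} outside (0, 1)")
        if not self.phi > 0.0:
            raise ValueError(f"phi={self.phi} must be positive")

    @property
    def alpha(self) -> float:
        return self.mu * self.phi

    @property
    def beta(self) -> float:
        return (1.0 - self.mu) * self.phi

    def frozen(self):
        return stats.beta(self.alpha, self.beta)


@dataclass(frozen=True)
class BetaGrowthModel:
    """A fitted spline beta regression: age -> beta distribution."""

    mean_basis: NaturalSplineBasis
    precision_basis: NaturalSplineBasis
    mean_coefs: np.ndarray      # intercept + spline weights, logit link
    precision_coefs: np.ndarray  # intercept + spline weights, log link
    loglik: float
    n_obs: int
    converged: bool

    @property
    def age_range(self) -> tuple[float, float]:
        lo_m, hi_m = self.mean_basis.boundary_knots
        lo_p, hi_p = self.precision_basis.boundary_knots
        return max(lo_m, lo_p), min(hi_m, hi_p)

    def _check_age(self, age) -> np.ndarray:
        a = np.atleast_1d(np.asarray(age, dtype=float))
        lo, hi = self.age_range
        if np.any(a < lo - 1e-9) or np.any(a > hi + 1e-9):
            raise ValueError(
                f"age outside the fitted range [{lo:g}, {hi:g}] months; "
                "extrapolation is refused"
            )
        return a


def _squeeze_boundary(y: np.ndarray) -> np.ndarray:
    """Pull scores of exactly 0 or 1 into the open interval.

    y' = (y (n - 1) + 0.5) / n, applied only to boundary scores, so
    interior observations are untouched.
    """
    y = np.asarray(y, dtype=float).copy()
    n = len(y)
    at_edge = (y <= 0.0) | (y >= 1.0)
    if at_edge.any():
        y[at_edge] = (y[at_edge] * (n - 1) + 0.5) / n
    return y


def _nll_and_grad(theta, Xm, Xp, y, log_y, log_1my, km):
    """Negative beta log-likelihood and its gradient.

    Parameters are (mean coefs | precision coefs); mu = expit(Xm b),
    phi = exp(Xp g).
    """
    b, g = theta[:km], theta[km:]
    eta = Xm @ b
    # clip to keep digamma/gammaln finite when the optimizer steps far out
    mu = np.clip(special.expit(eta), 1e-12, 1.0 - 1e-12)
    phi = np.exp(np.clip(Xp @ g, -30.0, 30.0))
    a = mu * phi
    c = (1.0 - mu) * phi
    ll = (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(c)
        + (a - 1.0) * log_y
        + (c - 1.0) * log_1my
    )
    ystar = log_y - log_1my
    dll_dmu = phi * (special.digamma(c) - special.digamma(a) + ystar)
    dll_dphi = (
        special.digamma(phi)
        - mu * special.digamma(a)
        - (1.0 - mu) * special.digamma(c)
        + mu * log_y
        + (1.0 - mu) * log_1my
    )
    grad_b = Xm.T @ (dll_dmu * mu * (1.0 - mu))
    grad_g = Xp.T @ (dll_dphi * phi)
    return -np.sum(ll), -np.concatenate([grad_b, grad_g])


def fit_beta_growth(
    cohort: Cohort | None = None,
    *,
    ages=None,
    scores=None,
    df_mean: int = DEFAULT_DF_MEAN,
    df_precision: int = DEFAULT_DF_PRECISION,
) -> BetaGrowthModel:
    """Fit the spline beta regression to one group's records by maximum
    likelihood.

    Accepts either a :class:`Cohort` (typically ``cohort.subset(group)``)
    or raw ``ages``/``scores`` arrays.  The optimizer is quasi-Newton
    (L-BFGS-B) with an analytic gradient, started deterministically from
    the intercept-only method-of-moments fit, so refits of the same data
    are bit-reproducible.

    Raises :class:`FitError` on non-convergence.
    """
    if cohort is not None:
        ages = cohort.ages
        scores = cohort.scores
    ages = np.asarray(ages, dtype=float)
    y = _squeeze_boundary(np.asarray(scores, dtype=float))
    if len(ages) != len(y):
        raise ValueError("ages and scores differ in length")
    if len(y) < 20:
        raise ValueError(f"need >= 20 observations to fit, got {len(y)}")
    if np.any((y <= 0.0) | (y >= 1.0)):
        raise ValueError("scores outside (0, 1) after boundary squeezing")

    mean_basis = build_basis(ages, df_mean)
    prec_basis = build_basis(ages, df_precision)
    Xm = mean_basis.design(ages)
    Xp = prec_basis.design(ages)
    km = Xm.shape[1]

    # deterministic start: logit of sample mean, log of moment precision
    ybar, yvar = float(np.mean(y)), float(np.var(y))
    phi0 = max(ybar * (1.0 - ybar) / max(yvar, 1e-12) - 1.0, 1e-2)
    theta0 = np.zeros(km + Xp.shape[1])
    theta0[0] = special.logit(np.clip(ybar, 1e-6, 1.0 - 1e-6))
    theta0[km] = np.log(phi0)

    log_y, log_1my = np.log(y), np.log1p(-y)
    res = optimize.minimize(
        _nll_and_grad,
        theta0,
        args=(Xm, Xp, y, log_y, log_1my, km),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": _REL_TOL * 1e-7, "gtol": _GRAD_TOL},
    )
    # accept line-search stalls at a stationary point: the mean
    # per-observation score must be negligible
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) or grad_norm / len(y) < 1e-4
    if not converged:
        raise FitError(
            f"beta regression failed to converge: {res.message} "
            f"(max |grad| = {grad_norm:.3g})"
        )
    return BetaGrowthModel(
        mean_basis=mean_basis,
        precision_basis=prec_basis,
        mean_coefs=res.x[:km].copy(),
        precision_coefs=res.x[km:].copy(),
        loglik=-float(res.fun),
        n_obs=len(y),
        converged=converged,
    )


# -- prediction surface --------------------------------------------------

def predict_distribution(model: BetaGrowthModel, age) -> AgeDistribution:
    """The fitted beta distribution at one age (months)."""
    a = model._check_age(age)
    if a.size != 1:
        raise ValueError("predict_distribution takes a single age")
    mu = float(special.expit(model.mean_basis.design(a) @ model.mean_coefs)[0])
    phi = float(np.exp(model.precision_basis.design(a) @ model.precision_coefs)[0])
    return AgeDistribution(mu=mu, phi=phi)


def _mu_phi(model: BetaGrowthModel, ages) -> tuple[np.ndarray, np.ndarray]:
    a = model._check_age(ages)
    mu = special.expit(model.mean_basis.design(a) @ model.mean_coefs)
    phi = np.exp(model.precision_basis.design(a) @ model.precision_coefs)
    return mu, phi


def model_quantile(model: BetaGrowthModel, age, p) -> np.ndarray | float:
    """The p-quantile of the fitted distribution at the given age(s)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("p must lie strictly inside (0, 1)")
    mu, phi = _mu_phi(model, age)
    out = stats.beta.ppf(p, mu * phi, (1.0 - mu) * phi)
    return out.item() if out.size == 1 else out


def model_cdf(model: BetaGrowthModel, age, y) -> np.ndarray | float:
    """P(score <= y) under the fitted distribution at the given age(s)."""
    y = np.asarray(y, dtype=float)
    if np.any((y < 0.0) | (y > 1.0)):
        raise ValueError("y must lie in [0, 1]")
    mu, phi = _mu_phi(model, age)
    out = stats.beta.cdf(y, mu * phi, (1.0 - mu) * phi)
    return out.item() if out.size == 1 else out


def model_density(model: BetaGrowthModel, age, y) -> np.ndarray | float:
    """Fitted density at score y for the given age(s)."""
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0.0) | (y >= 1.0)):
        raise ValueError("y must lie strictly inside (0, 1)")
    mu, phi = _mu_phi(model, age)
    out = stats.beta.pdf(y, mu * phi, (1.0 - mu) * phi)
    return out.item() if out.size == 1 else out


def quantile_curve(model: BetaGrowthModel, p: float, age_grid) -> np.ndarray:
    """The age-trajectory of the fitted p-quantile over a grid of months."""
    grid = np.asarray(age_grid, dtype=float)
    mu, phi = _mu_phi(model, grid)
    return stats.beta.ppf(p, mu * phi, (1.0 - mu) * phi)


def intercept_only_loglik(scores) -> float:
    """Maximized log-likelihood of the intercept-only beta model.

    Used to check the nesting property of the spline fit.
    """
    y = _squeeze_boundary(np.asarray(scores, dtype=float))
    log_y, log_1my = np.log(y), np.log1p(-y)

    def nll(theta):
        mu = special.expit(theta[0])
        phi = np.exp(theta[1])
        a, c = mu * phi, (1 - mu) * phi
        return -np.sum(
            special.gammaln(phi) - special.gammaln(a) - special.gammaln(c)
            + (a - 1) * log_y + (c - 1) * log_1my
        )

    ybar, yvar = np.mean(y), np.var(y)
    phi0 = max(ybar * (1 - ybar) / max(yvar, 1e-12) - 1, 1e-2)
    res = optimize.minimize(
        nll, np.array([special.logit(ybar), np.log(phi0)]), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10},
    )
    return -float(res.fun)


# -- plain-text serialization --------------------------------------------

def save_model(model: BetaGrowthModel, path: str | Path) -> None:
    """Write a fitted model as a plain-text key-value file."""
    def fmt(values) -> str:
        return ",".join(repr(float(v)) for v in values)

    lines = [
        f"mean_df = {model.mean_basis.df}",
        f"mean_interior_knots = {fmt(model.mean_basis.interior_knots)}",
        f"mean_boundary_knots = {fmt(model.mean_basis.boundary_knots)}",
        f"precision_df = {model.precision_basis.df}",
        f"precision_interior_knots = {fmt(model.precision_basis.interior_knots)}",
        f"precision_boundary_knots = {fmt(model.precision_basis.boundary_knots)}",
        f"mean_coefs = {fmt(model.mean_coefs)}",
        f"precision_coefs = {fmt(model.precision_coefs)}",
        f"loglik = {float(model.loglik)!r}",
        f"n_obs = {model.n_obs}",
        f"converged = {int(model.converged)}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> BetaGrowthModel:
    """Reload a model written by :func:`save_model`."""
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        kv[key.strip()] = val.strip()

    def floats(key: str) -> tuple[float, ...]:
        raw = kv[key]
        return tuple(float(v) for v in raw.split(",")) if raw else ()

    mean_basis = NaturalSplineBasis(
        df=int(kv["mean_df"]),
        interior_knots=floats("mean_interior_knots"),
        boundary_knots=floats("mean_boundary_knots"),
    )
    prec_basis = NaturalSplineBasis(
        df=int(kv["precision_df"]),
        interior_knots=floats("precision_interior_knots"),
        boundary_knots=floats("precision_boundary_knots"),
    )
    return BetaGrowthModel(
        mean_basis=mean_basis,
        precision_basis=prec_basis,
        mean_coefs=np.asarray(floats("mean_coefs")),
        precision_coefs=np.asarray(floats("precision_coefs")),
        loglik=float(kv["loglik"]),
        n_obs=int(kv["n_obs"]),
        converged=bool(int(kv["converged"])),
    )
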