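"""Natural cubic spline bases for age effects.

A natural cubic spline with ``df`` degrees of freedom uses ``df - 1``
interior knots plus two boundary knots, and is constrained to be linear
beyond the boundaries (second derivative zero at and outside the boundary
knots).  Interior knots are placed at the empirical quantiles that split
the observed ages into ``df`` equal-count bins, so with ``df = 3`` the age
range is divided into tertiles and with ``df = 2`` at the median.

The basis functions are the standard truncated-power natural spline basis:
with knots xi_1 < ... < xi_K (boundaries included),

    N_1(x) = x,
    N_{k+1}(x) = d_k(x) - d_{K-1}(x),          k = 1..K-2,
    d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k),

which spans the same space as R's ``splines::ns`` (without intercept).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class NaturalSplineBasis:
    """A natural cubic spline basis of dimension ``df`` on an age range."""

    df: int
    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if len(self.interior_knots) != self.df - 1:
            raise ValueError(
                f"df={self.df} requires {self.df - 1} interior knots, "
                f"got {len(self.interior_knots)}"
            )
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError("boundary knots must be increasing")
        if any(not lo < k < hi for k in self.interior_knots):
            raise ValueError("interior knots must lie strictly inside the boundaries")

    @property
    def all_knots(self) -> np.ndarray:
        return np.asarray(
            [self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1]]
        )

    def __call__(self, ages) -> np.ndarray:
        """Evaluate the basis; returns an array of shape ``(n, df)``.

        Ages are mapped affinely onto [0, 1] (boundary knots at 0 and 1)
        before the truncated-power formula, so every column is O(1);
        this leaves the spanned function space unchanged but keeps the
        downstream likelihood well conditioned.
        """
        lo, hi = self.boundary_knots
        x = (np.atleast_1d(np.asarray(ages, dtype=float)) - lo) / (hi - lo)
        knots = (self.all_knots - lo) / (hi - lo)
        K = len(knots)
        xi_K = knots[-1]

        def d(k: int) -> np.ndarray:
            num = np.clip(x - knots[k], 0.0, None) ** 3 - np.clip(x - xi_K, 0.0, None) ** 3
            return num / (xi_K - knots[k])

        cols = [x]
        if K >= 3:
            d_last = d(K - 2)
            for k in range(K - 2):
                cols.append(d(k) - d_last)
        return np.column_stack(cols)

    def design(self, ages) -> np.ndarray:
        """Basis with a leading intercept column, shape ``(n, df + 1)``."""
        x = np.atleast_1d(np.asarray(ages, dtype=float))
        return np.column_stack([np.ones(len(x)), self(x)])


def build_basis(ages, df: int) -> NaturalSplineBasis:
    """Build a natural spline basis from observed ages.

    Boundary knots sit at the min/max observed age; interior knots at the
    empirical quantiles splitting the observations into ``df`` equal-count
    bins (``df=3`` -> 33.3%/66.7% quantiles, ``df=2`` -> median).
    """
    if df not in (2, 3):
        raise ValueError(f"df must be 2 or 3, got {df}")
    a = np.asarray(ages, dtype=float)
    if len(np.unique(a)) < df + 1:
        raise ValueError(f"need at least {df + 1} distinct ages for df={df}")
    probs = np.arange(1, df) / df
    interior = np.quantile(a, probs)
    lo, hi = float(a.min()), float(a.max())
    # quantiles can collide with a boundary on extremely discrete data
    eps = 1e-9 * (hi - lo)
    interior = np.clip(interior, lo + eps, hi - eps)
    return NaturalSplineBasis(
        df=df,
        interior_knots=tuple(float(k) for k in interior),
        boundary_knots=(lo, hi),
    )
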