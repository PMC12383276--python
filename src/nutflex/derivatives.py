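"""Posterior first-derivative inference for fitted smooths.

For every posterior draw of a fitted smooth the first derivative is
estimated by forward finite differences — evaluate the smooth on a grid,
shift the grid by a very small step, evaluate again, difference and divide
by the step.  Grid points where the central credible interval of the slope
draws excludes zero mark credibly non-flat (increasing or decreasing)
regions of the response.  Intervals are pointwise, not simultaneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "SlopeDraws",
    "Region",
    "CredibleRegions",
    "finite_difference_slopes",
    "detect_nonflat_regions",
]

#: default step, as a fraction of the grid range
EPS_FRACTION = 1e-4


@dataclass
class SlopeDraws:
    """Draw-by-grid matrix of first-derivative values."""

    grid: np.ndarray
    slopes: np.ndarray  # (ndraws, ngrid)
    eps: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        self.slopes = np.asarray(self.slopes, float)
        if self.slopes.shape[1] != self.grid.size:
            raise ValueError("slopes and grid sizes differ")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")


@dataclass(frozen=True)
class Region:
    x_start: float
    x_end: float
    sign: Literal["increasing", "decreasing"]


@dataclass
class CredibleRegions:
    """Ordered, non-overlapping intervals of credibly nonzero slope."""

    regions: list[Region]
    level: float
    grid: np.ndarray = field(repr=False, default=None)
    flagged: np.ndarray = field(repr=False, default=None)  # per-grid-point bool

    def __len__(self) -> int:
        return len(self.regions)

    def covers(self, x: float) -> bool:
        return any(r.x_start <= x <= r.x_end for r in self.regions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.x_start, r.x_end, r.sign) for r in self.regions],
            columns=["x_start", "x_end", "sign"],
        )


def finite_difference_slopes(
    smooth: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    grid: np.ndarray,
    eps: float | None = None,
    *,
    shifted: np.ndarray | None = None,
) -> SlopeDraws:
    """Forward-difference slopes of posterior smooth draws on a grid.

    ``smooth`` is either a callable mapping grid points to a
    (ndraws, npoints) matrix (e.g. ``GAMMResults.smooth``) or a
    precomputed (ndraws, ngrid) matrix, in which case ``shifted`` — the
    same draws evaluated at ``grid + eps`` — must be supplied.  The step
    defaults to 1e-4 of the grid range.
    """
    grid = np.asarray(grid, float)
    if grid.size < 2:
        raise ValueError("need at least 2 grid points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if eps is None:
        eps = EPS_FRACTION * (grid[-1] - grid[0])
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if eps > 0.5 * np.min(np.diff(grid)):
        raise ValueError("eps exceeds half the minimum grid spacing; reduce eps")
    if callable(smooth):
        f0 = np.atleast_2d(smooth(grid))
        f1 = np.atleast_2d(smooth(grid + eps))
    else:
        if shifted is None:
            raise ValueError("precomputed draws require the grid+eps evaluations too")
        f0 = np.atleast_2d(np.asarray(smooth, float))
        f1 = np.atleast_2d(np.asarray(shifted, float))
    if f0.shape != f1.shape or f0.shape[1] != grid.size:
        raise ValueError("smooth evaluations have inconsistent shapes")
    return SlopeDraws(grid=grid, slopes=(f1 - f0) / eps, eps=float(eps))


def detect_nonflat_regions(slopes: SlopeDraws, level: float = 0.95) -> CredibleRegions:
    """Contiguous grid runs whose pointwise slope interval excludes zero.

    At each grid point the central ``level`` interval of the slope draws
    is computed; runs of consecutive points whose interval lies entirely
    above (increasing) or below (decreasing) zero become regions.
    Single-point runs are retained.
    """
    if not 0.5 < level < 1.0:
        raise ValueError("level must be in (0.5, 1)")
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(slopes.slopes, alpha, axis=0)
    hi = np.quantile(slopes.slopes, 1.0 - alpha, axis=0)
    sign = np.zeros(slopes.grid.size, int)
    sign[lo > 0] = 1
    sign[hi < 0] = -1
    regions: list[Region] = []
    i = 0
    n = sign.size
    while i < n:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and sign[j + 1] == sign[i]:
            j += 1
        regions.append(
            Region(
                x_start=float(slopes.grid[i]),
                x_end=float(slopes.grid[j]),
                sign="increasing" if sign[i] > 0 else "decreasing",
            )
        )
        i = j + 1
    return CredibleRegions(regions=regions, level=level, grid=slopes.grid, flagged=sign != 0)
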