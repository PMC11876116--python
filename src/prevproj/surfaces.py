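"""Age x calendar-year rate and prevalence surfaces, and the mortality-rate-ratio schedule.

These are the in-memory containers the projection operates on.  A surface is a
rectangular grid of values over (age, year) for one sex; evaluation between
nodes is bilinear and evaluation outside the grid hull clamps to the nearest
edge, so a surface behaves like a total function on age x year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

SEXES = ("female", "male")


def _check_grid(grid: np.ndarray, name: str) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError(f"{name} must be a 1-d grid with at least 2 nodes")
    if not np.all(np.diff(grid) > 0):
        raise ValueError(f"{name} must be strictly increasing")
    if not np.all(np.isfinite(grid)):
        raise ValueError(f"{name} contains non-finite values")
    return grid


@dataclass
class RateSurface:
    """Per-sex grid of rates (per person-year) over age x calendar year.

    Houses both the incidence rate and the general-population mortality rate.
    ``values[j, k]`` is the rate at ``(age_grid[j], year_grid[k])``.
    """

    sex: str
    age_grid: np.ndarray
    year_grid: np.ndarray
    values: np.ndarray
    _interp: RegularGridInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        self.age_grid = _check_grid(self.age_grid, "age_grid")
        self.year_grid = _check_grid(self.year_grid, "year_grid")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.age_grid.size, self.year_grid.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match grids "
                f"({self.age_grid.size}, {self.year_grid.size})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("rate surface contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("rate surface contains negative values")
        self._interp = RegularGridInterpolator(
            (self.age_grid, self.year_grid), self.values, method="linear"
        )

    def __call__(self, age, year):
        """Bilinear evaluation; coordinates outside the hull clamp to the edge."""
        scalar = np.ndim(age) == 0 and np.ndim(year) == 0
        age = np.clip(age, self.age_grid[0], self.age_grid[-1])
        year = np.clip(year, self.year_grid[0], self.year_grid[-1])
        pts = np.stack(np.broadcast_arrays(age, year), axis=-1)
        out = self._interp(pts)
        return float(out.reshape(())) if scalar else out

    @classmethod
    def constant(cls, sex, value, age_grid, year_grid) -> "RateSurface":
        age_grid = np.asarray(age_grid, float)
        year_grid = np.asarray(year_grid, float)
        return cls(sex, age_grid, year_grid, np.full((age_grid.size, year_grid.size), float(value)))

    @classmethod
    def from_function(cls, sex, fun, age_grid, year_grid) -> "RateSurface":
        """Tabulate ``fun(age, year)`` (vectorised over age) on the grid."""
        age_grid = np.asarray(age_grid, float)
        year_grid = np.asarray(year_grid, float)
        vals = np.empty((age_grid.size, year_grid.size))
        for k, y in enumerate(year_grid):
            vals[:, k] = fun(age_grid, y)
        return cls(sex, age_grid, year_grid, vals)


@dataclass
class PrevalenceSurface:
    """Per-sex grid of prevalence proportions over age x calendar year."""

    sex: str
    age_grid: np.ndarray
    year_grid: np.ndarray
    values: np.ndarray
    _interp: RegularGridInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        self.age_grid = _check_grid(self.age_grid, "age_grid")
        self.year_grid = _check_grid(self.year_grid, "year_grid")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.age_grid.size, self.year_grid.size):
            raise ValueError("values shape does not match grids")
        if np.any(self.values < 0) or np.any(self.values > 1) or not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("prevalence values must lie in [0, 1]")
        self._interp = RegularGridInterpolator(
            (self.age_grid, self.year_grid), self.values, method="linear"
        )

    def __call__(self, age, year):
        scalar = np.ndim(age) == 0 and np.ndim(year) == 0
        age = np.clip(age, self.age_grid[0], self.age_grid[-1])
        year = np.clip(year, self.year_grid[0], self.year_grid[-1])
        pts = np.stack(np.broadcast_arrays(age, year), axis=-1)
        out = self._interp(pts)
        return float(out.reshape(())) if scalar else out

    def at_year(self, year: float) -> np.ndarray:
        """Age profile at one grid year (exact column, no interpolation)."""
        k = np.flatnonzero(np.isclose(self.year_grid, year))
        if k.size != 1:
            raise KeyError(f"year {year} not on the surface's year grid")
        return self.values[:, k[0]].copy()

    def restrict_years(self, first: float, last: float) -> "PrevalenceSurface":
        keep = (self.year_grid >= first) & (self.year_grid <= last)
        return PrevalenceSurface(self.sex, self.age_grid, self.year_grid[keep], self.values[:, keep])


@dataclass
class MRRSchedule:
    """Mortality rate ratio (ill vs. healthy) by age, declining geometrically in time.

    The evaluated ratio is ``max(floor, base_mrr(age) * annual_factor**(year - base_year))``
    with ``base_mrr`` piecewise linear in age (edge-clamped).  The default
    annual factor 0.98 encodes a 2 %/year decline in excess mortality.
    """

    sex: str
    base_year: float
    base_ages: np.ndarray
    base_values: np.ndarray
    annual_factor: float = 0.98
    floor: float = 1.0

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        self.base_ages = _check_grid(self.base_ages, "base_ages")
        self.base_values = np.asarray(self.base_values, dtype=float)
        if self.base_values.shape != self.base_ages.shape:
            raise ValueError("base_values must match base_ages")
        if np.any(self.base_values < 1):
            raise ValueError("baseline MRR must be >= 1 at every age")
        if not 0 < self.annual_factor <= 1:
            raise ValueError("annual_factor must lie in (0, 1]")

    def base_mrr(self, age):
        return np.interp(age, self.base_ages, self.base_values)

    def __call__(self, age, year):
        decayed = self.base_mrr(age) * self.annual_factor ** (np.asarray(year, float) - self.base_year)
        return np.maximum(self.floor, decayed)

    @classmethod
    def constant(cls, sex, value, base_year=2010.0) -> "MRRSchedule":
        return cls(sex, base_year, np.array([0.0, 200.0]), np.array([value, value]), annual_factor=1.0)
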