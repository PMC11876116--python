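"""Prevalence projection in the illness-death model.

The model has three states (healthy, ill, dead) with incidence i(a, t),
mortality m0 among the healthy and m1 among the ill.  The age-specific
prevalence p(a, t) satisfies

    (d/dt + d/da) p = (1 - p) * [ i - p * (m1 - m0) ]

Because m0 is rarely observed, the excess-mortality term ``p * (m1 - m0)`` is
replaced by the algebraically equivalent expression

    p * (MRR - 1) * m / (p * (MRR - 1) + 1)

which only needs the general-population mortality m and the mortality rate
ratio MRR = m1 / m0.  Along a characteristic line a = a0 + s, t = t0 + s the
equation is an ordinary differential equation in s, which we integrate with a
classical 4th-order Runge-Kutta scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .surfaces import MRRSchedule, PrevalenceSurface, RateSurface

DEFAULT_STEP = 0.1  # years


def excess_mortality_term(p, m, mrr):
    """Excess mortality attributable to prevalent cases, p*(MRR-1)*m / (p*(MRR-1)+1).

    This equals p*(m1 - m0) when m is the all-state mortality and MRR = m1/m0.
    Accepts scalars or arrays; validates the epidemiological domain.
    """
    p = np.asarray(p, float)
    m = np.asarray(m, float)
    mrr = np.asarray(mrr, float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("prevalence p must lie in [0, 1]")
    if np.any(m < 0):
        raise ValueError("mortality m must be nonnegative")
    if np.any(mrr < 1):
        raise ValueError("mortality rate ratio must be >= 1")
    k = p * (mrr - 1.0)
    out = k * m / (k + 1.0)
    return float(out) if out.ndim == 0 else out


def prevalence_rhs(p, i, m, mrr):
    """Rate of change of prevalence along a characteristic: (1-p)*(i - excess)."""
    i = np.asarray(i, float)
    if np.any(i < 0):
        raise ValueError("incidence i must be nonnegative")
    out = (1.0 - np.asarray(p, float)) * (i - excess_mortality_term(p, m, mrr))
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class CharacteristicPath:
    """Prevalence along one age-time characteristic (age and year move in lockstep)."""

    start_age: float
    start_year: float
    step: float
    ages: np.ndarray
    years: np.ndarray
    prevalence: np.ndarray

    @property
    def final_prevalence(self) -> float:
        return float(self.prevalence[-1])


def _rhs_on_surfaces(p, age, year, incidence, mortality, mrr):
    i = incidence(age, year)
    m = mortality(age, year)
    r = mrr(age, year)
    bad = ~(np.isfinite(np.asarray(i)) & np.isfinite(np.asarray(m)) & np.isfinite(np.asarray(r)))
    if np.any(bad):
        a_bad = np.asarray(np.broadcast_to(age, np.shape(bad)))[bad] if np.ndim(bad) else age
        raise ArithmeticError(
            f"non-finite rate at age={a_bad}, year={year}: check input surfaces"
        )
    return prevalence_rhs(p, i, m, r)


def _rk4_step(p, age, year, h, incidence, mortality, mrr):
    """One classical Runge-Kutta step of size h along the characteristic."""
    k1 = _rhs_on_surfaces(p, age, year, incidence, mortality, mrr)
    k2 = _rhs_on_surfaces(
        np.clip(p + 0.5 * h * k1, 0.0, 1.0), age + 0.5 * h, year + 0.5 * h, incidence, mortality, mrr
    )
    k3 = _rhs_on_surfaces(
        np.clip(p + 0.5 * h * k2, 0.0, 1.0), age + 0.5 * h, year + 0.5 * h, incidence, mortality, mrr
    )
    k4 = _rhs_on_surfaces(
        np.clip(p + h * k3, 0.0, 1.0), age + h, year + h, incidence, mortality, mrr
    )
    return np.clip(p + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0, 1.0)


def integrate_characteristic(
    p_start: float,
    start_age: float,
    start_year: float,
    end_year: float,
    incidence: RateSurface,
    mortality: RateSurface,
    mrr: MRRSchedule,
    step: float = DEFAULT_STEP,
) -> CharacteristicPath:
    """Integrate prevalence along the characteristic from (start_age, start_year).

    Age and calendar year advance jointly in increments of ``step``; the final
    node sits at (start_age + D, end_year) with D = end_year - start_year.
    Prevalence is clipped to [0, 1] after every step.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if end_year < start_year:
        raise ValueError("end_year must not precede start_year")
    if not 0 <= p_start <= 1:
        raise ValueError("p_start must lie in [0, 1]")
    span = end_year - start_year
    n = max(1, int(round(span / step))) if span > 0 else 0
    h = span / n if n else 0.0
    p = float(p_start)
    ps = np.empty(n + 1)
    ps[0] = p
    for j in range(n):
        s = j * h
        p = float(_rk4_step(p, start_age + s, start_year + s, h, incidence, mortality, mrr))
        ps[j + 1] = p
    offs = np.arange(n + 1) * (h if n else 1.0)
    return CharacteristicPath(
        start_age=start_age,
        start_year=start_year,
        step=h if n else step,
        ages=start_age + offs,
        years=start_year + offs,
        prevalence=ps,
    )


def project_prevalence_surface(
    initial_prevalence: np.ndarray,
    boundary_prevalence: float,
    incidence: RateSurface,
    mortality: RateSurface,
    mrr: MRRSchedule,
    age_grid: np.ndarray,
    year_grid: np.ndarray,
    step: float = DEFAULT_STEP,
) -> PrevalenceSurface:
    """Project the full prevalence surface from a base-year age profile.

    One characteristic runs from every age node on the base-year line and from
    the minimum-age node of every later year line (cohorts entering adulthood
    at the boundary prevalence).  The grid uses unit year spacing, so the
    characteristics pass exactly through the grid nodes: advancing the whole
    base column diagonally fills the surface without any resampling error.
    """
    age_grid = np.asarray(age_grid, float)
    year_grid = np.asarray(year_grid, float)
    initial_prevalence = np.asarray(initial_prevalence, float)
    if initial_prevalence.shape != age_grid.shape:
        raise ValueError("initial prevalence must cover the age grid")
    if np.any(initial_prevalence < 0) or np.any(initial_prevalence > 1):
        raise ValueError("initial prevalence must lie in [0, 1]")
    if not 0 <= boundary_prevalence <= 1:
        raise ValueError("boundary prevalence must lie in [0, 1]")
    dyear = np.diff(year_grid)
    dage = np.diff(age_grid)
    if not (np.allclose(dyear, 1.0) and np.allclose(dage, 1.0)):
        raise ValueError(
            "characteristic geometry requires unit-spaced age and year grids"
        )
    n_sub = max(1, int(round(1.0 / step)))
    h = 1.0 / n_sub

    n_age, n_year = age_grid.size, year_grid.size
    surf = np.empty((n_age, n_year))
    surf[:, 0] = initial_prevalence
    col = initial_prevalence.copy()
    for k in range(n_year - 1):
        year = year_grid[k]
        for j in range(n_sub):
            s = j * h
            col = _rk4_step(col, age_grid + s, year + s, h, incidence, mortality, mrr)
        # node (a_j, y_k) has moved to (a_j + 1, y_{k+1}); the top value leaves the grid
        new = np.empty(n_age)
        new[0] = boundary_prevalence
        new[1:] = col[:-1]
        surf[:, k + 1] = new
        col = new
    return PrevalenceSurface(incidence.sex, age_grid, year_grid, surf)
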