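"""Scenario construction and orchestration of the prevalence projection.

Six scenarios are supported.  Five feed the illness-death projection with
different future courses of the incidence rate: the fitted trend is used for
2015 up to a scenario-specific end year (2021 for "constant incidence", else
2025/2030/2035/2040) and frozen per (sex, age) thereafter; years before 2015
reuse the 2015 prediction.  The sixth ("constant prevalence") bypasses the
projection and freezes the age-specific prevalence of the first reporting
year, so only demographic change moves the case counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import demio
from .projection import DEFAULT_STEP, project_prevalence_surface
from .surfaces import SEXES, MRRSchedule, PrevalenceSurface, RateSurface
from .trend import IncidenceTrendModel

TREND_FIT_START = 2015


@dataclass(frozen=True)
class ScenarioSpec:
    """One projection scenario: incidence-trend end year and time frame."""

    name: str
    trend_end_year: int | None  # None for the constant-prevalence counterfactual
    base_year: int = 2010
    horizon: int = 2040
    report_start: int = 2015

    def __post_init__(self) -> None:
        if self.trend_end_year is not None and not (
            2021 <= self.trend_end_year <= self.horizon
        ):
            raise ValueError("trend_end_year must lie in [2021, horizon]")

    @property
    def uses_pde(self) -> bool:
        return self.trend_end_year is not None


SCENARIOS: dict[str, ScenarioSpec] = {
    "constant_prevalence": ScenarioSpec("constant_prevalence", None),
    "constant_incidence": ScenarioSpec("constant_incidence", 2021),
    "trend_until_2025": ScenarioSpec("trend_until_2025", 2025),
    "trend_until_2030": ScenarioSpec("trend_until_2030", 2030),
    "trend_until_2035": ScenarioSpec("trend_until_2035", 2035),
    "trend_until_2040": ScenarioSpec("trend_until_2040", 2040),
}


def get_scenario(name: str, **overrides) -> ScenarioSpec:
    try:
        spec = SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        ) from None
    return replace(spec, **overrides) if overrides else spec


def build_incidence_surface(
    model: IncidenceTrendModel,
    scenario: ScenarioSpec,
    age_grid: np.ndarray,
    year_grid: np.ndarray,
    sex: str,
) -> RateSurface:
    """Scenario incidence surface on the projection grid.

    Every calendar year is mapped onto an effective prediction year clipped to
    [2015, trend_end_year]: before 2015 the 2015 prediction is reused, after
    the scenario's end year the incidence is frozen at its end-year value.
    """
    if not scenario.uses_pde:
        raise ValueError(
            "the constant-prevalence scenario has no incidence surface; "
            "it bypasses the illness-death projection"
        )
    age_grid = np.asarray(age_grid, float)
    year_grid = np.asarray(year_grid, float)
    vals = np.empty((age_grid.size, year_grid.size))
    for k, y in enumerate(year_grid):
        y_eff = min(max(y, TREND_FIT_START), scenario.trend_end_year)
        vals[:, k] = model.predict(sex, age_grid, y_eff)
    return RateSurface(sex, age_grid, year_grid, vals)


def mrr_at(schedule: MRRSchedule, sex: str, age, year):
    """Mortality rate ratio at (age, year): max(floor, base_mrr(age) * factor^(year-base))."""
    if sex != schedule.sex:
        raise ValueError(f"schedule is for sex={schedule.sex!r}, asked for {sex!r}")
    if np.any(np.asarray(year, float) < schedule.base_year):
        raise ValueError(f"year precedes the schedule's base year {schedule.base_year}")
    return schedule(age, year)


@dataclass
class ProjectionGrid:
    """Rectangular age x year grid of the projection (unit spacing)."""

    age_min: int = 18
    age_max: int = 100
    base_year: int = 2010
    horizon: int = 2040

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_min, self.age_max + 1, dtype=float)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.base_year, self.horizon + 1, dtype=float)


def run_scenario(
    scenario: ScenarioSpec,
    model: IncidenceTrendModel,
    baseline_prevalence: dict[str, np.ndarray],
    mortality: dict[str, RateSurface],
    mrr: dict[str, MRRSchedule],
    population: pd.DataFrame,
    grid: ProjectionGrid | None = None,
    step: float = DEFAULT_STEP,
) -> "demio.ProjectionResult":
    """Run one scenario end to end and attach population case counts.

    ``baseline_prevalence`` maps sex to the age profile at the grid's base
    year.  For projection scenarios the full prevalence surface is integrated
    from the base year to the horizon and reported from ``report_start``; the
    constant-prevalence counterfactual first needs the common projected
    prevalence of the first reporting year, which it takes from a projection
    run (all scenarios coincide up to 2021) and then freezes.
    """
    if grid is None:
        grid = ProjectionGrid(base_year=scenario.base_year, horizon=scenario.horizon)
    surfaces: dict[str, PrevalenceSurface] = {}
    if scenario.uses_pde:
        for sex in SEXES:
            inc = build_incidence_surface(model, scenario, grid.ages, grid.years, sex)
            full = project_prevalence_surface(
                baseline_prevalence[sex],
                float(baseline_prevalence[sex][0]),
                inc,
                mortality[sex],
                mrr[sex],
                grid.ages,
                grid.years,
                step=step,
            )
            surfaces[sex] = full.restrict_years(scenario.report_start, scenario.horizon)
        return demio.build_projection_result(scenario.name, surfaces, population)

    # constant prevalence: freeze the common report_start profile
    ref = get_scenario("constant_incidence", base_year=scenario.base_year, horizon=scenario.horizon)
    profiles: dict[str, np.ndarray] = {}
    for sex in SEXES:
        inc = build_incidence_surface(model, ref, grid.ages, grid.years, sex)
        full = project_prevalence_surface(
            baseline_prevalence[sex],
            float(baseline_prevalence[sex][0]),
            inc,
            mortality[sex],
            mrr[sex],
            grid.ages,
            grid.years,
            step=step,
        )
        profiles[sex] = full.at_year(scenario.report_start)
    years = np.arange(scenario.report_start, scenario.horizon + 1, dtype=float)
    return demio.constant_prevalence_projection(
        scenario.name, profiles, grid.ages, years, population
    )
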