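"""Synthetic study inputs with known ground truth, plus a cohort oracle.

The generator emulates the structure of the five inputs a national
prevalence projection needs — grouped incidence estimates by sex and year,
baseline age-specific prevalence, general-population mortality, a
mortality-rate-ratio profile, and a population projection — from a small set
of parametric laws:

* incidence:  log i = alpha(sex) + beta(sex) * s(age) + gamma(sex) * (year - 2015),
  with ``s`` a logistic age shape rising to a plateau near age 70;
* mortality:  Gompertz m = a(sex) * exp(b * age) with a per-year improvement
  factor;
* MRR: piecewise linear in age, declining from about 3 at age 30 to about
  1.3 at age 90, with a 2 %/year calendar decline;
* population: Gaussian-bell age pyramid whose mean age drifts upward.

The baseline prevalence is *model consistent*: it is produced by running the
independent cohort microsimulation (explicit Euler on healthy/ill occupancy,
not on prevalence) under the same laws, so a correct projector started from
it reproduces the ground-truth prevalence at any later year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .demio import write_table
from .scenarios import ProjectionGrid
from .surfaces import SEXES, MRRSchedule, RateSurface

DEFAULT_AGE_GROUPS = ("18-34", "35-49", "50-64", "65-79", "80+")
DEFAULT_YEARS = tuple(range(2015, 2022))
DEFAULT_NOISE_SD = 0.05  # log-scale sd of the sampled group estimates


@dataclass(frozen=True)
class GroundTruthParams:
    """Parameters of the generating laws (per-sex values keyed female/male)."""

    incidence_alpha: dict = field(default_factory=lambda: {"female": -6.85, "male": -6.65})
    incidence_beta: dict = field(default_factory=lambda: {"female": 3.6, "male": 3.6})
    incidence_gamma: dict = field(default_factory=lambda: {"female": 0.012, "male": 0.010})
    age_shape_center: float = 55.0
    age_shape_scale: float = 12.0
    mort_scale: dict = field(default_factory=lambda: {"female": 0.8e-5, "male": 1.2e-5})
    mort_gompertz_b: float = 0.10
    mort_improvement: float = 0.995  # per-year multiplicative factor
    mrr_young: float = 3.0  # at age 30
    mrr_old: float = 1.3  # at age 90
    mrr_annual_factor: float = 0.98
    base_year: int = 2010
    pop_scale: dict = field(default_factory=lambda: {"female": 7.5e5, "male": 7.2e5})
    pop_mean_age: float = 45.0
    pop_aging_per_year: float = 0.2
    pop_sd: float = 18.0
    entry_prevalence: float = 0.005  # prevalence at age 18

    def validate(self) -> None:
        for sex in SEXES:
            if not -12 < self.incidence_alpha[sex] < -2:
                raise ValueError(f"incidence_alpha[{sex}] out of admissible range (-12, -2)")
            if not 0 <= self.incidence_beta[sex] < 8:
                raise ValueError(f"incidence_beta[{sex}] out of admissible range [0, 8)")
            if abs(self.incidence_gamma[sex]) > 0.1:
                raise ValueError(f"incidence_gamma[{sex}] out of admissible range [-0.1, 0.1]")
            if self.mort_scale[sex] <= 0:
                raise ValueError(f"mort_scale[{sex}] must be positive")
            if self.pop_scale[sex] <= 0:
                raise ValueError(f"pop_scale[{sex}] must be positive")
        if not 0 < self.mort_gompertz_b < 0.2:
            raise ValueError("mort_gompertz_b out of admissible range (0, 0.2)")
        if not 0.9 <= self.mort_improvement <= 1.0:
            raise ValueError("mort_improvement out of admissible range [0.9, 1.0]")
        if self.mrr_young < self.mrr_old or self.mrr_old < 1:
            raise ValueError("MRR must decline with age and stay >= 1")
        if not 0 < self.mrr_annual_factor <= 1:
            raise ValueError("mrr_annual_factor must lie in (0, 1]")
        if not 0 <= self.entry_prevalence < 0.05:
            raise ValueError("entry_prevalence out of admissible range [0, 0.05)")
        if self.age_shape_scale <= 0 or self.pop_sd <= 0:
            raise ValueError("age_shape_scale and pop_sd must be positive")


@dataclass
class GroundTruth:
    """Evaluable generating laws for incidence, mortality, MRR and population."""

    params: GroundTruthParams
    _prev_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def age_shape(self, age):
        p = self.params
        return 1.0 / (1.0 + np.exp(-(np.asarray(age, float) - p.age_shape_center) / p.age_shape_scale))

    def incidence(self, sex, age, year):
        p = self.params
        log_i = (
            p.incidence_alpha[sex]
            + p.incidence_beta[sex] * self.age_shape(age)
            + p.incidence_gamma[sex] * (np.asarray(year, float) - 2015.0)
        )
        return np.exp(log_i)

    def mortality(self, sex, age, year):
        p = self.params
        return (
            p.mort_scale[sex]
            * np.exp(p.mort_gompertz_b * np.asarray(age, float))
            * p.mort_improvement ** (np.asarray(year, float) - p.base_year)
        )

    def mrr_schedule(self, sex) -> MRRSchedule:
        p = self.params
        return MRRSchedule(
            sex=sex,
            base_year=float(p.base_year),
            base_ages=np.array([18.0, 30.0, 90.0, 110.0]),
            base_values=np.array([p.mrr_young, p.mrr_young, p.mrr_old, p.mrr_old]),
            annual_factor=p.mrr_annual_factor,
        )

    def mrr(self, sex, age, year):
        return self.mrr_schedule(sex)(age, year)

    def population(self, sex, age, year):
        p = self.params
        mu = p.pop_mean_age + p.pop_aging_per_year * (np.asarray(year, float) - p.base_year)
        return p.pop_scale[sex] * np.exp(-((np.asarray(age, float) - mu) ** 2) / (2.0 * p.pop_sd**2))

    def incidence_surface(self, sex, age_grid, year_grid) -> RateSurface:
        return RateSurface.from_function(
            sex, lambda a, y: self.incidence(sex, a, y), age_grid, year_grid
        )

    def mortality_surface(self, sex, age_grid, year_grid) -> RateSurface:
        return RateSurface.from_function(
            sex, lambda a, y: self.mortality(sex, a, y), age_grid, year_grid
        )

    def population_table(self, age_grid, year_grid) -> pd.DataFrame:
        rows = []
        for sex in SEXES:
            for year in np.asarray(year_grid, float):
                rows.append(
                    pd.DataFrame(
                        {
                            "sex": sex,
                            "age": np.asarray(age_grid, float),
                            "year": year,
                            "count": self.population(sex, age_grid, year),
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def prevalence_profile(self, sex, age_grid, year, dt: float = 0.005) -> np.ndarray:
        """Model-consistent prevalence at ``year`` by running the cohort oracle.

        Every age node's cohort is simulated from adulthood (age 18, at the
        entry prevalence) forward to ``year`` under the generating laws.  The
        Euler recursion runs on all cohorts simultaneously, which keeps this
        exact per cohort while staying fast.
        """
        key = (sex, float(year), round(dt, 9), tuple(np.asarray(age_grid, float)))
        if key in self._prev_cache:
            return self._prev_cache[key].copy()
        ages = np.asarray(age_grid, float)
        p0 = self.params.entry_prevalence
        H = np.full(ages.size, 1.0 - p0)
        I = np.full(ages.size, p0)
        # cohort j is at age ages[j] in `year`, i.e. it turned 18 at year - (ages[j]-18)
        birth18 = float(year) - (ages - 18.0)
        n_steps = np.round((ages - 18.0) / dt).astype(int)
        max_steps = int(n_steps.max())
        for step_idx in range(max_steps):
            active = step_idx < n_steps
            s = step_idx * dt
            a = np.where(active, 18.0 + s, 18.0)
            t = np.where(active, birth18 + s, birth18)
            i = self.incidence(sex, a, t)
            m = self.mortality(sex, a, t)
            r = self.mrr(sex, a, t)
            p = I / (H + I)
            m0 = m / (p * (r - 1.0) + 1.0)
            m1 = r * m0
            H_new = H * (1.0 - (i + m0) * dt)
            I_new = I * (1.0 - m1 * dt) + H * i * dt
            H = np.where(active, H_new, H)
            I = np.where(active, I_new, I)
            if np.any(H < 0) or np.any(I < 0):
                raise ValueError("dt too large: state occupancy went negative")
        prof = I / (H + I)
        self._prev_cache[key] = prof.copy()
        return prof


def generate_ground_truth(params: GroundTruthParams | None = None, seed: int | None = None) -> GroundTruth:
    """Deterministic ground truth for given parameters.

    With ``seed`` set, the incidence/mortality parameters are jittered around
    the defaults (within their admissible ranges) to produce distinct but
    realistic parameter draws for validation studies; without a seed the
    documented defaults are used as-is.
    """
    if params is None:
        params = GroundTruthParams()
    if seed is not None:
        rng = np.random.default_rng(seed)
        params = replace(
            params,
            incidence_alpha={s: params.incidence_alpha[s] + rng.uniform(-0.3, 0.3) for s in SEXES},
            incidence_beta={s: params.incidence_beta[s] + rng.uniform(-0.4, 0.4) for s in SEXES},
            incidence_gamma={s: params.incidence_gamma[s] + rng.uniform(-0.005, 0.01) for s in SEXES},
            mort_scale={s: params.mort_scale[s] * rng.uniform(0.8, 1.25) for s in SEXES},
            mrr_young=params.mrr_young + rng.uniform(-0.5, 0.5),
            mrr_old=params.mrr_old + rng.uniform(-0.2, 0.2),
        )
    params.validate()
    return GroundTruth(params)


def group_incidence(truth: GroundTruth, sex: str, age_group: str, year: float, top_age: float = 100.0) -> float:
    """Person-time-weighted mean of the true incidence over a group's ages."""
    from .trend import parse_age_group

    lo, hi = parse_age_group(age_group, top_age=top_age)
    ages = np.arange(lo, hi + 1, dtype=float)
    w = truth.population(sex, ages, year)
    i = truth.incidence(sex, ages, year)
    return float((w * i).sum() / w.sum())


def sample_incidence_estimates(
    truth: GroundTruth,
    age_groups=DEFAULT_AGE_GROUPS,
    years=DEFAULT_YEARS,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
    pandemic_dip: float | None = None,
) -> pd.DataFrame:
    """Grouped incidence estimates as a study would publish them.

    Group rates are person-time-weighted means of the true rate (weights from
    the synthetic population), multiplied by exp(Normal(0, noise_sd)) noise.
    ``pandemic_dip`` optionally multiplies the 2020 rates by a factor < 1 to
    emulate the under-ascertainment dip seen in claims data during the
    pandemic year.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    for sex in SEXES:
        for g in age_groups:
            for y in years:
                rate = group_incidence(truth, sex, g, y)
                if pandemic_dip is not None and int(y) == 2020:
                    rate *= pandemic_dip
                if noise_sd > 0:
                    rate *= float(np.exp(rng.normal(0.0, noise_sd)))
                rows.append({"sex": sex, "age_group": g, "year": int(y), "rate": rate})
    return pd.DataFrame(rows)


def cohort_microsimulation(
    i_fun,
    m_fun,
    mrr_fun,
    p0: float,
    start_age: float,
    start_year: float,
    end_year: float,
    dt: float = 0.001,
):
    """Independent discrete-time oracle for one cohort's prevalence trajectory.

    Explicit Euler forward recursion on the healthy (H) and ill (I) occupancy
    fractions — structurally independent of the prevalence-ODE code path.  At
    each step the healthy-state mortality is recovered from the population
    mortality via m0 = m / (p*(MRR-1) + 1) and m1 = MRR * m0, then

        H <- H * (1 - (i + m0) dt),   I <- I * (1 - m1 dt) + H_old * i dt.

    Returns (times, prevalence) arrays with times in years since start.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not 0 <= p0 <= 1:
        raise ValueError("p0 must lie in [0, 1]")
    span = float(end_year) - float(start_year)
    if span < 0:
        raise ValueError("end_year must not precede start_year")
    n = max(1, int(round(span / dt))) if span > 0 else 0
    h = span / n if n else 0.0
    H, I = 1.0 - p0, p0
    prev = np.empty(n + 1)
    prev[0] = p0
    for j in range(n):
        s = j * h
        a, t = start_age + s, start_year + s
        i = float(i_fun(a, t))
        m = float(m_fun(a, t))
        r = float(mrr_fun(a, t))
        p = I / (H + I)
        m0 = m / (p * (r - 1.0) + 1.0)
        m1 = r * m0
        H_new = H * (1.0 - (i + m0) * h)
        I_new = I * (1.0 - m1 * h) + H * i * h
        if H_new < 0 or I_new < 0:
            raise ValueError(f"dt={dt} too large: occupancy went negative at step {j}")
        H, I = H_new, I_new
        prev[j + 1] = I / (H + I)
    times = np.arange(n + 1) * (h if n else 1.0)
    return times, prev


def write_input_tables(
    truth: GroundTruth,
    outdir,
    grid: ProjectionGrid | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
    pandemic_dip: float | None = None,
) -> dict[str, Path]:
    """Write all five input tables (CSV) so the pipeline runs end to end."""
    if grid is None:
        grid = ProjectionGrid()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ages, years = grid.ages, grid.years
    paths: dict[str, Path] = {}

    est = sample_incidence_estimates(truth, noise_sd=noise_sd, seed=seed, pandemic_dip=pandemic_dip)
    paths["incidence_estimates"] = outdir / "incidence_estimates.csv"
    write_table(est, paths["incidence_estimates"])

    mort = []
    for sex in SEXES:
        for y in years:
            mort.append(
                pd.DataFrame({"sex": sex, "age": ages, "year": y, "rate": truth.mortality(sex, ages, y)})
            )
    paths["mortality"] = outdir / "mortality.csv"
    write_table(pd.concat(mort, ignore_index=True), paths["mortality"])

    prev = []
    for sex in SEXES:
        prof = truth.prevalence_profile(sex, ages, grid.base_year)
        prev.append(
            pd.DataFrame({"sex": sex, "age": ages, "year": float(grid.base_year), "prevalence": prof})
        )
    paths["prevalence"] = outdir / "baseline_prevalence.csv"
    write_table(pd.concat(prev, ignore_index=True), paths["prevalence"])

    mrr = []
    for sex in SEXES:
        sched = truth.mrr_schedule(sex)
        mrr.append(
            pd.DataFrame(
                {"sex": sex, "age": ages, "year": float(grid.base_year), "mrr": sched.base_mrr(ages)}
            )
        )
    paths["mrr"] = outdir / "mrr.csv"
    write_table(pd.concat(mrr, ignore_index=True), paths["mrr"])

    paths["population"] = outdir / "population.csv"
    write_table(truth.population_table(ages, years), paths["population"])
    return paths
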