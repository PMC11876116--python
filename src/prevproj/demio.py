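"""Tabular input/output, prevalence-to-count conversion and aggregation.

All tables are comma-separated UTF-8 text with a header row.  Column
contracts by kind (rates are per person-year after loading; ``rate_scale``
handles per-1000 inputs):

====================  =============================================
kind                  columns
====================  =============================================
incidence_estimates   sex, age_group, year, rate
mortality             sex, age, year, rate
prevalence            sex, age, year, prevalence
mrr                   sex, age, year, mrr
population            sex, age, year, count
====================  =============================================

Age groups are written as ``"lo-hi"`` or ``"lo+"`` tokens.  Population ages
are single years with an open-ended top age that is assigned to the top node
of the projection grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .surfaces import SEXES, PrevalenceSurface, RateSurface
from .trend import parse_age_group

TABLE_SCHEMAS: dict[str, tuple[tuple[str, ...], str]] = {
    # kind -> (key columns, value column)
    "incidence_estimates": (("sex", "age_group", "year"), "rate"),
    "mortality": (("sex", "age", "year"), "rate"),
    "prevalence": (("sex", "age", "year"), "prevalence"),
    "mrr": (("sex", "age", "year"), "mrr"),
    "population": (("sex", "age", "year"), "count"),
}

#: value columns that are rates and may be given per 1000 person-years
_RATE_KINDS = {"incidence_estimates", "mortality"}


def write_table(df: pd.DataFrame, path) -> None:
    """CSV writer with %.17g floats so write-then-read round-trips exactly."""
    df.to_csv(path, index=False, float_format="%.17g")


def read_rate_table(path, kind: str, rate_scale: str = "per1") -> pd.DataFrame:
    """Read and validate one of the five input tables.

    ``rate_scale`` is ``"per1"`` or ``"per1000"`` and only applies to rate
    kinds; per-1000 values are rescaled to per-1 on load.  Raises ``ValueError``
    naming the offending column/row on any contract violation.
    """
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; choose from {sorted(TABLE_SCHEMAS)}")
    keys, value_col = TABLE_SCHEMAS[kind]
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in (*keys, value_col) if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table {path} is missing columns {missing}")
    bad_sex = set(df["sex"].astype(str)) - set(SEXES)
    if bad_sex:
        raise ValueError(f"{kind} table {path} has unknown sex labels {sorted(bad_sex)}")
    if df.duplicated(subset=list(keys)).any():
        dup = df[df.duplicated(subset=list(keys))].iloc[0]
        raise ValueError(f"{kind} table {path} has duplicate key {tuple(dup[list(keys)])}")
    vals = pd.to_numeric(df[value_col], errors="coerce")
    if vals.isna().any():
        row = int(vals.index[vals.isna()][0])
        raise ValueError(f"{kind} table {path}: non-numeric {value_col} in row {row}")
    if (vals < 0).any():
        row = int(vals.index[vals < 0][0])
        raise ValueError(f"{kind} table {path}: negative {value_col} in row {row}")
    if kind == "incidence_estimates":
        if (vals == 0).any():
            row = int(vals.index[vals == 0][0])
            raise ValueError(
                f"incidence_estimates table {path}: zero rate in row {row} "
                "(log-linear fitting needs positive rates)"
            )
        for g in df["age_group"].unique():
            parse_age_group(g)  # raises with the label on unparseable groups
    if kind == "prevalence" and (vals > 1).any():
        row = int(vals.index[vals > 1][0])
        raise ValueError(f"prevalence table {path}: value > 1 in row {row}")
    if kind == "mrr" and (vals < 1).any():
        row = int(vals.index[vals < 1][0])
        raise ValueError(f"mrr table {path}: ratio < 1 in row {row}")
    df[value_col] = vals
    if kind in _RATE_KINDS:
        if rate_scale == "per1000":
            df[value_col] = df[value_col] / 1000.0
        elif rate_scale != "per1":
            raise ValueError("rate_scale must be 'per1' or 'per1000'")
    df["sex"] = df["sex"].astype(str)
    return df


def surface_from_table(df: pd.DataFrame, sex: str, value_col: str = "rate") -> RateSurface:
    """Pivot a long (sex, age, year, value) table into a RateSurface for one sex."""
    sub = df[df["sex"] == sex]
    if sub.empty:
        raise ValueError(f"no rows for sex={sex!r}")
    wide = sub.pivot(index="age", columns="year", values=value_col).sort_index()
    if wide.isna().any().any():
        raise ValueError(f"(age, year) grid for sex={sex!r} is incomplete")
    return RateSurface(sex, wide.index.to_numpy(float), wide.columns.to_numpy(float), wide.to_numpy(float))


def surface_to_table(surface, value_col: str = "value") -> pd.DataFrame:
    """Long-format (sex, age, year, value) view of any surface."""
    ages = np.repeat(surface.age_grid, surface.year_grid.size)
    years = np.tile(surface.year_grid, surface.age_grid.size)
    return pd.DataFrame(
        {
            "sex": surface.sex,
            "age": ages,
            "year": years,
            value_col: surface.values.ravel(),
        }
    )


def _population_on_grid(population: pd.DataFrame, sex: str, year: float, age_grid: np.ndarray) -> np.ndarray:
    """Counts aligned to the surface age grid; ages above the top node pool there."""
    sub = population[(population["sex"] == sex) & (population["year"] == year)]
    if sub.empty:
        raise KeyError(f"population has no rows for sex={sex!r}, year={year}")
    counts = np.zeros(age_grid.size)
    top = age_grid[-1]
    for age, n in zip(sub["age"].to_numpy(float), sub["count"].to_numpy(float)):
        if age < age_grid[0]:
            continue  # below the adult range
        j = int(np.searchsorted(age_grid, min(age, top)))
        counts[j] += n
    return counts


def counts_from_prevalence(
    prevalence: PrevalenceSurface, population: pd.DataFrame, year: float
) -> tuple[pd.DataFrame, float]:
    """Age-specific case counts count(a) = p(a) * N(a) and their adult total."""
    p = prevalence.at_year(year)
    n = _population_on_grid(population, prevalence.sex, year, prevalence.age_grid)
    counts = p * n
    df = pd.DataFrame(
        {
            "sex": prevalence.sex,
            "age": prevalence.age_grid,
            "year": float(year),
            "prevalence": p,
            "population": n,
            "count": counts,
        }
    )
    return df, float(counts.sum())


def overall_prevalence(prevalence: PrevalenceSurface, population: pd.DataFrame, year: float) -> float:
    """Population-weighted (crude) adult prevalence, sum p*N / sum N."""
    p = prevalence.at_year(year)
    n = _population_on_grid(population, prevalence.sex, year, prevalence.age_grid)
    total = n.sum()
    if total <= 0:
        raise ValueError(f"zero adult population for sex={prevalence.sex!r}, year={year}")
    return float((p * n).sum() / total)


@dataclass
class ProjectionResult:
    """Scenario output: prevalence surfaces per sex plus counts and totals.

    ``counts`` holds one row per (sex, age, year) with prevalence, population
    and case count; ``totals`` one row per (sex, year) — including pooled
    ``sex="total"`` rows — with total population, total cases and crude
    prevalence.
    """

    scenario: str
    prevalence: dict[str, PrevalenceSurface]
    counts: pd.DataFrame
    totals: pd.DataFrame

    def total_row(self, sex: str, year: float) -> pd.Series:
        sel = self.totals[(self.totals["sex"] == sex) & (self.totals["year"] == year)]
        if sel.empty:
            raise KeyError(f"no totals for sex={sex!r}, year={year}")
        return sel.iloc[0]


def build_projection_result(
    scenario: str, surfaces: dict[str, PrevalenceSurface], population: pd.DataFrame
) -> ProjectionResult:
    """Assemble counts and totals for every reported year of a scenario run."""
    count_frames = []
    total_rows = []
    sexes = [s for s in SEXES if s in surfaces] or sorted(surfaces)
    years = surfaces[sexes[0]].year_grid
    for sex in sexes:
        for year in years:
            df, total = counts_from_prevalence(surfaces[sex], population, year)
            count_frames.append(df)
            pop = df["population"].sum()
            total_rows.append(
                {
                    "sex": sex,
                    "year": float(year),
                    "population": float(pop),
                    "cases": total,
                    "prevalence": total / pop,
                }
            )
    totals = pd.DataFrame(total_rows)
    pooled = (
        totals.groupby("year", as_index=False)[["population", "cases"]].sum().assign(sex="total")
    )
    pooled["prevalence"] = pooled["cases"] / pooled["population"]
    totals = pd.concat([totals, pooled[["sex", "year", "population", "cases", "prevalence"]]], ignore_index=True)
    return ProjectionResult(scenario, surfaces, pd.concat(count_frames, ignore_index=True), totals)


def constant_prevalence_projection(
    scenario: str,
    reference_prevalence: dict[str, np.ndarray],
    age_grid: np.ndarray,
    years: np.ndarray,
    population: pd.DataFrame,
) -> ProjectionResult:
    """Counterfactual where the age-specific prevalence profile never changes.

    Counts still move because the population projection reshapes the age
    pyramid: count(a, t) = p_ref(a) * N(a, t).
    """
    age_grid = np.asarray(age_grid, float)
    years = np.asarray(years, float)
    surfaces = {
        sex: PrevalenceSurface(
            sex, age_grid, years, np.tile(np.asarray(prof, float)[:, None], (1, years.size))
        )
        for sex, prof in reference_prevalence.items()
    }
    return build_projection_result(scenario, surfaces, population)
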