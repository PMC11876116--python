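"""Summary tables of projected prevalence and case counts.

The main product is a table with one row per (sex, scenario) plus a pooled
"total" block: prevalence at the start and end of the reporting window (in
percent, one decimal), case counts (in millions, one decimal) and relative
changes (integer percent).  Relative changes are computed from the unrounded
start/end values and rounded last, half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demio import ProjectionResult
from .surfaces import SEXES


def relative_change(start: float, end: float) -> float:
    """(end/start - 1) * 100; start must be positive."""
    if start <= 0:
        raise ValueError("relative change needs a positive start value")
    return (end / start - 1.0) * 100.0


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed epidemiological tables)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


@dataclass(frozen=True)
class SummaryRow:
    """One printed table row; prevalences in %, case counts in millions."""

    sex: str
    scenario: str
    prevalence_start: float
    cases_start: float
    prevalence_end: float
    cases_end: float
    relative_change_prevalence: float
    relative_change_cases: float


def summarize_result(
    result: ProjectionResult, sex: str, start_year: float, end_year: float
) -> SummaryRow:
    start = result.total_row(sex, start_year)
    end = result.total_row(sex, end_year)
    return SummaryRow(
        sex=sex,
        scenario=result.scenario,
        prevalence_start=round_half_away(start["prevalence"] * 100.0, 1),
        cases_start=round_half_away(start["cases"] / 1e6, 1),
        prevalence_end=round_half_away(end["prevalence"] * 100.0, 1),
        cases_end=round_half_away(end["cases"] / 1e6, 1),
        relative_change_prevalence=round_half_away(
            relative_change(start["prevalence"], end["prevalence"])
        ),
        relative_change_cases=round_half_away(relative_change(start["cases"], end["cases"])),
    )


def make_summary_table(
    results: list[ProjectionResult], start_year: float = 2015.0, end_year: float = 2040.0
) -> pd.DataFrame:
    """Rows for every (sex, scenario) and a pooled 'total' block.

    Total prevalence pools case counts and population over the sexes (it is
    not an average of the sex-specific prevalences).  Rounding happens after
    all arithmetic, at the printed precisions.
    """
    if not results:
        raise ValueError("no projection results to summarize")
    rows = []
    for sex in (*SEXES, "total"):
        for res in results:
            rows.append(summarize_result(res, sex, start_year, end_year).__dict__)
    return pd.DataFrame(rows)
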