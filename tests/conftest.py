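"""Shared fixtures: one default ground truth, fitted model and scenario runs.

The expensive pieces (model-consistent baseline prevalence, the six scenario
integrations) are session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from prevproj import SCENARIOS, SEXES, ProjectionGrid, get_scenario, run_scenario
from prevproj import synthetic
from prevproj.trend import fit_incidence_trend

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def truth():
    return synthetic.generate_ground_truth()


@pytest.fixture(scope="session")
def grid():
    return ProjectionGrid()


@pytest.fixture(scope="session")
def noise_free_estimates(truth):
    return synthetic.sample_incidence_estimates(truth, noise_sd=0.0)


@pytest.fixture(scope="session")
def fitted_model(noise_free_estimates):
    return fit_incidence_trend(noise_free_estimates)


@pytest.fixture(scope="session")
def projection_inputs(truth, grid):
    ages, years = grid.ages, grid.years
    return {
        "baseline": {s: truth.prevalence_profile(s, ages, grid.base_year) for s in SEXES},
        "mortality": {s: truth.mortality_surface(s, ages, years) for s in SEXES},
        "mrr": {s: truth.mrr_schedule(s) for s in SEXES},
        "population": truth.population_table(ages, years),
    }


@pytest.fixture(scope="session")
def scenario_results(fitted_model, projection_inputs, grid):
    """All six scenarios run on the default synthetic inputs."""
    out = {}
    for name in SCENARIOS:
        out[name] = run_scenario(
            get_scenario(name),
            fitted_model,
            projection_inputs["baseline"],
            projection_inputs["mortality"],
            projection_inputs["mrr"],
            projection_inputs["population"],
            grid=grid,
        )
    return out
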