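"""Shared fixtures: a truth-known census history and one fitted model.

The session-scoped fixtures simulate one desk-scale census history from the
default generating truth and fit the small-tree size-asymmetric model once,
so the evaluation and prediction tests can share the (relatively costly)
MCMC run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

import beechmort as bm

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def desk_scenario() -> bm.SyntheticScenario:
    """150-plot scenario sized to ~3000 small focal trees, no landslides."""
    return bm.SyntheticScenario(
        n_plots=150,
        stems_per_subplot_mean=2.2,
        seed=31,
        landslide=bm.LandslideRegime(enabled=False),
    )


@pytest.fixture(scope="session")
def census_history(desk_scenario) -> list[bm.TreeRecord]:
    return bm.simulate_history(desk_scenario)


@pytest.fixture(scope="session")
def fitted_small_model(desk_scenario, census_history):
    """(ModelData, PosteriorResult) for the full small-tree BAL model."""
    spec = bm.MortalityModelSpec(
        "small", desk_scenario.periods[0], "BAL", include_interaction=True
    )
    data = bm.build_design(census_history, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = bm.fit_mcmc(data, bm.MCMCSettings(seed=7))
    return data, result


def brute_force_crowding(records, census):
    """Quadratic-time oracle for BA/BAL: explicit double loop over trees."""
    out = {}
    live = [r for r in records if r.is_alive(census)]
    for focal in live:
        if not bm.is_focal_eligible(focal.subplot_row, focal.subplot_col):
            continue
        ba = 0.0
        bal = 0.0
        d_f = focal.diameter_at(census)
        for other in live:
            if other.tree_id == focal.tree_id or other.plot_id != focal.plot_id:
                continue
            if abs(other.subplot_row - focal.subplot_row) > 1:
                continue
            if abs(other.subplot_col - focal.subplot_col) > 1:
                continue
            area = float(bm.tree_basal_area_m2(other.diameter_at(census)))
            ba += area
            if other.diameter_at(census) > d_f:
                bal += area
        out[focal.tree_id] = (ba, bal)
    return out


@pytest.fixture(scope="session")
def crowding_oracle():
    return brute_force_crowding
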