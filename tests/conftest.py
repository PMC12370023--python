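"""Shared fixtures: the bundled base case and degenerate cohort configurations."""

import pytest

from cacscreen import load_parameters
from cacscreen.parameters import INCIDENCE_STRATA, EventIncidences, LifeTable


@pytest.fixture(scope="session")
def base_params():
    """The bundled base-case parameter set (do not mutate; copy first)."""
    return load_parameters()


def _zero_events(params):
    for stratum in INCIDENCE_STRATA:
        params.incidence[stratum] = EventIncidences(0.0, 0.0, 0.0)
    return params


@pytest.fixture()
def immortal_params(base_params):
    """Zero event rates and zero background mortality: nobody ever dies."""
    p = _zero_events(base_params.copy())
    p.life_table = LifeTable({age: 0.0 for age in range(p.start_age, p.end_age + 1)})
    return p


@pytest.fixture()
def immortal_full_utility_params(immortal_params):
    """Immortal cohort with utility 1 everywhere and all costs zero."""
    p = immortal_params
    p.utilities.no_cvd_by_age = {a: 1.0 for a in p.utilities.no_cvd_by_age}
    for f in (
        "statin_moderate_annual", "statin_high_annual", "cac_test",
        "mi_first_year", "mi_recurrent_first_year", "mi_followup_annual",
        "stroke_first_year", "stroke_recurrent_first_year",
        "stroke_followup_annual", "nonmed_mi_first_year", "nonmed_mi_followup",
        "nonmed_stroke_first_year", "nonmed_stroke_followup",
    ):
        setattr(p.costs, f, 0.0)
    return p


@pytest.fixture()
def two_state_params(base_params):
    """Two-state (No CVD / Dead) configuration: only a flat background
    mortality of 0.1/year acts, over a 3-cycle horizon."""
    p = _zero_events(base_params.copy())
    p.end_age = p.start_age + 3
    p.life_table = LifeTable({age: 0.1 for age in range(40, 76)})
    return p
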