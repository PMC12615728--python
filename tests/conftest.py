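"""Shared fixtures: a hand-built tiny survey and seeded generator runs.

Heavy scenario runs (quadratic solves on the full 79-category fixture) are
session-scoped so regression and audit tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from dietopt import (DietSurvey, FoodCategory, FoodGroup, RunConfig,
                     generate_survey, make_binding_spec, make_feasible_spec)
from dietopt.sensitivity import run_scenarios, run_variant

#: coarse ladder used in tests (the default 5%-step grid is configuration)
REDUCTIONS = (0.1, 0.2, 0.3, 0.4)

FIXTURE_SEED = 7


@pytest.fixture()
def tiny_survey() -> DietSurvey:
    """Five categories in two groups: meat (with a new food) and drinks."""
    cats = [
        FoodCategory("beef", "beef", "meat", 50.0, 10.0, 20.0, 100.0,
                     {"energy_kj": 800.0, "protein": 22.0}, 2.5, 1.5),
        FoodCategory("chicken", "chicken", "meat", 30.0, 8.0, 10.0, 80.0,
                     {"energy_kj": 900.0, "protein": 20.0}, 0.9, 0.7),
        FoodCategory("myco", "mycoprotein", "meat", 0.0, 9.0, 0.0, 0.0,
                     {"energy_kj": 355.6, "protein": 11.5}, 0.3, 1.3,
                     is_new_food=True),
        FoodCategory("water", "water", "drinks", 500.0, 100.0, 500.0, 500.0,
                     {"energy_kj": 0.0, "protein": 0.0}, 0.001, 0.001,
                     is_fixed=True),
        FoodCategory("juice", "juice", "drinks", 100.0, 30.0, 50.0, 200.0,
                     {"energy_kj": 180.0, "protein": 0.5}, 0.05, 0.2),
    ]
    groups = [
        FoodGroup("meat", "meat", ("beef", "chicken", "myco"), 80.0, 25.0,
                  2.0, p95=120.0),
        FoodGroup("drinks", "drinks", ("water", "juice"), 600.0, 120.0, 2.0,
                  p95=750.0),
    ]
    return DietSurvey("tiny", cats, groups)


@pytest.fixture(scope="session")
def survey7() -> DietSurvey:
    return generate_survey(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def feasible_spec7(survey7):
    return make_feasible_spec(survey7, slack=0.3)


@pytest.fixture(scope="session")
def binding_spec7(survey7):
    return make_binding_spec(survey7, "protein", push=0.1)


@pytest.fixture(scope="session")
def base_config(survey7, binding_spec7) -> RunConfig:
    return RunConfig(survey7, binding_spec7, REDUCTIONS, "qp")


@pytest.fixture(scope="session")
def base_run(base_config):
    return run_scenarios(base_config)


@pytest.fixture(scope="session")
def noweights_run(base_config):
    return run_variant(base_config, "no_category_weights")


@pytest.fixture(scope="session")
def lp_run(base_config):
    return run_variant(base_config, "engine_swap")


@pytest.fixture(scope="session")
def ghge_lo_run(base_config):
    return run_variant(base_config, "ghge_scale", {"scale": 0.5})


@pytest.fixture(scope="session")
def ghge_hi_run(base_config):
    return run_variant(base_config, "ghge_scale", {"scale": 1.5})
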