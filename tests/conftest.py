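"""Shared fixtures: the packaged Nigeria bundle and configurable toy models."""

from __future__ import annotations

import numpy as np
import pytest

from smokesim.param_model import (
    AGE_MIN, CaregiverModel, ConditionDef, CostCatalog, EconParams,
    KIND_ACUTE, ParameterSet, SimSettings,
)
from smokesim.synthetic_data import life_expectancy_from_q, nigeria_fixture


@pytest.fixture(scope="session")
def nigeria():
    return nigeria_fixture()


def make_toy_params(
    conditions=(("condA", KIND_ACUTE),),
    *,
    incidence=0.01,
    case_fatality=0.0,
    excess=0.0,
    q=0.0,
    max_age=36,
    prev_current=0.5,
    prev_former=0.0,
    rr_current=2.0,
    rr_former=1.5,
    utility=0.8,
    event_cost=0.0,
    population=1_000_000.0,
    wage=0.0,
    incidence_last_age_zero=False,
) -> ParameterSet:
    """Minimal valid ParameterSet: population concentrated at age 35 (male),
    constant rates, acute conditions without follow-up states."""
    A = max_age - AGE_MIN + 1
    C = len(conditions)
    conds = tuple(ConditionDef(cid, kind) for cid, kind in conditions)

    def bcast(v, shape):
        return np.broadcast_to(np.asarray(v, dtype=float), shape).copy()

    pop = np.zeros((2, A))
    pop[0, 0] = population
    inc = bcast(incidence, (C, 2, A))
    if incidence_last_age_zero:
        inc[:, :, -1] = 0.0
    q_arr = bcast(q, (2, A))
    costs = CostCatalog()
    for cid, kind in conditions:
        item = f"{cid}_event"
        costs.items[item] = float(event_cost)
        costs.roles[item] = (cid, "event" if kind == KIND_ACUTE else "first_year")
    return ParameterSet(
        conditions=conds,
        population=pop,
        prev_current=bcast(prev_current, (2, A)),
        prev_former=bcast(prev_former, (2, A)),
        incidence=inc,
        case_fatality=bcast(case_fatality, (C, 2, A)),
        excess_mortality=bcast(excess, (C, 2, A)),
        q=q_arr,
        life_exp=life_expectancy_from_q(q_arr),
        rr_current=bcast(rr_current, (C, 2)),
        rr_former=bcast(rr_former, (C, 2)),
        utilities=bcast(utility, (C,)),
        costs=costs,
        econ=EconParams(),
        wages=bcast(wage, (2, A)),
        caregiver=CaregiverModel(hourly_cost=100.0),
        settings=SimSettings(max_age=max_age),
    )


@pytest.fixture
def toy_params():
    return make_toy_params()
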