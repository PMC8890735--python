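"""Smoking-attributable burden: factual cohort minus never-smoker counterfactual.

Per-capita annual rates are read off the lifetime simulation in steady state
(totals divided by person-years at each sex and single age), differenced
between the two arms and scaled by the national population, yielding annual
national deaths, events, YLL/YLD/DALYs and direct costs by condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .param_model import FEMALE, MALE, ParameterSet, SEXES
from .simulation_engine import CohortOutcomes

logger = logging.getLogger(__name__)

SECONDHAND_ROW = "secondhand_other"

_COLS = [
    "total_deaths", "attr_deaths", "total_events", "attr_events",
    "attr_yll", "attr_yld", "attr_daly", "total_cost_mn", "attr_cost_mn",
]


@dataclass
class AttributableDetail:
    """National-scale attributable quantities kept at (sex, age) granularity
    for downstream costing (VSL by age at death, wage-weighted YLD)."""

    deaths: np.ndarray  # (2, A) condition-caused deaths
    yll: np.ndarray  # (2, A)
    yld: np.ndarray  # (2, A)
    condition_years: np.ndarray  # (C,) attributable state-years by condition
    direct_cost: np.ndarray  # (2, A) ₦


@dataclass
class BurdenTable:
    """Attributable deaths/events/DALYs/costs by condition with by-sex splits.

    ``by_condition`` rows are condition ids (plus the secondhand uplift row
    after :func:`apply_secondhand_uplift`); monetary columns are ₦ million.
    Percentages are always derived, never stored.
    """

    by_condition: pd.DataFrame
    by_sex: pd.DataFrame
    detail: AttributableDetail
    n: int
    seed: int

    def totals(self) -> pd.Series:
        return self.by_condition.sum(axis=0, skipna=True)

    def with_total(self) -> pd.DataFrame:
        df = self.by_condition.copy()
        df.loc["total"] = self.totals()
        return df

    def share_of_total(self, column: str) -> pd.Series:
        """Each row's share of the column total, in percent (derived)."""
        tot = self.by_condition[column].sum(skipna=True)
        if tot == 0:
            raise ZeroDivisionError(f"column {column} sums to zero")
        return 100.0 * self.by_condition[column] / tot


def _national(rate_diff: np.ndarray, pop: np.ndarray) -> np.ndarray:
    """Scale a per-person-year rate difference (2, A[, K]) by population."""
    if rate_diff.ndim == 3:
        return rate_diff * pop[..., None]
    return rate_diff * pop


def _check_match(current: CohortOutcomes, counterfactual: CohortOutcomes) -> None:
    if current.condition_ids != counterfactual.condition_ids:
        raise ValueError("mismatched condition sets between arms")
    if current.person_years.shape != counterfactual.person_years.shape:
        raise ValueError("mismatched strata shapes between arms")


def attributable_burden(
    current: CohortOutcomes,
    counterfactual: CohortOutcomes,
    p: ParameterSet,
) -> BurdenTable:
    """Difference the two arms' per-capita rates and scale to the population.

    Negative cells (Monte-Carlo noise) are reported as-is with a warning,
    never clipped.
    """
    _check_match(current, counterfactual)
    pop = p.population.astype(float)
    C = len(current.condition_ids)
    dw = 1.0 - p.utilities  # (C,)

    def nat(field_cur: np.ndarray, field_cf: np.ndarray) -> np.ndarray:
        return _national(current.rate(field_cur) - counterfactual.rate(field_cf), pop)

    def nat_total(field_cur: np.ndarray) -> np.ndarray:
        return _national(current.rate(field_cur), pop)

    cond_deaths_cur = current.deaths[:, :, :C]
    cond_deaths_cf = counterfactual.deaths[:, :, :C]
    attr_deaths = nat(cond_deaths_cur, cond_deaths_cf)  # (2, A, C)
    tot_deaths = nat_total(cond_deaths_cur)
    attr_events = nat(current.events, counterfactual.events)
    tot_events = nat_total(current.events)
    attr_yll = nat(current.yll[:, :, :C], counterfactual.yll[:, :, :C])
    attr_state_years = nat(current.state_years, counterfactual.state_years)
    attr_yld = attr_state_years * dw  # (2, A, C)
    attr_cost = nat(current.direct_cost, counterfactual.direct_cost)
    tot_cost = nat_total(current.direct_cost)

    by_condition = pd.DataFrame(
        {
            "total_deaths": tot_deaths.sum(axis=(0, 1)),
            "attr_deaths": attr_deaths.sum(axis=(0, 1)),
            "total_events": tot_events.sum(axis=(0, 1)),
            "attr_events": attr_events.sum(axis=(0, 1)),
            "attr_yll": attr_yll.sum(axis=(0, 1)),
            "attr_yld": attr_yld.sum(axis=(0, 1)),
            "total_cost_mn": tot_cost.sum(axis=(0, 1)) / 1e6,
            "attr_cost_mn": attr_cost.sum(axis=(0, 1)) / 1e6,
        },
        index=list(current.condition_ids),
    )
    by_condition["attr_daly"] = by_condition["attr_yll"] + by_condition["attr_yld"]
    by_condition = by_condition[_COLS]

    neg = (by_condition[["attr_deaths", "attr_events", "attr_yll", "attr_yld",
                         "attr_cost_mn"]] < 0)
    if neg.to_numpy().any():
        for cond in by_condition.index[neg.any(axis=1)]:
            logger.warning("negative attributable cell(s) for %s (sampling noise, "
                           "reported as-is)", cond)

    by_sex = pd.DataFrame(
        {
            "attr_deaths": attr_deaths.sum(axis=(1, 2)),
            "attr_yll": attr_yll.sum(axis=(1, 2)),
            "attr_yld": attr_yld.sum(axis=(1, 2)),
            "attr_cost_mn": attr_cost.sum(axis=(1, 2)) / 1e6,
        },
        index=list(SEXES),
    )
    by_sex["attr_daly"] = by_sex["attr_yll"] + by_sex["attr_yld"]

    detail = AttributableDetail(
        deaths=attr_deaths.sum(axis=2),
        yll=attr_yll.sum(axis=2),
        yld=attr_yld.sum(axis=2),
        condition_years=attr_state_years.sum(axis=(0, 1)),
        direct_cost=attr_cost.sum(axis=2),
    )
    return BurdenTable(by_condition=by_condition, by_sex=by_sex, detail=detail,
                       n=current.n, seed=current.seed)


def apply_secondhand_uplift(
    b: BurdenTable,
    uplift_male: float = 0.136,
    uplift_female: float = 0.12,
) -> BurdenTable:
    """Add the secondhand-smoke-and-other-causes row: the sex-specific uplift
    fraction applied to each sex's directly estimated attributable deaths,
    YLL, YLD, DALYs and costs.  Events are not applicable for this row."""
    if SECONDHAND_ROW in b.by_condition.index:
        raise ValueError("uplift already applied")
    upl = np.array([uplift_male, uplift_female])
    by_sex = b.by_sex.copy()
    row = {}
    for col in ("attr_deaths", "attr_yll", "attr_yld", "attr_daly", "attr_cost_mn"):
        add = upl * b.by_sex[col].to_numpy()
        by_sex[col] = b.by_sex[col] + add
        row[col] = float(add.sum())
    by_condition = b.by_condition.copy()
    by_condition.loc[SECONDHAND_ROW] = {
        "total_deaths": row["attr_deaths"],  # all deaths in this row are attributable
        "attr_deaths": row["attr_deaths"],
        "total_events": np.nan,
        "attr_events": np.nan,
        "attr_yll": row["attr_yll"],
        "attr_yld": row["attr_yld"],
        "attr_daly": row["attr_daly"],
        "total_cost_mn": row["attr_cost_mn"],
        "attr_cost_mn": row["attr_cost_mn"],
    }
    return BurdenTable(by_condition=by_condition, by_sex=by_sex, detail=b.detail,
                       n=b.n, seed=b.seed)


def daly_decomposition(
    current: CohortOutcomes,
    counterfactual: CohortOutcomes,
    p: ParameterSet,
) -> pd.DataFrame:
    """Attributable YLL, YLD and DALY by sex; ``daly = yll + yld`` exactly.

    No discounting and no age-weighting are applied.
    """
    b = attributable_burden(current, counterfactual, p)
    df = b.by_sex[["attr_yll", "attr_yld"]].copy()
    df.columns = ["yll", "yld"]
    df.loc["total"] = df.sum()
    df["daly"] = df["yll"] + df["yld"]
    return df
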