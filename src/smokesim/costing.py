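"""Indirect costs and the full cost breakdown.

Three indirect components are priced on top of the direct medical costs:

* premature-death productivity loss — a human-capital value of statistical
  life: discounted expected labour income from the year after death to
  retirement, with survival taken from the never-smoker life table;
* disability productivity loss — attributable quality-of-life loss among
  working ages valued at the sex/age wage;
* informal caregiving — attributable condition-years times care hours per day,
  valued at the opportunity cost of caregivers' time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .burden import AttributableDetail, BurdenTable
from .param_model import AGE_MIN, ParameterSet, SEXES

WORKING_DAYS = 250
HOURS_PER_DAY = 8


def vsl(
    sex: int | str,
    age_at_death: int,
    wages: np.ndarray,
    q: np.ndarray,
    g: float,
    r: float,
    retirement_age: int,
) -> float:
    """Human-capital value of a statistical life at death.

    Sum over future ages ``j`` in ``[age_at_death + 1, retirement_age - 1]``
    of ``S(j | age_at_death) * wage(sex, j) * ((1 + g) / (1 + r))**(j - age)``,
    where survival ``S`` compounds the background mortality ``q``.  Zero when
    death occurs at or after retirement.

    ``wages`` and ``q`` are ``(2, A)`` tables indexed from age 35.
    """
    if isinstance(sex, str):
        sex = SEXES.index(sex)
    if np.any(np.asarray(wages) < 0):
        raise ValueError("negative wages")
    if age_at_death >= retirement_age:
        return 0.0
    factor = (1.0 + g) / (1.0 + r)
    total = 0.0
    surv = 1.0
    for j in range(age_at_death + 1, retirement_age):
        prev_ai = j - 1 - AGE_MIN
        if 0 <= prev_ai < q.shape[1]:
            surv *= 1.0 - q[sex, prev_ai]
        ai = j - AGE_MIN
        wage = wages[sex, ai] if 0 <= ai < wages.shape[1] else 0.0
        total += surv * wage * factor ** (j - age_at_death)
    return float(total)


def vsl_table(p: ParameterSet) -> np.ndarray:
    """``(2, A)`` table of VSL by sex and age at death, from ``p``'s wages,
    never-smoker life table and economic parameters."""
    e = p.econ
    A = p.n_ages
    out = np.zeros((2, A))
    for s in range(2):
        for ai in range(A):
            out[s, ai] = vsl(s, ai + AGE_MIN, p.wages, p.q, e.g, e.r, e.retirement_age)
    return out


def productivity_loss_premature_death(detail: AttributableDetail,
                                      p: ParameterSet) -> float:
    """₦: attributable deaths by sex/age valued at the age-specific VSL."""
    return float((detail.deaths * vsl_table(p)).sum())


def productivity_loss_disability(
    yld_by_sex_age: np.ndarray, wages: np.ndarray, retirement_age: int
) -> float:
    """₦: attributable QALY loss among working ages times the wage.

    ``yld_by_sex_age`` is a ``(2, A)`` array of attributable
    disability-weighted life-years (ages indexed from 35).
    """
    if np.any(yld_by_sex_age < -1e-9) and np.sum(yld_by_sex_age) < 0:
        raise ValueError("total QALY loss must be >= 0")
    n_work = max(0, retirement_age - AGE_MIN)
    n_work = min(n_work, yld_by_sex_age.shape[1], wages.shape[1])
    return float((yld_by_sex_age[:, :n_work] * wages[:, :n_work]).sum())


def caregiver_hourly_cost(p: ParameterSet) -> float:
    """Opportunity cost of one caregiving hour: mean working-age wage divided
    by 250 working days of 8 hours (used when the bundle leaves it unset)."""
    if p.caregiver.hourly_cost > 0:
        return p.caregiver.hourly_cost
    n_work = p.econ.retirement_age - AGE_MIN
    mean_wage = float(p.wages[:, :n_work].mean())
    return mean_wage / (WORKING_DAYS * HOURS_PER_DAY)


def caregiver_cost(
    condition_years: dict[str, float], p: ParameterSet, *, hourly_cost: float | None = None
) -> float:
    """₦: Σ condition-years × hours/day × 365 × hourly opportunity cost.

    Hours per day come from the caregiver table, falling back to the linear
    disability-weight relation for conditions without literature values.
    """
    rate = caregiver_hourly_cost(p) if hourly_cost is None else hourly_cost
    total = 0.0
    for cond, years in condition_years.items():
        dw = 1.0 - p.utility_of(cond)
        hours = p.caregiver.hours_for(cond, dw)
        total += years * hours * 365.0 * rate
    return float(total)


@dataclass
class CostBreakdown:
    """Direct plus three indirect components; ``total`` is their exact sum.

    All amounts in ₦ million.
    """

    direct: float
    productivity_premature_death: float
    productivity_disability: float
    caregiver: float

    @property
    def total(self) -> float:
        return (self.direct + self.productivity_premature_death
                + self.productivity_disability + self.caregiver)

    @property
    def indirect(self) -> float:
        return (self.productivity_premature_death + self.productivity_disability
                + self.caregiver)

    def as_dict(self) -> dict[str, float]:
        return {
            "direct_mn": self.direct,
            "productivity_premature_death_mn": self.productivity_premature_death,
            "productivity_disability_mn": self.productivity_disability,
            "caregiver_mn": self.caregiver,
            "indirect_mn": self.indirect,
            "total_mn": self.total,
        }


def assemble_cost_breakdown(
    direct: float,
    productivity_premature_death: float,
    productivity_disability: float,
    caregiver: float,
) -> CostBreakdown:
    """Bundle the four components (₦ million); additivity holds exactly."""
    return CostBreakdown(
        direct=direct,
        productivity_premature_death=productivity_premature_death,
        productivity_disability=productivity_disability,
        caregiver=caregiver,
    )


def economic_burden(b: BurdenTable, p: ParameterSet, *, uplift: bool = True) -> CostBreakdown:
    """Full cost breakdown for an attributable-burden run (₦ million).

    Indirect components are computed from the (sex, age)-level attributable
    detail; when ``uplift`` is set the secondhand-and-other uplift fractions
    are applied to each sex's indirect components, mirroring its treatment of
    deaths and direct costs.
    """
    d = b.detail
    upl = np.array(p.secondhand_uplift) if uplift else np.zeros(2)
    scale = 1.0 + upl  # per-sex multiplier

    vt = vsl_table(p)
    premature = float(((d.deaths * vt).sum(axis=1) * scale).sum())

    n_work = max(0, min(p.econ.retirement_age - AGE_MIN,
                        d.yld.shape[1], p.wages.shape[1]))
    disability = float(
        ((d.yld[:, :n_work] * p.wages[:, :n_work]).sum(axis=1) * scale).sum())

    cond_ids = [c for c in b.by_condition.index if c != "secondhand_other"]
    cond_years = {cid: float(v) for cid, v in zip(cond_ids, d.condition_years)}
    care = caregiver_cost(cond_years, p)
    # caregiver detail has no sex split; use the population-weighted mean uplift
    if uplift:
        pop = p.population.sum(axis=1)
        care *= 1.0 + float((upl * pop).sum() / pop.sum())

    direct_mn = float(b.by_condition["attr_cost_mn"].sum(skipna=True))
    return assemble_cost_breakdown(
        direct=direct_mn,
        productivity_premature_death=premature / 1e6,
        productivity_disability=disability / 1e6,
        caregiver=care / 1e6,
    )
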