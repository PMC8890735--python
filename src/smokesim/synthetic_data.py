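"""Synthetic parameter bundles.

Two generators are provided: :func:`nigeria_fixture`, which embeds the
published Nigerian population/prevalence strata, unit-cost catalog and
economic parameters verbatim while filling the never-published inputs
(epidemiological rates, relative risks, utilities, wages, caregiver hours,
life table) with deterministic synthetic stand-ins; and
:func:`generate_bundle`, which produces fully randomized, internally
consistent bundles for testing.  Background mortality uses a Gompertz-form
hazard calibrated to a target residual life expectancy at age 35.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .param_model import (
    AGE_MIN, CaregiverModel, ConditionDef, CostCatalog, EconParams,
    KIND_ACUTE, KIND_CANCER, KIND_CHRONIC, ParameterSet, SimSettings,
    STANDARD_CONDITIONS, expand_bands,
)

# -- published strata: (band, men count, men current, men former,
#                             women count, women current, women former)
_POPULATION_TABLE = (
    ((35, 44), 9_257_215, 0.08, 0.05, 9_730_940, 0.05, 0.02),
    ((45, 64), 10_298_790, 0.11, 0.09, 8_095_575, 0.05, 0.03),
    ((65, 100), 3_490_399, 0.08, 0.20, 2_757_322, 0.09, 0.12),
)

# -- published direct medical unit costs, ₦ (thousands separators removed):
#    item -> (condition, role, cost)
_COST_TABLE = {
    "ami": ("ihd", "event", 402_411),
    "non_ami_ischemic": ("ihd", "event_alt", 1_173_994),
    "stroke_event": ("stroke", "event", 1_208_400),
    "pneumonia_event": ("pneumonia", "event", 61_249),
    "cvd_nonischemic_event": ("cvd_nonischemic", "event", 0),
    "chd_followup": ("ihd", "followup", 193_106),
    "stroke_followup": ("stroke", "followup", 363_348),
    "copd_mild": ("copd", "tier_mild", 86_782),
    "copd_moderate": ("copd", "tier_moderate", 232_556),
    "copd_severe": ("copd", "tier_severe", 3_863_457),
    "lung_cancer_y1": ("lung_cancer", "first_year", 3_851_526),
    "lung_cancer_y2": ("lung_cancer", "followup", 4_709_201),
    "mouth_cancer_y1": ("mouth_cancer", "first_year", 1_714_859),
    "mouth_cancer_y2": ("mouth_cancer", "followup", 1_277_677),
    "esophagus_cancer_y1": ("esophagus_cancer", "first_year", 1_264_945),
    "esophagus_cancer_y2": ("esophagus_cancer", "followup", 936_001),
    "stomach_cancer_y1": ("stomach_cancer", "first_year", 1_266_866),
    "stomach_cancer_y2": ("stomach_cancer", "followup", 1_072_434),
    "pancreas_cancer_y1": ("pancreas_cancer", "first_year", 1_918_056),
    "pancreas_cancer_y2": ("pancreas_cancer", "followup", 1_540_811),
    "kidney_cancer_y1": ("kidney_cancer", "first_year", 1_525_267),
    "kidney_cancer_y2": ("kidney_cancer", "followup", 1_074_893),
    "larynx_cancer_y1": ("larynx_cancer", "first_year", 1_792_030),
    "larynx_cancer_y2": ("larynx_cancer", "followup", 705_926),
    "leukemia_y1": ("leukemia", "first_year", 2_650_265),
    "leukemia_y2": ("leukemia", "followup", 3_153_983),
    "bladder_cancer_y1": ("bladder_cancer", "first_year", 1_241_534),
    "bladder_cancer_y2": ("bladder_cancer", "followup", 977_246),
    "cervix_cancer_y1": ("cervix_cancer", "first_year", 2_446_750),
    "cervix_cancer_y2": ("cervix_cancer", "followup", 1_828_462),
}


@dataclass
class SyntheticSpec:
    """Controls for randomized bundle generation; every generated value
    satisfies the parameter-model invariants by construction."""

    seed: int = 0
    conditions: tuple[ConditionDef, ...] = STANDARD_CONDITIONS
    #: current-smoker RR range by condition kind
    rr_ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        KIND_ACUTE: (1.5, 4.0),
        KIND_CHRONIC: (8.0, 25.0),
        KIND_CANCER: (2.0, 25.0),
    })
    #: utility range by condition kind
    utility_ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        KIND_ACUTE: (0.6, 0.9),
        KIND_CHRONIC: (0.5, 0.8),
        KIND_CANCER: (0.4, 0.75),
    })
    incidence_scale: tuple[float, float] = (2e-4, 2e-3)  # at age 35
    #: multiplier on the incidence scale by condition kind (cancers are far
    #: rarer than acute cardiovascular/respiratory events)
    kind_incidence_factor: dict[str, float] = field(default_factory=lambda: {
        KIND_ACUTE: 1.0,
        KIND_CHRONIC: 0.6,
        KIND_CANCER: 0.03,
    })
    incidence_age_slope: float = 0.05  # log-linear growth per year of age
    case_fatality_range: tuple[float, float] = (0.03, 0.3)
    excess_mortality_range: tuple[float, float] = (0.01, 0.08)
    target_e35: float = 40.0  # residual life expectancy at 35, years
    gompertz_slope: float = 0.09
    wage_level: float = 350_000.0  # ₦ / year around the mid-career peak
    max_age: int = 100

    def __post_init__(self) -> None:
        if not (35.0 <= self.target_e35 <= 45.0):
            raise ValueError("target_e35 must lie in [35, 45]")
        for label, ranges in (("rr", self.rr_ranges), ("utility", self.utility_ranges)):
            for name, (lo, hi) in ranges.items():
                if lo > hi or lo < 0:
                    raise ValueError(f"infeasible {label} range for {name}: ({lo}, {hi})")


# ---------------------------------------------------------------------------
# Life-table machinery
# ---------------------------------------------------------------------------


def gompertz_q(b: float, c: float, ages: np.ndarray) -> np.ndarray:
    """Annual death probability ``min(1, b * exp(c * (age - 35)))``."""
    return np.minimum(1.0, b * np.exp(c * (ages - AGE_MIN)))


def life_expectancy_from_q(q: np.ndarray) -> np.ndarray:
    """Residual life expectancy per age from annual death probabilities.

    Matches the engine's accounting: everyone dies by the last tabulated age
    and the death year earns a half-year credit, so
    ``e(a) = 0.5 + sum_k prod_{i<k} (1 - q(a+i))`` with ``q`` forced to 1 at
    the final age.
    """
    q = np.asarray(q, dtype=float).copy()
    q[..., -1] = 1.0
    A = q.shape[-1]
    e = np.zeros_like(q)
    for ai in range(A - 1, -1, -1):
        if ai == A - 1:
            e[..., ai] = 0.5
        else:
            # survive this year with prob (1-q): live the year plus e(next);
            # die with prob q: half-year credit
            e[..., ai] = (1 - q[..., ai]) * (1.0 + e[..., ai + 1]) + q[..., ai] * 0.5
    return e


def calibrated_life_table(target_e35: float, slope: float, max_age: int,
                          female_advantage: float = 0.9
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Gompertz life table ``(q, e)`` per sex, with the level parameter
    solved so that e(35) hits ``target_e35`` (women get a small advantage)."""
    ages = np.arange(AGE_MIN, max_age + 1)

    def solve(target: float) -> np.ndarray:
        def gap(log_b: float) -> float:
            qv = gompertz_q(np.exp(log_b), slope, ages)
            return life_expectancy_from_q(qv)[0] - target

        log_b = brentq(gap, -20.0, 0.0, xtol=1e-12)
        return gompertz_q(np.exp(log_b), slope, ages)

    q = np.stack([solve(target_e35), solve(min(45.0, target_e35 + female_advantage))])
    return q, life_expectancy_from_q(q)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _synthetic_epi(spec: SyntheticSpec, rng: np.random.Generator,
                   conditions: tuple[ConditionDef, ...], A: int
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    C = len(conditions)
    ages = np.arange(AGE_MIN, AGE_MIN + A)
    age_curve = np.exp(spec.incidence_age_slope * (ages - AGE_MIN))
    incidence = np.zeros((C, 2, A))
    case_fatality = np.zeros((C, 2, A))
    excess = np.zeros((C, 2, A))
    for ci, cond in enumerate(conditions):
        base = rng.uniform(*spec.incidence_scale) * \
            spec.kind_incidence_factor.get(cond.kind, 1.0)
        cf = rng.uniform(*spec.case_fatality_range)
        ex = rng.uniform(*spec.excess_mortality_range)
        for s in range(2):
            sex_adj = 1.0 if s == 0 else rng.uniform(0.6, 1.0)
            curve = np.minimum(base * sex_adj * age_curve, 0.05)
            incidence[ci, s] = curve
            case_fatality[ci, s] = np.minimum(cf * (1 + 0.01 * (ages - AGE_MIN)), 0.95)
            excess[ci, s] = ex
        if cond.id == "cvd_nonischemic":
            case_fatality[ci] = 1.0  # mortality-only condition, events are deaths
        if cond.sex_restriction == "female":
            incidence[ci, 0] = 0.0
        elif cond.sex_restriction == "male":
            incidence[ci, 1] = 0.0
    return incidence, case_fatality, excess


def _synthetic_rr(spec: SyntheticSpec, rng: np.random.Generator,
                  conditions: tuple[ConditionDef, ...]
                  ) -> tuple[np.ndarray, np.ndarray]:
    C = len(conditions)
    rr_c = np.ones((C, 2))
    rr_f = np.ones((C, 2))
    for ci, cond in enumerate(conditions):
        lo, hi = spec.rr_ranges[cond.kind]
        for s in range(2):
            rc = rng.uniform(lo, hi)
            rr_c[ci, s] = rc
            rr_f[ci, s] = 1.0 + rng.uniform(0.2, 0.6) * (rc - 1.0)
    return rr_c, rr_f


def _synthetic_wages(spec: SyntheticSpec, rng: np.random.Generator, A: int) -> np.ndarray:
    ages = np.arange(AGE_MIN, AGE_MIN + A)
    # hump-shaped age profile peaking near 45, women at a fraction of men
    profile = np.exp(-0.5 * ((ages - 45.0) / 18.0) ** 2)
    wages = np.zeros((2, A))
    wages[0] = spec.wage_level * profile
    wages[1] = spec.wage_level * rng.uniform(0.6, 0.9) * profile
    return np.round(wages, 2)


def _synthetic_caregiver(spec: SyntheticSpec, rng: np.random.Generator,
                         conditions: tuple[ConditionDef, ...],
                         wages: np.ndarray, retirement_age: int) -> CaregiverModel:
    mean_wage = float(wages[:, : retirement_age - AGE_MIN].mean())
    hours = {}
    for cond in conditions:
        if cond.kind != KIND_ACUTE and rng.random() < 0.6:  # "literature" values
            hours[cond.id] = round(float(rng.uniform(1.0, 6.0)), 2)
    return CaregiverModel(
        hours_per_day=hours,
        hourly_cost=round(mean_wage / (250 * 8), 2),
        intercept=0.0,
        slope=8.0,
    )


def generate_bundle(spec: SyntheticSpec) -> ParameterSet:
    """Randomized, internally consistent :class:`ParameterSet`.

    Deterministic given ``spec.seed``: incidences increase with age,
    ``1 <= rr(former) <= rr(current)`` and the life table yields a strictly
    decreasing residual life expectancy.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    conditions = spec.conditions
    max_age = spec.max_age
    A = max_age - AGE_MIN + 1

    population = np.stack([
        sum(expand_bands({band: men}, max_age, spread=True)
            for band, men, *_ in _POPULATION_TABLE),
        sum(expand_bands({band: women}, max_age, spread=True)
            for band, _, _, _, women, *_ in _POPULATION_TABLE),
    ])
    prev_current = np.stack([
        rng.uniform(0.05, 0.15) * np.ones(A),
        rng.uniform(0.03, 0.10) * np.ones(A),
    ])
    prev_former = np.stack([
        rng.uniform(0.03, 0.15) * np.ones(A),
        rng.uniform(0.02, 0.10) * np.ones(A),
    ])

    incidence, case_fatality, excess = _synthetic_epi(spec, rng, conditions, A)
    rr_c, rr_f = _synthetic_rr(spec, rng, conditions)
    utilities = np.array([
        rng.uniform(*spec.utility_ranges[c.kind]) for c in conditions
    ]).round(4)
    q, e = calibrated_life_table(spec.target_e35, spec.gompertz_slope, max_age)
    wages = _synthetic_wages(spec, rng, A)
    econ = EconParams()

    costs = CostCatalog()
    for item, (cond, role, cost) in _COST_TABLE.items():
        if any(c.id == cond for c in conditions):
            costs.items[item] = float(cost)
            costs.roles[item] = (cond, role)
    for cond in conditions:  # ensure every condition is priced
        if not any(c == cond.id for c, _ in costs.roles.values()):
            item = f"{cond.id}_event"
            costs.items[item] = float(np.round(rng.uniform(5e4, 4e6), 0))
            costs.roles[item] = (cond.id, "event" if cond.kind == KIND_ACUTE
                                 else "first_year")

    caregiver = _synthetic_caregiver(spec, rng, conditions, wages,
                                     econ.retirement_age)
    return ParameterSet(
        conditions=conditions,
        population=population,
        prev_current=prev_current.round(6),
        prev_former=prev_former.round(6),
        incidence=incidence,
        case_fatality=case_fatality,
        excess_mortality=excess,
        q=q, life_exp=e,
        rr_current=rr_c.round(4), rr_former=rr_f.round(4),
        utilities=utilities,
        costs=costs, econ=econ, wages=wages, caregiver=caregiver,
        settings=SimSettings(seed=spec.seed, max_age=max_age),
        synthetic_stand_in=(
            "epi_rates", "relative_risks", "utilities", "wages", "caregiver",
            "life_table", "prevalence", "population",
        ),
    )


def nigeria_fixture(seed: int = 0) -> ParameterSet:
    """The packaged Nigeria parameter bundle.

    Population and smoking prevalence strata, the direct medical unit-cost
    catalog and the economic parameters are the published values; age bands
    are expanded to single years by uniform assignment.  Epidemiological
    rates, relative risks, utilities, wages, caregiver hours and the life
    table are deterministic synthetic stand-ins (flagged in
    ``synthetic_stand_in``) because the source tables were never published.
    """
    spec = SyntheticSpec(seed=seed)
    p = generate_bundle(spec)

    max_age = spec.max_age
    pop_m, prev_c_m, prev_f_m = {}, {}, {}
    pop_f, prev_c_f, prev_f_f = {}, {}, {}
    for band, men, mc, mf, women, wc, wf in _POPULATION_TABLE:
        pop_m[band], prev_c_m[band], prev_f_m[band] = men, mc, mf
        pop_f[band], prev_c_f[band], prev_f_f[band] = women, wc, wf
    p.population = np.stack([
        expand_bands(pop_m, max_age, spread=True),
        expand_bands(pop_f, max_age, spread=True),
    ])
    p.prev_current = np.stack([
        expand_bands(prev_c_m, max_age), expand_bands(prev_c_f, max_age)])
    p.prev_former = np.stack([
        expand_bands(prev_f_m, max_age), expand_bands(prev_f_f, max_age)])

    p.costs = CostCatalog()
    for item, (cond, role, cost) in _COST_TABLE.items():
        p.costs.items[item] = float(cost)
        p.costs.roles[item] = (cond, role)

    p.econ = EconParams()  # published elasticities, FX, GDP etc. are defaults
    p.secondhand_uplift = (0.136, 0.12)
    p.synthetic_stand_in = (
        "epi_rates", "relative_risks", "utilities", "wages", "caregiver",
        "life_table",
    )
    return p
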