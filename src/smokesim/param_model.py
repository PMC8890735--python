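"""Parameter model: every input the simulation consumes, with validation and I/O.

A *parameter bundle* on disk is a directory holding one ``config.yaml`` (scalar
parameters) and a set of CSV tables (population, prevalence, epidemiological
rates, relative risks, utilities, costs, wages, caregiver hours, life table).
In memory the bundle is a :class:`ParameterSet`, which stores the tabular data
as dense numpy arrays indexed by ``(condition, sex, single-year age)`` so the
simulation engine can vectorise over individuals.

Sexes are coded ``0 = male, 1 = female``; smoking status is coded
``0 = never, 1 = current, 2 = former``; ages run from :data:`AGE_MIN` (35) to
``settings.max_age`` inclusive.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

AGE_MIN = 35
SEXES = ("male", "female")
MALE, FEMALE = 0, 1
STATUSES = ("never", "current", "former")
NEVER, CURRENT, FORMER = 0, 1, 2

#: Condition kinds understood by the engine.
KIND_ACUTE = "acute-event"
KIND_CHRONIC = "chronic-progressive"
KIND_CANCER = "cancer"

#: Reference exchange rate, Naira per US dollar.
NAIRA_PER_USD = 306.92

#: Age bands used by the published population/prevalence table.
AGE_BANDS = ((35, 44), (45, 64), (65, 100))


class ParameterError(ValueError):
    """Raised when a bundle cannot be loaded or fails validation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionDef:
    """One modelled smoking-related condition."""

    id: str
    kind: str  # acute-event | chronic-progressive | cancer
    icd_codes: tuple[str, ...] = ()
    sex_restriction: str | None = None  # "male"/"female" or None

    def __post_init__(self) -> None:
        if self.kind not in (KIND_ACUTE, KIND_CHRONIC, KIND_CANCER):
            raise ParameterError(f"condition {self.id}: unknown kind {self.kind!r}")
        if self.sex_restriction not in (None, "male", "female"):
            raise ParameterError(
                f"condition {self.id}: bad sex_restriction {self.sex_restriction!r}"
            )


#: The default modelled condition set (heart disease, stroke, COPD,
#: pneumonia/influenza and ten cancer sites / leukemia).
STANDARD_CONDITIONS: tuple[ConditionDef, ...] = (
    ConditionDef("ihd", KIND_ACUTE, ("I20", "I21-22", "I24-25")),
    ConditionDef("cvd_nonischemic", KIND_ACUTE, ("I00-I52", "I70")),
    ConditionDef("stroke", KIND_ACUTE, ("I60-I69",)),
    ConditionDef("copd", KIND_CHRONIC, ("J40-J43",)),
    ConditionDef("pneumonia", KIND_ACUTE, ("J10-J18",)),
    ConditionDef("lung_cancer", KIND_CANCER, ("C34",)),
    ConditionDef("mouth_cancer", KIND_CANCER, ("C00-C14",)),
    ConditionDef("larynx_cancer", KIND_CANCER, ("C32",)),
    ConditionDef("esophagus_cancer", KIND_CANCER, ("C15",)),
    ConditionDef("stomach_cancer", KIND_CANCER, ("C16",)),
    ConditionDef("pancreas_cancer", KIND_CANCER, ("C25",)),
    ConditionDef("kidney_cancer", KIND_CANCER, ("C64",)),
    ConditionDef("bladder_cancer", KIND_CANCER, ("C67",)),
    ConditionDef("cervix_cancer", KIND_CANCER, ("C53",), sex_restriction="female"),
    ConditionDef("leukemia", KIND_CANCER, ("C92.0",)),
)

#: Conditions whose averted events are grouped as "heart disease" in scenario
#: reports.
HEART_CONDITIONS = ("ihd", "cvd_nonischemic")


@dataclass
class EconParams:
    """Scalar economic parameters.

    Monetary aggregates (``baseline_tax_revenue``, ``gdp``) are in million ₦.
    """

    eps_d: float = -0.496  # own-price elasticity of demand
    eps_cp: float = 0.17  # cross-price elasticity licit -> illicit
    alpha: float = 0.94  # licit market share
    tax_share: float = 0.299  # taxes as fraction of retail price
    g: float = 0.0121  # annual wage growth
    r: float = 0.05  # annual discount rate for future income
    retirement_age: int = 60
    baseline_tax_revenue: float = 36_300.0  # ₦ million / year
    gdp: float = 145_639_000.0  # ₦ million
    the_share: float = 0.0376  # health expenditure share of GDP
    naira_per_usd: float = NAIRA_PER_USD


@dataclass
class CaregiverModel:
    """Informal-care hours per condition and their opportunity cost.

    Conditions missing from ``hours_per_day`` fall back to the linear map
    ``hours = intercept + slope * disability_weight`` (a stand-in for the
    unreported econometric fit; flagged in outputs).
    """

    hours_per_day: dict[str, float] = field(default_factory=dict)
    hourly_cost: float = 0.0  # ₦ / hour
    intercept: float = 0.0  # hours/day at dw = 0
    slope: float = 8.0  # hours/day per unit disability weight

    def hours_for(self, condition: str, disability_weight: float) -> float:
        if condition in self.hours_per_day:
            return self.hours_per_day[condition]
        return min(24.0, max(0.0, self.intercept + self.slope * disability_weight))


@dataclass
class CostCatalog:
    """Direct medical unit costs in ₦ (see bundle table ``costs.csv``).

    ``items`` maps a cost-item id (e.g. ``ami``, ``stroke_followup``,
    ``copd_severe``) to its ₦ amount; the ``event/first_year/followup/tier``
    views used by the engine are derived per condition.
    """

    items: dict[str, float] = field(default_factory=dict)
    #: item id -> (condition id, role); role in
    #: {event, event_alt, first_year, followup, tier_mild, tier_moderate, tier_severe}
    roles: dict[str, tuple[str, str]] = field(default_factory=dict)
    currency: str = "NGN"
    naira_per_usd: float = NAIRA_PER_USD

    def item_cost(self, item: str) -> float:
        return self.items[item]

    def _by_role(self, condition: str, role: str, default: float | None = None) -> float:
        for item, (cond, r) in self.roles.items():
            if cond == condition and r == role:
                return self.items[item]
        if default is None:
            raise KeyError(f"no cost item with role {role!r} for condition {condition!r}")
        return default

    def event_cost(self, condition: str, ami_share: float = 0.5) -> float:
        """Expected ₦ per acute event; the heart-disease event is a mix of the
        AMI and non-AMI items weighted by ``ami_share``."""
        main = self._by_role(condition, "event", 0.0)
        try:
            alt = self._by_role(condition, "event_alt")
        except KeyError:
            return main
        return ami_share * main + (1.0 - ami_share) * alt

    def first_year_cost(self, condition: str) -> float:
        return self._by_role(condition, "first_year", 0.0)

    def followup_cost(self, condition: str) -> float:
        return self._by_role(condition, "followup", 0.0)

    def copd_tier_costs(self, condition: str = "copd") -> tuple[float, float, float]:
        return (
            self._by_role(condition, "tier_mild", 0.0),
            self._by_role(condition, "tier_moderate", 0.0),
            self._by_role(condition, "tier_severe", 0.0),
        )


@dataclass
class SimSettings:
    """Simulation engine knobs."""

    cohort_size: int = 100_000
    max_age: int = 100
    seed: int = 0
    rr_target: str = "incidence"  # or "mortality"
    copd_progression: tuple[float, float] = (0.05, 0.05)  # mild->mod, mod->severe
    cancer_active_years: int = 5  # dx year + 4 follow-up years
    ami_share: float = 0.5  # share of heart-disease events costed as AMI


@dataclass
class ParameterSet:
    """The full, validated model input bundle.

    Array shapes (``C`` conditions, 2 sexes, ``A = max_age - 35 + 1`` ages):

    ============================ =============
    population, prev_current,    ``(2, A)``
    prev_former, q, life_exp,
    wages
    incidence, case_fatality,    ``(C, 2, A)``
    excess_mortality
    rr_current, rr_former        ``(C, 2)``
    utilities                    ``(C,)``
    ============================ =============
    """

    conditions: tuple[ConditionDef, ...]
    population: np.ndarray
    prev_current: np.ndarray
    prev_former: np.ndarray
    incidence: np.ndarray
    case_fatality: np.ndarray
    excess_mortality: np.ndarray
    q: np.ndarray  # background annual death probability
    life_exp: np.ndarray  # residual life expectancy e(sex, age)
    rr_current: np.ndarray
    rr_former: np.ndarray
    utilities: np.ndarray
    costs: CostCatalog
    econ: EconParams = field(default_factory=EconParams)
    wages: np.ndarray = None  # type: ignore[assignment]
    caregiver: CaregiverModel = field(default_factory=CaregiverModel)
    secondhand_uplift: tuple[float, float] = (0.136, 0.12)  # male, female
    settings: SimSettings = field(default_factory=SimSettings)
    synthetic_stand_in: tuple[str, ...] = ()

    # -- indexing helpers ---------------------------------------------------

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def condition_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.conditions)

    @property
    def ages(self) -> np.ndarray:
        return np.arange(AGE_MIN, self.settings.max_age + 1)

    @property
    def n_ages(self) -> int:
        return self.settings.max_age - AGE_MIN + 1

    def condition_index(self, cond_id: str) -> int:
        try:
            return self.condition_ids.index(cond_id)
        except ValueError:
            raise KeyError(f"unknown condition {cond_id!r}") from None

    def age_index(self, age: int | np.ndarray) -> int | np.ndarray:
        return age - AGE_MIN

    def utility_of(self, cond_id: str) -> float:
        return float(self.utilities[self.condition_index(cond_id)])

    def digest(self) -> str:
        """Content hash of the whole parameter set (for run manifests)."""
        h = hashlib.sha256()
        for arr in (
            self.population, self.prev_current, self.prev_former, self.incidence,
            self.case_fatality, self.excess_mortality, self.q, self.life_exp,
            self.rr_current, self.rr_former, self.utilities, self.wages,
        ):
            h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
        scalars = {
            "conditions": [dataclasses.asdict(c) for c in self.conditions],
            "costs_items": self.costs.items,
            "costs_roles": self.costs.roles,
            "econ": dataclasses.asdict(self.econ),
            "caregiver": dataclasses.asdict(self.caregiver),
            "uplift": list(self.secondhand_uplift),
            "settings": dataclasses.asdict(self.settings),
        }
        h.update(json.dumps(scalars, sort_keys=True, default=list).encode())
        return h.hexdigest()


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _check_prob(rep: ValidationReport, name: str, arr: np.ndarray) -> None:
    arr = np.asarray(arr, dtype=float)
    if np.any(np.isnan(arr)):
        rep.errors.append(f"{name}: contains NaN")
        return
    bad = (arr < 0) | (arr > 1)
    if np.any(bad):
        idx = tuple(int(i[0]) for i in np.nonzero(bad))
        rep.errors.append(
            f"{name}: value {arr[idx]:.4g} at index {idx} outside [0, 1]"
        )


def validate_parameters(p: ParameterSet) -> ValidationReport:
    """Check every type invariant; returns a report, never raises.

    Errors are hard violations (out-of-range probabilities, negative costs,
    missing cross-references). ``rr(former) > rr(current)`` and non-monotone
    background mortality only produce warnings.
    """
    rep = ValidationReport()
    ids = p.condition_ids
    if len(set(ids)) != len(ids):
        rep.errors.append("conditions: duplicate ids")

    if np.any(p.population < 0):
        rep.errors.append("population: negative count")
    _check_prob(rep, "prev_current", p.prev_current)
    _check_prob(rep, "prev_former", p.prev_former)
    tot = np.asarray(p.prev_current) + np.asarray(p.prev_former)
    if np.any(tot > 1 + 1e-12):
        s, a = (int(x[0]) for x in np.nonzero(tot > 1 + 1e-12))
        rep.errors.append(
            f"prevalence: current + former = {tot[s, a]:.3f} > 1 for "
            f"sex={SEXES[s]}, age={a + AGE_MIN}"
        )

    _check_prob(rep, "incidence", p.incidence)
    _check_prob(rep, "case_fatality", p.case_fatality)
    _check_prob(rep, "excess_mortality", p.excess_mortality)
    _check_prob(rep, "life_table.q", p.q)

    # e(sex, age) strictly decreasing in age
    de = np.diff(p.life_exp, axis=1)
    if np.any(de >= 0):
        s, a = (int(x[0]) for x in np.nonzero(de >= 0))
        rep.errors.append(
            f"life_table.e: not strictly decreasing at sex={SEXES[s]}, "
            f"age={a + AGE_MIN}->{a + AGE_MIN + 1}"
        )
    # q monotonicity is only advisory
    if np.any(np.diff(p.q, axis=1) < 0):
        rep.warnings.append("life_table.q: not monotone non-decreasing in age")

    if np.any(p.rr_current < 0) or np.any(p.rr_former < 0):
        rep.errors.append("relative_risks: negative rr")
    worse = p.rr_former > p.rr_current
    if np.any(worse):
        for ci, s in zip(*np.nonzero(worse)):
            rep.warnings.append(
                f"relative_risks: rr(former)={p.rr_former[ci, s]:.3g} > "
                f"rr(current)={p.rr_current[ci, s]:.3g} for {ids[ci]}, {SEXES[s]}"
            )

    bad_u = (p.utilities < 0) | (p.utilities > 1) | np.isnan(p.utilities)
    if np.any(bad_u):
        ci = int(np.nonzero(bad_u)[0][0])
        rep.errors.append(f"utilities: {ids[ci]} utility {p.utilities[ci]} outside [0, 1]")

    for item, cost in p.costs.items.items():
        if cost < 0:
            rep.errors.append(f"costs: item {item} negative ({cost})")
    for item in p.costs.items:
        if item not in p.costs.roles:
            rep.errors.append(f"costs: item {item} has no condition/role mapping")
    for item, (cond, role) in p.costs.roles.items():
        if cond not in ids:
            rep.errors.append(f"costs: item {item} references unknown condition {cond!r}")

    e = p.econ
    if not (0 < e.alpha <= 1):
        rep.errors.append(f"econ.alpha={e.alpha} outside (0, 1]")
    if not (0 < e.tax_share <= 1):
        rep.errors.append(f"econ.tax_share={e.tax_share} outside (0, 1]")
    if e.r <= 0:
        rep.errors.append(f"econ.r={e.r} must be > 0")
    if e.retirement_age <= AGE_MIN:
        rep.errors.append(f"econ.retirement_age={e.retirement_age} must exceed {AGE_MIN}")

    if np.any(np.asarray(p.wages) < 0):
        rep.errors.append("wages: negative wage")
    n_working = min(e.retirement_age, p.settings.max_age + 1) - AGE_MIN
    if p.wages.shape[1] < n_working:
        rep.errors.append("wages: not defined for all working ages")

    cg = p.caregiver
    for cond, h in cg.hours_per_day.items():
        if cond not in ids:
            rep.errors.append(f"caregiver: unknown condition {cond!r}")
        if not (0 <= h <= 24):
            rep.errors.append(f"caregiver: hours/day {h} for {cond} outside [0, 24]")
    if cg.slope < 0:
        rep.errors.append(f"caregiver: slope {cg.slope} must be >= 0")
    if cg.hourly_cost < 0:
        rep.errors.append("caregiver: negative hourly cost")

    um, uf = p.secondhand_uplift
    if um < 0 or uf < 0:
        rep.errors.append("secondhand_uplift: negative")

    # sex restriction: no exposure where restricted
    for ci, cond in enumerate(p.conditions):
        if cond.sex_restriction is None:
            continue
        banned = MALE if cond.sex_restriction == "female" else FEMALE
        if np.any(p.incidence[ci, banned, :] > 0):
            rep.errors.append(
                f"epi_rates: nonzero incidence of {cond.id} for restricted sex "
                f"{SEXES[banned]}"
            )
    return rep


# ---------------------------------------------------------------------------
# Age-band expansion
# ---------------------------------------------------------------------------


def expand_bands(
    band_values: Mapping[tuple[int, int], float],
    max_age: int = 100,
    *,
    spread: bool = False,
) -> np.ndarray:
    """Expand band-level values to single-year ages 35..max_age.

    With ``spread=True`` a band total is divided uniformly over the band's
    single ages (population counts); otherwise the band value is repeated
    (prevalences, rates).
    """
    out = np.zeros(max_age - AGE_MIN + 1)
    for (lo, hi), v in band_values.items():
        hi = min(hi, max_age)
        width = hi - lo + 1
        if width <= 0:
            raise ParameterError(f"empty age band {lo}-{hi}")
        out[lo - AGE_MIN : hi - AGE_MIN + 1] = v / width if spread else v
    return out


def band_of(age: int) -> tuple[int, int]:
    """The published reporting band containing ``age``."""
    for lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return (lo, hi)
    raise ValueError(f"age {age} outside modelled range")


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

_TABLES = (
    "population", "prevalence", "epi_rates", "relative_risks", "utilities",
    "costs", "wages", "caregiver", "life_table",
)


def _sex_idx(s: str) -> int:
    try:
        return SEXES.index(s)
    except ValueError:
        raise ParameterError(f"unknown sex {s!r}") from None


def write_parameters(p: ParameterSet, path: str | Path) -> Path:
    """Write ``p`` as a bundle directory (config.yaml + CSV tables)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ages = p.ages
    A = p.n_ages

    def sa_frame(arr: np.ndarray, col: str) -> pd.DataFrame:
        return pd.DataFrame({
            "sex": np.repeat(SEXES, A),
            "age": np.tile(ages, 2),
            col: np.concatenate([arr[0], arr[1]]),
        })

    sa_frame(p.population, "count").to_csv(path / "population.csv", index=False)
    prev = sa_frame(p.prev_current, "current")
    prev["former"] = np.concatenate([p.prev_former[0], p.prev_former[1]])
    prev.to_csv(path / "prevalence.csv", index=False)

    rows = []
    for ci, cond in enumerate(p.conditions):
        for s in range(2):
            for ai, age in enumerate(ages):
                rows.append((cond.id, SEXES[s], age,
                             p.incidence[ci, s, ai], p.case_fatality[ci, s, ai],
                             p.excess_mortality[ci, s, ai]))
    pd.DataFrame(rows, columns=[
        "condition", "sex", "age", "baseline_incidence", "case_fatality",
        "excess_mortality",
    ]).to_csv(path / "epi_rates.csv", index=False)

    rows = []
    for ci, cond in enumerate(p.conditions):
        for s in range(2):
            rows.append((cond.id, SEXES[s], "current", p.rr_current[ci, s]))
            rows.append((cond.id, SEXES[s], "former", p.rr_former[ci, s]))
    pd.DataFrame(rows, columns=["condition", "sex", "status", "rr"]).to_csv(
        path / "relative_risks.csv", index=False)

    pd.DataFrame(
        [("healthy", 1.0)] + [(c.id, p.utilities[ci]) for ci, c in enumerate(p.conditions)],
        columns=["condition", "utility"],
    ).to_csv(path / "utilities.csv", index=False)

    pd.DataFrame(
        [(item, *p.costs.roles[item], cost) for item, cost in p.costs.items.items()],
        columns=["item", "condition", "role", "cost"],
    ).to_csv(path / "costs.csv", index=False)

    sa_frame(p.wages, "annual_wage").to_csv(path / "wages.csv", index=False)

    pd.DataFrame(
        sorted(p.caregiver.hours_per_day.items()),
        columns=["condition", "hours_per_day"],
    ).to_csv(path / "caregiver.csv", index=False)

    lt = sa_frame(p.q, "q")
    lt["e"] = np.concatenate([p.life_exp[0], p.life_exp[1]])
    lt.to_csv(path / "life_table.csv", index=False)

    config = {
        "bundle_format": 1,
        "conditions": [
            {"id": c.id, "kind": c.kind, "icd_codes": list(c.icd_codes),
             "sex_restriction": c.sex_restriction}
            for c in p.conditions
        ],
        "econ": dataclasses.asdict(p.econ),
        "secondhand_uplift": {"male": p.secondhand_uplift[0],
                              "female": p.secondhand_uplift[1]},
        "caregiver": {"hourly_cost": p.caregiver.hourly_cost,
                      "intercept": p.caregiver.intercept,
                      "slope": p.caregiver.slope},
        "settings": {
            "cohort_size": p.settings.cohort_size,
            "max_age": p.settings.max_age,
            "seed": p.settings.seed,
            "rr_target": p.settings.rr_target,
            "copd_progression": list(p.settings.copd_progression),
            "cancer_active_years": p.settings.cancer_active_years,
            "ami_share": p.settings.ami_share,
        },
        "costs_meta": {"currency": p.costs.currency,
                       "naira_per_usd": p.costs.naira_per_usd},
        "synthetic_stand_in": list(p.synthetic_stand_in),
    }
    (path / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    return path


def load_parameters(bundle_path: str | Path, *, validate: bool = True) -> ParameterSet:
    """Load a bundle directory into a validated :class:`ParameterSet`.

    Raises :class:`ParameterError` naming the missing table or the offending
    field/stratum/value when the bundle is malformed.
    """
    path = Path(bundle_path)
    if not (path / "config.yaml").exists():
        raise ParameterError(f"missing required file config.yaml in {path}")
    for t in _TABLES:
        if not (path / f"{t}.csv").exists():
            raise ParameterError(f"missing required table {t}.csv in {path}")

    config = yaml.safe_load((path / "config.yaml").read_text())
    conditions = tuple(
        ConditionDef(c["id"], c["kind"], tuple(c.get("icd_codes") or ()),
                     c.get("sex_restriction"))
        for c in config["conditions"]
    )
    ids = [c.id for c in conditions]
    cfg_set = config.get("settings", {})
    settings = SimSettings(
        cohort_size=int(cfg_set.get("cohort_size", 100_000)),
        max_age=int(cfg_set.get("max_age", 100)),
        seed=int(cfg_set.get("seed", 0)),
        rr_target=str(cfg_set.get("rr_target", "incidence")),
        copd_progression=tuple(cfg_set.get("copd_progression", (0.05, 0.05))),
        cancer_active_years=int(cfg_set.get("cancer_active_years", 5)),
        ami_share=float(cfg_set.get("ami_share", 0.5)),
    )
    if settings.rr_target not in ("incidence", "mortality"):
        raise ParameterError(f"settings.rr_target={settings.rr_target!r} unknown")
    econ = EconParams(**config.get("econ", {}))
    upl = config.get("secondhand_uplift", {})
    uplift = (float(upl.get("male", 0.136)), float(upl.get("female", 0.12)))

    A = settings.max_age - AGE_MIN + 1
    C = len(conditions)

    def read_sa(table: str, col: str) -> np.ndarray:
        df = pd.read_csv(path / f"{table}.csv")
        if col not in df.columns:
            raise ParameterError(f"{table}.csv: missing column {col!r}")
        out = np.zeros((2, A))
        seen = np.zeros((2, A), dtype=bool)
        for row in df.itertuples(index=False):
            s = _sex_idx(row.sex)
            ai = int(row.age) - AGE_MIN
            if not (0 <= ai < A):
                raise ParameterError(f"{table}.csv: age {row.age} outside 35..{settings.max_age}")
            out[s, ai] = getattr(row, col)
            seen[s, ai] = True
        if not seen.all():
            s, ai = (int(x[0]) for x in np.nonzero(~seen))
            raise ParameterError(
                f"{table}.csv: missing row for sex={SEXES[s]}, age={ai + AGE_MIN}")
        return out

    population = read_sa("population", "count")
    prev_current = read_sa("prevalence", "current")
    prev_former = read_sa("prevalence", "former")

    epi = pd.read_csv(path / "epi_rates.csv")
    incidence = np.zeros((C, 2, A))
    case_fatality = np.zeros((C, 2, A))
    excess = np.zeros((C, 2, A))
    for row in epi.itertuples(index=False):
        if row.condition not in ids:
            raise ParameterError(f"epi_rates.csv: undeclared condition {row.condition!r}")
        ci = ids.index(row.condition)
        s = _sex_idx(row.sex)
        ai = int(row.age) - AGE_MIN
        incidence[ci, s, ai] = row.baseline_incidence
        case_fatality[ci, s, ai] = row.case_fatality
        excess[ci, s, ai] = row.excess_mortality

    rrdf = pd.read_csv(path / "relative_risks.csv")
    rr_current = np.ones((C, 2))
    rr_former = np.ones((C, 2))
    for row in rrdf.itertuples(index=False):
        if row.condition not in ids:
            raise ParameterError(f"relative_risks.csv: undeclared condition {row.condition!r}")
        ci = ids.index(row.condition)
        s = _sex_idx(row.sex)
        if row.status == "current":
            rr_current[ci, s] = row.rr
        elif row.status == "former":
            rr_former[ci, s] = row.rr
        else:
            raise ParameterError(f"relative_risks.csv: unknown status {row.status!r}")

    udf = pd.read_csv(path / "utilities.csv")
    util_map = dict(zip(udf["condition"], udf["utility"]))
    if util_map.get("healthy", 1.0) != 1.0:
        raise ParameterError(f"utilities.csv: u(healthy)={util_map['healthy']} must be 1")
    utilities = np.ones(C)
    for cid, u in util_map.items():
        if cid == "healthy":
            continue
        if cid not in ids:
            raise ParameterError(f"utilities.csv: undeclared condition {cid!r}")
        utilities[ids.index(cid)] = u

    cdf = pd.read_csv(path / "costs.csv")
    meta = config.get("costs_meta", {})
    costs = CostCatalog(currency=meta.get("currency", "NGN"),
                        naira_per_usd=float(meta.get("naira_per_usd", NAIRA_PER_USD)))
    for row in cdf.itertuples(index=False):
        costs.items[row.item] = float(row.cost)
        costs.roles[row.item] = (row.condition, row.role)

    wages = read_sa("wages", "annual_wage")

    cg_cfg = config.get("caregiver", {})
    cgdf = pd.read_csv(path / "caregiver.csv")
    caregiver = CaregiverModel(
        hours_per_day={r.condition: float(r.hours_per_day)
                       for r in cgdf.itertuples(index=False)},
        hourly_cost=float(cg_cfg.get("hourly_cost", 0.0)),
        intercept=float(cg_cfg.get("intercept", 0.0)),
        slope=float(cg_cfg.get("slope", 8.0)),
    )

    q = read_sa("life_table", "q")
    life_exp = read_sa("life_table", "e")

    p = ParameterSet(
        conditions=conditions, population=population, prev_current=prev_current,
        prev_former=prev_former, incidence=incidence, case_fatality=case_fatality,
        excess_mortality=excess, q=q, life_exp=life_exp, rr_current=rr_current,
        rr_former=rr_former, utilities=utilities, costs=costs, econ=econ,
        wages=wages, caregiver=caregiver, secondhand_uplift=uplift,
        settings=settings,
        synthetic_stand_in=tuple(config.get("synthetic_stand_in", ())),
    )
    if validate:
        rep = validate_parameters(p)
        if not rep.ok:
            raise ParameterError("invalid parameter bundle:\n  " + "\n  ".join(rep.errors))
        for w in rep.warnings:
            logger.warning("parameter bundle: %s", w)
    return p


def parameters_equal(a: ParameterSet, b: ParameterSet) -> bool:
    """Field-by-field equality (used by the round-trip property)."""
    if a.conditions != b.conditions:
        return False
    for fld in ("population", "prev_current", "prev_former", "incidence",
                "case_fatality", "excess_mortality", "q", "life_exp",
                "rr_current", "rr_former", "utilities", "wages"):
        if not np.allclose(getattr(a, fld), getattr(b, fld), rtol=0, atol=1e-12):
            return False
    return (
        a.costs.items == b.costs.items
        and a.costs.roles == b.costs.roles
        and dataclasses.asdict(a.econ) == dataclasses.asdict(b.econ)
        and a.caregiver.hours_per_day == b.caregiver.hours_per_day
        and a.caregiver.hourly_cost == b.caregiver.hourly_cost
        and a.caregiver.intercept == b.caregiver.intercept
        and a.caregiver.slope == b.caregiver.slope
        and a.secondhand_uplift == b.secondhand_uplift
        and dataclasses.asdict(a.settings) == dataclasses.asdict(b.settings)
    )
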