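"""First-order Monte Carlo lifetime simulation.

Individuals carry a fixed sex, entry age and smoking status and are advanced
through annual cycles until death or ``max_age``.  Each cycle draws incident
events per condition (baseline never-smoker risk times the status-specific
relative risk), lets mortality compete in a fixed order (event-year case
fatality, then chronic-state excess mortality, then background mortality) and
accrues state occupancy, utility-weighted QALYs and direct costs.

The cohort simulator is vectorised over individuals but consumes random
numbers on a *fixed per-age schedule that does not depend on anyone's state*:
every uniform variate is drawn for all ``n`` slots whether or not the
individual is alive.  Two runs that share a seed therefore see identical
randomness slot-for-slot, which is what makes common-random-number
counterfactual comparisons (and the policy arms) low-variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .param_model import (
    AGE_MIN, CURRENT, FEMALE, FORMER, KIND_ACUTE, KIND_CANCER, KIND_CHRONIC,
    MALE, NEVER, ParameterSet, SEXES, STATUSES,
)

logger = logging.getLogger(__name__)

BACKGROUND = "background"

# sub-stream labels for SeedSequence spawning
_STREAM_COMPOSITION = 0
_STREAM_EVENTS = 1
_STREAM_QUIT = 2


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def annual_event_probability(
    baseline: float, rr: float, status: int | str, *, cap_log: list | None = None
) -> float:
    """Annual probability of an event: ``baseline * rr(status)``, capped at 1.

    ``rr`` is ignored for never-smokers (their multiplier is identically 1).
    A cap event is appended to ``cap_log`` when the product exceeds 1.
    """
    if baseline < 0 or rr < 0:
        raise ValueError(f"negative input: baseline={baseline}, rr={rr}")
    if baseline > 1:
        raise ValueError(f"baseline probability {baseline} > 1")
    if isinstance(status, str):
        status = STATUSES.index(status)
    mult = 1.0 if status == NEVER else rr
    prob = baseline * mult
    if prob > 1.0:
        if cap_log is not None:
            cap_log.append((baseline, rr, status))
        logger.warning("event probability capped at 1 (baseline=%g, rr=%g)", baseline, rr)
        return 1.0
    return prob


def disability_weight(u: float) -> float:
    """Disability weight ``1 - utility``."""
    if not (0.0 <= u <= 1.0):
        raise ValueError(f"utility {u} outside [0, 1]")
    return 1.0 - u


def yll_for_death(sex: int | str, age_at_death: int, life_exp: np.ndarray) -> float:
    """Years of life lost for one death: residual life expectancy
    ``e(sex, age_at_death)`` (undiscounted, un-age-weighted).

    ``life_exp`` is the ``(2, A)`` residual-life-expectancy table of a
    :class:`~smokesim.param_model.ParameterSet`.
    """
    if isinstance(sex, str):
        sex = SEXES.index(sex)
    ai = int(age_at_death) - AGE_MIN
    if not (0 <= ai < life_exp.shape[1]):
        raise ValueError(f"age {age_at_death} outside life table")
    return float(life_exp[sex, ai])


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class LifeHistory:
    """One simulated individual's trajectory."""

    sex: int
    entry_age: int
    status: int
    events: list[tuple[int, str, str]] = field(default_factory=list)  # (age, condition, kind)
    occupancy: list[tuple[int, str]] = field(default_factory=list)  # (age, condition-state)
    death_age: int | None = None
    death_cause: str | None = None  # condition id or "background"
    life_years: float = 0.0
    qalys: float = 0.0
    direct_cost: float = 0.0


@dataclass
class CohortOutcomes:
    """Aggregated outcomes of a simulated cohort.

    All arrays are raw cohort totals (not rates); the cause axis of ``deaths``
    and ``yll`` has ``C + 1`` entries, the last one being background mortality.
    Person-years use a half-year credit in the year of death.
    """

    condition_ids: tuple[str, ...]
    n: int
    seed: int
    person_years: np.ndarray  # (2, A)
    qaly_years: np.ndarray  # (2, A) utility-weighted person-years
    morbidity_loss: np.ndarray  # (2, A) (1 - combined utility) person-years
    deaths: np.ndarray  # (2, A, C+1) by age at death and cause
    yll: np.ndarray  # (2, A, C+1)
    events: np.ndarray  # (2, A, C)
    state_years: np.ndarray  # (2, A, C) occupancy incl. event years
    direct_cost: np.ndarray  # (2, A, C) ₦
    cap_events: int = 0

    @property
    def total_life_years(self) -> float:
        return float(self.person_years.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.qaly_years.sum())

    @property
    def total_deaths(self) -> float:
        return float(self.deaths.sum())

    def rate(self, numer: np.ndarray) -> np.ndarray:
        """Per-person-year rate of a ``(2, A[, ...])`` total, 0 where empty."""
        py = self.person_years
        if numer.ndim > py.ndim:
            py = py[..., None]
        return np.divide(numer, py, out=np.zeros_like(numer, dtype=float),
                         where=py > 0)

    def summary(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "person_years": self.total_life_years,
            "qalys": self.total_qalys,
            "deaths": self.total_deaths,
            "events": float(self.events.sum()),
            "direct_cost": float(self.direct_cost.sum()),
            "cap_events": int(self.cap_events),
        }


# ---------------------------------------------------------------------------
# Cohort composition
# ---------------------------------------------------------------------------


@dataclass
class CohortDraw:
    """Fixed composition shared by all arms of a comparison."""

    sex: np.ndarray  # (n,) 0/1
    entry_age: np.ndarray  # (n,) int
    status: np.ndarray  # (n,) 0/1/2 as drawn from baseline prevalence
    u_quit: np.ndarray  # (n,) uniforms reserved for policy quitting


def draw_cohort(p: ParameterSet, n: int, seed: int) -> CohortDraw:
    """Draw ``n`` individuals matching the population strata and baseline
    smoking prevalence.  Deterministic given ``(p, n, seed)``."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    ss = np.random.SeedSequence([int(seed), _STREAM_COMPOSITION])
    rng = np.random.Generator(np.random.PCG64(ss))
    weights = p.population.ravel().astype(float)
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    weights = weights / weights.sum()
    flat = rng.choice(weights.size, size=n, p=weights)
    sex, age_idx = np.unravel_index(flat, p.population.shape)
    entry_age = age_idx + AGE_MIN

    u_status = rng.random(n)
    pc = p.prev_current[sex, age_idx]
    pf = p.prev_former[sex, age_idx]
    status = np.full(n, NEVER, dtype=np.int8)
    status[u_status < pc] = CURRENT
    status[(u_status >= pc) & (u_status < pc + pf)] = FORMER

    ss_q = np.random.SeedSequence([int(seed), _STREAM_QUIT])
    u_quit = np.random.Generator(np.random.PCG64(ss_q)).random(n)
    return CohortDraw(sex=sex.astype(np.int8), entry_age=entry_age.astype(np.int16),
                      status=status, u_quit=u_quit)


# ---------------------------------------------------------------------------
# Engine core
# ---------------------------------------------------------------------------


def _rr_table(p: ParameterSet) -> np.ndarray:
    """(C, 3 statuses, 2 sexes) multiplier table with rr(never) = 1."""
    C = p.n_conditions
    t = np.ones((C, 3, 2))
    t[:, CURRENT, :] = p.rr_current
    t[:, FORMER, :] = p.rr_former
    return t


def simulate_cohort_arm(
    p: ParameterSet,
    draw: CohortDraw,
    seed: int,
    *,
    status: np.ndarray | None = None,
    record: bool = False,
) -> CohortOutcomes | tuple[CohortOutcomes, list[LifeHistory]]:
    """Simulate one arm over a fixed cohort composition.

    ``status`` overrides the drawn smoking statuses (e.g. all-never for the
    counterfactual arm); the event stream depends only on ``seed``, so arms
    sharing a seed are driven by common random numbers.
    """
    n = draw.sex.size
    sex = draw.sex.astype(np.intp)
    entry_age = draw.entry_age
    status = draw.status if status is None else np.asarray(status, dtype=np.int8)

    C = p.n_conditions
    A = p.n_ages
    max_age = p.settings.max_age
    ids = p.condition_ids
    kinds = [c.kind for c in p.conditions]
    cancer_idx = [ci for ci, k in enumerate(kinds) if k == KIND_CANCER]
    copd_ci = ids.index("copd") if "copd" in ids else None
    ihd_ci = ids.index("ihd") if "ihd" in ids else None
    stroke_ci = ids.index("stroke") if "stroke" in ids else None
    rr_tab = _rr_table(p)  # (C, 3, 2)
    rr_on_incidence = p.settings.rr_target == "incidence"
    u_cond = p.utilities
    active_years = p.settings.cancer_active_years
    prog_mild, prog_mod = p.settings.copd_progression

    # cost vectors
    event_cost = np.array([p.costs.event_cost(c, p.settings.ami_share) for c in ids])
    first_cost = np.array([p.costs.first_year_cost(c) for c in ids])
    follow_cost = np.array([p.costs.followup_cost(c) for c in ids])
    tier_cost = np.array([0.0, *p.costs.copd_tier_costs()]) if copd_ci is not None \
        else np.zeros(4)

    # state
    alive = np.ones(n, dtype=bool)
    copd_state = np.zeros(n, dtype=np.int8)  # 0 none, 1 mild, 2 moderate, 3 severe
    chd_followup = np.zeros(n, dtype=bool)
    stroke_followup = np.zeros(n, dtype=bool)
    cancer_age = np.full((len(cancer_idx), n), -1, dtype=np.int16)  # years since dx, -1 none

    out = CohortOutcomes(
        condition_ids=ids, n=n, seed=seed,
        person_years=np.zeros((2, A)), qaly_years=np.zeros((2, A)),
        morbidity_loss=np.zeros((2, A)),
        deaths=np.zeros((2, A, C + 1)), yll=np.zeros((2, A, C + 1)),
        events=np.zeros((2, A, C)), state_years=np.zeros((2, A, C)),
        direct_cost=np.zeros((2, A, C)),
    )
    histories: list[LifeHistory] | None = None
    if record:
        histories = [LifeHistory(int(draw.sex[i]), int(entry_age[i]), int(status[i]))
                     for i in range(n)]

    ss = np.random.SeedSequence([int(seed), _STREAM_EVENTS])
    rng = np.random.Generator(np.random.Philox(ss))

    def tally(arr2d: np.ndarray, mask: np.ndarray, vals: np.ndarray | float, ai: int):
        """arr2d is a (2, A) or (2, A, K) slice target at age ai by sex."""
        for s in (MALE, FEMALE):
            m = mask & (sex == s)
            if np.any(m):
                v = vals[m].sum() if isinstance(vals, np.ndarray) else vals * m.sum()
                arr2d[s, ai] += v

    for age in range(AGE_MIN, max_age + 1):
        ai = age - AGE_MIN
        active = alive & (entry_age <= age)

        # ---- fixed draw schedule (state-independent) ----
        U_inc = rng.random((C, n))
        U_cf = rng.random((C, n))
        U_prog = rng.random((2, n))
        U_excess = rng.random((C, n))
        U_bg = rng.random(n)

        # ---- incident events / diagnoses ----
        occur = np.zeros((C, n), dtype=bool)
        for ci in range(C):
            base = p.incidence[ci, sex, ai]
            mult = rr_tab[ci, status, sex] if rr_on_incidence else 1.0
            prob = base * mult
            capped = prob > 1.0
            if np.any(capped & active):
                out.cap_events += int((capped & active).sum())
                logger.warning("capped %d event probabilities at 1 for %s, age %d",
                               int((capped & active).sum()), ids[ci], age)
                prob = np.minimum(prob, 1.0)
            elig = active
            if kinds[ci] == KIND_CHRONIC:
                elig = elig & (copd_state == 0)
            elif kinds[ci] == KIND_CANCER:
                elig = elig & (cancer_age[cancer_idx.index(ci)] < 0)
            occur[ci] = elig & (U_inc[ci] < prob)

        # state entry
        if copd_ci is not None:
            copd_state[occur[copd_ci]] = 1
        for k, ci in enumerate(cancer_idx):
            cancer_age[k, occur[ci]] = 0

        # ---- mortality competition ----
        dead_now = np.zeros(n, dtype=bool)
        cause = np.full(n, -1, dtype=np.int16)

        def kill(mask: np.ndarray, ci: int):
            nonlocal dead_now
            new = mask & ~dead_now
            cause[new] = ci
            dead_now |= new

        for ci in range(C):
            cf = p.case_fatality[ci, sex, ai]
            if not rr_on_incidence:
                cf = np.minimum(cf * rr_tab[ci, status, sex], 1.0)
            kill(occur[ci] & (U_cf[ci] < cf), ci)

        # chronic-state excess mortality (COPD any tier, heart/stroke follow-up,
        # cancers in post-diagnosis follow-up years)
        for ci in range(C):
            ex = p.excess_mortality[ci, sex, ai]
            if not rr_on_incidence:
                ex = np.minimum(ex * rr_tab[ci, status, sex], 1.0)
            if kinds[ci] == KIND_CHRONIC:
                in_state = (copd_state > 0) & ~occur[ci]
            elif kinds[ci] == KIND_CANCER:
                ca = cancer_age[cancer_idx.index(ci)]
                in_state = (ca >= 1) & (ca < active_years)
            elif ci == ihd_ci:
                in_state = chd_followup & ~occur[ci]
            elif ci == stroke_ci:
                in_state = stroke_followup & ~occur[ci]
            else:
                in_state = np.zeros(n, dtype=bool)
            kill(active & in_state & (U_excess[ci] < ex), ci)

        q = p.q[sex, ai] if age < max_age else np.ones(n)
        kill(active & (U_bg < q), C)  # background; forced at max_age

        dead_now &= active

        # ---- occupancy, utility, costs ----
        credit = np.where(dead_now, 0.5, 1.0)
        util = np.ones(n)
        present = np.zeros((C, n), dtype=bool)
        for ci in range(C):
            if kinds[ci] == KIND_ACUTE:
                pres = occur[ci].copy()
                if ci == ihd_ci:
                    pres |= chd_followup
                elif ci == stroke_ci:
                    pres |= stroke_followup
            elif kinds[ci] == KIND_CHRONIC:
                pres = copd_state > 0
            else:
                ca = cancer_age[cancer_idx.index(ci)]
                pres = (ca >= 0) & (ca < active_years)
            pres &= active
            present[ci] = pres
            util[pres] *= u_cond[ci]

        tally(out.person_years, active, credit, ai)
        tally(out.qaly_years, active, credit * util, ai)
        tally(out.morbidity_loss, active, credit * (1.0 - util), ai)

        cost_i = np.zeros((C, n))
        for ci in range(C):
            if kinds[ci] == KIND_ACUTE:
                cost_i[ci][occur[ci]] += event_cost[ci]
                if ci == ihd_ci:
                    cost_i[ci][chd_followup & active] += follow_cost[ci] * \
                        credit[chd_followup & active]
                elif ci == stroke_ci:
                    cost_i[ci][stroke_followup & active] += follow_cost[ci] * \
                        credit[stroke_followup & active]
            elif kinds[ci] == KIND_CHRONIC:
                m = present[ci]
                cost_i[ci][m] += tier_cost[copd_state[m]] * credit[m]
            else:
                ca = cancer_age[cancer_idx.index(ci)]
                dx = (ca == 0) & active
                fu = (ca >= 1) & (ca < active_years) & active
                cost_i[ci][dx] += first_cost[ci]
                cost_i[ci][fu] += follow_cost[ci] * credit[fu]

        for s in (MALE, FEMALE):
            ms = active & (sex == s)
            if np.any(ms):
                out.events[s, ai] += occur[:, ms].sum(axis=1)
                out.state_years[s, ai] += (present[:, ms] * credit[ms]).sum(axis=1)
                out.direct_cost[s, ai] += cost_i[:, ms].sum(axis=1)

        # deaths and YLL
        if np.any(dead_now):
            e_here = p.life_exp[sex, ai]
            for s in (MALE, FEMALE):
                for c in range(C + 1):
                    m = dead_now & (sex == s) & (cause == c)
                    k = int(m.sum())
                    if k:
                        out.deaths[s, ai, c] += k
                        out.yll[s, ai, c] += e_here[m].sum()

        if record:
            for i in np.nonzero(active)[0]:
                h = histories[i]
                for ci in range(C):
                    if occur[ci, i]:
                        h.events.append((age, ids[ci], "event"))
                    if present[ci, i]:
                        state = ids[ci]
                        if ci == copd_ci:
                            state += ("", "_mild", "_moderate", "_severe")[copd_state[i]]
                        h.occupancy.append((age, state))
                h.life_years += credit[i]
                h.qalys += credit[i] * util[i]
                h.direct_cost += cost_i[:, i].sum()
                if dead_now[i]:
                    h.death_age = age
                    h.death_cause = ids[cause[i]] if cause[i] < C else BACKGROUND

        # ---- end-of-year state updates (survivors only) ----
        surv = active & ~dead_now
        if copd_ci is not None:
            sev = surv & (copd_state == 2) & (U_prog[1] < prog_mod)
            mod = surv & (copd_state == 1) & (U_prog[0] < prog_mild)
            copd_state[sev] = 3
            copd_state[mod] = 2
        if ihd_ci is not None:
            chd_followup |= surv & occur[ihd_ci]
        if stroke_ci is not None:
            stroke_followup |= surv & occur[stroke_ci]
        for k in range(len(cancer_idx)):
            adv = cancer_age[k] >= 0
            cancer_age[k, adv] += 1
        alive &= ~dead_now

    if record:
        return out, histories
    return out


def simulate_cohort(
    p: ParameterSet, n: int, seed: int, *, status: np.ndarray | None = None
) -> CohortOutcomes:
    """Draw a cohort matching the population strata and prevalence of ``p``
    and simulate it.  Deterministic given ``(p, n, seed)``."""
    draw = draw_cohort(p, n, seed)
    return simulate_cohort_arm(p, draw, seed, status=status)


def simulate_individual(profile: tuple[int | str, int, int | str],
                        p: ParameterSet, seed: int) -> LifeHistory:
    """Simulate a single individual ``(sex, entry_age, status)``.

    Deterministic given ``(profile, p, seed)``; runs the same engine as
    :func:`simulate_cohort` with ``n = 1`` and event recording on.
    """
    sex, entry_age, status = profile
    if isinstance(sex, str):
        sex = SEXES.index(sex)
    if isinstance(status, str):
        status = STATUSES.index(status)
    if entry_age < AGE_MIN:
        raise ValueError(f"entry age {entry_age} below {AGE_MIN}")
    draw = CohortDraw(
        sex=np.array([sex], dtype=np.int8),
        entry_age=np.array([entry_age], dtype=np.int16),
        status=np.array([status], dtype=np.int8),
        u_quit=np.zeros(1),
    )
    _, histories = simulate_cohort_arm(p, draw, seed, record=True)
    return histories[0]


def counterfactual_status(draw: CohortDraw) -> np.ndarray:
    """All-never-smoker status vector for the 'smokers never existed' arm."""
    return np.full(draw.sex.size, NEVER, dtype=np.int8)
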