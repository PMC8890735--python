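"""Tax-driven price-increase scenarios.

The closed-form layer converts a proportional retail price increase into a
prevalence change (own-price elasticity, optionally blended with the
cross-price elasticity toward illicit products), a tax-revenue change under
full pass-through, and the share of economic gains retained when illicit
substitution is accounted for.

The scenario runner moves the implied share of current smokers to former
status (they acquire ex-smoker relative risks immediately) and re-simulates
with common random numbers, accumulating averted deaths, events, DALYs and
costs over the horizon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .burden import attributable_burden
from .costing import economic_burden
from .param_model import CURRENT, FORMER, HEART_CONDITIONS, KIND_CANCER, ParameterSet
from .simulation_engine import CohortDraw, draw_cohort, simulate_cohort_arm

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Closed-form layer
# ---------------------------------------------------------------------------


def prevalence_coefficient(alpha: float, eps_d: float, eps_cp: float) -> float:
    """Combined elasticity coefficient ``alpha*eps_d + (1 - alpha)*eps_cp``."""
    return alpha * eps_d + (1.0 - alpha) * eps_cp


def post_policy_prevalence(
    prev_b: float,
    alpha: float,
    eps_d: float,
    eps_cp: float,
    delta_p: float,
    ip: float,
) -> float:
    """Smoking prevalence after a proportional price increase ``delta_p``:
    ``prev_b * (1 + (alpha*eps_d + (1-alpha)*eps_cp) * delta_p * ip)``.

    The result is clamped to [0, 1] with a warning if clamping triggers.
    """
    if not (0.0 <= prev_b <= 1.0):
        raise ValueError(f"prev_b={prev_b} outside [0, 1]")
    out = prev_b * (1.0 + prevalence_coefficient(alpha, eps_d, eps_cp) * delta_p * ip)
    if out < 0.0 or out > 1.0:
        logger.warning("post-policy prevalence %g clamped to [0, 1]", out)
        out = min(1.0, max(0.0, out))
    return out


def revenue_change(eps_d: float, delta_p: float, tax_share: float,
                   *, tax_term: str = "ratio") -> float:
    """Proportional tax-revenue change
    ``(1 + eps_d*delta_p) * (1 + delta_p/tax_share) - 1``.

    Full pass-through between price and excises is assumed, so a retail price
    increase of ``delta_p`` requires the tax rate to grow by
    ``delta_p / tax_share`` (the default "ratio" reading); ``tax_term =
    "product"`` exposes the multiplicative reading ``delta_p * tax_share``
    for sensitivity analysis.
    """
    if tax_share <= 0:
        raise ValueError("tax_share must be > 0")
    if tax_term == "ratio":
        t = delta_p / tax_share
    elif tax_term == "product":
        t = delta_p * tax_share
    else:
        raise ValueError(f"unknown tax_term {tax_term!r}")
    return (1.0 + eps_d * delta_p) * (1.0 + t) - 1.0


def tax_rate_increase(delta_p: float, tax_share: float) -> float:
    """Proportional increase of the tax rate needed for ``delta_p`` under
    full pass-through (``delta_p / tax_share``)."""
    if tax_share <= 0:
        raise ValueError("tax_share must be > 0")
    return delta_p / tax_share


def illicit_retention(alpha: float, eps_d: float, eps_cp: float) -> float:
    """Fraction of economic gains retained under illicit substitution: the
    prevalence-effect coefficient with substitution over the coefficient
    without it, ``(alpha*eps_d + (1-alpha)*eps_cp) / eps_d``."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    if eps_d == 0:
        raise ValueError("eps_d must be nonzero")
    return prevalence_coefficient(alpha, eps_d, eps_cp) / eps_d


# ---------------------------------------------------------------------------
# Scenario runner
# ---------------------------------------------------------------------------


@dataclass
class PolicyScenario:
    """One price-increase scenario."""

    delta_p: float  # proportional retail price increase, e.g. 0.5
    horizon: int = 10
    #: consumption-to-prevalence share by simulation year (1-based);
    #: default 0.5 for years 1-5 and 0.75 for years 6-10.
    ip_schedule: tuple[float, ...] = field(default=None)  # type: ignore[assignment]
    illicit_adjustment: bool = False

    def __post_init__(self) -> None:
        if self.delta_p < 0:
            raise ValueError("delta_p must be >= 0")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.ip_schedule is None:
            self.ip_schedule = tuple(
                0.5 if y <= 5 else 0.75 for y in range(1, self.horizon + 1))
        self.ip_schedule = tuple(self.ip_schedule)
        if len(self.ip_schedule) != self.horizon:
            raise ValueError("ip_schedule length must equal horizon")
        if any(not (0.0 <= ip <= 1.0) for ip in self.ip_schedule):
            raise ValueError("Ip values must lie in [0, 1]")


@dataclass
class ScenarioOutcomes:
    """Ten-year averted burden, avoided costs and revenue gain (₦ million)."""

    delta_p: float
    horizon: int
    deaths_prevented: float
    heart_disease_avoided: float
    strokes_avoided: float
    cancers_avoided: float
    copd_avoided: float
    dalys_avoided: float
    health_costs_avoided_mn: float
    caregiver_costs_avoided_mn: float
    productivity_losses_avoided_mn: float
    tax_gain_mn: float
    n: int = 0
    seed: int = 0

    @property
    def total_benefit_mn(self) -> float:
        """Exact sum of the four monetary components."""
        return (self.health_costs_avoided_mn + self.caregiver_costs_avoided_mn
                + self.productivity_losses_avoided_mn + self.tax_gain_mn)

    def as_dict(self) -> dict[str, float]:
        return {
            "delta_p": self.delta_p,
            "horizon": self.horizon,
            "deaths_prevented": self.deaths_prevented,
            "heart_disease_avoided": self.heart_disease_avoided,
            "strokes_avoided": self.strokes_avoided,
            "cancers_avoided": self.cancers_avoided,
            "copd_avoided": self.copd_avoided,
            "dalys_avoided": self.dalys_avoided,
            "health_costs_avoided_mn": self.health_costs_avoided_mn,
            "caregiver_costs_avoided_mn": self.caregiver_costs_avoided_mn,
            "productivity_losses_avoided_mn": self.productivity_losses_avoided_mn,
            "tax_gain_mn": self.tax_gain_mn,
            "total_benefit_mn": self.total_benefit_mn,
            "n": self.n,
            "seed": self.seed,
        }


def quit_fraction(p: ParameterSet, s: PolicyScenario, ip: float) -> float:
    """Fraction of current smokers who quit under the scenario at a given Ip:
    the relative prevalence reduction implied by the prevalence formula."""
    e = p.econ
    alpha = e.alpha if s.illicit_adjustment else 1.0
    k = prevalence_coefficient(alpha, e.eps_d, e.eps_cp)
    return min(1.0, max(0.0, -k * s.delta_p * ip))


def policy_status(draw: CohortDraw, frac: float) -> np.ndarray:
    """Move the quitting share of current smokers to former status, using the
    cohort's reserved quit uniforms so larger fractions nest smaller ones."""
    status = draw.status.copy()
    movers = (status == CURRENT) & (draw.u_quit < frac)
    status[movers] = FORMER
    return status


def run_scenario(p: ParameterSet, s: PolicyScenario, n: int, seed: int) -> ScenarioOutcomes:
    """Simulate baseline and policy arms with common random numbers and
    accumulate averted annual quantities over the horizon.

    One policy arm is simulated per distinct Ip value in the schedule; each
    horizon year contributes that year's arm's annual averted quantities.
    The tax gain applies the closed-form revenue change to the baseline tax
    revenue in every year.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    draw = draw_cohort(p, n, seed)
    baseline = simulate_cohort_arm(p, draw, seed)

    years_by_ip: dict[float, int] = {}
    for ip in s.ip_schedule:
        years_by_ip[ip] = years_by_ip.get(ip, 0) + 1

    ids = p.condition_ids
    cancer_ids = [c.id for c in p.conditions if c.kind == KIND_CANCER]
    totals = {k: 0.0 for k in ("deaths", "heart", "stroke", "cancer", "copd",
                               "daly", "health_mn", "care_mn", "prod_mn")}
    for ip, years in sorted(years_by_ip.items()):
        status = policy_status(draw, quit_fraction(p, s, ip))
        arm = simulate_cohort_arm(p, draw, seed, status=status)
        # annual averted quantities: baseline burden relative to the policy arm
        b = attributable_burden(baseline, arm, p)
        costs = economic_burden(b, p, uplift=False)
        bc = b.by_condition

        def group_events(group: list[str]) -> float:
            present = [c for c in group if c in bc.index]
            return float(bc.loc[present, "attr_events"].sum()) if present else 0.0

        totals["deaths"] += years * float(bc["attr_deaths"].sum())
        totals["heart"] += years * group_events(list(HEART_CONDITIONS))
        totals["stroke"] += years * group_events(["stroke"])
        totals["cancer"] += years * group_events(cancer_ids)
        totals["copd"] += years * group_events(["copd"])
        totals["daly"] += years * float(bc["attr_daly"].sum())
        totals["health_mn"] += years * costs.direct
        totals["care_mn"] += years * costs.caregiver
        totals["prod_mn"] += years * (costs.productivity_premature_death
                                      + costs.productivity_disability)

    dr = revenue_change(p.econ.eps_d, s.delta_p, p.econ.tax_share)
    tax_gain = s.horizon * p.econ.baseline_tax_revenue * dr

    return ScenarioOutcomes(
        delta_p=s.delta_p, horizon=s.horizon,
        deaths_prevented=totals["deaths"],
        heart_disease_avoided=totals["heart"],
        strokes_avoided=totals["stroke"],
        cancers_avoided=totals["cancer"],
        copd_avoided=totals["copd"],
        dalys_avoided=totals["daly"],
        health_costs_avoided_mn=totals["health_mn"],
        caregiver_costs_avoided_mn=totals["care_mn"],
        productivity_losses_avoided_mn=totals["prod_mn"],
        tax_gain_mn=tax_gain,
        n=n, seed=seed,
    )
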