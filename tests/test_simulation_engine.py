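"""Engine tests: elementary operations, determinism, conservation laws and
independent oracles (closed forms and exhaustive path enumeration)."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smokesim.param_model import CURRENT, KIND_ACUTE, NEVER
from smokesim.simulation_engine import (
    annual_event_probability, counterfactual_status, disability_weight,
    draw_cohort, simulate_cohort, simulate_cohort_arm, simulate_individual,
    yll_for_death,
)
from smokesim.synthetic_data import life_expectancy_from_q

from conftest import make_toy_params


class TestAnnualEventProbability:
    def test_direct_product(self):
        assert annual_event_probability(0.01, 2.0, "current") == pytest.approx(0.02)

    def test_never_smoker_identity(self):
        assert annual_event_probability(0.03, 17.0, "never") == pytest.approx(0.03)

    def test_cap_rule(self):
        log = []
        assert annual_event_probability(0.6, 2.0, CURRENT, cap_log=log) == 1.0
        assert len(log) == 1

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            annual_event_probability(-0.1, 2.0, "current")
        with pytest.raises(ValueError):
            annual_event_probability(0.1, -2.0, "current")

    @given(st.floats(0, 1), st.floats(0, 50), st.integers(0, 2))
    @settings(max_examples=200, deadline=None)
    def test_always_a_probability(self, base, rr, status):
        out = annual_event_probability(base, rr, status)
        assert 0.0 <= out <= 1.0


class TestDisabilityWeight:
    @pytest.mark.parametrize("u,dw", [(0.8, 0.2), (1.0, 0.0), (0.0, 1.0)])
    def test_values(self, u, dw):
        assert disability_weight(u) == pytest.approx(dw)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            disability_weight(1.2)
        with pytest.raises(ValueError):
            disability_weight(-0.1)


class TestYll:
    def test_lookup(self):
        life_exp = np.zeros((2, 66))
        life_exp[0, 70 - 35] = 10.0
        assert yll_for_death("male", 70, life_exp) == pytest.approx(10.0)

    def test_monotone_in_age(self):
        q = np.full((2, 66), 0.1)
        e = life_expectancy_from_q(q)
        assert yll_for_death(0, 50, e) > yll_for_death(0, 60, e)

    def test_geometric_table(self):
        # constant q = 0.5 with the engine's half-year death-year credit:
        # e = 0.5 + sum_k (1-q)^k = 0.5 + 1 = 1.5 (truncation negligible)
        q = np.full((2, 66), 0.5)
        e = life_expectancy_from_q(q)
        assert yll_for_death(0, 35, e) == pytest.approx(1.5, abs=1e-6)

    def test_outside_table_errors(self):
        with pytest.raises(ValueError):
            yll_for_death(0, 20, np.zeros((2, 66)))


class TestSimulateIndividual:
    def test_degenerate_healthy_run(self):
        p = make_toy_params(incidence=0.0, q=0.0, max_age=100)
        h = simulate_individual(("male", 35, "never"), p, seed=3)
        assert h.death_age == 100
        assert h.death_cause == "background"
        # ages 35..99 earn a full year, the forced death year a half
        assert h.life_years == pytest.approx(65.5)
        assert h.qalys == pytest.approx(h.life_years)
        assert h.events == []

    def test_determinism(self):
        p = make_toy_params(incidence=0.02, case_fatality=0.3, q=0.05, max_age=60)
        h1 = simulate_individual(("female", 40, "current"), p, seed=11)
        h2 = simulate_individual(("female", 40, "current"), p, seed=11)
        assert h1 == h2

    def test_no_events_after_death(self):
        p = make_toy_params(incidence=0.1, case_fatality=0.5, q=0.1, max_age=80)
        for seed in range(20):
            h = simulate_individual(("male", 35, "current"), p, seed=seed)
            if h.death_age is not None and h.events:
                assert max(age for age, _, _ in h.events) <= h.death_age

    def test_qalys_bounded_by_life_years(self):
        p = make_toy_params(incidence=0.1, utility=0.7, q=0.05, max_age=70)
        for seed in range(10):
            h = simulate_individual(("male", 35, "current"), p, seed=seed)
            assert h.qalys <= h.life_years + 1e-12


class TestGeometricLifetime:
    def test_mean_lifespan_matches_closed_form(self):
        # all incidences 0, constant q = 0.2: life-years per person are
        # (K - 1) + 0.5 with K ~ Geometric(q), so the mean is
        # (1-q)/q + 0.5 = 4.5 (oracle recomputed under the half-cycle
        # convention; truncation at age 100 is ~0.8^65, negligible)
        q = 0.2
        n = 50_000
        p = make_toy_params(incidence=0.0, q=q, max_age=100)
        out = simulate_cohort(p, n, seed=5)
        mean_ly = out.total_life_years / n
        exact = (1 - q) / q + 0.5
        se = math.sqrt((1 - q) / q**2) / math.sqrt(n)
        assert abs(mean_ly - exact) < 3 * se


class TestCohort:
    def test_rejects_empty_cohort(self, toy_params):
        with pytest.raises(ValueError):
            simulate_cohort(toy_params, 0, seed=1)

    def test_deterministic_given_seed(self, toy_params):
        a = simulate_cohort(toy_params, 500, seed=9)
        b = simulate_cohort(toy_params, 500, seed=9)
        assert np.array_equal(a.deaths, b.deaths)
        assert np.array_equal(a.events, b.events)
        assert a.summary() == b.summary()

    def test_conservation_of_deaths_and_person_years(self):
        p = make_toy_params(incidence=0.05, case_fatality=0.2, q=0.1, max_age=60)
        n = 2_000
        out = simulate_cohort(p, n, seed=2)
        # everyone is dead by max_age (forced), so deaths sum to n
        assert out.deaths.sum() == pytest.approx(n)
        # person-years equal summed life-years by construction
        assert out.person_years.sum() == pytest.approx(out.total_life_years)

    def test_qaly_le_person_years_and_equality_without_morbidity(self):
        p = make_toy_params(incidence=0.05, utility=0.7, q=0.1, max_age=60)
        out = simulate_cohort(p, 2_000, seed=4)
        assert out.total_qalys < out.total_life_years
        p0 = make_toy_params(incidence=0.0, q=0.1, max_age=60)
        out0 = simulate_cohort(p0, 2_000, seed=4)
        assert out0.total_qalys == pytest.approx(out0.total_life_years)

    def test_rr_one_makes_status_irrelevant(self):
        # common seed: rr = 1 must give *identical* outcomes whatever the
        # smoking prevalence, because probabilities coincide draw-for-draw
        p = make_toy_params(incidence=0.03, case_fatality=0.2, q=0.05,
                            rr_current=1.0, rr_former=1.0, max_age=60)
        draw = draw_cohort(p, 3_000, seed=7)
        a = simulate_cohort_arm(p, draw, seed=7)
        b = simulate_cohort_arm(p, draw, seed=7, status=counterfactual_status(draw))
        assert np.array_equal(a.deaths, b.deaths)
        assert np.array_equal(a.events, b.events)
        assert np.array_equal(a.direct_cost, b.direct_cost)

    def test_mc_se_scaling(self):
        # doubling n shrinks the seed-to-seed SD of deaths-per-capita by
        # about 1/sqrt(2); fixed seed set, 20% tolerance
        p = make_toy_params(incidence=0.05, case_fatality=0.5, q=0.02, max_age=45)
        seeds = range(100, 124)

        def death_rate(n, seed):
            out = simulate_cohort(p, n, seed=seed)
            return out.deaths[:, :, 0].sum() / n  # condition-caused deaths

        sd_n = np.std([death_rate(1_000, s) for s in seeds], ddof=1)
        sd_2n = np.std([death_rate(2_000, s) for s in seeds], ddof=1)
        ratio = sd_2n / sd_n
        assert abs(ratio - 1 / math.sqrt(2)) < 0.2 * (1 / math.sqrt(2))


def _enumerate_two_year_toy(pA, cfA, pB, cfB, q1):
    """Exact expectations for the 2-condition, 2-year toy model by
    exhaustive enumeration of outcome paths (year 2 is the forced-death
    year: background q = 1, events still drawn).

    Returns (E[events A], E[events B], E[deaths by cause A], B, background).
    """
    e_events_A = e_events_B = 0.0
    d_A = d_B = d_bg = 0.0
    # year 1 at age 35
    for evA in (0, 1):
        prA = pA if evA else 1 - pA
        for evB in (0, 1):
            prB = pB if evB else 1 - pB
            pr_path = prA * prB
            e_events_A += pr_path * evA
            e_events_B += pr_path * evB
            # mortality competition: A's case fatality, then B's, then q1
            p_die_A = cfA if evA else 0.0
            p_die_B = cfB if evB else 0.0
            d_A += pr_path * p_die_A
            d_B += pr_path * (1 - p_die_A) * p_die_B
            alive = (1 - p_die_A) * (1 - p_die_B)
            d_bg += pr_path * alive * q1
            surv = alive * (1 - q1)
            # year 2 at age 36 (max age): events drawn, then forced death
            e_events_A += pr_path * surv * pA
            e_events_B += pr_path * surv * pB
            d_A += pr_path * surv * pA * cfA
            d_B += pr_path * surv * (1 - pA * cfA) * pB * cfB
            d_bg += pr_path * surv * (1 - pA * cfA) * (1 - pB * cfB)
    return e_events_A, e_events_B, d_A, d_B, d_bg


class TestEnumerationOracle:
    def test_two_condition_toy_matches_exact_enumeration(self):
        pA_base, cfA = 0.04, 0.3
        pB_base, cfB = 0.02, 0.5
        q1 = 0.1
        rr = 2.0
        n = 100_000
        p = make_toy_params(
            conditions=(("condA", KIND_ACUTE), ("condB", KIND_ACUTE)),
            case_fatality=np.array([[[cfA, cfA]] * 2, [[cfB, cfB]] * 2]).reshape(2, 2, 2),
            incidence=np.array([[[pA_base, pA_base]] * 2,
                                [[pB_base, pB_base]] * 2]).reshape(2, 2, 2),
            q=q1, max_age=36, prev_current=1.0, rr_current=rr,
        )
        out = simulate_cohort(p, n, seed=12)
        # whole cohort smokes: effective probabilities are base * rr
        eA, eB, dA, dB, dbg = _enumerate_two_year_toy(
            pA_base * rr, cfA, pB_base * rr, cfB, q1)

        def check(total, expect):
            per = total / n
            se = math.sqrt(max(expect, 1e-12) / n)  # Poisson-scale bound
            assert abs(per - expect) < 3 * max(se, 1e-4)

        check(out.events[:, :, 0].sum(), eA)
        check(out.events[:, :, 1].sum(), eB)
        check(out.deaths[:, :, 0].sum(), dA)
        check(out.deaths[:, :, 1].sum(), dB)
        check(out.deaths[:, :, 2].sum(), dbg)
        assert out.deaths.sum() == n  # everyone dead by max age
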