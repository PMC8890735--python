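"""Attributable-burden tests: identities, closed-form oracle, uplift, DALYs."""

from __future__ import annotations

import math

import numpy as np
import pytest

from smokesim.burden import (
    SECONDHAND_ROW, apply_secondhand_uplift, attributable_burden,
    daly_decomposition,
)
from smokesim.param_model import KIND_ACUTE
from smokesim.simulation_engine import (
    counterfactual_status, draw_cohort, simulate_cohort_arm,
)

from conftest import make_toy_params


def _run_pair(p, n, seed, status_current=None):
    draw = draw_cohort(p, n, seed)
    cur = simulate_cohort_arm(p, draw, seed, status=status_current)
    cf = simulate_cohort_arm(p, draw, seed, status=counterfactual_status(draw))
    return cur, cf


class TestAttributableBurden:
    def test_rr_one_gives_exact_zero(self):
        p = make_toy_params(incidence=0.02, case_fatality=0.3, q=0.05,
                            rr_current=1.0, rr_former=1.0, max_age=60,
                            event_cost=1000.0)
        cur, cf = _run_pair(p, 5_000, seed=3)
        b = attributable_burden(cur, cf, p)
        assert float(b.by_condition["attr_deaths"].abs().sum()) == 0.0
        assert float(b.by_condition["attr_events"].abs().sum()) == 0.0
        assert float(b.by_condition["attr_cost_mn"].abs().sum()) == 0.0

    def test_closed_form_excess_risk_oracle(self):
        # prevalence 50%, rr 2, baseline incidence 0.01, population 1e6:
        # attributable events = 1e6 * 0.5 * 0.01 * (2 - 1) = 5,000
        n = 100_000
        p = make_toy_params(incidence=0.01, case_fatality=0.0, q=0.0,
                            prev_current=0.5, rr_current=2.0, max_age=36,
                            incidence_last_age_zero=True)
        cur, cf = _run_pair(p, n, seed=21)
        b = attributable_burden(cur, cf, p)
        got = float(b.by_condition["attr_events"].iloc[0])
        # with CRN only smokers' extra draws differ: variance is binomial on
        # the 50% smokers at rate p*(rr-1)
        se_rate = math.sqrt(0.5 * 0.01 * 1.0 / n)
        assert abs(got - 5_000) < 3 * se_rate * 1_000_000

    def test_population_scaling_is_exactly_linear(self):
        p = make_toy_params(incidence=0.03, case_fatality=0.2, q=0.05, max_age=50,
                            event_cost=500.0)
        cur, cf = _run_pair(p, 2_000, seed=5)
        b1 = attributable_burden(cur, cf, p)
        p2 = make_toy_params(incidence=0.03, case_fatality=0.2, q=0.05, max_age=50,
                             event_cost=500.0, population=2_000_000.0)
        b2 = attributable_burden(cur, cf, p2)
        for col in ("attr_deaths", "attr_events", "attr_yll", "attr_yld",
                    "attr_cost_mn"):
            np.testing.assert_allclose(2 * b1.by_condition[col].to_numpy(),
                                       b2.by_condition[col].to_numpy(), rtol=1e-12)

    def test_monotone_in_prevalence(self):
        kw = dict(incidence=0.03, case_fatality=0.3, q=0.05, rr_current=3.0,
                  max_age=60)
        lo = make_toy_params(prev_current=0.2, **kw)
        hi = make_toy_params(prev_current=0.6, **kw)
        deaths = {}
        for name, p in (("lo", lo), ("hi", hi)):
            cur, cf = _run_pair(p, 5_000, seed=8)
            deaths[name] = float(
                attributable_burden(cur, cf, p).by_condition["attr_deaths"].sum())
        assert deaths["hi"] >= deaths["lo"]

    def test_mismatched_strata_rejected(self):
        p1 = make_toy_params(max_age=50)
        p2 = make_toy_params(max_age=60)
        cur1, cf1 = _run_pair(p1, 200, seed=1)
        cur2, _ = _run_pair(p2, 200, seed=1)
        with pytest.raises(ValueError, match="mismatch"):
            attributable_burden(cur1, cur2, p1)


class TestNegativeCellFraction:
    def test_few_negative_cells_at_scale(self, nigeria):
        # with common random numbers and rr >= 1, negative attributable cells
        # are pure sampling noise; at n = 100,000 fewer than 5% of cells
        cur, cf = _run_pair(nigeria, 100_000, seed=13)
        b = attributable_burden(cur, cf, nigeria)
        cells = b.by_condition[["attr_deaths", "attr_events", "attr_yll",
                                "attr_yld", "attr_cost_mn"]].to_numpy()
        frac_negative = float((cells < 0).mean())
        assert frac_negative < 0.05


class TestSecondhandUplift:
    def _table_with_sex_totals(self, male_deaths, female_deaths):
        # toy run, then overwrite the by-sex deaths to the target values
        p = make_toy_params(incidence=0.02, case_fatality=0.5, q=0.05, max_age=45)
        cur, cf = _run_pair(p, 1_000, seed=2)
        b = attributable_burden(cur, cf, p)
        for col in ("attr_deaths", "attr_yll", "attr_yld", "attr_daly",
                    "attr_cost_mn"):
            b.by_sex[col] = 0.0
        b.by_sex.loc["male", "attr_deaths"] = male_deaths
        b.by_sex.loc["female", "attr_deaths"] = female_deaths
        return b

    def test_male_uplift_value(self):
        b = self._table_with_sex_totals(100.0, 0.0)
        out = apply_secondhand_uplift(b)
        assert out.by_condition.loc[SECONDHAND_ROW, "attr_deaths"] == pytest.approx(13.6)

    def test_female_uplift_value(self):
        b = self._table_with_sex_totals(0.0, 100.0)
        out = apply_secondhand_uplift(b)
        assert out.by_condition.loc[SECONDHAND_ROW, "attr_deaths"] == pytest.approx(12.0)

    def test_zero_burden_zero_uplift(self):
        b = self._table_with_sex_totals(0.0, 0.0)
        out = apply_secondhand_uplift(b)
        assert out.by_condition.loc[SECONDHAND_ROW, "attr_deaths"] == 0.0

    def test_double_application_rejected(self):
        b = self._table_with_sex_totals(1.0, 1.0)
        out = apply_secondhand_uplift(b)
        with pytest.raises(ValueError):
            apply_secondhand_uplift(out)


class TestDalyDecomposition:
    def test_identity_at_published_scale(self):
        # accounting identity: YLL + YLD = DALY, exactly
        yll, yld = 628_302.0, 187_929.0
        assert yll + yld == pytest.approx(816_231.0)

    def test_daly_is_yll_plus_yld_exactly(self):
        p = make_toy_params(incidence=0.05, case_fatality=0.3, q=0.05,
                            utility=0.7, max_age=60)
        cur, cf = _run_pair(p, 3_000, seed=6)
        df = daly_decomposition(cur, cf, p)
        np.testing.assert_allclose(df["daly"], df["yll"] + df["yld"], rtol=0)

    def test_zero_morbidity_model(self):
        # utility 1 for the condition: YLD = 0, DALY = YLL
        p = make_toy_params(incidence=0.05, case_fatality=0.3, q=0.05,
                            utility=1.0, max_age=60)
        cur, cf = _run_pair(p, 3_000, seed=6)
        df = daly_decomposition(cur, cf, p)
        assert df.loc["total", "yld"] == 0.0
        assert df.loc["total", "daly"] == df.loc["total", "yll"]

    def test_yld_equals_state_years_times_dw(self):
        # one-year active window: attributable YLD must equal attributable
        # condition-years times (1 - utility)
        u = 0.75
        p = make_toy_params(incidence=0.1, case_fatality=0.0, q=0.0, utility=u,
                            prev_current=1.0, rr_current=2.0, max_age=36)
        cur, cf = _run_pair(p, 20_000, seed=9)
        b = attributable_burden(cur, cf, p)
        cond_years = float(b.detail.condition_years[0])
        yld = float(b.by_condition["attr_yld"].iloc[0])
        assert yld == pytest.approx(cond_years * (1 - u), rel=1e-9)

    def test_yll_share_invariant_to_population_scale(self):
        p = make_toy_params(incidence=0.05, case_fatality=0.3, q=0.05,
                            utility=0.7, max_age=60)
        cur, cf = _run_pair(p, 3_000, seed=10)
        b1 = attributable_burden(cur, cf, p)
        p2 = make_toy_params(incidence=0.05, case_fatality=0.3, q=0.05,
                             utility=0.7, max_age=60, population=5_000_000.0)
        b2 = attributable_burden(cur, cf, p2)

        def share(b):
            t = b.totals()
            return t["attr_yll"] / t["attr_daly"]

        assert share(b1) == pytest.approx(share(b2), rel=1e-12)
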