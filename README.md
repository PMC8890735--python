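# smokesim

Individual-level Monte Carlo model of the health and economic burden of
smoking, with a closed-form tobacco tax-policy layer.

The engine follows hypothetical cohorts through annual cycles of disease
events, chronic-state progression and death, with event risks equal to
baseline never-smoker risks times status-specific relative risks. Burden
attributable to smoking is the difference between the observed-prevalence
population and a counterfactual in which smokers never existed, simulated
under common random numbers and scaled to national population strata, with a
fixed secondhand-smoke uplift. On top sit:

- **DALY accounting** — YLL from residual life expectancy at death, YLD from
  disability-weighted condition-years; no discounting or age-weighting.
- **Costing** — direct medical costs from a unit-cost catalog (event,
  first-year, follow-up and COPD-severity-tier costs); indirect costs from a
  human-capital value of statistical life, wage-valued disability loss, and
  opportunity-cost-valued informal caregiving.
- **Tax policy** — prevalence response to price via own-price elasticity
  (optionally blended with cross-price substitution toward illicit products),
  tax-revenue change under full pass-through, the illicit-retention share,
  and a 10-year scenario runner that moves the implied quitters from current
  to former smoker status and accumulates averted burden and avoided costs.

A packaged Nigeria parameter bundle embeds the published population and
smoking-prevalence strata, the direct-cost catalog and the economic
parameters; the never-published epidemiological inputs (baseline rates,
relative risks, utilities, wages, life table) are deterministic synthetic
stand-ins, flagged as such in the bundle. Randomized synthetic bundles for
testing come from `smokesim.synthetic_data.generate_bundle`.

## CLI

```bash
# attributable burden + economic burden for the packaged Nigeria bundle
smokesim burden --n 100000 --seed 1 --out results/burden

# 10-year price-increase scenarios (25/50/75% by default)
smokesim policy --price-increase 50 --n 100000 --seed 1 --out results/policy

# use your own parameter bundle (directory of config.yaml + CSV tables;
# see smokesim.param_model docstrings for the layout)
smokesim burden --params my_bundle/ --n 100000 --seed 1 --out results/burden
```

Outputs are CSV tables (burden by condition and by sex, economic-burden
components with derived percentage indicators, scenario columns) plus a JSON
summary and a run manifest recording seed, cohort size and a parameter-set
content hash. Reruns with an equal manifest are byte-identical.

Python API: `smokesim.nigeria_fixture()`, `smokesim.simulate_cohort`,
`smokesim.attributable_burden`, `smokesim.economic_burden`,
`smokesim.run_scenario`, and the closed-form operations
(`post_policy_prevalence`, `revenue_change`, `illicit_retention`, `vsl`).

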