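# htnsim

Individual-based microsimulation of hypertension screening and treatment
policies in adult populations of sub-Saharan Africa, with cardiovascular
disease (CVD) outcomes, health-system costs, DALYs and cross-policy
cost-effectiveness analysis.

The package is for health-economic modellers and epidemiologists who want to
compare delivery policies for hypertension care — not to forecast any single
country, but to ask *which policy is cost-effective, where, and at what
willingness-to-pay* across a wide band of plausible settings.

## The model in brief

Each individual's systolic blood pressure (SBP) evolves over the life course
in 3-month steps; measured SBP adds noise, and a person is diagnosed when
measured SBP ≥ 140 mmHg on two consecutive occasions, ≥ 160 mmHg once, or
treatment starts. Incident ischemic heart disease and stroke follow
per-quarter hazards

    h = h₀(age, sex) · scalar · RR_SBP(max(SBP, 115)) · RR_HIV · RR_prior ,

with RR_SBP log-linear in SBP above a 115 mmHg floor and an age-attenuated
slope. Three delivery policies are compared:

* **SOC** — standard of care (clinic-based measurement, quarterly visits);
* **CCC** — hypertension care integrated in HIV primary-care clinics
  (measurement at ART visits, 6-monthly visits while controlled, better
  retention);
* **CHW** — CCC plus annual community-health-worker screening of adults ≥ 40.

Costs (screening $3/person, visits $10/$5 by control status, drugs
$1.5–3/quarter, emergency CVD care) and DALYs (YLD from disability weights,
YLL to age 80) are discounted at 3% to 2024 over a 50-year horizon and
scaled to 10 million adults. Policies are compared by dominance-pruned
incremental cost-effectiveness ratios (ICERs) and by net DALYs averted,

    net DALYs averted = DALYs averted − incremental cost / λ ,

with the cost-effective policy maximizing net DALYs averted at threshold λ
(primary λ = $500/DALY). Uncertainty is handled by *setting-scenarios*:
independently sampled parameter vectors (SBP distributions, care-cascade
propensities, HIV burden, CVD rates, costs) whose standard-of-care output is
calibrated to published care-cascade envelopes. See `docs/methods.md` for
the full model description.

## Worked example

```python
from htnsim import RunConfig, run_experiment, report

cfg = RunConfig(n_scenarios=8, n_individuals=8000, master_seed=11)
bundle = run_experiment(cfg)
tables = report(bundle)
print(tables["cea"][["policy", "dalys_averted_thousands",
                     "incremental_cost_millions", "net_dalys_thousands"]])
```

prints (mean with empirical 90% range across the 8 scenarios):

```
policy dalys_averted_thousands incremental_cost_millions    net_dalys_thousands
   SOC              0 (0 to 0)                0 (0 to 0)             0 (0 to 0)
   CCC    15.3 (-2.78 to 31.8)       7.94 (5.04 to 10.6) -0.575 (-15.4 to 15.1)
   CHW    16.2 (-1.96 to 37.7)       27.5 (26.6 to 28.7)   -38.7 (-55.6 to -18)
```

Per 10 million adults per year, integrated chronic-care clinics (CCC) avert
a mean 15,300 DALYs at $7.9M incremental cost; adding CHW screening averts
slightly more DALYs in this small demo batch but at $27.5M, so at the $500
per DALY threshold its net DALYs averted are negative (the cost, valued in
DALYs forgone elsewhere, exceeds the health gain). The cascade summary from
the same run shows why the policies differ — hypertension control among
adults 45–64 rises from 7% (SOC) to 19% (CCC) to 41% (CHW):

```
           metric                       SOC                    CCC                    CHW
controlled_45-64  0.0708 (0.0444 to 0.0988)   0.19 (0.128 to 0.293)  0.413 (0.351 to 0.489)
```

Batches this small are demos; analysis-grade runs use more scenarios and
n = 20,000+ individuals (see `RunConfig`). A command-line interface wraps
the same pipeline:

```bash
htnsim sample-scenarios --n 50 --seed 1 --out scenarios.jsonl
htnsim simulate --n-scenarios 50 --seed 1 --out results/
htnsim cea --results results/ --lam 500
htnsim report --results results/
```

## Layout

```
src/htnsim/scenarios.py    setting-scenario model, sampler, calibration envelopes
src/htnsim/population.py   structure-of-arrays population, demography, SBP dynamics
src/htnsim/cascade.py      screening, diagnosis rule, visits, retention, policies
src/htnsim/cvd.py          CVD hazards, severity, acute outcomes, sequelae
src/htnsim/health_econ.py  cost components, discounting, DALY ledgers
src/htnsim/cea.py          dominance, ICERs, net DALYs, sweeps, stratified tables
src/htnsim/runner.py       scenario x policy orchestration, common random numbers
src/htnsim/cli.py          command-line interface
src/htnsim/data/default_ranges.yaml   shipped sampling configuration
```
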