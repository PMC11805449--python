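# Methods

`htnsim` is an individual-based (microsimulation) model of hypertension and
cardiovascular disease (CVD) in adult populations of sub-Saharan Africa, with
a health-system cost and DALY ledger and a cross-policy cost-effectiveness
layer. This note records the model, its assumptions, the default parameter
choices, and what the synthetic setting-scenarios do and do not emulate.

## Model overview

Each simulated individual carries: age, sex, true pre-treatment systolic
blood pressure (SBP), a reduced HIV state (negative / on ART / untreated), the
care-cascade state (two most recent measured SBPs, diagnosis, engagement in
care, drugs prescribed 0–3, quarterly adherence, next scheduled visit),
CVD history (prior ischemic heart disease or stroke, chronic disability
weight, chronic excess mortality), and cost/DALY ledgers. State updates in
3-month steps from 1989; policies diverge at the start of 2024 and run for a
50-year horizon.

Fixed within-quarter order: entry of 15-year-olds (replacing last quarter's
deaths, plus net population growth) → SBP drift → HIV incidence → care
cascade (retention, annual community screening where applicable, scheduled
clinic visits, background clinic contacts, adherence) → incident CVD events
with acute outcomes → background/HIV/chronic-CVD death resolution → ledger
accrual. Events are drawn before deaths are resolved so event rates are not
biased by within-quarter mortality.

### Blood pressure

Pre-treatment SBP = a population mean profile over age (piecewise-linear
through decade midpoints, per sex) + a setting-level shift and tilt + a
between-person normal offset at entry (SD ≈ 12 mmHg) + a within-person
random walk (SD ≈ 0.35 mmHg/quarter) + a secular trend of 0, 0.5 or
1 mmHg per decade applied after 2015. While engaged, treated and adherent,
true SBP = pre-treatment SBP − (drugs × per-drug reduction), floored at
90 mmHg. Hypertension is true current-or-pre-treatment SBP ≥ 140 mmHg;
control is true SBP < 140 among hypertensives.

### Care cascade and policies

Measurement adds Gaussian noise (SD 6–10 mmHg). Diagnosis: measured SBP
≥ 140 on the two most recent consecutive measurement occasions (regardless
of calendar gap), ≥ 160 once, or treatment initiation. At a visit with a
diagnosed patient measuring ≥ 140, treatment initiates with a sampled
probability, or intensifies deterministically by one drug (cap three).
Retention is a two-state per-quarter disengage/re-engage process, with a
sampled fraction of the population permanently non-engaging.

* **SOC** — clinic-based measurement only, at background contact rates;
  hypertension visits every quarter; weaker retention.
* **CCC** — hypertension care integrated within HIV primary-care clinics:
  BP measured at ART visits, 6-monthly visits while controlled, chronic-care
  retention. Clinic contact rates are otherwise unchanged.
* **CHW** — CCC plus an annual household screening round for adults ≥ 40
  (≥ 50 in sensitivity mode): screen-positives link to a confirmatory clinic
  visit next quarter with a sampled probability. The screening measurement
  counts as a diagnosis occasion.

### Cardiovascular disease

Per-quarter IHD and stroke hazards: Gompertz-in-age baseline (slope
0.095/yr) per type and sex × a setting base-rate scalar × a log-linear SBP
relative risk above a 115 mmHg floor (RR 0.80 per 10 mmHg lower SBP at age
50, attenuating linearly to 0.90 at age 80 — a configurable default, not an
estimate from any specific trial) × an HIV multiplier × a prior-event
multiplier (2.5). Severity is mild/moderate/severe; moderate/severe IHD
represents myocardial infarction, mild events are asymptomatic and never
seek care. Moderate/severe events seek emergency care with setting
probability {0.2, 0.4, 0.8}; sought care is effective with probability
{0.125, 0.25, 0.5}; effective care reduces acute mortality by 30%.
Survivors carry the maximum chronic disability weight over their events and
a severity-specific chronic excess mortality. Reported incidence counts
moderate/severe events only.

### Demography and the HIV layer

The initial adult (15–90) pyramid decays exponentially with age
(rate 0.045/yr). Background mortality is Gompertz per sex
(a·exp(0.09·(age−50)); a = 0.0028 women, 0.0038 men). Deaths are replaced
by 15-year-old entrants each quarter, plus a Poisson inflow giving ~1%/yr
net adult population growth — a deliberate simplification of the region's
growing populations that keeps all-cause adult mortality near 1.4 per 100
person-years. HIV prevalence (15–49) is sampled log-uniformly (3–40%) and
held roughly stationary by a prevalence-proportional incidence; the layer
carries an ART split, excess mortality by treatment state, and a CVD hazard
multiplier. There is no transmission network, CD4 or viral-load dynamics.

### Costs and DALYs

Health-system perspective, 2024 USD, four components: screening ($3 per
person screened), clinic (visits: $10 uncontrolled / $5 controlled;
integrated visits for people on ART cost $0 or 50% of standalone, split
across scenarios; plus a fixed annual training cost of $500 per 10,000
adults under CCC/CHW), drugs ($1.5/quarter for lines 1–2, $3 for line 3),
and emergency CVD care (by type and severity; ineffective care costs a
sampled fraction {25%, 50%, 100%} of effective care). Costs and DALYs are
discounted at 3% (5% in sensitivity) to 2024. YLD = chronic disability
weight × time lived; YLL accrues at death before age 80 for the remaining
years to 80 as a discounted continuous stream — for all causes of death, so
that lives extended by treatment are netted correctly in incremental
comparisons. No person-time at or beyond age 80 accrues DALYs.

### Cost-effectiveness

Per scenario, policies are compared by DALYs averted versus SOC and
discounted cost, both rescaled linearly in person-time to 10 million adults
and annualized (divided by the 50-year horizon). Strictly dominated policies
are removed; ICERs are computed along the effectiveness-ordered chain with
extended dominance applied (an addition beyond strict dominance, standard in
CEA practice; switchable off). The cost-effective policy at threshold λ
maximizes net DALYs averted = DALYs averted − incremental cost/λ (primary
λ = $500/DALY; sweep $100–$1,000 in $50 steps). Pooled ICERs divide mean
incremental cost by mean incremental DALYs averted across scenarios.
"90% range" is always the empirical 5th–95th percentile. Cost-sensitivity
rows (component multipliers 0.25–4×) re-scale the component ledgers rather
than re-running the simulation, exploiting linearity of costs in unit costs.

## Setting-scenarios: what the generator emulates

A setting-scenario is one independently sampled parameter vector standing in
for a (sub)national setting plus parameter uncertainty. All ranges live in
`src/htnsim/data/default_ranges.yaml`; continuous parameters sample
uniformly (log-uniformly for HIV prevalence), categorical parameters
uniformly over their stated choice sets. Scenario `k` depends only on
`(master_seed, k)`, so batches are stable under changing batch size.

The defaults were calibrated once, by analytic design followed by short
standard-of-care runs, so that SOC output for 2013–2016 falls inside the
published calibration envelopes for the 45–64 band (prevalence 30–54%,
diagnosed 18–40%, treated 3–12%, controlled 1–7.1%): with the shipped
ranges, roughly 85% of scenarios land inside all four simultaneously. The
generator emulates between-setting heterogeneity in epidemiology, care and
costs; it does not emulate within-country spatial structure, time-varying
care-seeking secular trends, co-morbidity (diabetes, kidney disease), or
correlated parameters (all fields sample independently). Passing tests
therefore show internal consistency and calibration of the stand-in
parameterization, not fidelity to any particular country's surveillance
data.

## Numerical choices

* Population state is a structure-of-arrays over numpy vectors; a quarter
  updates in a few milliseconds at n = 20,000, which makes the
  200-scenario calibration and 50-scenario policy-ordering test batches
  affordable on one CPU.
* Default problem sizes: 20,000 individuals per scenario (the experiment
  runner accepts any n; per-capita rates are size-invariant up to Monte
  Carlo error), 50 scenarios per batch in the test suite, full 1989–2074
  horizon.
* RNG streams: numpy `default_rng` seeded by `[scenario_seed, k]` with
  fixed stream indices for initialization, burn-in and each policy, so
  policies share a byte-identical burn-in state (common random numbers)
  and diverge only after 2023.
* The burn-in runs the full standard-of-care dynamics from 1989 (no
  reduced-fidelity shortcut): it is cheap and avoids a second code path.
* Ties in cost-effectiveness selection break toward lower cost; zero
  incremental effectiveness yields an undefined, flagged ICER.
* Degenerate inputs: empty age bands yield NaN metrics flagged undefined
  (never silent zeros); zero person-time rates likewise.

## Known limitations

* The care-cascade, CVD risk, severity, mortality and acute-cost parameters
  are stand-in defaults calibrated to published envelope targets, not
  estimates from primary data; absolute DALY and cost levels are therefore
  indicative, and the package's value is in the policy contrasts.
* Policy effects on CVD here are smaller than the strongest published
  trial-calibrated models; orderings (CHW > CCC > SOC benefit) are robust
  but relative-risk magnitudes are conservative.
* Only IHD and stroke are modeled; hypertensive heart disease and chronic
  kidney disease are excluded, understating treatment benefit.
* No societal-perspective costs (transport, productivity), no diastolic
  pressure, no fixed-dose combination therapy.
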