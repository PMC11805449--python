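"""Orchestration: scenario batches x policies over the full horizon.

Each scenario runs one standard-of-care burn-in from 1989 to the end of
2023 to establish a realistic population state; every policy then continues
from an identical copy of that state (common random numbers for the
pre-policy history) with its own RNG substream, so cross-policy differences
are not confounded by burn-in noise.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cascade, cvd as cvd_mod, health_econ
from .cascade import PolicySpec
from .cea import PolicyResult, icer, net_dalys_averted, rank_and_dominate, summarize_across_scenarios, threshold_sweep
from .health_econ import EconLedger, aggregate_costs
from .history import QuarterlyHistory
from .population import Population, init_population, quarter_of_year, step_quarter
from .scenarios import SettingScenario, load_default_ranges, sample_scenarios

__all__ = ["RunConfig", "ScenarioRun", "ResultBundle", "run_scenario", "run_experiment", "report", "run_soc_calibration"]

log = logging.getLogger("htnsim")

_POLICY_FACTORY = {
    "SOC": lambda cfg: PolicySpec.soc(),
    "CCC": lambda cfg: PolicySpec.ccc(),
    "CHW": lambda cfg: PolicySpec.chw(min_age=float(cfg.chw_min_age)),
}


@dataclass
class RunConfig:
    """Configuration of a simulation experiment."""

    n_scenarios: int = 50
    n_individuals: int = 20_000
    start_year: int = 1989
    policy_start_year: int = 2024
    horizon_years: int = 50
    discount_rate: float = 0.03
    lam: float = 500.0
    policies: tuple[str, ...] = ("SOC", "CCC", "CHW")
    chw_min_age: int = 40
    scale_to: float = 10_000_000.0
    master_seed: int = 1
    metrics_start_year: int = 2013
    ranges: dict | None = None
    output_dir: str | None = None
    run_cea: bool = True

    def __post_init__(self) -> None:
        if self.discount_rate not in (0.03, 0.05):
            raise ValueError("discount_rate must be 0.03 or 0.05")
        if self.chw_min_age not in (40, 50):
            raise ValueError("chw_min_age must be 40 or 50")
        if self.policy_start_year <= self.start_year:
            raise ValueError("policy start must come after the burn-in start")
        if self.run_cea and "SOC" not in self.policies:
            raise ValueError("CEA requires the SOC comparator among the policies")
        for p in self.policies:
            if p not in _POLICY_FACTORY:
                raise ValueError(f"unknown policy {p!r}")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ScenarioRun:
    """All outputs for one scenario: results per policy plus shared features."""

    scenario: SettingScenario
    features: dict[str, float]
    results: list[PolicyResult]
    histories: dict[str, QuarterlyHistory]
    econs: dict[str, EconLedger]
    burnin_digest: bytes


@dataclass
class ResultBundle:
    config: RunConfig
    runs: dict[int, ScenarioRun] = field(default_factory=dict)
    failed: list[int] = field(default_factory=list)

    @property
    def results(self) -> dict[int, list[PolicyResult]]:
        return {sid: run.results for sid, run in self.runs.items()}

    def features_frame(self) -> pd.DataFrame:
        rows = [{"scenario_id": sid, **run.features} for sid, run in self.runs.items()]
        return pd.DataFrame(rows)


def _summary_metrics(
    history: QuarterlyHistory,
    window: tuple[int, int],
    soc_history: QuarterlyHistory | None,
) -> dict[str, float]:
    cm = cascade.cascade_metrics(history, window, ("18+", "25-44", "45-64", "65+"))
    out = {}
    for _, row in cm.iterrows():
        out[f"{row['metric']}_{row['age_band']}"] = row["value"]
    rates = cvd_mod.cvd_rates(history, window, ("18+", "45-64"), comparator=soc_history)
    for _, row in rates.iterrows():
        out[f"{row['metric']}_{row['age_band']}"] = row["rate_per_100py"]
        if "relative_risk" in row and not pd.isna(row.get("relative_risk", np.nan)):
            out[f"rr_{row['metric']}_{row['age_band']}"] = row["relative_risk"]
    return out


def run_scenario(scenario: SettingScenario, config: RunConfig) -> ScenarioRun:
    """Simulate one scenario under every configured policy."""
    t_policy = quarter_of_year(config.policy_start_year)
    t_end = t_policy + 4 * config.horizon_years
    seed = scenario.seed

    pop = init_population(
        scenario, config.n_individuals, config.start_year,
        rng=np.random.default_rng([seed, 0]),
    )
    hist_burn = QuarterlyHistory(t_end)
    soc_policy = PolicySpec.soc()
    rng_burn = np.random.default_rng([seed, 1])
    for t in range(quarter_of_year(config.start_year), t_policy):
        step_quarter(pop, scenario, soc_policy, t, rng_burn, history=hist_burn)
    snapshot = pop.copy()
    burn_digest = snapshot.state_digest()

    # setting characteristics at the end of burn-in (Table-5-style strata)
    baseline = _summary_metrics(hist_burn, (config.policy_start_year - 3, config.policy_start_year - 1), None)
    features = {
        "mean_sbp_45_64": baseline["mean_sbp_45-64"],
        "prevalence_45_64": baseline["prevalence_45-64"],
        "diagnosed_45_64": baseline["diagnosed_45-64"],
        "treated_45_64": baseline["treated_45-64"],
        "controlled_45_64": baseline["controlled_45-64"],
        "cvd_mortality_45_64_per_100k": baseline["cvd_mortality_45-64"] * 1000.0,
        "sbp_secular_trend": scenario.sbp_secular_trend,
        "care_seek_prob": scenario.care_seek_prob,
        "care_effective_prob": scenario.care_effective_prob,
        "ineffective_cost_fraction": scenario.ineffective_cost_fraction,
        "hiv_prevalence_15_49": scenario.hiv_prevalence_15_49,
    }

    histories: dict[str, QuarterlyHistory] = {}
    econs: dict[str, EconLedger] = {}
    window = (config.policy_start_year, config.policy_start_year + config.horizon_years - 1)
    for i, name in enumerate(config.policies):
        policy = _POLICY_FACTORY[name](config)
        p = snapshot.copy()
        hist = copy.deepcopy(hist_burn)
        econ = EconLedger(
            t_policy, config.horizon_years, config.discount_rate,
            charge_training=policy.name != "SOC",
        )
        rng = np.random.default_rng([seed, 2 + i])
        tic = time.perf_counter()
        for t in range(t_policy, t_end):
            step_quarter(p, scenario, policy, t, rng, history=hist, econ=econ)
        log.info(
            "scenario %d policy %s simulated in %.1fs",
            scenario.scenario_id, name, time.perf_counter() - tic,
        )
        histories[name] = hist
        econs[name] = econ

    soc_hist = histories.get("SOC")
    results = []
    for name in config.policies:
        econ = econs[name]
        agg = aggregate_costs(econ, config.scale_to)
        mean_adults = econ.person_years_15plus.sum() / config.horizon_years
        scale = config.scale_to / mean_adults
        comps = {
            c: agg[c] / config.horizon_years for c in EconLedger.components
        }
        dalys = econ.dalys.total * scale / config.horizon_years
        metrics = _summary_metrics(histories[name], window, soc_hist if name != "SOC" else None)
        results.append(
            PolicyResult(
                scenario_id=scenario.scenario_id,
                policy=name,
                component_costs=comps,
                dalys=dalys,
                metrics=metrics,
            )
        )
    soc_res = next(r for r in results if r.policy == "SOC")
    for r in results:
        r.dalys_averted_vs_soc = soc_res.dalys - r.dalys

    return ScenarioRun(
        scenario=scenario,
        features=features,
        results=results,
        histories=histories,
        econs=econs,
        burnin_digest=burn_digest,
    )


def run_experiment(config: RunConfig) -> ResultBundle:
    """Run the full scenario batch; failures are flagged, not fatal."""
    ranges = config.ranges if config.ranges is not None else load_default_ranges()
    scenarios = sample_scenarios(config.n_scenarios, config.master_seed, ranges)
    bundle = ResultBundle(config=config)
    for sc in scenarios:
        try:
            bundle.runs[sc.scenario_id] = run_scenario(sc, config)
        except Exception:  # noqa: BLE001 - batch continues, failure flagged
            log.exception("scenario %d failed; continuing", sc.scenario_id)
            bundle.failed.append(sc.scenario_id)
    if config.output_dir:
        write_outputs(bundle, Path(config.output_dir))
    return bundle


def run_soc_calibration(
    scenario: SettingScenario, n_individuals: int, end_year: int = 2016
) -> QuarterlyHistory:
    """Standard-of-care run from 1989 through ``end_year`` (calibration use)."""
    t_end = quarter_of_year(end_year + 1)
    pop = init_population(
        scenario, n_individuals, rng=np.random.default_rng([scenario.seed, 0])
    )
    hist = QuarterlyHistory(t_end)
    policy = PolicySpec.soc()
    rng = np.random.default_rng([scenario.seed, 1])
    for t in range(0, t_end):
        step_quarter(pop, scenario, policy, t, rng, history=hist)
    return hist


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def _fmt_mean_range(values) -> str:
    mean, (lo, hi) = summarize_across_scenarios(values)
    return f"{mean:.3g} ({lo:.3g} to {hi:.3g})"


def results_table(bundle: ResultBundle) -> pd.DataFrame:
    """Tidy per-scenario-per-policy results (costs annual USD, DALYs/yr)."""
    rows = []
    for sid, rs in bundle.results.items():
        for r in rs:
            row = {
                "scenario_id": sid,
                "policy": r.policy,
                "dalys": r.dalys,
                "dalys_averted_vs_soc": r.dalys_averted_vs_soc,
                "total_cost": r.total_cost,
            }
            row.update({f"cost_{c}": v for c, v in r.component_costs.items()})
            row.update(r.metrics)
            rows.append(row)
    return pd.DataFrame(rows).sort_values(["scenario_id", "policy"]).reset_index(drop=True)


def report(bundle: ResultBundle) -> dict[str, pd.DataFrame]:
    """Summary tables: care cascade, CVD, cost-effectiveness, sweep."""
    if not bundle.runs:
        raise ValueError("empty result bundle")
    df = results_table(bundle)
    policies = list(bundle.config.policies)

    cascade_rows = []
    for metric in ("prevalence_45-64", "diagnosed_45-64", "treated_45-64",
                   "controlled_45-64", "overdiagnosis_45-64", "mean_sbp_45-64",
                   "cvd_mortality_18+", "all_cause_mortality_18+"):
        if metric not in df.columns:
            continue
        row = {"metric": metric}
        for p in policies:
            row[p] = _fmt_mean_range(df.loc[df.policy == p, metric].dropna())
        cascade_rows.append(row)
    outcomes = pd.DataFrame(cascade_rows)

    lam = bundle.config.lam
    cea_rows = []
    soc_cost = {sid: next(r for r in rs if r.policy == "SOC").total_cost
                for sid, rs in bundle.results.items()}
    for p in policies:
        sub = df[df.policy == p]
        averted = sub["dalys_averted_vs_soc"].to_numpy()
        inc_cost = np.array(
            [row.total_cost - soc_cost[row.scenario_id] for row in sub.itertuples()]
        )
        entry = {
            "policy": p,
            "dalys_averted_thousands": _fmt_mean_range(averted / 1e3),
            "total_cost_millions": _fmt_mean_range(sub["total_cost"] / 1e6),
            "incremental_cost_millions": _fmt_mean_range(inc_cost / 1e6),
        }
        for c in EconLedger.components:
            entry[f"cost_{c}_millions"] = _fmt_mean_range(sub[f"cost_{c}"] / 1e6)
        entry["net_dalys_thousands"] = _fmt_mean_range(
            (averted - inc_cost / lam) / 1e3
        )
        cea_rows.append(entry)
    cea_table = pd.DataFrame(cea_rows)

    # pooled ICERs from mean incremental costs / mean incremental DALYs
    pooled = []
    for p in policies:
        sub = df[df.policy == p]
        pooled.append(
            PolicyResult.from_components(
                scenario_id=-1, policy=p,
                dalys_averted_vs_soc=float(sub["dalys_averted_vs_soc"].mean()),
                clinic=float(sub["total_cost"].mean()),
            )
        )
    pooled_icers = icer(rank_and_dominate(pooled))

    sweep = threshold_sweep(bundle.results)

    # proportion cost-effective by baseline setting characteristics
    from .cea import stratified_ce_table

    features = bundle.features_frame()
    strata = {
        "prevalence_45_64": [
            ("<35%", 0.0, 0.35), ("35 to <43%", 0.35, 0.43),
            ("43 to <50%", 0.43, 0.50), (">=50%", 0.50, 1.01),
        ],
        "controlled_45_64": [
            ("<2%", 0.0, 0.02), ("2 to <4%", 0.02, 0.04),
            ("4 to <6%", 0.04, 0.06), (">=6%", 0.06, 1.01),
        ],
        "hiv_prevalence_15_49": [
            ("<5%", 0.0, 0.05), ("5 to <10%", 0.05, 0.10),
            ("10 to <15%", 0.10, 0.15), (">=15%", 0.15, 1.01),
        ],
        "sbp_secular_trend": [
            ("0 mmHg", -0.01, 0.25), ("0.5 mmHg", 0.25, 0.75), ("1 mmHg", 0.75, 1.25),
        ],
    }
    stratified = stratified_ce_table(features, bundle.results, strata, lam=lam)

    return {
        "outcomes": outcomes,
        "cea": cea_table,
        "pooled_icers": pooled_icers,
        "sweep": sweep,
        "stratified": stratified,
    }


def write_outputs(bundle: ResultBundle, outdir: Path) -> None:
    """Write the result CSVs and a reproducibility manifest."""
    outdir.mkdir(parents=True, exist_ok=True)
    results_table(bundle).to_csv(outdir / "policy_results.csv", index=False, float_format="%.10g")
    bundle.features_frame().to_csv(outdir / "scenario_features.csv", index=False, float_format="%.10g")
    if bundle.config.run_cea and bundle.runs:
        sweep = threshold_sweep(bundle.results)
        sweep.to_csv(outdir / "threshold_sweep.csv", index=False, float_format="%.10g")
    manifest = {
        "config": {
            k: v
            for k, v in asdict(bundle.config).items()
            if k not in ("ranges", "output_dir")
        },
        "config_hash": bundle.config.config_hash(),
        "scenario_seeds": {sid: run.scenario.seed for sid, run in bundle.runs.items()},
        "failed_scenarios": bundle.failed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
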