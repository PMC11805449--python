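"""Cross-policy cost-effectiveness: dominance, ICERs, net DALYs, sweeps.

The decision framework follows standard practice: policies are ranked by
effectiveness (DALYs averted versus standard of care), strictly dominated
policies (less effective and at least as costly) are removed, incremental
cost-effectiveness ratios (ICERs) are computed against the next most
effective non-dominated alternative with extended dominance applied along
the chain, and the cost-effective policy at a willingness-to-pay threshold
``lambda`` is the one maximizing net DALYs averted:

    net DALYs averted = DALYs averted - incremental cost / lambda

Net-benefit maximization and walking the ICER chain against ``lambda`` are
equivalent decision rules; both are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scenarios import COST_COMPONENTS

__all__ = [
    "PolicyResult",
    "rank_and_dominate",
    "icer",
    "net_dalys_averted",
    "select_cost_effective",
    "select_by_icer_chain",
    "threshold_sweep",
    "stratified_ce_table",
    "summarize_across_scenarios",
    "apply_cost_multipliers",
]


@dataclass
class PolicyResult:
    """Discounted outcomes of one policy in one setting-scenario.

    Costs are average annual discounted USD scaled to the target population;
    ``dalys_averted_vs_soc`` is the average annual discounted DALY difference
    versus standard of care (0 for SOC itself).
    """

    scenario_id: int
    policy: str
    component_costs: dict[str, float]
    dalys: float
    dalys_averted_vs_soc: float = 0.0
    metrics: dict[str, float] = field(default_factory=dict)

    @property
    def total_cost(self) -> float:
        return float(sum(self.component_costs.values()))

    @staticmethod
    def from_components(
        scenario_id: int,
        policy: str,
        dalys_averted_vs_soc: float = 0.0,
        dalys: float = 0.0,
        **components: float,
    ) -> "PolicyResult":
        unknown = set(components) - set(COST_COMPONENTS)
        if unknown:
            raise ValueError(f"unknown cost components: {sorted(unknown)}")
        return PolicyResult(
            scenario_id=scenario_id,
            policy=policy,
            component_costs=dict(components),
            dalys=dalys,
            dalys_averted_vs_soc=dalys_averted_vs_soc,
        )


def _soc_cost(results: list[PolicyResult]) -> float:
    for r in results:
        if r.policy == "SOC":
            return r.total_cost
    raise ValueError("results must include the SOC comparator")


def rank_and_dominate(results: list[PolicyResult]) -> list[PolicyResult]:
    """Order policies by effectiveness and drop strictly dominated ones.

    A policy is strictly dominated when some alternative is both more
    effective and less costly.  Effectiveness ties are broken toward lower
    cost; weakly dominated policies surface as undefined or unfavourable
    ICERs in the chain (and fall to extended dominance there).
    """
    if len(results) < 2:
        raise ValueError("need at least two policies")
    keep = []
    for r in results:
        dominated = any(
            o.dalys_averted_vs_soc > r.dalys_averted_vs_soc
            and o.total_cost < r.total_cost
            for o in results
            if o is not r
        )
        if not dominated:
            keep.append(r)
    return sorted(keep, key=lambda r: (r.dalys_averted_vs_soc, r.total_cost))


def icer(
    ordered: list[PolicyResult], extended_dominance: bool = True
) -> pd.DataFrame:
    """ICERs along the effectiveness-ordered non-dominated chain.

    Each ICER divides the incremental cost by the incremental DALYs averted
    versus the next most effective retained alternative; the least effective
    policy anchors the chain with no ICER.  With ``extended_dominance``,
    policies whose ICER exceeds that of a more effective alternative are
    removed and the chain recomputed.  Zero incremental effectiveness yields
    an undefined (NaN) ICER, flagged.
    """
    chain = list(ordered)
    while True:
        rows = []
        for i, r in enumerate(chain):
            if i == 0:
                rows.append((r, np.nan, True))
                continue
            prev = chain[i - 1]
            d_eff = r.dalys_averted_vs_soc - prev.dalys_averted_vs_soc
            d_cost = r.total_cost - prev.total_cost
            rows.append((r, d_cost / d_eff if d_eff != 0 else np.nan, d_eff != 0))
        if not extended_dominance or len(chain) <= 2:
            break
        # extended dominance: ICERs must be increasing along the chain
        bad = None
        for i in range(2, len(chain)):
            if rows[i][1] < rows[i - 1][1]:
                bad = i - 1
                break
        if bad is None:
            break
        del chain[bad]
    return pd.DataFrame(
        {
            "policy": [r.policy for r, _, _ in rows],
            "dalys_averted": [r.dalys_averted_vs_soc for r, _, _ in rows],
            "total_cost": [r.total_cost for r, _, _ in rows],
            "icer": [v for _, v, _ in rows],
            "icer_defined": [d for _, _, d in rows],
        }
    )


def net_dalys_averted(
    result: PolicyResult, soc_result: PolicyResult, lam: float
) -> float:
    """Net DALYs averted versus SOC at threshold ``lam`` (USD per DALY).

    DALYs averted minus incremental cost valued in DALYs at the threshold;
    the cost-effective policy maximizes this.
    """
    if lam <= 0:
        raise ValueError("cost-effectiveness threshold must be > 0")
    inc_cost = result.total_cost - soc_result.total_cost
    return result.dalys_averted_vs_soc - inc_cost / lam


def select_cost_effective(results: list[PolicyResult], lam: float) -> PolicyResult:
    """The policy maximizing net DALYs averted (ties toward lower cost)."""
    soc = next(r for r in results if r.policy == "SOC")
    return max(
        results,
        key=lambda r: (net_dalys_averted(r, soc, lam), -r.total_cost),
    )


def select_by_icer_chain(results: list[PolicyResult], lam: float) -> PolicyResult:
    """Decision by walking the extended-dominance ICER chain against ``lam``.

    Accept each more effective alternative while its ICER is at or below the
    threshold; equivalent to net-benefit maximization.
    """
    ordered = rank_and_dominate(results)
    table = icer(ordered, extended_dominance=True)
    chosen = table.iloc[0]["policy"]
    for _, row in table.iloc[1:].iterrows():
        if row["icer_defined"] and row["icer"] <= lam:
            chosen = row["policy"]
        else:
            break
    return next(r for r in results if r.policy == chosen)


def threshold_sweep(
    all_results: dict[int, list[PolicyResult]],
    lambda_grid: np.ndarray | list[float] | None = None,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability across thresholds.

    For each threshold, the fraction of setting-scenarios in which each
    policy maximizes net DALYs averted (fractions sum to 1), plus the median
    and 90% range of net DALYs averted per policy.
    """
    if lambda_grid is None:
        lambda_grid = np.arange(100, 1001, 50)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    if not all_results:
        raise ValueError("no scenario results supplied")
    policies = sorted({r.policy for rs in all_results.values() for r in rs})
    rows = []
    for lam in lambda_grid:
        chosen = []
        nets: dict[str, list[float]] = {p: [] for p in policies}
        for rs in all_results.values():
            soc = next(r for r in rs if r.policy == "SOC")
            for r in rs:
                nets[r.policy].append(net_dalys_averted(r, soc, lam))
            chosen.append(select_cost_effective(rs, lam).policy)
        chosen = np.asarray(chosen)
        for p in policies:
            vals = np.asarray(nets[p])
            rows.append(
                {
                    "lambda": lam,
                    "policy": p,
                    "prop_cost_effective": float((chosen == p).mean()),
                    "net_dalys_median": float(np.median(vals)),
                    "net_dalys_p5": float(np.percentile(vals, 5)),
                    "net_dalys_p95": float(np.percentile(vals, 95)),
                }
            )
    return pd.DataFrame(rows)


def stratified_ce_table(
    features: pd.DataFrame,
    all_results: dict[int, list[PolicyResult]],
    strata_definitions: dict[str, list[tuple[str, float, float]]],
    lam: float = 500.0,
) -> pd.DataFrame:
    """Proportion of scenarios where each policy is cost-effective, by stratum.

    ``features`` holds one row per scenario (indexed by ``scenario_id``) with
    the characteristic columns; ``strata_definitions`` maps a characteristic
    to labelled half-open intervals [lo, hi).  Every scenario must fall in
    exactly one stratum per characteristic; row proportions sum to 100%.
    """
    policies = sorted({r.policy for rs in all_results.values() for r in rs})
    chosen = {
        sid: select_cost_effective(rs, lam).policy for sid, rs in all_results.items()
    }
    feat = features.set_index("scenario_id") if "scenario_id" in features else features
    rows = []
    for char, bins in strata_definitions.items():
        if char not in feat.columns:
            raise ValueError(f"features lack characteristic {char!r}")
        for label, lo, hi in bins:
            members = [
                sid
                for sid in chosen
                if lo <= float(feat.loc[sid, char]) < hi
            ]
            if not members:
                continue
            row = {"characteristic": char, "stratum": label, "n": len(members)}
            for p in policies:
                row[p] = 100.0 * sum(chosen[sid] == p for sid in members) / len(members)
            rows.append(row)
        # every scenario must be assignable exactly once
        for sid in chosen:
            v = float(feat.loc[sid, char])
            k = sum(lo <= v < hi for _, lo, hi in bins)
            if k != 1:
                raise ValueError(
                    f"scenario {sid} falls in {k} strata of {char!r} (value {v})"
                )
    return pd.DataFrame(rows)


def summarize_across_scenarios(values) -> tuple[float, tuple[float, float]]:
    """Arithmetic mean with the empirical 90% range (5th-95th percentiles)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no values to summarize")
    return float(arr.mean()), (
        float(np.percentile(arr, 5)),
        float(np.percentile(arr, 95)),
    )


def apply_cost_multipliers(
    results: list[PolicyResult], multipliers: dict[str, float]
) -> list[PolicyResult]:
    """Re-scale component costs for a cost-sensitivity scenario.

    Cost components are linear in their unit costs, so sensitivity analyses
    over component cost multipliers re-scale the ledgers rather than re-run
    the simulation.
    """
    out = []
    for r in results:
        comps = {
            c: v * multipliers.get(c, 1.0) for c, v in r.component_costs.items()
        }
        out.append(
            PolicyResult(
                scenario_id=r.scenario_id,
                policy=r.policy,
                component_costs=comps,
                dalys=r.dalys,
                dalys_averted_vs_soc=r.dalys_averted_vs_soc,
                metrics=dict(r.metrics),
            )
        )
    return out
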