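"""Cost-effectiveness decision rules against brute-force oracles."""

import numpy as np
import pytest

from htnsim.cea import (
    PolicyResult,
    apply_cost_multipliers,
    icer,
    net_dalys_averted,
    rank_and_dominate,
    select_by_icer_chain,
    select_cost_effective,
    stratified_ce_table,
    summarize_across_scenarios,
    threshold_sweep,
)


def _pr(policy, averted, cost, sid=0):
    return PolicyResult.from_components(
        scenario_id=sid, policy=policy, dalys_averted_vs_soc=averted, clinic=cost
    )


def _random_instance(rng, sid=0):
    """3-5 policies with continuous effects/costs; SOC anchors at 0 averted."""
    k = int(rng.integers(3, 6))
    names = ["SOC"] + [f"P{j}" for j in range(1, k)]
    out = [_pr("SOC", 0.0, float(rng.uniform(0, 1e6)), sid)]
    for nm in names[1:]:
        out.append(_pr(nm, float(rng.normal(0, 5e4)), float(rng.uniform(0, 1e6)), sid))
    return out


def _brute_nondominated(results):
    # exhaustive pairwise check: dominated = less effective AND more costly
    keep = []
    for r in results:
        dominated = any(
            o.dalys_averted_vs_soc > r.dalys_averted_vs_soc and o.total_cost < r.total_cost
            for o in results
            if o is not r
        )
        if not dominated:
            keep.append(r.policy)
    return set(keep)


def test_dominance_simple_example():
    a = _pr("SOC", 0, 0.5e6)
    b = _pr("A", 10_000, 1e6)
    c = _pr("B", 5_000, 2e6)  # less effective and more costly than A
    kept = rank_and_dominate([a, b, c])
    assert [r.policy for r in kept] == ["SOC", "A"]


def test_no_dominance_keeps_all_in_effectiveness_order():
    a = _pr("SOC", 0, 1e6)
    b = _pr("A", 5_000, 2e6)
    c = _pr("B", 10_000, 4e6)
    assert [r.policy for r in rank_and_dominate([c, a, b])] == ["SOC", "A", "B"]


def test_dominance_matches_bruteforce_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(300):
        inst = _random_instance(rng)
        kept = {r.policy for r in rank_and_dominate(inst)}
        assert kept == _brute_nondominated(inst)


def test_icer_reproduces_published_worked_example():
    """Pooled Table-level means: CHW vs CCC costs $389/DALY averted."""
    soc = _pr("SOC", 0.0, 28.1e6)
    ccc = _pr("CCC", 19.8e3, 29.5e6)
    chw = _pr("CHW", 61.5e3, 45.7e6)
    table = icer(rank_and_dominate([soc, ccc, chw])).set_index("policy")
    assert table.loc["CHW", "icer"] == pytest.approx(16.2e6 / 41.7e3)
    assert abs(table.loc["CHW", "icer"] - 389.0) <= 1.0
    assert table.loc["CCC", "icer"] == pytest.approx(1.4e6 / 19.8e3)


def test_icer_zero_incremental_effect_flagged():
    soc = _pr("SOC", 0.0, 1e6)
    tie = _pr("A", 0.0, 2e6)
    # A is dominated (same effect, higher cost); force the chain manually
    table = icer([soc, tie], extended_dominance=False)
    assert not table.iloc[1]["icer_defined"]
    assert np.isnan(table.iloc[1]["icer"])


def test_icer_equal_cost_extra_effect_is_zero():
    soc = _pr("SOC", 0.0, 1e6)
    a = _pr("A", 5_000, 1e6)
    table = icer(rank_and_dominate([soc, a])).set_index("policy")
    assert table.loc["A", "icer"] == 0.0


def test_net_dalys_formula_and_limit():
    soc = _pr("SOC", 0.0, 28.1e6)
    ccc = _pr("CCC", 19.8e3, 29.5e6)
    assert net_dalys_averted(ccc, soc, 500.0) == pytest.approx(19.8e3 - 1.4e6 / 500)
    # lambda -> infinity recovers raw DALYs averted
    assert net_dalys_averted(ccc, soc, 1e15) == pytest.approx(19.8e3)
    with pytest.raises(ValueError):
        net_dalys_averted(ccc, soc, 0.0)


def test_net_benefit_and_icer_chain_decisions_agree():
    rng = np.random.default_rng(7)
    for _ in range(300):
        inst = _random_instance(rng)
        lam = float(rng.uniform(50, 2000))
        assert select_cost_effective(inst, lam).policy == select_by_icer_chain(inst, lam).policy


def test_threshold_sweep_partitions_and_monotonicity():
    rng = np.random.default_rng(3)
    all_results = {sid: _random_instance(rng, sid) for sid in range(40)}
    grid = np.arange(100, 1001, 50)
    sweep = threshold_sweep(all_results, grid)
    for lam, grp in sweep.groupby("lambda"):
        assert grp["prop_cost_effective"].sum() == pytest.approx(1.0)
    # the most effective policy gains (weakly) as the threshold rises
    most_effective = {
        sid: max(rs, key=lambda r: r.dalys_averted_vs_soc).policy
        for sid, rs in all_results.items()
    }
    chosen_share = []
    for lam in grid:
        picks = [select_cost_effective(rs, float(lam)).policy for rs in all_results.values()]
        chosen_share.append(
            np.mean([p == most_effective[sid] for sid, p in zip(all_results, picks)])
        )
    assert all(b >= a - 1e-12 for a, b in zip(chosen_share, chosen_share[1:]))


def test_threshold_sweep_single_scenario_indicator():
    inst = [_pr("SOC", 0, 1e6), _pr("A", 1e4, 1.2e6)]
    sweep = threshold_sweep({0: inst}, [500.0])
    props = sweep.set_index("policy")["prop_cost_effective"]
    assert set(props) == {0.0, 1.0}
    with pytest.raises(ValueError):
        threshold_sweep({0: inst}, [])


def test_threshold_sweep_matches_per_scenario_selection():
    rng = np.random.default_rng(9)
    all_results = {sid: _random_instance(rng, sid) for sid in range(10)}
    lam = 400.0
    sweep = threshold_sweep(all_results, [lam]).set_index("policy")
    picks = [select_cost_effective(rs, lam).policy for rs in all_results.values()]
    for p in set(picks):
        assert sweep.loc[p, "prop_cost_effective"] == pytest.approx(
            picks.count(p) / len(picks)
        )


def test_stratified_table_rows_sum_to_100():
    import pandas as pd

    rng = np.random.default_rng(5)
    all_results = {}
    feats = []
    for sid in range(20):
        all_results[sid] = _random_instance(rng, sid)
        feats.append({"scenario_id": sid, "prev": float(rng.uniform(0.2, 0.6))})
    features = pd.DataFrame(feats)
    strata = {"prev": [("low", 0.0, 0.4), ("high", 0.4, 1.0)]}
    table = stratified_ce_table(features, all_results, strata, lam=500.0)
    policies = [c for c in table.columns if c not in ("characteristic", "stratum", "n")]
    for _, row in table.iterrows():
        assert sum(row[p] for p in policies) == pytest.approx(100.0)
    # hand tally for one stratum
    low_ids = [f["scenario_id"] for f in feats if f["prev"] < 0.4]
    picks = {sid: select_cost_effective(all_results[sid], 500.0).policy for sid in low_ids}
    low_row = table[table.stratum == "low"].iloc[0]
    for p in policies:
        assert low_row[p] == pytest.approx(
            100.0 * sum(v == p for v in picks.values()) / len(low_ids)
        )


def test_stratified_table_unassignable_scenario_errors():
    import pandas as pd

    rng = np.random.default_rng(6)
    all_results = {0: _random_instance(rng, 0)}
    features = pd.DataFrame([{"scenario_id": 0, "prev": 0.9}])
    strata = {"prev": [("low", 0.0, 0.4)]}
    with pytest.raises(ValueError, match="scenario 0"):
        stratified_ce_table(features, all_results, strata)


def test_summarize_across_scenarios():
    mean, (lo, hi) = summarize_across_scenarios([3.0, 3.0, 3.0])
    assert (mean, lo, hi) == (3.0, 3.0, 3.0)
    mean1, (lo1, hi1) = summarize_across_scenarios([7.5])
    assert mean1 == lo1 == hi1 == 7.5
    rng = np.random.default_rng(0)
    u = rng.uniform(0, 1, 10_000)
    m, (l5, u95) = summarize_across_scenarios(u)
    assert m == pytest.approx(0.5, abs=0.02)
    assert l5 == pytest.approx(0.05, abs=0.02)
    assert u95 == pytest.approx(0.95, abs=0.02)
    with pytest.raises(ValueError):
        summarize_across_scenarios([])


def test_cost_multiplier_rescaling():
    r = PolicyResult.from_components(0, "CHW", clinic=10.0, drug=4.0, screening=2.0)
    (out,) = apply_cost_multipliers([r], {"drug": 2.0})
    assert out.component_costs["drug"] == 8.0
    assert out.component_costs["clinic"] == 10.0
    assert out.total_cost == pytest.approx(20.0)
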