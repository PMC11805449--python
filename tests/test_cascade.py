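"""Care cascade: diagnosis rule, screening, visits, retention, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from htnsim.cascade import (
    CCC,
    CHW,
    SOC,
    PolicySpec,
    apply_diagnosis_rule,
    cascade_metrics,
    chw_screen_round,
    clinic_visit,
    measure_sbp,
    schedule_next_visit,
    update_retention,
)
from htnsim.history import QuarterlyHistory
from htnsim.population import init_population, step_quarter


@pytest.mark.parametrize(
    "history,started,expected",
    [
        ([142, 141], False, True),  # two consecutive >= 140
        ([165], False, True),  # single occasion >= 160
        ([138, 142], False, False),  # highs not consecutive
        ([142, 138], False, False),
        ([139, 139], False, False),
        ([], False, False),
        ([120], True, True),  # therapy started implies diagnosed
    ],
)
def test_diagnosis_rule(history, started, expected):
    assert apply_diagnosis_rule(history, started) is expected


@given(
    st.lists(st.floats(min_value=60, max_value=220), min_size=0, max_size=2),
    st.booleans(),
)
@settings(derandomize=True, max_examples=200)
def test_diagnosis_rule_properties(history, started):
    got = apply_diagnosis_rule(history, started)
    if started:
        assert got
    elif any(v >= 160 for v in history):
        assert got
    elif len(history) == 2 and min(history) >= 140:
        assert got
    elif all(v < 140 for v in history) and not started:
        assert not got


@pytest.mark.parametrize(
    "policy,measured,interval",
    [(CCC, 132, 2), (CCC, 148, 1), (SOC, 132, 1), (SOC, 148, 1), (CHW, 132, 2)],
)
def test_visit_scheduling(policy, measured, interval):
    assert schedule_next_visit(policy, measured, t=100) == 100 + interval


def test_policy_spec_validation():
    with pytest.raises(ValueError):
        PolicySpec("XXX")
    with pytest.raises(ValueError):
        PolicySpec.chw(min_age=45)
    assert SOC.visit_interval_controlled == 1 and SOC.visit_interval_uncontrolled == 1
    for p in (CCC, CHW):
        assert p.visit_interval_controlled == 2 and p.visit_interval_uncontrolled == 1


def test_measurement_noise_free_returns_true_sbp(scenario_with, make_population):
    sc = scenario_with(measurement_noise_sd=0.0)
    pop = make_population([{"age": 50, "sbp_pre": 150.0}])
    vals = measure_sbp(pop, np.array([0]), sc, np.random.default_rng(0))
    assert vals[0] == 150.0
    assert pop.last_meas[0] == 150.0


def test_measurement_noise_sd_contract(scenario_with, make_population):
    sc = scenario_with(measurement_noise_sd=8.0)
    pop = make_population([{"age": 50, "sbp_pre": 150.0}] * 10_000)
    vals = measure_sbp(pop, np.arange(10_000), sc, np.random.default_rng(1))
    assert np.std(vals) == pytest.approx(8.0, abs=0.25)
    assert np.mean(vals) == pytest.approx(150.0, abs=0.25)


def test_measurement_occupies_most_recent_slot(scenario_with, make_population):
    sc = scenario_with(measurement_noise_sd=0.0)
    pop = make_population([{"age": 50, "sbp_pre": 145.0, "last_meas": 142.0}])
    measure_sbp(pop, np.array([0]), sc, np.random.default_rng(0))
    assert pop.last_meas[0] == 145.0
    assert pop.prev_meas[0] == 142.0


def test_measurement_rejects_dead(scenario_with, make_population):
    sc = scenario_with()
    pop = make_population([{"age": 50, "alive": False}])
    with pytest.raises(ValueError, match="dead"):
        measure_sbp(pop, np.array([0]), sc, np.random.default_rng(0))


def test_chw_age_eligibility(scenario_with, make_population):
    sc = scenario_with(chw_coverage=1.0, measurement_noise_sd=0.0)
    pop = make_population([{"age": 39, "sbp_pre": 170.0}, {"age": 45, "sbp_pre": 170.0}], t=140)
    screened = chw_screen_round(pop, CHW, sc, t=140, rng=np.random.default_rng(0))
    assert screened.tolist() == [1]  # 39-year-old below the age-40 floor

    pop2 = make_population([{"age": 45, "sbp_pre": 170.0}, {"age": 55, "sbp_pre": 170.0}], t=140)
    chw50 = PolicySpec.chw(min_age=50.0)
    screened2 = chw_screen_round(pop2, chw50, sc, t=140, rng=np.random.default_rng(0))
    assert screened2.tolist() == [1]  # sensitivity mode: only the 55-year-old


def test_chw_zero_coverage_screens_nobody(scenario_with, make_population):
    sc = scenario_with(chw_coverage=0.0)
    pop = make_population([{"age": 60}] * 10, t=140)
    assert chw_screen_round(pop, CHW, sc, 140, np.random.default_rng(0)).size == 0


def test_chw_round_requires_screening_policy(scenario_with, make_population):
    sc = scenario_with()
    pop = make_population([{"age": 60}])
    with pytest.raises(ValueError, match="screening"):
        chw_screen_round(pop, SOC, sc, 140, np.random.default_rng(0))


def test_visit_intensifies_one_drug_step_with_cap(scenario_with, make_population):
    sc = scenario_with(measurement_noise_sd=0.0, per_drug_sbp_reduction=0.0)
    pop = make_population(
        [
            {"age": 50, "sbp_pre": 150.0, "diagnosed": True, "on_treatment": True, "n_drugs": 1},
            {"age": 50, "sbp_pre": 150.0, "diagnosed": True, "on_treatment": True, "n_drugs": 3},
            {"age": 50, "sbp_pre": 128.0, "diagnosed": True, "on_treatment": True, "n_drugs": 1},
        ]
    )
    clinic_visit(pop, np.arange(3), SOC, sc, t=100, rng=np.random.default_rng(0))
    assert pop.n_drugs[0] == 2  # measured 150 -> one step up
    assert pop.n_drugs[1] == 3  # cap
    assert pop.n_drugs[2] == 1  # measured 128 -> no intensification


def test_visit_rejects_dead(scenario_with, make_population):
    sc = scenario_with()
    pop = make_population([{"age": 50, "alive": False}])
    with pytest.raises(ValueError, match="dead"):
        clinic_visit(pop, np.array([0]), SOC, sc, 100, np.random.default_rng(0))


def test_retention_contracts(scenario_with, make_population):
    from htnsim.scenarios import RetentionParams

    never = {
        "SOC": RetentionParams(disengage=0.0, reengage=0.0),
        "CCC": RetentionParams(disengage=0.0, reengage=0.0),
        "CHW": RetentionParams(disengage=0.0, reengage=0.0),
    }
    sc = scenario_with(retention_params=never)
    pop = make_population([{"age": 50, "diagnosed": True, "engaged": True}])
    for t in range(100, 120):
        update_retention(pop, sc, SOC, t, np.random.default_rng(t))
    assert pop.engaged[0]

    always_back = {
        k: RetentionParams(disengage=0.0, reengage=1.0) for k in ("SOC", "CCC", "CHW")
    }
    sc2 = scenario_with(retention_params=always_back)
    pop2 = make_population([{"age": 50, "diagnosed": True, "engaged": False}])
    update_retention(pop2, sc2, SOC, t=100, rng=np.random.default_rng(0))
    assert pop2.engaged[0]
    assert pop2.next_visit_q[0] == 101  # back in care next quarter


def test_permanent_nonengager_never_diagnosed_via_clinic(base_scenario):
    """Under clinic-only care, never-engaging people are never diagnosed."""
    pop = init_population(base_scenario, 3000, rng=np.random.default_rng(8))
    rng = np.random.default_rng(9)
    for t in range(0, 80):
        step_quarter(pop, base_scenario, SOC, t, rng)
    ne = pop.never_engage[: pop.n]
    assert not pop.diagnosed[: pop.n][ne].any()


def test_cascade_metrics_match_hand_computed_roster(scenario_with, make_population):
    """Six crafted individuals reproduce hand-computed cascade fractions."""
    sc = scenario_with(per_drug_sbp_reduction=15.0)
    t0 = (2013 - 1989) * 4
    rows = [
        # hypertensive, treated and controlled (150 - 15 = 135)
        {"age": 50, "sbp_pre": 150.0, "diagnosed": True, "on_treatment": True, "n_drugs": 1},
        # hypertensive, undiagnosed
        {"age": 55, "sbp_pre": 160.0},
        # hypertensive, diagnosed, never treated
        {"age": 60, "sbp_pre": 145.0, "diagnosed": True},
        # normotensive, overdiagnosed
        {"age": 52, "sbp_pre": 130.0, "diagnosed": True},
        # normotensive
        {"age": 58, "sbp_pre": 120.0},
        # hypertensive, diagnosed, previously treated, currently non-adherent
        {"age": 62, "sbp_pre": 142.0, "diagnosed": True, "on_treatment": True,
         "ever_treated": True, "adherent": False},
    ]
    pop = make_population(rows, t=t0)
    hist = QuarterlyHistory(t0 + 4)
    for t in range(t0, t0 + 4):  # constant state over one calendar year
        hist.record(pop, sc, t, {}, np.array([], dtype=int))
    m = cascade_metrics(hist, (2013, 2013), ("45-64",)).set_index("metric")["value"]
    assert m["prevalence"] == pytest.approx(4 / 6)
    assert m["diagnosed"] == pytest.approx(3 / 4)
    assert m["treated"] == pytest.approx(1 / 4)
    assert m["ever_treated"] == pytest.approx(2 / 4)
    assert m["controlled"] == pytest.approx(1 / 4)
    assert m["overdiagnosis"] == pytest.approx(1 / 2)
    assert m["overtreatment"] == pytest.approx(0.0)
    assert m["overdx_mean_pre_sbp"] == pytest.approx(130.0)


def test_cascade_metrics_empty_band_flagged_undefined(scenario_with, make_population):
    sc = scenario_with()
    pop = make_population([{"age": 30, "sbp_pre": 120.0}], t=96)
    hist = QuarterlyHistory(100)
    for t in range(96, 100):
        hist.record(pop, sc, t, {}, np.array([], dtype=int))
    m = cascade_metrics(hist, (2013, 2013), ("65+",))
    diag = m[m.metric == "diagnosed"].iloc[0]
    assert not diag["defined"] and np.isnan(diag["value"])


def test_cascade_nesting_invariant(soc_history):
    """controlled <= treated <= ever treated <= diagnosed in every band."""
    m = cascade_metrics(soc_history, (2013, 2016), ("18+", "25-44", "45-64", "65+"))
    for band, grp in m.groupby("age_band"):
        v = grp.set_index("metric")["value"]
        assert v["controlled"] <= v["treated"] + 1e-12
        assert v["treated"] <= v["ever_treated"] + 1e-12
        assert v["ever_treated"] <= v["diagnosed"] + 1e-12
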