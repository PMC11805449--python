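"""Hypertension care cascade: screening, diagnosis, treatment, retention.

Implements the three delivery policies:

* ``SOC`` — standard of care: clinic-based measurement only, hypertension
  visits scheduled every quarter.
* ``CCC`` — chronic-care clinic: hypertension care integrated within HIV
  primary care clinics; blood pressure measured at ART visits, multi-month
  scripts (6-monthly visits while controlled), better retention.
* ``CHW`` — CCC plus an annual community-health-worker screening round for
  adults at or above a minimum age (40 by default, 50 in sensitivity mode).

The diagnosis rule is measured SBP >= 140 mmHg on two consecutive
measurement occasions, >= 160 mmHg on a single occasion, or initiation of
antihypertensive therapy.  Occasions are the two most recent measurements
regardless of the calendar gap between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .history import BAND_MAP, QuarterlyHistory
from .population import _NO_MEAS, _NO_VISIT, HIV_ART, Population, START_YEAR
from .scenarios import SettingScenario

__all__ = [
    "PolicySpec",
    "SOC",
    "CCC",
    "CHW",
    "apply_diagnosis_rule",
    "visit_interval",
    "schedule_next_visit",
    "measure_sbp",
    "chw_screen_round",
    "clinic_visit",
    "update_retention",
    "step_cascade",
    "cascade_metrics",
]

DIAG_THRESHOLD = 140.0
SINGLE_OCCASION_THRESHOLD = 160.0
MAX_DRUGS = 3


@dataclass(frozen=True)
class PolicySpec:
    """A hypertension care-delivery policy."""

    name: str
    chw_screening: bool = False
    chw_min_age: float = 40.0
    visit_interval_controlled: int = 1  # quarters
    visit_interval_uncontrolled: int = 1
    integrated_with_hiv_clinic: bool = False

    def __post_init__(self):
        if self.name not in ("SOC", "CCC", "CHW"):
            raise ValueError(f"unknown policy name {self.name!r}")
        if self.chw_min_age not in (40.0, 50.0):
            raise ValueError("chw_min_age must be 40 or 50")

    @staticmethod
    def soc() -> "PolicySpec":
        return PolicySpec("SOC")

    @staticmethod
    def ccc() -> "PolicySpec":
        return PolicySpec(
            "CCC",
            visit_interval_controlled=2,
            visit_interval_uncontrolled=1,
            integrated_with_hiv_clinic=True,
        )

    @staticmethod
    def chw(min_age: float = 40.0) -> "PolicySpec":
        return PolicySpec(
            "CHW",
            chw_screening=True,
            chw_min_age=min_age,
            visit_interval_controlled=2,
            visit_interval_uncontrolled=1,
            integrated_with_hiv_clinic=True,
        )


SOC = PolicySpec.soc()
CCC = PolicySpec.ccc()
CHW = PolicySpec.chw()


def apply_diagnosis_rule(history, started_treatment: bool = False) -> bool:
    """Diagnosis rule on the 0-2 most recent measurement occasions.

    True iff the two most recent consecutive measurements are both >= 140,
    any single measurement is >= 160, or antihypertensive therapy was started.
    """
    if started_treatment:
        return True
    vals = list(history)
    if any(v >= SINGLE_OCCASION_THRESHOLD for v in vals):
        return True
    if len(vals) >= 2 and vals[-1] >= DIAG_THRESHOLD and vals[-2] >= DIAG_THRESHOLD:
        return True
    return False


def _rule_vec(prev: np.ndarray, last: np.ndarray) -> np.ndarray:
    return (last >= SINGLE_OCCASION_THRESHOLD) | (
        (last >= DIAG_THRESHOLD) & (prev >= DIAG_THRESHOLD)
    )


def visit_interval(policy: PolicySpec, measured: float | np.ndarray):
    """Quarters until the next scheduled visit given the measured SBP."""
    controlled = np.asarray(measured) < DIAG_THRESHOLD
    return np.where(
        controlled, policy.visit_interval_controlled, policy.visit_interval_uncontrolled
    )


def schedule_next_visit(policy: PolicySpec, measured: float, t: int) -> int:
    """Calendar quarter of the next visit after a visit at quarter ``t``."""
    return t + int(visit_interval(policy, measured))


def measure_sbp(
    pop: Population,
    idx: np.ndarray,
    scenario: SettingScenario,
    rng: np.random.Generator,
) -> np.ndarray:
    """Measure SBP for individuals ``idx``: true SBP plus Gaussian noise.

    The measurement is recorded as the most recent occasion (shifting the
    previous one back) and returned.
    """
    idx = np.atleast_1d(idx)
    if not pop.alive[idx].all():
        raise ValueError("cannot measure SBP on a dead individual")
    true = pop.true_sbp(scenario)[idx]
    vals = true + rng.normal(0.0, scenario.measurement_noise_sd, idx.size)
    pop.prev_meas[idx] = pop.last_meas[idx]
    pop.last_meas[idx] = vals
    return vals


def chw_screen_round(
    pop: Population,
    policy: PolicySpec,
    scenario: SettingScenario,
    t: int,
    rng: np.random.Generator,
    econ=None,
) -> np.ndarray:
    """Annual CHW household screening round; returns screened indices.

    Each living adult at or above the policy's minimum age is screened with
    probability ``chw_coverage``.  Screen-positive, non-engaged individuals
    link to a confirmatory clinic visit next quarter with probability
    ``linkage_prob`` (permanent non-engagers never link).
    """
    if not policy.chw_screening:
        raise ValueError(f"CHW screening round called under policy {policy.name}")
    n = pop.n
    age = pop.age(t)
    eligible = pop.alive[:n] & (age >= policy.chw_min_age)
    idx = np.flatnonzero(eligible)
    screened = idx[rng.random(idx.size) < scenario.chw_coverage]
    if screened.size == 0:
        return screened
    if econ is not None:
        econ.add_cost(
            "screening",
            t,
            screened.size
            * scenario.unit_costs.chw_screen_per_person
            * scenario.cost_multiplier_scenario.get("screening", 1.0),
        )
    vals = measure_sbp(pop, screened, scenario, rng)
    newly = _rule_vec(pop.prev_meas[screened], pop.last_meas[screened])
    pop.diagnosed[screened] |= newly
    positive = vals >= DIAG_THRESHOLD
    linkable = positive & ~pop.never_engage[screened] & ~pop.engaged[screened]
    cand = screened[linkable]
    linked = cand[rng.random(cand.size) < scenario.linkage_prob]
    pop.next_visit_q[linked] = t + 1
    return screened


def clinic_visit(
    pop: Population,
    idx: np.ndarray,
    policy: PolicySpec,
    scenario: SettingScenario,
    t: int,
    rng: np.random.Generator,
    econ=None,
) -> None:
    """Run hypertension clinic visits for the due individuals ``idx``.

    Measures SBP, applies the diagnosis rule, initiates (with probability
    ``treat_initiation_prob``) or intensifies treatment (one drug per visit,
    three-drug cap) when the measured SBP is >= 140 in a diagnosed person,
    schedules the next visit, and charges the visit cost.
    """
    idx = np.atleast_1d(idx)
    if idx.size == 0:
        return
    if not pop.alive[idx].all():
        raise ValueError("clinic visit for a dead individual")
    vals = measure_sbp(pop, idx, scenario, rng)
    newly = _rule_vec(pop.prev_meas[idx], pop.last_meas[idx])
    pop.diagnosed[idx] |= newly
    diag = pop.diagnosed[idx]

    # treatment initiation / intensification
    eligible = diag & (vals >= DIAG_THRESHOLD)
    start = eligible & ~pop.on_treatment[idx] & (
        rng.random(idx.size) < scenario.treat_initiation_prob
    )
    sidx = idx[start]
    pop.on_treatment[sidx] = True
    pop.ever_treated[sidx] = True
    pop.n_drugs[sidx] = 1
    pop.adherent[sidx] = rng.random(sidx.size) < scenario.adherence_prob
    intensify = eligible & pop.on_treatment[idx] & ~start
    iidx = idx[intensify]
    pop.n_drugs[iidx] = np.minimum(pop.n_drugs[iidx] + 1, MAX_DRUGS)

    # diagnosed attendees are (or remain) engaged in care; a failed
    # confirmatory visit leads nowhere
    pop.engaged[idx] |= diag
    nxt = np.where(
        diag,
        t + visit_interval(policy, vals),
        _NO_VISIT,
    )
    pop.next_visit_q[idx] = nxt.astype(np.int32)

    if econ is not None:
        from .health_econ import visit_cost_array

        integrated = (pop.hiv[idx] == HIV_ART) & policy.integrated_with_hiv_clinic
        costs = visit_cost_array(vals < DIAG_THRESHOLD, integrated, scenario)
        econ.add_cost("clinic", t, float(costs.sum()))


def update_retention(
    pop: Population,
    scenario: SettingScenario,
    policy: PolicySpec,
    t: int,
    rng: np.random.Generator,
) -> None:
    """Per-quarter disengagement from and re-engagement with care."""
    params = scenario.retention_params[policy.name]
    n = pop.n
    engaged = pop.alive[:n] & pop.engaged[:n]
    eidx = np.flatnonzero(engaged)
    out = eidx[rng.random(eidx.size) < params.disengage]
    pop.engaged[out] = False
    pop.adherent[out] = False
    pop.next_visit_q[out] = _NO_VISIT

    dis = (
        pop.alive[:n]
        & pop.diagnosed[:n]
        & ~pop.engaged[:n]
        & ~pop.never_engage[:n]
    )
    dis[out] = False  # cannot re-engage in the quarter of disengagement
    didx = np.flatnonzero(dis)
    back = didx[rng.random(didx.size) < params.reengage]
    pop.engaged[back] = True
    pop.next_visit_q[back] = t + 1


def _background_presentations(
    pop: Population,
    policy: PolicySpec,
    scenario: SettingScenario,
    t: int,
    rng: np.random.Generator,
) -> None:
    """Blood-pressure-measuring clinic contacts outside scheduled care.

    Under integrated policies, people on ART have BP measured at their
    routine HIV visits; otherwise the age-band contact probability applies.
    These contacts carry no hypertension visit cost, but a diagnosis made
    here starts hypertension care.
    """
    n = pop.n
    cand = pop.alive[:n] & ~pop.never_engage[:n] & ~pop.engaged[:n]
    idx = np.flatnonzero(cand)
    age = (t - pop.birth_q[idx]) * 0.25
    p = scenario.presentation_prob(age)
    if policy.integrated_with_hiv_clinic:
        on_art = pop.hiv[idx] == HIV_ART
        p = np.where(on_art, np.maximum(p, scenario.hiv_clinic_presentation_prob), p)
    pres = idx[rng.random(idx.size) < p]
    if pres.size == 0:
        return
    vals = measure_sbp(pop, pres, scenario, rng)
    newly = _rule_vec(pop.prev_meas[pres], pop.last_meas[pres])
    pop.diagnosed[pres] |= newly
    ndx = pres[newly]
    if ndx.size == 0:
        return
    pop.engaged[ndx] = True
    nvals = vals[newly]
    start = (nvals >= DIAG_THRESHOLD) & (
        rng.random(ndx.size) < scenario.treat_initiation_prob
    )
    sidx = ndx[start]
    pop.on_treatment[sidx] = True
    pop.ever_treated[sidx] = True
    pop.n_drugs[sidx] = 1
    pop.adherent[sidx] = rng.random(sidx.size) < scenario.adherence_prob
    pop.next_visit_q[ndx] = (t + visit_interval(policy, nvals)).astype(np.int32)


def step_cascade(
    pop: Population,
    scenario: SettingScenario,
    policy: PolicySpec,
    t: int,
    rng: np.random.Generator,
    econ=None,
) -> None:
    """One quarter of care-cascade dynamics under ``policy``."""
    update_retention(pop, scenario, policy, t, rng)

    if policy.chw_screening and t % 4 == 0:
        chw_screen_round(pop, policy, scenario, t, rng, econ=econ)

    n = pop.n
    due = pop.alive[:n] & (pop.next_visit_q[:n] <= t)
    clinic_visit(pop, np.flatnonzero(due), policy, scenario, t, rng, econ=econ)

    _background_presentations(pop, policy, scenario, t, rng)

    # quarterly adherence draw for people with dispensed drugs
    n = pop.n
    on = pop.alive[:n] & pop.on_treatment[:n] & pop.engaged[:n]
    oidx = np.flatnonzero(on)
    pop.adherent[oidx] = rng.random(oidx.size) < scenario.adherence_prob

    if econ is not None:
        from .health_econ import drug_cost

        drugs = pop.n_drugs[oidx]
        total = sum(drug_cost(int(k), scenario) * int((drugs == k).sum()) for k in (1, 2, 3))
        econ.add_cost("drug", t, total)


_CASCADE_METRICS = (
    "prevalence",
    "diagnosed",
    "treated",
    "ever_treated",
    "controlled",
    "overdiagnosis",
    "overtreatment",
    "mean_sbp",
    "overdx_mean_pre_sbp",
)


def cascade_metrics(
    history: QuarterlyHistory,
    window: tuple[int, int],
    age_bands: tuple[str, ...] = ("18+", "25-44", "45-64", "65+"),
) -> pd.DataFrame:
    """Person-time-weighted cascade metrics over a calendar-year window.

    Proportions are on the 0-1 scale: hypertension prevalence among all
    person-time; diagnosed / currently treated / ever treated / controlled
    among true hypertensives; overdiagnosis and overtreatment among true
    normotensives.  Empty denominators yield NaN flagged ``defined=False``.
    """
    q = history.quarters_of_years(window[0], window[1], START_YEAR)
    if not history.recorded[q].all():
        raise ValueError("metrics window covers unrecorded quarters")
    rows = []
    for band in age_bands:
        if band not in BAND_MAP:
            raise ValueError(f"unknown age band {band!r}")
        pt = history.window_sum("pt", q, band)
        hyp = history.window_sum("hyp", q, band)
        norm = pt - hyp
        values = {
            "prevalence": (hyp, pt),
            "diagnosed": (history.window_sum("hyp_diag", q, band), hyp),
            "treated": (history.window_sum("hyp_treat", q, band), hyp),
            "ever_treated": (history.window_sum("hyp_ever_treat", q, band), hyp),
            "controlled": (history.window_sum("hyp_controlled", q, band), hyp),
            "overdiagnosis": (history.window_sum("norm_diag", q, band), norm),
            "overtreatment": (history.window_sum("norm_treat", q, band), norm),
            "mean_sbp": (history.window_sum("sum_true_sbp", q, band), pt),
            "overdx_mean_pre_sbp": (
                history.window_sum("overdx_sum_pre_sbp", q, band),
                history.window_sum("norm_diag", q, band),
            ),
        }
        for metric, (num, den) in values.items():
            defined = den > 0
            rows.append(
                {
                    "age_band": band,
                    "metric": metric,
                    "value": num / den if defined else float("nan"),
                    "defined": bool(defined),
                }
            )
    return pd.DataFrame(rows)
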