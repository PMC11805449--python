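"""Cardiovascular disease: incidence, severity, acute outcomes, sequelae.

Each quarter, incident ischemic heart disease (IHD) and stroke are drawn per
person from hazards that combine a Gompertz-in-age baseline (per type and
sex, scaled by the setting's base-rate multipliers), a log-linear SBP
relative risk above a 115 mmHg floor with an age-attenuated slope, an HIV
hazard multiplier, and a prior-event multiplier.  Moderate/severe IHD events
represent myocardial infarction; mild events (angina / silent infarction,
minor stroke) are asymptomatic, never seek care, and carry no acute
mortality by default.

Moderate/severe events may seek emergency care (setting-level probability);
care that is sought may be effective, reducing acute mortality; ineffective
care still costs a configurable fraction of effective care.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .history import BAND_MAP, N_FINE, QuarterlyHistory, fine_band_index
from .population import CAUSE_CVD_ACUTE, Population, START_YEAR
from .scenarios import SettingScenario

__all__ = [
    "EVENT_TYPES",
    "SEVERITIES",
    "cvd_hazard",
    "draw_severity",
    "acute_phase",
    "post_event_state",
    "step_cvd",
    "cvd_rates",
]

EVENT_TYPES = ("IHD", "stroke")
SEVERITIES = ("mild", "moderate", "severe")
SBP_RISK_FLOOR = 115.0


def _rr_per_mmhg(age: np.ndarray, scenario: SettingScenario) -> np.ndarray:
    """Log relative risk per mmHg of SBP above the floor, attenuated with age.

    Defined from the relative risk per 10 mmHg *lower* SBP at ages 50 and 80
    (linear in between, clamped outside).
    """
    theta50 = -np.log(scenario.rr10_age50) / 10.0
    theta80 = -np.log(scenario.rr10_age80) / 10.0
    frac = np.clip((np.asarray(age, dtype=float) - 50.0) / 30.0, 0.0, 1.0)
    return theta50 + frac * (theta80 - theta50)


def cvd_hazard(
    pop: Population,
    scenario: SettingScenario,
    event_type: str,
    t: int,
    idx: np.ndarray | None = None,
) -> np.ndarray:
    """Per-quarter event probability for individuals ``idx`` (default: all).

    hazard = baseline(age, sex) x base-rate scalar x RR_SBP(max(SBP, 115))
             x HIV multiplier x prior-CVD multiplier, clipped to [0, 1].
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    n = pop.n
    if idx is None:
        idx = np.arange(n)
    age = (t - pop.birth_q[idx]) * 0.25
    sexmult = np.where(
        pop.sex[idx] == 1,
        scenario.cvd_sex_mult[event_type]["M"],
        scenario.cvd_sex_mult[event_type]["F"],
    )
    base = (
        scenario.cvd_base_quarterly[event_type]
        * scenario.cvd_base_rate_scalar[event_type]
        * sexmult
        * np.exp(scenario.cvd_age_log_slope * (age - 60.0))
    )
    sbp = pop.true_sbp(scenario)[idx]
    rr_sbp = np.exp(_rr_per_mmhg(age, scenario) * (np.maximum(sbp, SBP_RISK_FLOOR) - SBP_RISK_FLOOR))
    hiv_mult = np.where(pop.hiv[idx] > 0, scenario.hiv_cvd_rr, 1.0)
    prior = pop.prior_ihd[idx] | pop.prior_stroke[idx]
    prior_mult = np.where(prior, scenario.prior_cvd_rr, 1.0)
    return np.clip(base * rr_sbp * hiv_mult * prior_mult, 0.0, 1.0)


def draw_severity(
    event_type: str, k: int, scenario: SettingScenario, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``k`` severities (0 mild, 1 moderate, 2 severe) for an event type."""
    probs = np.asarray(scenario.severity_probs[event_type])
    return np.searchsorted(np.cumsum(probs), rng.random(k), side="right").clip(0, 2)


def acute_phase(
    event_type: str,
    severity: np.ndarray,
    scenario: SettingScenario,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Resolve emergency care seeking, effectiveness, death and cost.

    Only moderate/severe events may seek care.  The acute death probability
    is the severity-specific unattended level, reduced by the effective-care
    mortality reduction when care was sought and effective.  Cost is the full
    effective-care cost when effective, the ineffective fraction of it when
    sought but ineffective, and zero when not sought.
    """
    k = severity.size
    modsev = severity >= 1
    sought = modsev & (rng.random(k) < scenario.care_seek_prob)
    effective = sought & (rng.random(k) < scenario.care_effective_prob)

    am = scenario.acute_mortality[event_type]
    p_death = np.select(
        [severity == 0, severity == 1, severity == 2],
        [am["mild"], am["moderate"], am["severe"]],
    )
    p_death = np.where(
        effective, p_death * (1.0 - scenario.effective_care_mortality_reduction), p_death
    )
    died = rng.random(k) < p_death

    uc = scenario.unit_costs.acute_cvd_effective[event_type]
    full = np.select(
        [severity == 0, severity == 1, severity == 2],
        [uc["mild"], uc["moderate"], uc["severe"]],
    )
    cost = np.where(
        effective,
        full,
        np.where(sought, full * scenario.ineffective_cost_fraction, 0.0),
    ) * scenario.cost_multiplier_scenario.get("cvd_care", 1.0)
    return {"sought": sought, "effective": effective, "died": died, "cost": cost}


def post_event_state(
    pop: Population,
    idx: np.ndarray,
    event_type: str,
    severity: np.ndarray,
    scenario: SettingScenario,
) -> None:
    """Apply sequelae to acute-phase survivors ``idx``.

    Sets the prior-event flag, takes the maximum of the current and new
    chronic disability weight, and raises the long-term (chronic CVD)
    mortality hazard to the severity's level if higher.
    """
    if event_type == "IHD":
        pop.prior_ihd[idx] = True
    else:
        pop.prior_stroke[idx] = True
    dw = scenario.disability_weights[event_type]
    new_w = np.select(
        [severity == 0, severity == 1, severity == 2],
        [dw["mild"], dw["moderate"], dw["severe"]],
    )
    pop.disability_weight[idx] = np.maximum(pop.disability_weight[idx], new_w)
    cm = scenario.chronic_cvd_mortality
    new_q = np.select(
        [severity == 0, severity == 1, severity == 2],
        [cm["mild"], cm["moderate"], cm["severe"]],
    )
    pop.chronic_q[idx] = np.maximum(pop.chronic_q[idx], new_q)


def events_to_frame(log: list[dict]) -> pd.DataFrame:
    """Flatten an event log (as filled by :func:`step_cvd`) into a tidy frame
    with one row per event: person, quarter, type, severity, care pathway,
    acute outcome and cost."""
    if not log:
        return pd.DataFrame(
            columns=["person_id", "quarter", "type", "severity", "sought_care",
                     "care_effective", "died_acutely", "acute_cost"]
        )
    parts = []
    for entry in log:
        parts.append(
            pd.DataFrame(
                {
                    "person_id": entry["person_id"],
                    "quarter": entry["quarter"],
                    "type": entry["type"],
                    "severity": np.array(SEVERITIES)[entry["severity"]],
                    "sought_care": entry["sought"],
                    "care_effective": entry["effective"],
                    "died_acutely": entry["died"],
                    "acute_cost": entry["cost"],
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def step_cvd(
    pop: Population,
    scenario: SettingScenario,
    t: int,
    rng: np.random.Generator,
    econ=None,
    log: list | None = None,
) -> dict[str, np.ndarray]:
    """Draw and resolve this quarter's CVD events; returns per-band tallies.

    IHD is resolved before stroke; a person who dies acutely of IHD cannot
    also have a stroke in the same quarter.  At most one event per type per
    quarter.
    """
    out = {
        "ihd_all": np.zeros(N_FINE),
        "ihd_ms": np.zeros(N_FINE),
        "stroke_all": np.zeros(N_FINE),
        "stroke_ms": np.zeros(N_FINE),
    }
    total_cost = 0.0
    for event_type, key in (("IHD", "ihd"), ("stroke", "stroke")):
        n = pop.n
        alive_idx = np.flatnonzero(pop.alive[:n])
        if alive_idx.size == 0:
            continue
        h = cvd_hazard(pop, scenario, event_type, t, alive_idx)
        hit = alive_idx[rng.random(alive_idx.size) < h]
        if hit.size == 0:
            continue
        severity = draw_severity(event_type, hit.size, scenario, rng)
        acute = acute_phase(event_type, severity, scenario, rng)
        total_cost += float(acute["cost"].sum())
        if log is not None:
            log.append(
                {
                    "person_id": hit,
                    "quarter": t,
                    "type": event_type,
                    "severity": severity,
                    **{k: acute[k] for k in ("sought", "effective", "died", "cost")},
                }
            )

        band = fine_band_index((t - pop.birth_q[hit]) * 0.25)
        out[f"{key}_all"] += np.bincount(band, minlength=N_FINE)
        out[f"{key}_ms"] += np.bincount(
            band, weights=(severity >= 1).astype(float), minlength=N_FINE
        )

        died = acute["died"]
        didx = hit[died]
        pop.alive[didx] = False
        pop.died_q[didx] = t
        pop.death_cause[didx] = CAUSE_CVD_ACUTE
        surv = hit[~died]
        post_event_state(pop, surv, event_type, severity[~died], scenario)

    if econ is not None and total_cost > 0:
        econ.add_cost("cvd_care", t, total_cost)
    return out


def cvd_rates(
    history: QuarterlyHistory,
    window: tuple[int, int],
    age_bands: tuple[str, ...] = ("18+", "25-44", "45-64", "65+"),
    comparator: QuarterlyHistory | None = None,
) -> pd.DataFrame:
    """Incidence and mortality rates per 100 person-years over a window.

    Event rates count moderate/severe events only (mild events are
    asymptomatic).  With a ``comparator`` history (e.g. standard of care),
    relative risks are reported alongside.  Zero person-time yields NaN
    flagged ``defined=False``.
    """
    q = history.quarters_of_years(window[0], window[1], START_YEAR)

    def rates_for(h: QuarterlyHistory, band: str) -> dict[str, float]:
        py = h.window_sum("pt", q, band) * 0.25
        py_hiv = h.window_sum("pt_hiv", q, band) * 0.25
        if py == 0:
            return {"_defined": False}
        vals = {
            "ihd_incidence": h.window_sum("ihd_ms", q, band) / py * 100.0,
            "stroke_incidence": h.window_sum("stroke_ms", q, band) / py * 100.0,
            "cvd_mortality": h.window_sum("deaths_cvd", q, band) / py * 100.0,
            "all_cause_mortality": h.window_sum("deaths_all", q, band) / py * 100.0,
            "_defined": True,
        }
        if py_hiv > 0:
            vals["cvd_mortality_hiv"] = (
                h.window_sum("deaths_cvd_hiv", q, band) / py_hiv * 100.0
            )
            vals["all_cause_mortality_hiv"] = (
                h.window_sum("deaths_all_hiv", q, band) / py_hiv * 100.0
            )
        return vals

    rows = []
    for band in age_bands:
        if band not in BAND_MAP:
            raise ValueError(f"unknown age band {band!r}")
        vals = rates_for(history, band)
        comp = rates_for(comparator, band) if comparator is not None else None
        for metric, value in vals.items():
            if metric.startswith("_"):
                continue
            row = {
                "age_band": band,
                "metric": metric,
                "rate_per_100py": value,
                "defined": vals["_defined"],
            }
            if comp is not None and comp.get(metric, 0) not in (None,) and comp["_defined"]:
                denom = comp.get(metric, float("nan"))
                row["relative_risk"] = value / denom if denom else float("nan")
            rows.append(row)
    return pd.DataFrame(rows)
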