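"""Costs and disability-adjusted life years, with discounting.

Costs are tracked from the health-system perspective in four components —
community screening, clinic visits (including annual clinic training under
the chronic-care policies), antihypertensive drugs, and emergency CVD care —
per calendar year, both undiscounted and discounted to the policy start
year.  DALYs combine years lived with disability (chronic post-event
disability weights) and years of life lost (to age 80, all causes); no
person-time at or beyond age 80 accrues either.
"""

from __future__ import annotations

import math

import numpy as np

from .scenarios import COST_COMPONENTS, SettingScenario

__all__ = [
    "BASE_YEAR",
    "DALY_AGE_CAP",
    "DalyLedger",
    "EconLedger",
    "visit_cost",
    "visit_cost_array",
    "drug_cost",
    "discount",
    "years_of_life_lost",
    "accrue_quarter",
    "aggregate_costs",
    "budget_impact",
]

BASE_YEAR = 2024
DALY_AGE_CAP = 80.0


def discount(amount, years_from_base, rate: float):
    """Present value of ``amount`` accruing ``years_from_base`` after 2024."""
    if np.any(np.asarray(years_from_base) < 0):
        raise ValueError("years_from_base must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return amount / (1.0 + rate) ** years_from_base


def years_of_life_lost(age_at_death: float, rate: float = 0.0, years_from_base: float = 0.0):
    """Discounted YLL for a death before age 80.

    The remaining years to 80 are valued as a continuous stream starting at
    the time of death (itself discounted back to the base year).
    """
    L = np.maximum(DALY_AGE_CAP - np.asarray(age_at_death, dtype=float), 0.0)
    if rate == 0.0:
        return L * np.ones_like(np.asarray(years_from_base, dtype=float))
    lr = math.log1p(rate)
    return discount(1.0, years_from_base, rate) * (1.0 - (1.0 + rate) ** (-L)) / lr


def visit_cost(
    policy,
    integrated_this_visit: bool,
    controlled: bool,
    scenario: SettingScenario,
) -> float:
    """Cost (USD) of one hypertension clinic visit.

    Standalone visits cost $10 (uncontrolled, measured SBP >= 140) or $5
    (controlled).  Visits integrated with an HIV care visit cost nothing or
    half the standalone cost, depending on the scenario's integration mode.
    The scenario's clinic cost multiplier is applied exactly once, here.
    """
    return float(
        visit_cost_array(
            np.asarray([controlled]), np.asarray([integrated_this_visit]), scenario
        )[0]
    )


def visit_cost_array(
    controlled: np.ndarray, integrated: np.ndarray, scenario: SettingScenario
) -> np.ndarray:
    uc = scenario.unit_costs
    standalone = np.where(controlled, uc.visit_controlled, uc.visit_uncontrolled)
    if scenario.integrated_visit_mode == "zero_added_cost":
        cost = np.where(integrated, 0.0, standalone)
    else:
        cost = np.where(integrated, 0.5 * standalone, standalone)
    return cost * scenario.cost_multiplier_scenario.get("clinic", 1.0)


def drug_cost(n_drugs: int, scenario: SettingScenario) -> float:
    """Quarterly antihypertensive drug cost for ``n_drugs`` (0-3) drugs.

    First and second line cost $1.5 per quarter each, third line $3; the
    scenario's drug cost multiplier is applied exactly once, here.
    """
    if n_drugs not in (0, 1, 2, 3):
        raise ValueError(f"n_drugs must be 0-3, got {n_drugs}")
    uc = scenario.unit_costs
    base = min(n_drugs, 2) * uc.drug_quarter_line12 + (n_drugs == 3) * uc.drug_quarter_line3
    return base * scenario.cost_multiplier_scenario.get("drug", 1.0)


class DalyLedger:
    """Accumulates YLD and YLL, discounted and undiscounted."""

    def __init__(self, rate: float) -> None:
        self.rate = rate
        self.yld = 0.0
        self.yll = 0.0
        self.yld_undisc = 0.0
        self.yll_undisc = 0.0

    def add_yld(self, weights: np.ndarray, years: float, years_from_base: float) -> None:
        total = float(np.sum(weights)) * years
        self.yld_undisc += total
        self.yld += float(discount(total, years_from_base, self.rate))

    def add_yll(self, ages_at_death: np.ndarray, years_from_base: float) -> None:
        ages = np.asarray(ages_at_death, dtype=float)
        ages = ages[ages < DALY_AGE_CAP]
        if ages.size == 0:
            return
        self.yll_undisc += float(np.sum(DALY_AGE_CAP - ages))
        self.yll += float(np.sum(years_of_life_lost(ages, self.rate, years_from_base)))

    @property
    def total(self) -> float:
        return self.yld + self.yll

    @property
    def total_undisc(self) -> float:
        return self.yld_undisc + self.yll_undisc


class EconLedger:
    """Per-year cost components and DALYs for one scenario x policy run."""

    components = COST_COMPONENTS

    def __init__(
        self,
        start_quarter: int,
        horizon_years: int,
        rate: float,
        charge_training: bool = False,
    ) -> None:
        self.t0 = start_quarter
        self.horizon_years = horizon_years
        self.rate = rate
        self.charge_training = charge_training
        k = len(self.components)
        self.cost = np.zeros((horizon_years, k))  # discounted
        self.cost_undisc = np.zeros((horizon_years, k))
        self.dalys = DalyLedger(rate)
        self.person_years_15plus = np.zeros(horizon_years)
        self._accrued_quarters: set[int] = set()

    def years_from_base(self, t: int) -> float:
        """Mid-quarter offset in years from the base quarter."""
        return (t - self.t0) * 0.25 + 0.125

    def add_cost(self, component: str, t: int, amount: float) -> None:
        if not self.t0 <= t < self.t0 + 4 * self.horizon_years:
            return
        j = self.components.index(component)
        y = (t - self.t0) // 4
        self.cost_undisc[y, j] += amount
        self.cost[y, j] += float(discount(amount, self.years_from_base(t), self.rate))


def accrue_quarter(pop, scenario: SettingScenario, t: int, died_idx: np.ndarray, econ: EconLedger) -> None:
    """Accrue the per-quarter DALY, training-cost and person-time ledgers.

    Called exactly once per simulated quarter; a second call for the same
    quarter is an accounting error and raises.
    """
    if not econ.t0 <= t < econ.t0 + 4 * econ.horizon_years:
        return
    if t in econ._accrued_quarters:
        raise RuntimeError(f"ledger already accrued for quarter {t}")
    econ._accrued_quarters.add(t)

    yfb = econ.years_from_base(t)
    y = (t - econ.t0) // 4

    n = pop.n
    alive = pop.alive[:n]
    age = (t - pop.birth_q[:n]) * 0.25
    econ.person_years_15plus[y] += float(alive.sum()) * 0.25

    if econ.charge_training and t % 4 == 0:
        per_10k = scenario.unit_costs.clinic_training_annual_per_10k
        amount = (
            per_10k
            * (float(alive.sum()) / 10_000.0)
            * scenario.cost_multiplier_scenario.get("clinic", 1.0)
        )
        econ.add_cost("clinic", t, amount)

    with_disability = alive & (pop.disability_weight[:n] > 0) & (age < DALY_AGE_CAP)
    if with_disability.any():
        econ.dalys.add_yld(pop.disability_weight[:n][with_disability], 0.25, yfb)

    if died_idx.size:
        dage = (t - pop.birth_q[died_idx]) * 0.25
        econ.dalys.add_yll(dage, yfb)


def aggregate_costs(econ: EconLedger, scale_to: float) -> dict[str, float]:
    """Discounted component totals, rescaled to ``scale_to`` adults aged >= 15.

    Rescaling is linear in person-time: simulated totals are multiplied by
    ``scale_to`` over the mean number of simulated adults alive across the
    horizon.  The overall total is the exact sum of the components.
    """
    if scale_to <= 0:
        raise ValueError("scale_to must be > 0")
    mean_adults = econ.person_years_15plus.sum() / econ.horizon_years
    scale = scale_to / mean_adults if mean_adults > 0 else 0.0
    out = {
        comp: float(econ.cost[:, j].sum()) * scale
        for j, comp in enumerate(econ.components)
    }
    out["total"] = float(sum(out[c] for c in econ.components))
    return out


def budget_impact(econ: EconLedger, scale_to: float, years: int = 5):
    """Undiscounted annual costs by component for the first ``years`` years."""
    import pandas as pd

    if years > econ.horizon_years:
        raise ValueError("years exceeds the simulated horizon")
    mean_adults = econ.person_years_15plus.sum() / econ.horizon_years
    scale = scale_to / mean_adults if mean_adults > 0 else 0.0
    df = pd.DataFrame(
        econ.cost_undisc[:years] * scale,
        columns=list(econ.components),
        index=pd.Index(range(BASE_YEAR, BASE_YEAR + years), name="year"),
    )
    df["total"] = df.sum(axis=1)
    return df
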