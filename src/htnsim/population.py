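"""Individual-level population state and quarterly dynamics.

The population is held as a structure-of-arrays (one numpy array per
individual variable) so that a 3-month update over tens of thousands of
individuals is a handful of vectorized operations.  Time is indexed by
integer quarters with ``t = 0`` at 1989-Q1; ``age = (t - birth_q) / 4``.

Demography is deliberately simple: the initial adult pyramid decays
exponentially with age, background (non-CVD, non-HIV) mortality is a
two-parameter Gompertz per sex, and each quarter the deaths of the previous
quarter are replaced by new 15-year-old entrants, keeping the simulated
population size constant.  The analysis works with per-capita rates and
person-time scaling, so replacement demography is sufficient.
"""

from __future__ import annotations

import numpy as np

from .scenarios import SettingScenario

__all__ = [
    "Population",
    "START_YEAR",
    "quarter_of_year",
    "year_of_quarter",
    "init_population",
    "update_true_sbp",
    "step_quarter",
]

START_YEAR = 1989
#: Secular SBP trend applies to quarters after 2015, i.e. from 2016-Q1 on.
TREND_START_Q = (2016 - START_YEAR) * 4

_NO_VISIT = np.iinfo(np.int32).max
_NO_MEAS = -1.0e9

# HIV state codes
HIV_NEG, HIV_ART, HIV_UNTREATED = 0, 1, 2
# death cause codes
CAUSE_BACKGROUND, CAUSE_HIV, CAUSE_CVD_ACUTE, CAUSE_CVD_CHRONIC = 0, 1, 2, 3


def quarter_of_year(year: int) -> int:
    return (year - START_YEAR) * 4


def year_of_quarter(t: int) -> int:
    return START_YEAR + t // 4


class Population:
    """Structure-of-arrays container for the simulated individuals."""

    _FLOAT = ("sbp_pre", "last_meas", "prev_meas", "disability_weight", "chronic_q")
    _BOOL = (
        "alive",
        "never_engage",
        "diagnosed",
        "on_treatment",
        "ever_treated",
        "engaged",
        "adherent",
        "prior_ihd",
        "prior_stroke",
    )
    _INT = ("birth_q", "next_visit_q", "died_q")
    _INT8 = ("sex", "hiv", "n_drugs", "death_cause")

    def __init__(self, capacity: int) -> None:
        self.n = 0
        self.pending_entries = 0
        for name in self._FLOAT:
            setattr(self, name, np.zeros(capacity, dtype=np.float64))
        for name in self._BOOL:
            setattr(self, name, np.zeros(capacity, dtype=bool))
        for name in self._INT:
            setattr(self, name, np.zeros(capacity, dtype=np.int32))
        for name in self._INT8:
            setattr(self, name, np.zeros(capacity, dtype=np.int8))

    # -- storage ------------------------------------------------------------

    @property
    def capacity(self) -> int:
        return self.alive.shape[0]

    def _ensure(self, extra: int) -> None:
        need = self.n + extra
        if need <= self.capacity:
            return
        new_cap = max(need, 2 * self.capacity)
        for name in self._FLOAT + self._BOOL + self._INT + self._INT8:
            old = getattr(self, name)
            new = np.zeros(new_cap, dtype=old.dtype)
            new[: self.n] = old[: self.n]
            setattr(self, name, new)

    def copy(self) -> "Population":
        """Deep copy (used to branch policies off a shared burn-in state)."""
        out = Population(self.n)
        out.n = self.n
        out.pending_entries = self.pending_entries
        for name in self._FLOAT + self._BOOL + self._INT + self._INT8:
            setattr(out, name, getattr(self, name)[: self.n].copy())
        return out

    def state_digest(self) -> bytes:
        """Byte digest of the full state (for determinism checks)."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.int64(self.n).tobytes())
        for name in self._FLOAT + self._BOOL + self._INT + self._INT8:
            h.update(getattr(self, name)[: self.n].tobytes())
        return h.digest()

    def to_frame(self, t: int):
        """One-row-per-individual snapshot (debugging aid, CSV-friendly)."""
        import pandas as pd

        n = self.n
        return pd.DataFrame(
            {
                "person_id": np.arange(n),
                "alive": self.alive[:n],
                "sex": np.where(self.sex[:n] == 1, "M", "F"),
                "age": self.age(t),
                "sbp_pre": self.sbp_pre[:n],
                "hiv": self.hiv[:n],
                "diagnosed": self.diagnosed[:n],
                "engaged": self.engaged[:n],
                "on_treatment": self.on_treatment[:n],
                "n_drugs": self.n_drugs[:n],
                "adherent": self.adherent[:n],
                "prior_ihd": self.prior_ihd[:n],
                "prior_stroke": self.prior_stroke[:n],
                "disability_weight": self.disability_weight[:n],
            }
        )

    # -- derived ------------------------------------------------------------

    def age(self, t: int) -> np.ndarray:
        """Age in years at quarter ``t`` for all stored individuals."""
        return (t - self.birth_q[: self.n]) * 0.25

    def true_sbp(self, scenario: SettingScenario) -> np.ndarray:
        """Current true SBP: pre-treatment SBP minus the active drug effect.

        The drug effect applies only while engaged in care, on treatment and
        adherent, and is floored at the physiologic minimum.
        """
        n = self.n
        pre = self.sbp_pre[:n]
        active = self.engaged[:n] & self.on_treatment[:n] & self.adherent[:n]
        red = np.where(active, self.n_drugs[:n] * scenario.per_drug_sbp_reduction, 0.0)
        return np.maximum(pre - red, scenario.sbp_floor)

    def currently_treated(self) -> np.ndarray:
        """On antihypertensive drugs this quarter (dispensed and adherent)."""
        n = self.n
        return self.on_treatment[:n] & self.engaged[:n] & self.adherent[:n]

    # -- entry --------------------------------------------------------------

    def add_entrants(self, k: int, t: int, scenario: SettingScenario, rng: np.random.Generator) -> None:
        """Add ``k`` 15-year-old entrants at quarter ``t``."""
        if k <= 0:
            return
        self._ensure(k)
        sl = slice(self.n, self.n + k)
        sex = (rng.random(k) < 0.5).astype(np.int8)
        self.sex[sl] = sex
        self.birth_q[sl] = t - 60
        self.alive[sl] = True
        mean = scenario.mean_sbp_profile(np.full(k, 15.0), sex)
        self.sbp_pre[sl] = mean + rng.normal(0.0, scenario.sbp_sd, k)
        self.hiv[sl] = HIV_NEG
        self.never_engage[sl] = rng.random(k) < scenario.never_engage_frac
        self.last_meas[sl] = _NO_MEAS
        self.prev_meas[sl] = _NO_MEAS
        self.next_visit_q[sl] = _NO_VISIT
        self.died_q[sl] = -1
        # remaining flags/ledgers start at zero/False
        self.diagnosed[sl] = False
        self.on_treatment[sl] = False
        self.ever_treated[sl] = False
        self.engaged[sl] = False
        self.adherent[sl] = False
        self.prior_ihd[sl] = False
        self.prior_stroke[sl] = False
        self.n_drugs[sl] = 0
        self.disability_weight[sl] = 0.0
        self.chronic_q[sl] = 0.0
        self.death_cause[sl] = -1
        self.n += k


def init_population(
    scenario: SettingScenario,
    n_individuals: int,
    start_year: int = START_YEAR,
    rng: np.random.Generator | None = None,
) -> Population:
    """Create the initial adult population at ``start_year``.

    Ages 15-90 follow a truncated-exponential pyramid, HIV states are drawn to
    match the scenario's 15-49 prevalence in expectation, and all care-cascade
    flags start false.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    t0 = quarter_of_year(start_year)
    pop = Population(int(n_individuals * 2.2))
    n = n_individuals

    # truncated exponential ages on [15, 90]
    lam = scenario.init_age_decay
    u = rng.random(n)
    ages = 15.0 - np.log1p(-u * (1.0 - np.exp(-lam * 75.0))) / lam

    pop._ensure(n)
    sl = slice(0, n)
    sex = (rng.random(n) < 0.5).astype(np.int8)
    pop.sex[sl] = sex
    pop.birth_q[sl] = t0 - np.round(ages * 4.0).astype(np.int32)
    pop.alive[sl] = True

    mean = scenario.mean_sbp_profile(ages, sex)
    sd = np.sqrt(scenario.sbp_sd**2 + scenario.sbp_rw_sd**2 * 4.0 * (ages - 15.0))
    pop.sbp_pre[sl] = mean + rng.normal(0.0, 1.0, n) * sd

    hiv = np.zeros(n, dtype=np.int8)
    young = (ages >= 15.0) & (ages < 50.0)
    pos = young & (rng.random(n) < scenario.hiv_prevalence_15_49)
    on_art = pos & (rng.random(n) < scenario.hiv_art_coverage)
    hiv[pos] = HIV_UNTREATED
    hiv[on_art] = HIV_ART
    pop.hiv[sl] = hiv

    pop.never_engage[sl] = rng.random(n) < scenario.never_engage_frac
    pop.last_meas[sl] = _NO_MEAS
    pop.prev_meas[sl] = _NO_MEAS
    pop.next_visit_q[sl] = _NO_VISIT
    pop.died_q[sl] = -1
    pop.death_cause[sl] = -1
    pop.n = n
    return pop


def update_true_sbp(
    pop: Population, scenario: SettingScenario, t: int, rng: np.random.Generator
) -> None:
    """Advance pre-treatment SBP by one quarter for all living individuals.

    Adds the age-profile increment, the secular trend (per decade, after
    2015), and a mean-zero within-person random-walk step.
    """
    n = pop.n
    alive = pop.alive[:n]
    idx = np.flatnonzero(alive)
    age = (t - pop.birth_q[idx]) * 0.25
    sex = pop.sex[idx]
    delta = scenario.mean_sbp_profile(age + 0.25, sex) - scenario.mean_sbp_profile(age, sex)
    if t >= TREND_START_Q:
        delta = delta + scenario.sbp_secular_trend / 40.0
    if scenario.sbp_rw_sd > 0:
        delta = delta + rng.normal(0.0, scenario.sbp_rw_sd, idx.size)
    pop.sbp_pre[idx] += delta


def _hiv_incidence(pop: Population, scenario: SettingScenario, t: int, rng) -> None:
    n = pop.n
    age = pop.age(t)
    risk = pop.alive[:n] & (pop.hiv[:n] == HIV_NEG) & (age >= 15) & (age < 50)
    p = scenario.hiv_incidence_scalar * scenario.hiv_prevalence_15_49
    if p <= 0:
        return
    idx = np.flatnonzero(risk)
    inf = idx[rng.random(idx.size) < p]
    if inf.size:
        art = rng.random(inf.size) < scenario.hiv_art_coverage
        pop.hiv[inf] = np.where(art, HIV_ART, HIV_UNTREATED).astype(np.int8)


def _mortality(
    pop: Population, scenario: SettingScenario, t: int, rng: np.random.Generator
) -> np.ndarray:
    """Resolve background, HIV-excess and chronic-CVD mortality; returns died idx."""
    n = pop.n
    idx = np.flatnonzero(pop.alive[:n])
    age = (t - pop.birth_q[idx]) * 0.25
    a = np.where(pop.sex[idx] == 1, scenario.gompertz_a_m, scenario.gompertz_a_f)
    mu_yr = a * np.exp(scenario.gompertz_b * (age - 50.0))
    q_bg = 1.0 - np.exp(-mu_yr / 4.0)
    hiv = pop.hiv[idx]
    q_hiv = np.where(
        hiv == HIV_ART,
        scenario.hiv_excess_mortality["on_art"],
        np.where(hiv == HIV_UNTREATED, scenario.hiv_excess_mortality["untreated"], 0.0),
    )
    q_cvd = pop.chronic_q[idx]
    q_tot = 1.0 - (1.0 - q_bg) * (1.0 - q_hiv) * (1.0 - q_cvd)
    died = rng.random(idx.size) < q_tot
    didx = idx[died]
    if didx.size:
        # allocate cause proportionally to the component hazards
        w = np.stack([q_bg[died], q_hiv[died], q_cvd[died]], axis=1)
        w /= w.sum(axis=1, keepdims=True)
        u = rng.random(didx.size)
        cause = np.where(
            u < w[:, 0],
            CAUSE_BACKGROUND,
            np.where(u < w[:, 0] + w[:, 1], CAUSE_HIV, CAUSE_CVD_CHRONIC),
        )
        pop.alive[didx] = False
        pop.died_q[didx] = t
        pop.death_cause[didx] = cause.astype(np.int8)
    return didx


def step_quarter(
    pop: Population,
    scenario: SettingScenario,
    policy,
    t: int,
    rng: np.random.Generator,
    history=None,
    econ=None,
) -> None:
    """Advance the population by one 3-month step under ``policy``.

    Fixed update order: (1) entry of 15-year-olds replacing last quarter's
    deaths; (2) SBP drift; (3) HIV incidence; (4) care-cascade events
    (retention, CHW screening round, clinic visits, background presentations,
    adherence); (5) CVD events with acute outcomes; (6) background / HIV /
    chronic-CVD death resolution; (7) history and ledger accrual.  Events are
    drawn before death resolution so that event rates are not biased by
    within-quarter mortality.
    """
    from . import cascade, cvd, health_econ

    if policy.name not in ("SOC", "CCC", "CHW"):
        raise ValueError(f"unknown policy {policy.name!r}")

    pop.add_entrants(pop.pending_entries, t, scenario, rng)
    pop.pending_entries = 0

    update_true_sbp(pop, scenario, t, rng)
    _hiv_incidence(pop, scenario, t, rng)

    cascade.step_cascade(pop, scenario, policy, t, rng, econ=econ)
    events = cvd.step_cvd(pop, scenario, t, rng, econ=econ)
    _mortality(pop, scenario, t, rng)
    died_idx = np.flatnonzero(pop.died_q[: pop.n] == t)  # incl. acute CVD deaths

    if history is not None:
        history.record(pop, scenario, t, events, died_idx)
    if econ is not None:
        health_econ.accrue_quarter(pop, scenario, t, died_idx, econ)
    # replacement plus net growth of the adult population
    growth = 0
    if scenario.pop_growth_annual > 0:
        n_alive = int(pop.alive[: pop.n].sum())
        growth = int(rng.poisson(n_alive * scenario.pop_growth_annual / 4.0))
    pop.pending_entries = int(died_idx.size) + growth
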