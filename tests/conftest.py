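import numpy as np
import pytest

from htnsim.population import Population
from htnsim.scenarios import load_default_ranges, sample_scenario

_NO_VISIT = np.iinfo(np.int32).max


@pytest.fixture(scope="session")
def default_ranges():
    return load_default_ranges()


@pytest.fixture(scope="session")
def base_scenario():
    """One deterministic default-sampled scenario shared across tests."""
    return sample_scenario(0, 1234)


@pytest.fixture()
def scenario_with(base_scenario):
    """Factory: the base scenario with selected parameters pinned.

    Uses a validated copy where possible; tests may pin values outside the
    sampled choice sets (e.g. zero measurement noise) to isolate mechanisms.
    """

    def make(**updates):
        return base_scenario.model_copy(update=updates, deep=True)

    return make


@pytest.fixture()
def make_population(base_scenario):
    """Factory building a small population from explicit per-person rows.

    Each row is a dict with at least ``age``; other fields default to a
    healthy, undiagnosed, HIV-negative adult.  ``t`` is the current quarter.
    """

    def build(rows, t=0, scenario=None):
        pop = Population(max(len(rows), 1))
        k = len(rows)
        pop._ensure(k)
        for i, row in enumerate(rows):
            pop.alive[i] = row.get("alive", True)
            pop.sex[i] = row.get("sex", 0)
            pop.birth_q[i] = t - int(round(row["age"] * 4))
            pop.sbp_pre[i] = row.get("sbp_pre", 120.0)
            pop.hiv[i] = row.get("hiv", 0)
            pop.never_engage[i] = row.get("never_engage", False)
            pop.diagnosed[i] = row.get("diagnosed", False)
            pop.on_treatment[i] = row.get("on_treatment", False)
            pop.ever_treated[i] = row.get("ever_treated", row.get("on_treatment", False))
            pop.engaged[i] = row.get("engaged", row.get("on_treatment", False))
            pop.adherent[i] = row.get("adherent", row.get("on_treatment", False))
            pop.n_drugs[i] = row.get("n_drugs", 0)
            pop.last_meas[i] = row.get("last_meas", -1.0e9)
            pop.prev_meas[i] = row.get("prev_meas", -1.0e9)
            pop.next_visit_q[i] = row.get("next_visit_q", _NO_VISIT)
            pop.disability_weight[i] = row.get("disability_weight", 0.0)
            pop.chronic_q[i] = row.get("chronic_q", 0.0)
            pop.prior_ihd[i] = row.get("prior_ihd", False)
            pop.prior_stroke[i] = row.get("prior_stroke", False)
            pop.died_q[i] = row.get("died_q", -1)
        pop.n = k
        return pop

    return build


@pytest.fixture(scope="session")
def soc_history(base_scenario):
    """A short standard-of-care run used by several invariant tests."""
    from htnsim.runner import run_soc_calibration

    return run_soc_calibration(base_scenario, 6000, end_year=2016)
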