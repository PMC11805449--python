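"""Per-quarter, per-age-band accumulators recorded during a simulation run.

Cascade and CVD summary metrics are person-time weighted, so the engine
records small per-quarter tallies (counts by fine age band) rather than full
population snapshots.  Fine bands are aggregated on demand into the summary
bands the analysis reports (18+, 25-44, 45-64, 65+, and the 10-year bands).
"""

from __future__ import annotations

import numpy as np

FINE_EDGES = np.array([18.0, 25.0, 35.0, 45.0, 55.0, 65.0, 75.0])
FINE_BANDS = ("15-17", "18-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75+")
N_FINE = len(FINE_BANDS)

#: Summary band -> indices of the fine bands it aggregates.
BAND_MAP: dict[str, tuple[int, ...]] = {
    "15+": tuple(range(8)),
    "18+": tuple(range(1, 8)),
    "25-34": (2,),
    "35-44": (3,),
    "45-54": (4,),
    "55-64": (5,),
    "25-44": (2, 3),
    "45-64": (4, 5),
    "65+": (6, 7),
}

_FIELDS = (
    "pt",  # person-quarters alive
    "hyp",  # true (current-or-pre-treatment) SBP >= 140
    "hyp_diag",
    "hyp_treat",  # currently on drugs and adherent
    "hyp_ever_treat",
    "hyp_controlled",  # hypertensive with current true SBP < 140
    "norm_diag",  # overdiagnosed
    "norm_treat",  # overtreated
    "sum_true_sbp",
    "overdx_sum_pre_sbp",
    "ihd_ms",  # moderate/severe events
    "stroke_ms",
    "ihd_all",
    "stroke_all",
    "deaths_all",
    "deaths_cvd",
    "pt_hiv",
    "deaths_all_hiv",
    "deaths_cvd_hiv",
)


def fine_band_index(age: np.ndarray) -> np.ndarray:
    return np.digitize(age, FINE_EDGES)


class QuarterlyHistory:
    """Fixed-horizon store of per-quarter, per-fine-band tallies."""

    def __init__(self, n_quarters: int) -> None:
        self.n_quarters = n_quarters
        self.recorded = np.zeros(n_quarters, dtype=bool)
        for f in _FIELDS:
            setattr(self, f, np.zeros((n_quarters, N_FINE)))

    def record(self, pop, scenario, t: int, events: dict, died_idx: np.ndarray) -> None:
        """Tally the end-of-quarter state (survivors) plus this quarter's
        events and deaths."""
        n = pop.n
        alive = pop.alive[:n]
        idx = np.flatnonzero(alive)
        age = (t - pop.birth_q[idx]) * 0.25
        band = fine_band_index(age)

        def tally(mask_or_weights) -> np.ndarray:
            return np.bincount(band, weights=mask_or_weights, minlength=N_FINE)

        true_sbp = pop.true_sbp(scenario)[idx]
        pre = pop.sbp_pre[idx]
        hyp = pre >= 140.0
        diag = pop.diagnosed[idx]
        cur = pop.currently_treated()[idx]
        ever = pop.ever_treated[idx]
        ctrl = hyp & (true_sbp < 140.0)
        norm = ~hyp

        self.pt[t] += tally(np.ones(idx.size))
        self.hyp[t] += tally(hyp.astype(float))
        self.hyp_diag[t] += tally((hyp & diag).astype(float))
        self.hyp_treat[t] += tally((hyp & cur).astype(float))
        self.hyp_ever_treat[t] += tally((hyp & ever).astype(float))
        self.hyp_controlled[t] += tally(ctrl.astype(float))
        self.norm_diag[t] += tally((norm & diag).astype(float))
        self.norm_treat[t] += tally((norm & diag & cur).astype(float))
        self.sum_true_sbp[t] += tally(true_sbp)
        self.overdx_sum_pre_sbp[t] += tally(np.where(norm & diag, pre, 0.0))
        self.pt_hiv[t] += tally((pop.hiv[idx] > 0).astype(float))

        for key in ("ihd_ms", "stroke_ms", "ihd_all", "stroke_all"):
            getattr(self, key)[t] += events.get(key, 0.0)

        if died_idx.size:
            dage = (t - pop.birth_q[died_idx]) * 0.25
            dband = fine_band_index(dage)
            cvd_death = pop.death_cause[died_idx] >= 2  # acute or chronic CVD
            hiv_pos = pop.hiv[died_idx] > 0
            self.deaths_all[t] += np.bincount(dband, minlength=N_FINE)
            self.deaths_cvd[t] += np.bincount(
                dband, weights=cvd_death.astype(float), minlength=N_FINE
            )
            self.deaths_all_hiv[t] += np.bincount(
                dband, weights=hiv_pos.astype(float), minlength=N_FINE
            )
            self.deaths_cvd_hiv[t] += np.bincount(
                dband, weights=(cvd_death & hiv_pos).astype(float), minlength=N_FINE
            )
        self.recorded[t] = True

    # -- aggregation --------------------------------------------------------

    def window_sum(self, field: str, quarters: slice, band: str) -> float:
        """Sum a tally over a quarter slice and a summary band."""
        arr = getattr(self, field)[quarters]
        cols = list(BAND_MAP[band])
        return float(arr[:, cols].sum())

    def quarters_of_years(self, start_year: int, end_year: int, t0_year: int) -> slice:
        """Quarter slice covering calendar years [start_year, end_year]."""
        lo = (start_year - t0_year) * 4
        hi = (end_year - t0_year + 1) * 4
        if lo < 0 or hi > self.n_quarters:
            raise ValueError(
                f"window {start_year}-{end_year} outside the simulated span"
            )
        return slice(lo, hi)
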