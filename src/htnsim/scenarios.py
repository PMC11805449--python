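"""Setting-scenario definition and sampling.

A *setting-scenario* is one sampled parameter vector describing a simulated
setting: the baseline SBP distribution and its drift, the care-cascade
propensities (clinic contact, screening, linkage, treatment, retention), a
reduced HIV layer, CVD incidence and severity parameters, and unit costs.
Scenarios are sampled independently from a plain-text configuration of
ranges/choice sets; the shipped defaults live in ``data/default_ranges.yaml``.

Every scenario is reproducible from ``(master_seed, scenario_id)`` alone and
serializes to versioned JSON with a schema check on load.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "AGE_BANDS",
    "BAND_MIDPOINTS",
    "CALIBRATION_ENVELOPES",
    "ConfigError",
    "CostSchedule",
    "RetentionParams",
    "SettingScenario",
    "load_default_ranges",
    "load_ranges",
    "sample_scenario",
    "sample_scenarios",
    "read_scenarios",
    "write_scenarios",
    "validate_calibration",
]

SCHEMA_VERSION = "1"

#: Ten-year age bands used for SBP profiles and clinic-contact propensities.
AGE_BANDS = ("15-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75+")
BAND_MIDPOINTS = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)

_SECULAR_TRENDS = (0.0, 0.5, 1.0)
_CARE_SEEK_SET = (0.2, 0.4, 0.8)
_CARE_EFFECTIVE_SET = (0.125, 0.25, 0.5)
_INEFFECTIVE_COST_SET = (0.25, 0.5, 1.0)
_COST_FACTOR_SET = (0.25, 0.5, 1.0, 2.0, 4.0)
COST_COMPONENTS = ("screening", "clinic", "drug", "cvd_care")


class ConfigError(ValueError):
    """A sampling configuration is missing a field or holds an invalid value."""


class CostSchedule(BaseModel):
    """Unit costs (2024 USD) from the health-system perspective."""

    chw_screen_per_person: float = 3.0
    visit_uncontrolled: float = 10.0
    visit_controlled: float = 5.0
    drug_quarter_line12: float = 1.5
    drug_quarter_line3: float = 3.0
    clinic_training_annual_per_10k: float = 2000.0
    acute_cvd_effective: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "IHD": {"mild": 0.0, "moderate": 1200.0, "severe": 2500.0},
            "stroke": {"mild": 0.0, "moderate": 1500.0, "severe": 3000.0},
        }
    )

    @model_validator(mode="after")
    def _nonnegative(self) -> "CostSchedule":
        for name in (
            "chw_screen_per_person",
            "visit_uncontrolled",
            "visit_controlled",
            "drug_quarter_line12",
            "drug_quarter_line3",
            "clinic_training_annual_per_10k",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"unit cost {name} must be >= 0")
        for per_type in self.acute_cvd_effective.values():
            if any(v < 0 for v in per_type.values()):
                raise ValueError("acute CVD costs must be >= 0")
        return self


class RetentionParams(BaseModel):
    """Per-quarter disengagement and re-engagement probabilities."""

    disengage: float = Field(ge=0.0, le=1.0)
    reengage: float = Field(ge=0.0, le=1.0)


def _prob(v: float, name: str) -> float:
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
    return v


class SettingScenario(BaseModel):
    """One sampled parameter vector defining a simulated setting."""

    schema_version: str = SCHEMA_VERSION
    scenario_id: int
    seed: int

    # -- blood pressure dynamics -------------------------------------------
    sbp_baseline_mean_by_age_sex: dict[str, dict[str, float]]
    sbp_sd: float = Field(gt=0.0)  # between-person SD at entry, mmHg
    sbp_rw_sd: float = Field(ge=0.0)  # within-person random walk, mmHg/quarter
    sbp_age_slope: float  # extra profile tilt, mmHg per year about age 50
    sbp_secular_trend: float  # mmHg per decade after 2015
    sbp_floor: float = 90.0
    measurement_noise_sd: float = Field(ge=0.0)

    # -- care cascade -------------------------------------------------------
    clinic_presentation_prob: dict[str, float]  # per-quarter, by age band
    hiv_clinic_presentation_prob: float
    chw_coverage: float
    linkage_prob: float
    treat_initiation_prob: float
    adherence_prob: float
    never_engage_frac: float
    per_drug_sbp_reduction: float = Field(ge=0.0)
    retention_params: dict[str, RetentionParams]

    # -- HIV layer ----------------------------------------------------------
    hiv_prevalence_15_49: float
    hiv_art_coverage: float
    hiv_cvd_rr: float = Field(ge=1.0)
    hiv_excess_mortality: dict[str, float]  # per-quarter, keys on_art/untreated
    hiv_incidence_scalar: float = Field(ge=0.0)

    # -- cardiovascular disease --------------------------------------------
    cvd_base_rate_scalar: dict[str, float]  # keys IHD/stroke
    cvd_base_quarterly: dict[str, float]
    cvd_age_log_slope: float
    cvd_sex_mult: dict[str, dict[str, float]]
    rr10_age50: float = Field(gt=0.0, le=1.0)
    rr10_age80: float = Field(gt=0.0, le=1.0)
    severity_probs: dict[str, tuple[float, float, float]]  # mild/moderate/severe
    acute_mortality: dict[str, dict[str, float]]
    effective_care_mortality_reduction: float
    care_seek_prob: float
    care_effective_prob: float
    chronic_cvd_mortality: dict[str, float]  # per-quarter by worst severity
    prior_cvd_rr: float = Field(ge=1.0)
    disability_weights: dict[str, dict[str, float]]

    # -- economics ----------------------------------------------------------
    unit_costs: CostSchedule = Field(default_factory=CostSchedule)
    ineffective_cost_fraction: float
    integrated_visit_mode: Literal["zero_added_cost", "half_standalone_cost"]
    cost_multiplier_scenario: dict[str, float] = Field(
        default_factory=lambda: {c: 1.0 for c in COST_COMPONENTS}
    )

    # -- demography ---------------------------------------------------------
    gompertz_a_f: float = Field(gt=0.0)
    gompertz_a_m: float = Field(gt=0.0)
    gompertz_b: float = Field(gt=0.0)
    init_age_decay: float = Field(gt=0.0)
    pop_growth_annual: float = Field(ge=0.0, default=0.0)

    @field_validator("sbp_secular_trend")
    @classmethod
    def _trend_in_set(cls, v: float) -> float:
        if v not in _SECULAR_TRENDS:
            raise ValueError(f"sbp_secular_trend must be one of {_SECULAR_TRENDS}, got {v}")
        return v

    @field_validator("care_seek_prob")
    @classmethod
    def _seek_in_set(cls, v: float) -> float:
        if v not in _CARE_SEEK_SET:
            raise ValueError(f"care_seek_prob must be one of {_CARE_SEEK_SET}, got {v}")
        return v

    @field_validator("care_effective_prob")
    @classmethod
    def _eff_in_set(cls, v: float) -> float:
        if v not in _CARE_EFFECTIVE_SET:
            raise ValueError(f"care_effective_prob must be one of {_CARE_EFFECTIVE_SET}, got {v}")
        return v

    @field_validator("ineffective_cost_fraction")
    @classmethod
    def _frac_in_set(cls, v: float) -> float:
        if v not in _INEFFECTIVE_COST_SET:
            raise ValueError(
                f"ineffective_cost_fraction must be one of {_INEFFECTIVE_COST_SET}, got {v}"
            )
        return v

    @field_validator("severity_probs")
    @classmethod
    def _severity_simplex(cls, v: dict) -> dict:
        for etype, probs in v.items():
            if len(probs) != 3 or any(p < 0 for p in probs):
                raise ValueError(f"severity_probs[{etype}] must be 3 probabilities >= 0")
            if not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
                raise ValueError(f"severity_probs[{etype}] must sum to 1, got {sum(probs)}")
        return v

    @field_validator("cost_multiplier_scenario")
    @classmethod
    def _factors_in_set(cls, v: dict[str, float]) -> dict[str, float]:
        for comp, f in v.items():
            if comp not in COST_COMPONENTS:
                raise ValueError(f"unknown cost component {comp!r}")
            if f not in _COST_FACTOR_SET:
                raise ValueError(f"cost multiplier for {comp} must be in {_COST_FACTOR_SET}")
        return v

    @model_validator(mode="after")
    def _probabilities(self) -> "SettingScenario":
        for name in (
            "hiv_clinic_presentation_prob",
            "chw_coverage",
            "linkage_prob",
            "treat_initiation_prob",
            "adherence_prob",
            "never_engage_frac",
            "hiv_prevalence_15_49",
            "hiv_art_coverage",
            "effective_care_mortality_reduction",
        ):
            _prob(getattr(self, name), name)
        for band, p in self.clinic_presentation_prob.items():
            _prob(p, f"clinic_presentation_prob[{band}]")
        for k, p in self.hiv_excess_mortality.items():
            _prob(p, f"hiv_excess_mortality[{k}]")
        for etype, per_sev in self.acute_mortality.items():
            for sev, p in per_sev.items():
                _prob(p, f"acute_mortality[{etype}][{sev}]")
        for sev, p in self.chronic_cvd_mortality.items():
            _prob(p, f"chronic_cvd_mortality[{sev}]")
        return self

    # -- derived helpers ----------------------------------------------------

    def mean_sbp_profile(self, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
        """Population mean pre-treatment SBP at ``age`` for ``sex`` (1=M, 0=F)."""
        mids = np.asarray(BAND_MIDPOINTS)
        vals_m = np.array([self.sbp_baseline_mean_by_age_sex[b]["M"] for b in AGE_BANDS])
        vals_f = np.array([self.sbp_baseline_mean_by_age_sex[b]["F"] for b in AGE_BANDS])
        base = np.where(
            np.asarray(sex) == 1,
            np.interp(age, mids, vals_m),
            np.interp(age, mids, vals_f),
        )
        return base

    def presentation_prob(self, age: np.ndarray) -> np.ndarray:
        """Per-quarter clinic-contact probability by age."""
        edges = np.array([25.0, 35.0, 45.0, 55.0, 65.0, 75.0])
        probs = np.array([self.clinic_presentation_prob[b] for b in AGE_BANDS])
        return probs[np.digitize(age, edges)]


# ---------------------------------------------------------------------------
# sampling configuration
# ---------------------------------------------------------------------------


def load_default_ranges() -> dict:
    """Load the shipped default sampling configuration."""
    text = resources.files("htnsim.data").joinpath("default_ranges.yaml").read_text()
    return yaml.safe_load(text)


def load_ranges(path: str | Path) -> dict:
    """Load a sampling configuration from a YAML or JSON file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _is_leaf(node: Any) -> bool:
    return isinstance(node, dict) and set(node) & {"uniform", "loguniform", "choices", "const"}


def _sample_leaf(node: dict, rng: np.random.Generator) -> Any:
    if "const" in node:
        return node["const"]
    if "uniform" in node:
        lo, hi = node["uniform"]
        return float(rng.uniform(lo, hi))
    if "loguniform" in node:
        lo, hi = node["loguniform"]
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if "choices" in node:
        opts = node["choices"]
        return opts[int(rng.integers(len(opts)))]
    raise ConfigError(f"unrecognized sampling spec: {node!r}")


def _sample_tree(node: Any, rng: np.random.Generator) -> Any:
    if _is_leaf(node):
        return _sample_leaf(node, rng)
    if isinstance(node, dict):
        return {k: _sample_tree(v, rng) for k, v in node.items()}
    return node


class _Raw:
    """Wraps the sampled raw tree; attribute errors name the missing field."""

    def __init__(self, tree: dict, path: str = "") -> None:
        self._tree = tree
        self._path = path

    def __getitem__(self, key: str) -> Any:
        here = f"{self._path}.{key}" if self._path else key
        try:
            val = self._tree[key]
        except (KeyError, TypeError):
            raise ConfigError(f"sampling configuration is missing field {here!r}") from None
        if isinstance(val, dict):
            return _Raw(val, here)
        return val

    def raw(self, key: str) -> Any:
        val = self[key]
        return val._tree if isinstance(val, _Raw) else val


def _assemble(raw_tree: dict, scenario_id: int, seed: int) -> SettingScenario:
    r = _Raw(raw_tree)
    sbp, care, hiv, cvd, econ, demo = (
        r["sbp"], r["care"], r["hiv"], r["cvd"], r["econ"], r["demography"]
    )

    anchors = {float(k): float(v) for k, v in sbp.raw("anchors").items()}
    shift, tilt, off = sbp["level_shift"], sbp["tilt_per_year"], sbp["sex_offset"]
    profile = {}
    for band, mid in zip(AGE_BANDS, BAND_MIDPOINTS):
        centre = anchors[mid] + shift + tilt * (mid - 50.0)
        profile[band] = {"M": centre + off, "F": centre - off}

    base_p = care["presentation_base"]
    mult = care.raw("presentation_age_mult")
    presentation = {band: float(base_p) * float(mult[band]) for band in AGE_BANDS}

    ret = care["retention"]
    retention = {
        "SOC": RetentionParams(disengage=ret["soc_disengage"], reengage=ret["soc_reengage"]),
        "CCC": RetentionParams(disengage=ret["ccc_disengage"], reengage=ret["ccc_reengage"]),
        "CHW": RetentionParams(disengage=ret["ccc_disengage"], reengage=ret["ccc_reengage"]),
    }

    def _simplex(mild: float, severe: float) -> tuple[float, float, float]:
        return (mild, 1.0 - mild - severe, severe)

    return SettingScenario(
        schema_version=str(r["schema_version"]),
        scenario_id=scenario_id,
        seed=seed,
        sbp_baseline_mean_by_age_sex=profile,
        sbp_sd=sbp["sd_between"],
        sbp_rw_sd=sbp["rw_sd"],
        sbp_age_slope=tilt,
        sbp_secular_trend=sbp["secular_trend"],
        sbp_floor=sbp["floor"],
        measurement_noise_sd=r["measurement_noise_sd"],
        clinic_presentation_prob=presentation,
        hiv_clinic_presentation_prob=care["hiv_clinic_presentation_prob"],
        chw_coverage=care["chw_coverage"],
        linkage_prob=care["linkage_prob"],
        treat_initiation_prob=care["treat_initiation_prob"],
        adherence_prob=care["adherence_prob"],
        never_engage_frac=care["never_engage_frac"],
        per_drug_sbp_reduction=care["per_drug_sbp_reduction"],
        retention_params=retention,
        hiv_prevalence_15_49=hiv["prevalence_15_49"],
        hiv_art_coverage=hiv["art_coverage"],
        hiv_cvd_rr=hiv["cvd_rr"],
        hiv_excess_mortality={
            "on_art": hiv["excess_mortality_on_art"],
            "untreated": hiv["excess_mortality_untreated"],
        },
        hiv_incidence_scalar=hiv["incidence_scalar"],
        cvd_base_rate_scalar={
            "IHD": cvd["base_rate_scalar_ihd"],
            "stroke": cvd["base_rate_scalar_stroke"],
        },
        cvd_base_quarterly={
            "IHD": cvd["base_quarterly_ihd"],
            "stroke": cvd["base_quarterly_stroke"],
        },
        cvd_age_log_slope=cvd["age_log_slope"],
        cvd_sex_mult=cvd.raw("sex_mult"),
        rr10_age50=cvd["rr10_age50"],
        rr10_age80=cvd["rr10_age80"],
        severity_probs={
            "IHD": _simplex(cvd["severity_mild_ihd"], cvd["severity_severe_ihd"]),
            "stroke": _simplex(cvd["severity_mild_stroke"], cvd["severity_severe_stroke"]),
        },
        acute_mortality=cvd.raw("acute_mortality"),
        effective_care_mortality_reduction=cvd["effective_care_mortality_reduction"],
        care_seek_prob=cvd["care_seek_prob"],
        care_effective_prob=cvd["care_effective_prob"],
        chronic_cvd_mortality=cvd.raw("chronic_mortality"),
        prior_cvd_rr=cvd["prior_cvd_rr"],
        disability_weights=cvd.raw("disability_weights"),
        unit_costs=CostSchedule(**econ.raw("unit_costs")),
        ineffective_cost_fraction=econ["ineffective_cost_fraction"],
        integrated_visit_mode=econ["integrated_visit_mode"],
        cost_multiplier_scenario=econ.raw("cost_multipliers"),
        gompertz_a_f=demo["gompertz_a_f"],
        gompertz_a_m=demo["gompertz_a_m"],
        gompertz_b=demo["gompertz_b"],
        init_age_decay=demo["init_age_decay"],
        pop_growth_annual=demo["pop_growth_annual"],
    )


def sample_scenario(
    scenario_id: int, master_seed: int, ranges: dict | None = None
) -> SettingScenario:
    """Sample one setting-scenario.

    The RNG stream depends only on ``(master_seed, scenario_id)``, so scenario
    ``k`` is identical regardless of how many scenarios are drawn.
    """
    if ranges is None:
        ranges = load_default_ranges()
    seed = int(
        np.random.SeedSequence([int(master_seed), int(scenario_id)]).generate_state(1)[0]
        % (2**31 - 1)
    )
    rng = np.random.default_rng([int(master_seed), int(scenario_id), 0xA5])
    raw = _sample_tree(ranges, rng)
    return _assemble(raw, scenario_id, seed)


def sample_scenarios(
    n: int, master_seed: int, ranges: dict | None = None
) -> list[SettingScenario]:
    """Sample ``n`` independent setting-scenarios deterministically."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if ranges is None:
        ranges = load_default_ranges()
    return [sample_scenario(i, master_seed, ranges) for i in range(n)]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_scenarios(scenarios: Iterable[SettingScenario], path: str | Path) -> None:
    """Write scenarios to a JSON-lines file (one scenario per line)."""
    with open(path, "w") as fh:
        for sc in scenarios:
            fh.write(sc.model_dump_json() + "\n")


def read_scenarios(path: str | Path) -> list[SettingScenario]:
    """Read scenarios from a JSON-lines file, validating the schema."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            data = json.loads(line)
            if str(data.get("schema_version")) != SCHEMA_VERSION:
                raise ConfigError(
                    f"unsupported scenario schema version {data.get('schema_version')!r}"
                )
            out.append(SettingScenario.model_validate(data))
    return out


# ---------------------------------------------------------------------------
# calibration envelopes
# ---------------------------------------------------------------------------

#: Published 90% calibration envelopes (percent) for standard-of-care cascade
#: output averaged over 2013-2016, by metric and age band.
CALIBRATION_ENVELOPES: dict[str, dict[str, tuple[float, float]]] = {
    "prevalence": {
        "25-34": (13.0, 22.0),
        "35-44": (17.0, 35.0),
        "45-54": (26.0, 50.0),
        "55-64": (37.0, 60.0),
        "65+": (47.0, 67.0),
        "45-64": (30.0, 54.0),
    },
    "diagnosed": {
        "25-34": (6.0, 16.0),
        "35-44": (9.0, 24.0),
        "45-54": (15.0, 36.0),
        "55-64": (20.0, 44.0),
        "65+": (25.0, 52.0),
        "45-64": (18.0, 40.0),
    },
    "treated": {
        "18+": (2.0, 8.0),
        "25-44": (1.0, 4.0),
        "45-64": (3.0, 12.0),
        "65+": (3.0, 16.0),
    },
    "controlled": {
        "18+": (1.0, 5.0),
        "25-44": (0.0, 3.0),
        "45-64": (1.0, 7.1),
        "65+": (1.0, 9.0),
    },
}


def validate_calibration(scenario: SettingScenario, soc_metrics) -> "pd.DataFrame":
    """Check standard-of-care cascade metrics against the calibration envelopes.

    ``soc_metrics`` is a tidy frame as returned by
    :func:`htnsim.cascade.cascade_metrics` for a standard-of-care run averaged
    over 2013-2016, indexed by (age_band, metric) with a ``value`` column on
    the proportion scale.

    Returns a frame with one row per envelope entry, the simulated value (in
    percent), the envelope bounds, and an ``inside`` flag.
    """
    import pandas as pd

    rows = []
    lookup = soc_metrics.set_index(["age_band", "metric"])["value"]
    for metric, bands in CALIBRATION_ENVELOPES.items():
        for band, (lo, hi) in bands.items():
            try:
                val = 100.0 * float(lookup.loc[(band, metric)])
            except KeyError:
                raise ValueError(
                    f"soc_metrics does not cover metric {metric!r} in band {band!r}"
                ) from None
            rows.append(
                {
                    "scenario_id": scenario.scenario_id,
                    "metric": metric,
                    "age_band": band,
                    "value_pct": val,
                    "lower_pct": lo,
                    "upper_pct": hi,
                    "inside": bool(lo <= val <= hi),
                }
            )
    return pd.DataFrame(rows)
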