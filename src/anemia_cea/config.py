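"""Model inputs: parameter types, validation, defaults, and config I/O.

Every input of the decision model lives in a frozen dataclass with its
invariants enforced at construction time.  The module also exposes a flat
parameter registry (:data:`PARAMETER_TABLE`) mapping dotted names to
locations inside the bundle, together with the uncertainty range and
distribution family used by the sensitivity analyses, plus CSV export /
re-import of the whole table.

Units follow the sources: event rates are per patient-month, the
hospitalization rate and costs are per patient-year, utilities are
preference weights on [0, 1].  Rates are converted only inside the cohort
engine; the bundle stores source values verbatim.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .errors import ConfigError, ValidationError

__all__ = [
    "CohortProfile",
    "SurvivalAnchors",
    "TierProfile",
    "HospitalizationInputs",
    "HypertensionInputs",
    "EconomicInputs",
    "ScenarioFlags",
    "ModelSettings",
    "ParameterBundle",
    "ParamDef",
    "PARAMETER_TABLE",
    "default_bundle",
    "load_config",
    "cpi_adjust",
    "export_parameter_table",
    "import_parameter_table",
]


def _check(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValidationError(field_name, msg)


@dataclass(frozen=True)
class CohortProfile:
    """Baseline cohort at model entry.

    The survival anchors are already adjusted for age, sex and primary
    renal disease, so these fields are descriptive metadata: they are
    validated but never enter the computation.
    """

    start_age: int = 67
    male_fraction: float = 0.63
    disease_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "diabetes": 0.24,
            "hypertension_vascular": 0.19,
            "glomerulonephritis": 0.11,
            "other": 0.46,
        }
    )

    def __post_init__(self):
        _check(18 <= self.start_age < 100, "cohort.start_age", "must be in [18, 100)")
        _check(0.0 <= self.male_fraction <= 1.0, "cohort.male_fraction", "must be in [0, 1]")
        total = sum(self.disease_mix.values())
        _check(abs(total - 1.0) <= 1e-9, "cohort.disease_mix",
               f"proportions sum to {total!r}, expected 1.0")
        for k, v in self.disease_mix.items():
            _check(0.0 <= v <= 1.0, f"cohort.disease_mix.{k}", "must be in [0, 1]")


@dataclass(frozen=True)
class SurvivalAnchors:
    """Registry cumulative survival at 1, 2 and 5 years after dialysis start."""

    s1: float = 0.857
    s2: float = 0.755
    s5: float = 0.474
    #: optional constant annual death probability used beyond year 5 instead
    #: of the rate implied by the year 2-5 hazard (sensitivity analysis knob)
    tail_annual_mortality_override: Optional[float] = None

    def __post_init__(self):
        _check(1.0 > self.s1 > self.s2 > self.s5 > 0.0, "anchors",
               f"require 1 > s1 > s2 > s5 > 0, got ({self.s1}, {self.s2}, {self.s5})")
        if self.tail_annual_mortality_override is not None:
            _check(0.0 < self.tail_annual_mortality_override < 1.0,
                   "anchors.tail_annual_mortality_override", "must be in (0, 1)")


@dataclass(frozen=True)
class TierProfile:
    """Comparator-tier baseline event rates and intervention effect sizes.

    Tiers stratify comparator clinics by hemoglobin-target achievement
    (tier 1 < 70%, tier 2 70-80%, tier 3 > 80% of patients in range).
    Event rates are events per patient-month; relative risks apply to the
    intervention arm; ``diff_esa_free_months`` is the additional proportion
    of patient-months without any ESA administration.
    """

    tier_id: int
    inappropriate_esa_rate: float
    severe_anemia_rate: float
    rr_inappropriate_esa: float
    rr_severe_anemia: float
    diff_esa_free_months: float

    def __post_init__(self):
        p = f"tiers.{self.tier_id}"
        _check(self.tier_id in (1, 2, 3), "tier_id", "must be 1, 2 or 3")
        for name in ("inappropriate_esa_rate", "severe_anemia_rate"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{p}.{name}", "monthly rate must be in [0, 1]")
        for name in ("rr_inappropriate_esa", "rr_severe_anemia"):
            _check(getattr(self, name) > 0.0, f"{p}.{name}", "relative risk must be > 0")
        _check(0.0 <= self.diff_esa_free_months <= 1.0,
               f"{p}.diff_esa_free_months", "must be in [0, 1]")


@dataclass(frozen=True)
class HospitalizationInputs:
    base_rate_per_year: float = 0.836          # admissions per patient-year, no intervention
    arr: float = 0.126                         # absolute risk reduction, admissions/patient-year
    drg_cost: float = 4210.59                  # € per admission (DRG national base rate)

    def __post_init__(self):
        _check(self.drg_cost > 0.0, "hospitalization.drg_cost", "must be > 0")
        _check(0.0 <= self.arr <= self.base_rate_per_year, "hospitalization.arr",
               "must satisfy 0 <= arr <= base_rate_per_year")


@dataclass(frozen=True)
class HypertensionInputs:
    """ESA-attributable hypertension: prevalence shift and management costs."""

    baseline_prevalence: float = 0.92
    or_esa: float = 2.10                       # odds ratio, hypertension under ESA vs control
    atenolol_pack_cost: float = 23.31          # € per 100 tablets of 100 mg
    tablets_per_year: int = 156                # 100 mg three times weekly
    visit_fee: float = 18.34                   # € per outpatient visit
    visits_per_year: int = 2

    def __post_init__(self):
        _check(0.0 < self.baseline_prevalence < 1.0,
               "hypertension.baseline_prevalence", "must be in (0, 1)")
        _check(self.or_esa > 0.0, "hypertension.or_esa", "must be > 0")
        for name in ("atenolol_pack_cost", "visit_fee"):
            _check(getattr(self, name) >= 0.0, f"hypertension.{name}", "must be >= 0")
        for name in ("tablets_per_year", "visits_per_year"):
            _check(getattr(self, name) >= 0, f"hypertension.{name}", "must be >= 0")

    @property
    def annual_management_cost(self) -> float:
        """€ per treated patient-year: fractional atenolol packs plus visits."""
        return (self.tablets_per_year / 100.0) * self.atenolol_pack_cost \
            + self.visits_per_year * self.visit_fee


@dataclass(frozen=True)
class EconomicInputs:
    utility_hd: float = 0.69                   # preference weight on hemodialysis
    disutility_severe_anemia: float = 0.03     # decrement while Hb < 9 g/dL
    annual_hd_cost_2017: float = 54604.0       # € per patient-year, 2017 prices
    #: consumer-price-index multiplier 2017 -> 2024.  The default is calibrated
    #: so the 2024 annual cost ~ €67,572 per patient-year; substitute the
    #: official index value if available.
    cpi_factor_2017_to_2024: float = 1.2375
    esa_annual_cost: float = 5200.0            # € per patient-year of ESA therapy
    discount_rate: float = 0.03                # per year, applied to costs and QALYs

    def __post_init__(self):
        _check(0.0 <= self.utility_hd <= 1.0, "economics.utility_hd", "must be in [0, 1]")
        _check(0.0 <= self.disutility_severe_anemia <= self.utility_hd,
               "economics.disutility_severe_anemia", "must be in [0, utility_hd]")
        for name in ("annual_hd_cost_2017", "esa_annual_cost"):
            _check(getattr(self, name) >= 0.0, f"economics.{name}", "must be >= 0")
        _check(self.cpi_factor_2017_to_2024 > 0.0,
               "economics.cpi_factor_2017_to_2024", "must be > 0")
        _check(0.0 <= self.discount_rate <= 0.2, "economics.discount_rate",
               "must be in [0, 0.2]")

    @property
    def annual_hd_cost_2024(self) -> float:
        return cpi_adjust(self.annual_hd_cost_2017, self.cpi_factor_2017_to_2024)


_EFFECT_DURATIONS = ("lifetime", "first_year_only")
_ESA_SAVING_MODES = ("full", "esa_free_only")


@dataclass(frozen=True)
class ScenarioFlags:
    acm_effect_duration: str = "lifetime"
    prevalent_5y_cohort: bool = False
    qol_effect_enabled: bool = True
    esa_saving_mode: str = "full"
    tier: int = 1

    def __post_init__(self):
        _check(self.acm_effect_duration in _EFFECT_DURATIONS,
               "scenario.acm_effect_duration", f"must be one of {_EFFECT_DURATIONS}")
        _check(self.esa_saving_mode in _ESA_SAVING_MODES,
               "scenario.esa_saving_mode", f"must be one of {_ESA_SAVING_MODES}")
        _check(self.tier in (1, 2, 3), "scenario.tier", "must be 1, 2 or 3")
        _check(isinstance(self.prevalent_5y_cohort, bool),
               "scenario.prevalent_5y_cohort", "must be boolean")
        _check(isinstance(self.qol_effect_enabled, bool),
               "scenario.qol_effect_enabled", "must be boolean")


_DISCOUNT_TIMINGS = ("midcycle", "endcycle")


@dataclass(frozen=True)
class ModelSettings:
    horizon_age: int = 100
    #: exponent convention of the annual discount factor: "midcycle" uses
    #: (1+r)^-(t-1/2), consistent with half-cycle accrual; "endcycle" uses
    #: (1+r)^-t.
    discount_timing: str = "midcycle"

    def __post_init__(self):
        _check(self.horizon_age <= 100, "settings.horizon_age", "must be <= 100")
        _check(self.discount_timing in _DISCOUNT_TIMINGS,
               "settings.discount_timing", f"must be one of {_DISCOUNT_TIMINGS}")


def _default_tiers() -> Mapping[int, TierProfile]:
    return {
        1: TierProfile(1, inappropriate_esa_rate=0.1079, severe_anemia_rate=0.0490,
                       rr_inappropriate_esa=0.37, rr_severe_anemia=0.41,
                       diff_esa_free_months=0.186),
        2: TierProfile(2, inappropriate_esa_rate=0.0818, severe_anemia_rate=0.0316,
                       rr_inappropriate_esa=0.49, rr_severe_anemia=0.64,
                       diff_esa_free_months=0.129),
        3: TierProfile(3, inappropriate_esa_rate=0.0604, severe_anemia_rate=0.0217,
                       rr_inappropriate_esa=0.66, rr_severe_anemia=0.94,
                       diff_esa_free_months=0.097),
    }


@dataclass(frozen=True)
class ParameterBundle:
    """The complete, validated input set of the decision model."""

    cohort: CohortProfile = field(default_factory=CohortProfile)
    anchors: SurvivalAnchors = field(default_factory=SurvivalAnchors)
    tiers: Mapping[int, TierProfile] = field(default_factory=_default_tiers)
    hospitalization: HospitalizationInputs = field(default_factory=HospitalizationInputs)
    hypertension: HypertensionInputs = field(default_factory=HypertensionInputs)
    economics: EconomicInputs = field(default_factory=EconomicInputs)
    scenario: ScenarioFlags = field(default_factory=ScenarioFlags)
    settings: ModelSettings = field(default_factory=ModelSettings)

    def __post_init__(self):
        _check(set(self.tiers) == {1, 2, 3}, "tiers", "must define tiers 1, 2 and 3")
        for tid, tier in self.tiers.items():
            _check(tier.tier_id == tid, f"tiers.{tid}", "tier_id mismatch")

    # -- flat parameter access --------------------------------------------

    def get_param(self, name: str) -> Any:
        return _param_def(name).get(self)

    def replace_param(self, name: str, value: Any) -> "ParameterBundle":
        """Return a new bundle with one registry parameter replaced.

        Validation runs again on construction, so an out-of-support value
        raises :class:`ValidationError` rather than building silently.
        """
        return _param_def(name).set(self, value)

    def replace_params(self, values: Mapping[str, Any]) -> "ParameterBundle":
        bundle = self
        for name, value in values.items():
            bundle = bundle.replace_param(name, value)
        return bundle


def cpi_adjust(amount_2017: float, factor: float) -> float:
    """Inflate an amount from 2017 euros with a consumer-price-index factor."""
    if factor <= 0.0:
        raise ValidationError("cpi_factor", "must be > 0")
    if amount_2017 < 0.0:
        raise ValidationError("amount_2017", "must be >= 0")
    return amount_2017 * factor


def default_bundle() -> ParameterBundle:
    """The packaged base-case parameter set."""
    return ParameterBundle()


# ---------------------------------------------------------------------------
# parameter registry


@dataclass(frozen=True)
class ParamDef:
    """One flat model parameter: its location, range and distribution family.

    ``family`` names the marginal used by the probabilistic sensitivity
    analysis ("fixed" parameters are never sampled); ``low``/``high`` give
    the one-way range (95% CI bounds or hard min/max as printed by the
    sources).  ``psa`` marks parameters sampled by default in the PSA.
    """

    name: str
    path: tuple
    family: str = "fixed"
    low: Optional[float] = None
    high: Optional[float] = None
    psa: bool = False
    source: str = ""

    def get(self, bundle: ParameterBundle) -> Any:
        obj: Any = bundle
        for key in self.path:
            obj = obj[key] if isinstance(obj, Mapping) else getattr(obj, key)
        return obj

    def set(self, bundle: ParameterBundle, value: Any) -> ParameterBundle:
        return _replace_path(bundle, self.path, value)


def _replace_path(obj: Any, path: tuple, value: Any) -> Any:
    if not path:
        return value
    key, rest = path[0], path[1:]
    if isinstance(obj, Mapping):
        new = dict(obj)
        new[key] = _replace_path(obj[key], rest, value)
        return new
    return replace(obj, **{key: _replace_path(getattr(obj, key), rest, value)})


def _tier_defs(tid: int, rr_in, rr_sev, diff, rate_in, rate_sev) -> list:
    t = ("tiers", tid)
    return [
        ParamDef(f"rr_inappropriate_esa_tier{tid}", t + ("rr_inappropriate_esa",),
                 "lognormal", *rr_in, psa=True, source="effect study"),
        ParamDef(f"rr_severe_anemia_tier{tid}", t + ("rr_severe_anemia",),
                 "lognormal", *rr_sev, psa=True, source="effect study"),
        ParamDef(f"diff_esa_free_months_tier{tid}", t + ("diff_esa_free_months",),
                 "normal", *diff, psa=True, source="effect study"),
        ParamDef(f"inappropriate_esa_rate_tier{tid}", t + ("inappropriate_esa_rate",),
                 "beta", *rate_in, psa=True, source="effect study"),
        ParamDef(f"severe_anemia_rate_tier{tid}", t + ("severe_anemia_rate",),
                 "beta", *rate_sev, psa=True, source="effect study"),
    ]


#: Flat registry of every numeric model input.  Ranges are the printed 95%
#: CIs or hard min/max of the sources; ``family`` follows the support of the
#: quantity (beta on [0,1], lognormal for ratios, gamma for costs, ...).
PARAMETER_TABLE: tuple = tuple(
    [
        # survival anchors (one-way only; excluded from the PSA by default)
        ParamDef("survival_s1", ("anchors", "s1"), "beta", 0.856, 0.859, source="registry"),
        ParamDef("survival_s2", ("anchors", "s2"), "beta", 0.752, 0.757, source="registry"),
        ParamDef("survival_s5", ("anchors", "s5"), "beta", 0.471, 0.477, source="registry"),
        ParamDef("tail_annual_mortality", ("anchors", "tail_annual_mortality_override"),
                 "fixed", 0.10, 0.20, source="assumption"),
        # hospitalization
        ParamDef("hospitalization_base_rate", ("hospitalization", "base_rate_per_year"),
                 "uniform", 0.775, 0.836, psa=True, source="hospitalization study"),
        ParamDef("hospitalization_arr", ("hospitalization", "arr"),
                 "uniform", 0.063, 0.189, psa=True, source="hospitalization study"),
        ParamDef("drg_cost", ("hospitalization", "drg_cost"), "fixed", source="DRG catalogue"),
    ]
    + _tier_defs(1, (0.35, 0.38), (0.39, 0.44), (0.1818, 0.1902), (0.1059, 0.11), (0.0477, 0.0505))
    + _tier_defs(2, (0.47, 0.51), (0.61, 0.68), (0.1244, 0.1336), (0.08, 0.0837), (0.0305, 0.0328))
    + _tier_defs(3, (0.63, 0.69), (0.88, 1.00), (0.0928, 0.1012), (0.0588, 0.0620), (0.0207, 0.0227))
    + [
        # hypertension
        ParamDef("hypertension_or", ("hypertension", "or_esa"),
                 "lognormal", 1.22, 3.59, psa=True, source="Cochrane review"),
        ParamDef("hypertension_baseline_prevalence", ("hypertension", "baseline_prevalence"),
                 "fixed", source="ESKD cohort"),
        ParamDef("atenolol_pack_cost", ("hypertension", "atenolol_pack_cost"), "fixed"),
        ParamDef("hypertension_visit_fee", ("hypertension", "visit_fee"), "fixed"),
        # economics
        ParamDef("utility_hd", ("economics", "utility_hd"),
                 "beta", 0.59, 0.80, psa=True, source="utility meta-analysis"),
        ParamDef("disutility_severe_anemia", ("economics", "disutility_severe_anemia"),
                 "uniform", 0.0, 0.03, psa=True, source="EQ-5D survey"),
        ParamDef("annual_hd_cost_2017", ("economics", "annual_hd_cost_2017"),
                 "gamma", 53514.0, 55693.0, psa=True, source="claims data"),
        ParamDef("esa_annual_cost", ("economics", "esa_annual_cost"),
                 "triangular", 1529.0, 8918.0, psa=True, source="net drug costs"),
        ParamDef("cpi_factor_2017_to_2024", ("economics", "cpi_factor_2017_to_2024"), "fixed"),
        ParamDef("discount_rate", ("economics", "discount_rate"),
                 "fixed", 0.0, 0.05, source="guideline"),
        # cohort metadata (validated, never used in computation)
        ParamDef("cohort_start_age", ("cohort", "start_age"), "fixed"),
        ParamDef("cohort_male_fraction", ("cohort", "male_fraction"), "fixed"),
    ]
)

_REGISTRY = {p.name: p for p in PARAMETER_TABLE}


def _param_def(name: str) -> ParamDef:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValidationError(name, "unknown parameter") from None


# ---------------------------------------------------------------------------
# config file I/O


_SECTIONS = ("cohort", "anchors", "hospitalization", "hypertension",
             "economics", "scenario", "settings")


def load_config(path) -> ParameterBundle:
    """Load a YAML or JSON configuration, fill gaps with defaults, validate.

    The file may specify any subset of sections/fields; omitted fields take
    the packaged base-case values.  Tier overrides live under ``tiers:``
    keyed by tier number.
    """
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"could not parse {path}{line}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ConfigError(f"could not parse {path} at line {exc.lineno}: {exc.msg}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return bundle_from_dict(raw)


def bundle_from_dict(raw: Mapping[str, Any]) -> ParameterBundle:
    base = default_bundle()
    kwargs: dict = {}
    for section in _SECTIONS:
        overrides = raw.get(section, {})
        if overrides is None:
            overrides = {}
        if not isinstance(overrides, Mapping):
            raise ConfigError(f"section {section!r} must be a mapping")
        current = getattr(base, section)
        unknown = set(overrides) - {f.name for f in dataclasses.fields(current)}
        if unknown:
            raise ValidationError(f"{section}.{sorted(unknown)[0]}", "unknown field")
        kwargs[section] = replace(current, **overrides) if overrides else current
    tiers = dict(base.tiers)
    for tid, overrides in (raw.get("tiers") or {}).items():
        tid = int(tid)
        if tid not in tiers:
            raise ValidationError(f"tiers.{tid}", "tier must be 1, 2 or 3")
        tiers[tid] = replace(tiers[tid], **overrides)
    unknown_sections = set(raw) - set(_SECTIONS) - {"tiers"}
    if unknown_sections:
        raise ConfigError(f"unknown section {sorted(unknown_sections)[0]!r}")
    return ParameterBundle(tiers=tiers, **kwargs)


_CSV_HEADER = ("name", "mean", "low", "high", "distribution", "source")


def export_parameter_table(bundle: ParameterBundle, path) -> None:
    """Write the flat parameter table as CSV (one row per registry entry)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for p in PARAMETER_TABLE:
            value = p.get(bundle)
            writer.writerow([
                p.name,
                "" if value is None else repr(float(value)),
                "" if p.low is None else repr(float(p.low)),
                "" if p.high is None else repr(float(p.high)),
                p.family,
                p.source,
            ])


def import_parameter_table(path) -> ParameterBundle:
    """Rebuild a bundle from an exported parameter CSV (exact round trip)."""
    bundle = default_bundle()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != _CSV_HEADER:
            raise ConfigError(f"{path}: unexpected header {reader.fieldnames}")
        for row in reader:
            if row["mean"] == "":
                continue
            value: Any = float(row["mean"])
            pdef = _param_def(row["name"])
            if pdef.path[-1] in ("start_age", "tablets_per_year", "visits_per_year"):
                value = int(value)
            bundle = bundle.replace_param(row["name"], value)
    return bundle
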