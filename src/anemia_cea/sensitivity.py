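"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-runs the full pipeline at each bound of a parameter's
range (with everything else at base) and orders the resulting net monetary
benefit intervals into a tornado.  The probabilistic analysis samples every
uncertain parameter from its family (beta for probabilities and utilities,
lognormal for relative risks and odds ratios, gamma for the dialysis cost,
triangular for the ESA cost, uniform and normal where the sources give
only ranges), couples the hospitalization absolute risk reduction with the
severe-anemia relative risk through a Gaussian copula (normal-score
correlation 0.5, Cholesky factorization), and classifies each draw's
incremental cost-effect pair on the cost-effectiveness plane.

λ is held at its deterministic base-case value across draws by default, so
the threshold acts as a fixed decision rule rather than a resampled
quantity; set ``resample_wtp=True`` to recompute it per draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import run_base_case
from .config import PARAMETER_TABLE, ParamDef, ParameterBundle
from .errors import FitError, ValidationError
from .survival import LifeTable

__all__ = [
    "DistributionSpec",
    "CorrelationSpec",
    "PsaSummary",
    "TornadoEntry",
    "fit_distribution",
    "default_distribution_specs",
    "sample_correlated",
    "run_psa",
    "one_way",
    "one_way_all",
    "tornado",
    "DEFAULT_ONE_WAY_PARAMETERS",
    "SCENARIO_TOGGLES",
]

log = logging.getLogger(__name__)

_Z95 = 3.92  # width of a 95% normal CI in standard errors


@dataclass(frozen=True)
class DistributionSpec:
    """A parameter's marginal: family, target moments, fitted distribution."""

    name: str
    family: str
    mean: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    frozen: Any = None          # scipy frozen distribution after fitting
    params: Mapping[str, float] = field(default_factory=dict)

    def ppf(self, u):
        if self.family == "fixed" or self.frozen is None:
            return np.full_like(np.asarray(u, dtype=float), self.mean)
        return self.frozen.ppf(u)


def fit_distribution(name: str, family: str, mean: float,
                     ci_low: Optional[float] = None,
                     ci_high: Optional[float] = None) -> DistributionSpec:
    """Resolve a distribution family to a frozen scipy distribution.

    Where a 95% CI is given, SE = (ci_high - ci_low)/3.92.  Beta and gamma
    are fitted by the method of moments so their mean matches the target;
    the lognormal is fitted on the log scale with its median at the target
    value; the triangular uses the midpoint of (min, max) as its mode; the
    normal for the ESA-free-month difference is truncated to [0, 1].
    """
    if family == "fixed":
        return DistributionSpec(name, family, mean, ci_low, ci_high)
    if ci_low is None or ci_high is None:
        raise FitError(f"{name}: family {family!r} needs ci_low and ci_high")
    if not ci_low <= mean <= ci_high:
        raise FitError(f"{name}: mean {mean} outside [{ci_low}, {ci_high}]")
    se = (ci_high - ci_low) / _Z95
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise FitError(f"{name}: beta requires mean in (0, 1)")
        nu = mean * (1.0 - mean) / se**2 - 1.0
        if nu <= 0.0:
            raise FitError(f"{name}: SE {se:.4g} too large for beta support")
        a, b = mean * nu, (1.0 - mean) * nu
        return DistributionSpec(name, family, mean, ci_low, ci_high,
                                stats.beta(a, b), {"a": a, "b": b})
    if family == "gamma":
        shape = (mean / se) ** 2
        scale = se**2 / mean
        return DistributionSpec(name, family, mean, ci_low, ci_high,
                                stats.gamma(shape, scale=scale),
                                {"shape": shape, "scale": scale})
    if family == "lognormal":
        if mean <= 0.0 or ci_low <= 0.0:
            raise FitError(f"{name}: lognormal requires positive support")
        sigma = (np.log(ci_high) - np.log(ci_low)) / _Z95
        return DistributionSpec(name, family, mean, ci_low, ci_high,
                                stats.lognorm(sigma, scale=mean),
                                {"sigma": sigma, "median": mean})
    if family == "triangular":
        mode = (ci_low + ci_high) / 2.0
        return DistributionSpec(name, family, mean, ci_low, ci_high,
                                stats.triang(0.5, loc=ci_low, scale=ci_high - ci_low),
                                {"mode": mode})
    if family == "uniform":
        return DistributionSpec(name, family, mean, ci_low, ci_high,
                                stats.uniform(ci_low, ci_high - ci_low), {})
    if family == "normal":
        # proportion-valued differences: truncate the tails outside [0, 1]
        a, b = (0.0 - mean) / se, (1.0 - mean) / se
        return DistributionSpec(name, family, mean, ci_low, ci_high,
                                stats.truncnorm(a, b, loc=mean, scale=se),
                                {"se": se})
    raise FitError(f"{name}: unknown family {family!r}")


def default_distribution_specs(bundle: ParameterBundle) -> dict:
    """Fitted marginals for every PSA-sampled registry parameter."""
    specs = {}
    for p in PARAMETER_TABLE:
        if not p.psa:
            continue
        specs[p.name] = fit_distribution(p.name, p.family,
                                         float(p.get(bundle)), p.low, p.high)
    return specs


@dataclass(frozen=True)
class CorrelationSpec:
    """Normal-score correlation between one parameter pair."""

    param_a: str = "hospitalization_arr"
    param_b: str = "rr_severe_anemia_tier1"
    coefficient: float = 0.5

    def __post_init__(self):
        if not -1.0 < self.coefficient < 1.0:
            raise ValidationError("correlation.coefficient", "must be in (-1, 1)")


def sample_correlated(specs: Mapping[str, DistributionSpec],
                      corr: Optional[CorrelationSpec],
                      n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` joint parameter samples through a Gaussian copula.

    Standard-normal scores are correlated via the Cholesky factor of the
    correlation matrix and mapped through each marginal's inverse CDF, so
    marginals are preserved exactly.  Column order (and therefore the draw
    stream) is the sorted parameter name order, making runs seed-stable.
    """
    if n < 1:
        raise ValidationError("n", "need at least one draw")
    names = sorted(specs)
    k = len(names)
    corr_matrix = np.eye(k)
    if corr is not None and corr.param_a in names and corr.param_b in names:
        ia, ib = names.index(corr.param_a), names.index(corr.param_b)
        corr_matrix[ia, ib] = corr_matrix[ib, ia] = corr.coefficient
    try:
        chol = np.linalg.cholesky(corr_matrix)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("correlation", "matrix not positive definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, k)) @ chol.T
    u = stats.norm.cdf(z)
    data = {name: specs[name].ppf(u[:, i]) for i, name in enumerate(names)}
    return pd.DataFrame(data, columns=names)


@dataclass(frozen=True)
class PsaSummary:
    n: int
    quadrant_shares: Mapping[str, float]   # NE/SE/SW/NW proportions
    mean_delta_cost: float
    sd_delta_cost: float
    mean_delta_qaly: float
    sd_delta_qaly: float
    mean_nmb: float
    sd_nmb: float
    draws: pd.DataFrame                    # per-draw parameters and outcomes

    def __post_init__(self):
        total = sum(self.quadrant_shares.values())
        if abs(total - 1.0) > 1e-12:
            raise ValidationError("quadrant_shares", f"sum to {total}, expected 1")
        if self.n != len(self.draws):
            raise ValidationError("n", "must equal the number of draw rows")


def classify_quadrant(delta_qaly: float, delta_cost: float) -> str:
    """Cost-effectiveness plane quadrant; boundaries count as non-SE."""
    if delta_qaly > 0.0 and delta_cost < 0.0:
        return "SE"
    if delta_qaly > 0.0 and delta_cost >= 0.0:
        return "NE"
    if delta_qaly <= 0.0 and delta_cost < 0.0:
        return "SW"
    return "NW"


def run_psa(bundle: ParameterBundle, n: int = 1000, seed: int = 0,
            life_table: Optional[LifeTable] = None,
            corr: Optional[CorrelationSpec] = None,
            specs: Optional[Mapping[str, DistributionSpec]] = None,
            resample_wtp: bool = False) -> PsaSummary:
    """Monte-Carlo propagation of parameter uncertainty to ΔC, ΔE and NMB."""
    if corr is None:
        corr = CorrelationSpec(
            param_b=f"rr_severe_anemia_tier{bundle.scenario.tier}")
    base = run_base_case(bundle, life_table)
    wtp0 = base.wtp
    if specs is None:
        specs = default_distribution_specs(bundle)
    samples = sample_correlated(specs, corr, n, seed)

    records = []
    rejected = 0
    for i in range(n):
        values = samples.iloc[i].to_dict()
        try:
            draw_bundle = bundle.replace_params(values)
            res = run_base_case(draw_bundle, life_table,
                                wtp=None if resample_wtp else wtp0)
        except (ValidationError, FitError) as exc:
            rejected += 1
            log.warning("draw %d rejected: %s", i, exc)
            continue
        cmp_ = res.comparison
        records.append({"draw": i, "delta_qaly": cmp_.delta_qaly,
                        "delta_cost": cmp_.delta_cost, "nmb": cmp_.nmb,
                        "quadrant": classify_quadrant(cmp_.delta_qaly, cmp_.delta_cost),
                        **values})
    if rejected > 0.01 * n:
        raise ValidationError("psa", f"{rejected}/{n} draws rejected")
    df = pd.DataFrame.from_records(records)
    shares = {q: float((df["quadrant"] == q).mean()) for q in ("NE", "SE", "SW", "NW")}
    return PsaSummary(
        n=len(df), quadrant_shares=shares,
        mean_delta_cost=float(df["delta_cost"].mean()),
        sd_delta_cost=float(df["delta_cost"].std(ddof=1)),
        mean_delta_qaly=float(df["delta_qaly"].mean()),
        sd_delta_qaly=float(df["delta_qaly"].std(ddof=1)),
        mean_nmb=float(df["nmb"].mean()), sd_nmb=float(df["nmb"].std(ddof=1)),
        draws=df)


# ---------------------------------------------------------------------------
# one-way sensitivity analysis


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    nmb_low: float
    nmb_high: float

    @property
    def width(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


#: registry parameters varied by the default one-way analysis: every entry
#: with a printed range, for the active tier, plus model-level knobs
DEFAULT_ONE_WAY_PARAMETERS: tuple = (
    "survival_s1", "survival_s2", "survival_s5",
    "tail_annual_mortality",
    "hospitalization_base_rate", "hospitalization_arr",
    "hypertension_or",
    "utility_hd", "disutility_severe_anemia",
    "annual_hd_cost_2017", "esa_annual_cost",
    "discount_rate",
)

#: scenario switches explored alongside the numeric ranges, as
#: (name, base value, alternative value)
SCENARIO_TOGGLES: tuple = (
    ("qol_effect_enabled", True, False),
    ("esa_saving_mode", "full", "esa_free_only"),
    ("acm_effect_duration", "lifetime", "first_year_only"),
    ("prevalent_5y_cohort", False, True),
)

_TOGGLE_FIELDS = {name for name, _, _ in SCENARIO_TOGGLES}


def _with_value(bundle: ParameterBundle, name: str, value) -> ParameterBundle:
    from dataclasses import replace
    if name in _TOGGLE_FIELDS:
        return replace(bundle, scenario=replace(bundle.scenario, **{name: value}))
    return bundle.replace_param(name, value)


def one_way(bundle: ParameterBundle, parameter: str, low, high,
            life_table: Optional[LifeTable] = None) -> TornadoEntry:
    """NMB at each bound of one parameter, all else at base values."""
    nmbs = []
    for value in (low, high):
        res = run_base_case(_with_value(bundle, parameter, value), life_table)
        nmbs.append(res.comparison.nmb)
    return TornadoEntry(parameter=parameter, nmb_low=nmbs[0], nmb_high=nmbs[1])


def _tier_one_way_names(tier: int) -> tuple:
    return (f"rr_inappropriate_esa_tier{tier}", f"rr_severe_anemia_tier{tier}",
            f"diff_esa_free_months_tier{tier}", f"inappropriate_esa_rate_tier{tier}",
            f"severe_anemia_rate_tier{tier}")


def one_way_all(bundle: ParameterBundle,
                life_table: Optional[LifeTable] = None,
                parameters: Optional[Sequence[str]] = None) -> list:
    """Run the default one-way battery; returns unordered TornadoEntry list."""
    registry = {p.name: p for p in PARAMETER_TABLE}
    if parameters is None:
        parameters = DEFAULT_ONE_WAY_PARAMETERS + _tier_one_way_names(bundle.scenario.tier)
    if not parameters:
        raise ValidationError("parameters", "one-way parameter list is empty")
    entries = []
    for name in parameters:
        p = registry.get(name)
        if p is None or p.low is None or p.high is None:
            raise ValidationError(name, "no range available for one-way analysis")
        entries.append(one_way(bundle, name, p.low, p.high, life_table))
    for name, base_value, alt_value in SCENARIO_TOGGLES:
        entries.append(one_way(bundle, name, base_value, alt_value, life_table))
    return entries


def tornado(entries: Sequence[TornadoEntry]) -> list:
    """Order entries by NMB interval width, widest first; ties alphabetical."""
    if not entries:
        raise ValidationError("entries", "need at least one entry")
    return sorted(entries, key=lambda e: (-e.width, e.parameter))
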