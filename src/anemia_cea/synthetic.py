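"""Synthetic inputs: perturbed parameter bundles, life tables, toy oracles.

Everything the pipeline consumes can be generated here without downloads:
parameter bundles jittered around the packaged defaults (for fuzzing the
validation layer), a Gompertz-shaped general-population life table (a
synthetic stand-in for the official national table), and constant-hazard
toy scenarios whose discounted life-years, QALYs and costs have closed
forms, used as independent oracles for the cohort engine.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import ParameterBundle, default_bundle
from .errors import ValidationError
from .survival import LifeTable

__all__ = [
    "generate_parameter_bundle",
    "generate_life_table",
    "ToyScenario",
    "toy_scenario",
]

_PROPORTION_EPS = 1e-6


def _clamp(value: float, low: float, high: float) -> float:
    return min(max(value, low), high)


def generate_parameter_bundle(seed: int, perturbation: float = 0.1) -> ParameterBundle:
    """A valid bundle with defaults jittered by seeded lognormal noise.

    ``perturbation`` is the log-scale noise SD (0 returns the exact
    defaults).  Multiplicative noise preserves positivity; proportions are
    re-clamped into (0, 1) and ordering constraints (survival anchors,
    disutility <= utility, ARR <= base rate) re-imposed so every output
    passes validation.
    """
    if not 0.0 <= perturbation <= 0.5:
        raise ValidationError("perturbation", "must be in [0, 0.5]")
    base = default_bundle()
    if perturbation == 0.0:
        return base
    rng = np.random.default_rng(seed)

    def jit(value: float, low: float = None, high: float = None) -> float:
        out = value * float(np.exp(rng.normal(0.0, perturbation)))
        if low is not None or high is not None:
            out = _clamp(out, low if low is not None else -np.inf,
                         high if high is not None else np.inf)
        return out

    s1 = jit(base.anchors.s1, _PROPORTION_EPS, 1 - _PROPORTION_EPS)
    s2 = _clamp(jit(base.anchors.s2), _PROPORTION_EPS, s1 - _PROPORTION_EPS)
    s5 = _clamp(jit(base.anchors.s5), _PROPORTION_EPS, s2 - _PROPORTION_EPS)
    anchors = replace(base.anchors, s1=s1, s2=s2, s5=s5)

    tiers = {}
    for tid, tier in base.tiers.items():
        tiers[tid] = replace(
            tier,
            inappropriate_esa_rate=jit(tier.inappropriate_esa_rate, _PROPORTION_EPS, 1 / 12),
            severe_anemia_rate=jit(tier.severe_anemia_rate, _PROPORTION_EPS, 1 / 12),
            rr_inappropriate_esa=jit(tier.rr_inappropriate_esa, _PROPORTION_EPS, None),
            rr_severe_anemia=jit(tier.rr_severe_anemia, _PROPORTION_EPS, None),
            diff_esa_free_months=jit(tier.diff_esa_free_months, _PROPORTION_EPS,
                                     1 - _PROPORTION_EPS))

    base_rate = jit(base.hospitalization.base_rate_per_year, _PROPORTION_EPS, None)
    hosp = replace(base.hospitalization,
                   base_rate_per_year=base_rate,
                   arr=_clamp(jit(base.hospitalization.arr), 0.0, base_rate),
                   drg_cost=jit(base.hospitalization.drg_cost, _PROPORTION_EPS, None))
    ht = replace(base.hypertension,
                 baseline_prevalence=jit(base.hypertension.baseline_prevalence,
                                         _PROPORTION_EPS, 1 - _PROPORTION_EPS),
                 or_esa=jit(base.hypertension.or_esa, _PROPORTION_EPS, None),
                 atenolol_pack_cost=jit(base.hypertension.atenolol_pack_cost, 0.0, None),
                 visit_fee=jit(base.hypertension.visit_fee, 0.0, None))
    utility = jit(base.economics.utility_hd, _PROPORTION_EPS, 1.0)
    econ = replace(base.economics,
                   utility_hd=utility,
                   disutility_severe_anemia=_clamp(
                       jit(base.economics.disutility_severe_anemia), 0.0, utility),
                   annual_hd_cost_2017=jit(base.economics.annual_hd_cost_2017, 0.0, None),
                   esa_annual_cost=jit(base.economics.esa_annual_cost, 0.0, None),
                   discount_rate=_clamp(jit(base.economics.discount_rate), 0.0, 0.2))
    return replace(base, anchors=anchors, tiers=tiers, hospitalization=hosp,
                   hypertension=ht, economics=econ)


def generate_life_table(start_age: int = 18, modal_age: int = 86,
                        steepness: float = 0.12) -> LifeTable:
    """Gompertz-shaped synthetic life table over ages start_age..100.

    The annual hazard is h(a) = steepness * exp(steepness * (a - modal_age))
    (so the modal age of death is approximately ``modal_age``), converted to
    a death probability qx = 1 - exp(-h).  Steepness 0 degenerates to a
    constant (zero) qx.
    """
    if not start_age < modal_age <= 100:
        raise ValidationError("modal_age", "need start_age < modal_age <= 100")
    if steepness < 0.0:
        raise ValidationError("steepness", "must be >= 0")
    ages = np.arange(start_age, 101)
    hazard = steepness * np.exp(steepness * (ages - modal_age))
    qx = 1.0 - np.exp(-hazard)
    return LifeTable(ages=ages, qx=qx)


@dataclass(frozen=True)
class ToyScenario:
    """Constant-hazard cohort with closed-form discounted accruals.

    With constant annual survival ``p``, utility ``u``, annual cost ``c``
    and discount rate ``r``, the half-cycle discounted life expectancy over
    ``T`` cycles is the geometric series
    sum_t p^(t-1) (1+p)/2 d(t) with d(t) = (1+r)^-(t-1/2), and QALYs and
    costs scale it by ``u`` and ``c``.
    """

    p: float
    u: float
    c: float
    r: float
    T: int
    expected_life_years: float
    expected_qalys: float
    expected_cost: float


def toy_scenario(p: float, u: float = 1.0, c: float = 0.0,
                 r: float = 0.0, T: int = 10,
                 discount_timing: str = "midcycle") -> ToyScenario:
    """Closed-form oracle for a constant-hazard cohort."""
    if not 0.0 < p <= 1.0:
        raise ValidationError("p", "annual survival must be in (0, 1]")
    if T < 1:
        raise ValidationError("T", "need at least one cycle")
    y = p / (1.0 + r)
    # sum_{t=1..T} y^t, stable for y == 1
    geo = float(T) if y == 1.0 else y * (1.0 - y**T) / (1.0 - y)
    half_shift = (1.0 + r) ** 0.5 if discount_timing == "midcycle" else 1.0
    ly = (1.0 + p) / (2.0 * p) * half_shift * geo
    return ToyScenario(p=p, u=u, c=c, r=r, T=T,
                       expected_life_years=ly,
                       expected_qalys=u * ly,
                       expected_cost=c * ly)
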