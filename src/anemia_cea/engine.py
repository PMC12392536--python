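"""Two-state Markov cohort engine: per-cycle cost and QALY accrual.

The model has two health states (alive, dead).  Hospitalizations,
inappropriate ESA administration and severe anemia are not separate
states: they are within-cycle modifiers that attach costs and utility
decrements to the alive state.  Each 12-month cycle, survivors accrue the
annual hemodialysis cost minus (in the intervention arm, while its effect
is active) the annual savings from avoided hospitalizations, reduced ESA
use, and reduced ESA-induced hypertension, together with utility weighted
by the severe-anemia decrement.  Membership is half-cycle weighted and
discounted per the configured convention.

Monthly event rates are annualized by multiplying by 12 into annual
exposure proportions (capped at one patient-year), which are then valued
against full-year costs and disutilities.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .config import (EconomicInputs, HospitalizationInputs, HypertensionInputs,
                     ParameterBundle, ScenarioFlags, TierProfile)
from .economics import or_to_prevalence
from .errors import ValidationError
from .survival import SurvivalCurve, discount_factors

__all__ = [
    "ArmSpec",
    "CycleRecord",
    "ArmResult",
    "annualize_monthly_rate",
    "annual_quality_decrement",
    "annual_savings",
    "run_arm",
    "build_arm_specs",
    "write_trace",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArmSpec:
    arm_id: str                      # "acm" or "no_acm"
    tier: TierProfile
    effects_active_per_cycle: np.ndarray  # bool, length = number of cycles

    def __post_init__(self):
        if self.arm_id not in ("acm", "no_acm"):
            raise ValidationError("arm_id", "must be 'acm' or 'no_acm'")
        object.__setattr__(self, "effects_active_per_cycle",
                           np.asarray(self.effects_active_per_cycle, dtype=bool))


@dataclass(frozen=True)
class CycleRecord:
    cycle: int
    person_years: float
    cost: float
    cost_discounted: float
    qaly: float
    qaly_discounted: float
    cost_breakdown: Mapping[str, float]   # base HD cost and (negative) savings


@dataclass(frozen=True)
class ArmResult:
    arm_id: str
    lifetime_cost: float
    life_years: float
    qalys: float
    trace: Sequence[CycleRecord]
    undiscounted_cost: float
    undiscounted_life_years: float
    undiscounted_qalys: float


def annualize_monthly_rate(rate: float, rr: float = 1.0) -> float:
    """Annual exposure proportion from a monthly event rate and relative risk.

    Returns ``rate * rr * 12`` capped at 1.0 (a patient cannot accumulate
    more than one full patient-year of exposure); the cap is logged.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValidationError("rate", "monthly rate must be in [0, 1]")
    if rr < 0.0:
        raise ValidationError("rr", "relative risk must be >= 0")
    annual = rate * rr * 12.0
    if annual > 1.0:
        log.warning("annual exposure %.4f exceeds one patient-year; capped", annual)
        return 1.0
    return annual


def annual_quality_decrement(severe_anemia_monthly: float, rr: float,
                             disutility: float, enabled: bool = True) -> float:
    """QALY decrement per person-year from time spent in severe anemia."""
    if not enabled:
        return 0.0
    return annualize_monthly_rate(severe_anemia_monthly, rr) * disutility


def annual_savings(tier: TierProfile,
                   hosp: HospitalizationInputs,
                   ht: HypertensionInputs,
                   econ: EconomicInputs,
                   mode: str = "full") -> tuple[float, dict]:
    """Intervention savings in € per person-year, with component breakdown.

    hospitalization : ARR x DRG reimbursement per admission.
    esa             : in ``full`` mode, avoided inappropriate administrations
                      (rate x (1 - RR) x 12, valued at the annual ESA cost)
                      plus the additional ESA-free patient-month proportion
                      valued at the annual ESA cost; in ``esa_free_only``
                      mode only the latter (guards the double-counting risk).
    hypertension    : ESA-attributable prevalence shift (odds-ratio method)
                      x additional ESA-free proportion x annual management
                      cost (atenolol + outpatient visits).
    """
    if mode not in ("full", "esa_free_only"):
        raise ValidationError("esa_saving_mode", f"unknown mode {mode!r}")
    hospitalization = hosp.arr * hosp.drg_cost
    esa_free = tier.diff_esa_free_months * econ.esa_annual_cost
    if mode == "full":
        avoided_inappropriate = annualize_monthly_rate(
            tier.inappropriate_esa_rate, 1.0 - tier.rr_inappropriate_esa)
        esa = avoided_inappropriate * econ.esa_annual_cost + esa_free
    else:
        esa = esa_free
    delta_prevalence = (or_to_prevalence(ht.baseline_prevalence, ht.or_esa)
                        - ht.baseline_prevalence)
    hypertension = delta_prevalence * tier.diff_esa_free_months * ht.annual_management_cost
    breakdown = {"hospitalization": hospitalization, "esa": esa,
                 "hypertension": hypertension}
    return hospitalization + esa + hypertension, breakdown


def build_arm_specs(bundle: ParameterBundle, n_cycles: int) -> tuple[ArmSpec, ArmSpec]:
    """The intervention and comparator arm for the bundle's scenario."""
    tier = bundle.tiers[bundle.scenario.tier]
    active = np.ones(n_cycles, dtype=bool)
    if bundle.scenario.acm_effect_duration == "first_year_only":
        active[1:] = False
    return (ArmSpec("acm", tier, active),
            ArmSpec("no_acm", tier, np.zeros(n_cycles, dtype=bool)))


def run_arm(spec: ArmSpec, curve: SurvivalCurve, bundle: ParameterBundle) -> ArmResult:
    """Accrue discounted costs and QALYs for one arm over the whole horizon."""
    econ = bundle.economics
    flags = bundle.scenario
    T = curve.n_cycles
    if len(spec.effects_active_per_cycle) != T:
        raise ValidationError("effects_active_per_cycle",
                              f"length {len(spec.effects_active_per_cycle)} != horizon {T}")

    weights = curve.membership_weights()
    d = discount_factors(T, econ.discount_rate, bundle.settings.discount_timing)

    hd_cost = econ.annual_hd_cost_2024
    saving_total, saving_parts = annual_savings(
        spec.tier, bundle.hospitalization, bundle.hypertension, econ,
        flags.esa_saving_mode)
    rr_sev = spec.tier.rr_severe_anemia
    decrement_base = annual_quality_decrement(
        spec.tier.severe_anemia_rate, 1.0, econ.disutility_severe_anemia,
        flags.qol_effect_enabled)
    decrement_acm = annual_quality_decrement(
        spec.tier.severe_anemia_rate, rr_sev, econ.disutility_severe_anemia,
        flags.qol_effect_enabled)

    trace = []
    tot_cost = tot_cost_d = tot_qaly = tot_qaly_d = tot_ly = tot_ly_d = 0.0
    for t in range(1, T + 1):
        py = weights[t - 1]
        active = spec.arm_id == "acm" and bool(spec.effects_active_per_cycle[t - 1])
        saving = saving_total if active else 0.0
        parts = {"hd_base": py * hd_cost}
        for name, value in saving_parts.items():
            parts[f"saving_{name}"] = -py * value if active else 0.0
        cost = py * (hd_cost - saving)
        decrement = decrement_acm if active else decrement_base
        qaly = py * (econ.utility_hd - decrement)
        trace.append(CycleRecord(
            cycle=t, person_years=py,
            cost=cost, cost_discounted=cost * d[t - 1],
            qaly=qaly, qaly_discounted=qaly * d[t - 1],
            cost_breakdown=parts))
        tot_cost += cost
        tot_cost_d += cost * d[t - 1]
        tot_qaly += qaly
        tot_qaly_d += qaly * d[t - 1]
        tot_ly += py
        tot_ly_d += py * d[t - 1]
    return ArmResult(
        arm_id=spec.arm_id,
        lifetime_cost=tot_cost_d, life_years=tot_ly_d, qalys=tot_qaly_d,
        trace=tuple(trace),
        undiscounted_cost=tot_cost, undiscounted_life_years=tot_ly,
        undiscounted_qalys=tot_qaly)


def write_trace(path, results: Iterable[ArmResult]) -> None:
    """Write one CSV row per cycle per arm with the CycleRecord fields."""
    results = list(results)
    part_names = sorted({k for r in results for rec in r.trace for k in rec.cost_breakdown})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["arm", "cycle", "person_years", "cost", "cost_discounted",
                         "qaly", "qaly_discounted"] + part_names)
        for r in results:
            for rec in r.trace:
                writer.writerow(
                    [r.arm_id, rec.cycle, f"{rec.person_years:.6f}",
                     f"{rec.cost:.2f}", f"{rec.cost_discounted:.2f}",
                     f"{rec.qaly:.6f}", f"{rec.qaly_discounted:.6f}"]
                    + [f"{rec.cost_breakdown.get(k, 0.0):.2f}" for k in part_names])
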