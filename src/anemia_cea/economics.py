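"""Cost-effectiveness arithmetic: willingness-to-pay, ICER, NMB.

The willingness-to-pay threshold λ is endogenous: it is the cost-utility
ratio of hemodialysis itself against no treatment (immediate death, zero
cost, zero QALYs), i.e. the comparator arm's lifetime discounted cost per
discounted QALY.  The net monetary benefit of the intervention is then
NMB = λ·ΔE − ΔC and is annualized by dividing by the comparator's
discounted life expectancy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Optional, Union

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .engine import ArmResult

__all__ = [
    "CEComparison",
    "willingness_to_pay",
    "compare",
    "annualize_nmb",
    "or_to_prevalence",
    "write_results_table",
]


@dataclass(frozen=True)
class CEComparison:
    delta_cost: float          # intervention minus comparator, €
    delta_qaly: float
    delta_ly: float
    wtp: float                 # λ, € per QALY
    icer: Union[float, str]    # € per QALY, or a dominance label
    nmb: float                 # λ·ΔE − ΔC, €
    nmb_annual: float          # NMB per comparator discounted life-year


def or_to_prevalence(p: float, odds_ratio: float) -> float:
    """Shift a prevalence through an odds ratio (odds scale and back)."""
    if not 0.0 < p < 1.0:
        raise ValidationError("prevalence", "must be strictly inside (0, 1)")
    if odds_ratio <= 0.0:
        raise ValidationError("odds_ratio", "must be > 0")
    odds = odds_ratio * p / (1.0 - p)
    return odds / (1.0 + odds)


def willingness_to_pay(no_acm: "ArmResult") -> float:
    """λ as lifetime discounted cost per discounted QALY of untreated-arm HD."""
    if no_acm.qalys <= 0.0:
        raise ValidationError("qalys", "comparator QALYs must be > 0 to define λ")
    return no_acm.lifetime_cost / no_acm.qalys


def compare(acm: "ArmResult", no_acm: "ArmResult", wtp: float) -> CEComparison:
    """Incremental comparison at threshold ``wtp`` with dominance handling.

    The ICER ΔC/ΔE is reported only when both increments share a sign;
    otherwise the quadrant is labelled "dominant" (more QALYs, lower cost)
    or "dominated" (fewer QALYs, higher cost).
    """
    d_cost = acm.lifetime_cost - no_acm.lifetime_cost
    d_qaly = acm.qalys - no_acm.qalys
    d_ly = acm.life_years - no_acm.life_years
    icer: Union[float, str]
    if d_cost < 0.0 and d_qaly > 0.0:
        icer = "dominant"
    elif d_cost > 0.0 and d_qaly < 0.0:
        icer = "dominated"
    elif d_qaly == 0.0:
        icer = "dominant" if d_cost < 0.0 else ("dominated" if d_cost > 0.0 else 0.0)
    else:
        icer = d_cost / d_qaly
    nmb = wtp * d_qaly - d_cost
    nmb_annual = annualize_nmb(nmb, no_acm.life_years)
    return CEComparison(delta_cost=d_cost, delta_qaly=d_qaly, delta_ly=d_ly,
                        wtp=wtp, icer=icer, nmb=nmb, nmb_annual=nmb_annual)


def annualize_nmb(nmb: float, discounted_ly: float) -> float:
    """NMB per patient-year of remaining (discounted) life expectancy."""
    if discounted_ly <= 0.0:
        raise ValidationError("discounted_ly", "life expectancy must be > 0")
    return nmb / discounted_ly


def write_results_table(path, blocks: Mapping[str, tuple]) -> None:
    """Write a per-discounting-block results CSV (arm rows, cost/LY/QALY columns).

    ``blocks`` maps a block label (e.g. "3%") to a tuple
    (acm: ArmResult, no_acm: ArmResult, comparison: CEComparison).
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["discounting", "arm", "lifetime_cost", "life_years",
                         "qalys", "icer_per_ly", "icer_per_qaly",
                         "wtp_per_qaly", "nmb", "nmb_annual"])
        for label, (acm, no_acm, cmp_) in blocks.items():
            icer_ly = (acm.lifetime_cost - no_acm.lifetime_cost)
            icer_ly_label = "dominates" if icer_ly < 0 and cmp_.delta_ly >= 0 else (
                f"{icer_ly / cmp_.delta_ly:.2f}" if cmp_.delta_ly else "dominates")
            icer_q = cmp_.icer if isinstance(cmp_.icer, str) else f"{cmp_.icer:.2f}"
            writer.writerow([label, "acm", f"{acm.lifetime_cost:.2f}",
                             f"{acm.life_years:.4f}", f"{acm.qalys:.4f}",
                             icer_ly_label, icer_q, "", "", ""])
            cost_per_ly = no_acm.lifetime_cost / no_acm.life_years
            writer.writerow([label, "no_acm", f"{no_acm.lifetime_cost:.2f}",
                             f"{no_acm.life_years:.4f}", f"{no_acm.qalys:.4f}",
                             f"{cost_per_ly:.2f}", f"{cmp_.wtp:.2f}",
                             f"{cmp_.wtp:.2f}", f"{cmp_.nmb:.2f}",
                             f"{cmp_.nmb_annual:.2f}"])
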