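"""Cohort survival: anchor interpolation, exponential tail, mortality floor.

The annual survival trajectory is assembled from three registry anchors
(cumulative survival 1, 2 and 5 years after dialysis initiation), assuming
a constant hazard between years 2 and 5 (geometric interpolation) and a
constant annual mortality beyond year 5 implied by that hazard.  In every
cycle the dialysis-specific death probability is floored by the
age-specific death probability of the general population.  Life-years are
accrued with the life-table (half-cycle) method: state membership counts
the average of start- and end-of-cycle survivors, and the default discount
factor is evaluated at mid-cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .config import ModelSettings, SurvivalAnchors
from .errors import ValidationError

__all__ = [
    "LifeTable",
    "SurvivalCurve",
    "load_default_life_table",
    "interpolate_survival",
    "implied_tail_mortality",
    "apply_general_population_floor",
    "build_survival_curve",
    "discount_factors",
    "discounted_life_years",
]


@dataclass(frozen=True)
class LifeTable:
    """General-population annual death probabilities by single year of age."""

    ages: np.ndarray   # integer years, contiguous
    qx: np.ndarray     # annual death probability at each age

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or ages.shape != qx.shape:
            raise ValidationError("life_table", "ages and qx must be 1-D and aligned")
        if len(ages) and not np.all(np.diff(ages) == 1):
            raise ValidationError("life_table.ages", "ages must be contiguous")
        if np.any((qx < 0.0) | (qx > 1.0)):
            raise ValidationError("life_table.qx", "probabilities must be in [0, 1]")

    def qx_at(self, age: int) -> float:
        if not len(self.ages) or age < self.ages[0] or age > self.ages[-1]:
            raise ValidationError("life_table", f"age {age} outside table span")
        return float(self.qx[age - self.ages[0]])

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        if not {"age", "qx"} <= set(df.columns):
            raise ValidationError("life_table", "CSV must have columns 'age' and 'qx'")
        df = df.sort_values("age")
        return cls(df["age"].to_numpy(), df["qx"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "qx": self.qx}).to_csv(path, index=False)


def load_default_life_table() -> LifeTable:
    """The packaged synthetic general-population life table.

    A Gompertz-shaped stand-in resembling the German national period table
    at advanced ages; replace with the official CSV for production use.
    """
    with resources.files("anemia_cea.data").joinpath("life_table_synthetic.csv").open() as fh:
        return LifeTable.from_csv(fh)


@dataclass(frozen=True)
class SurvivalCurve:
    """Annual cohort survival S(t) for t = 0..T and per-cycle mortality q(t)."""

    survival: np.ndarray          # length T+1, S(0) = 1, nonincreasing
    annual_mortality: np.ndarray  # length T, q(t) = 1 - S(t)/S(t-1)

    def __post_init__(self):
        S = np.asarray(self.survival, dtype=float)
        q = np.asarray(self.annual_mortality, dtype=float)
        object.__setattr__(self, "survival", S)
        object.__setattr__(self, "annual_mortality", q)
        if len(S) != len(q) + 1:
            raise ValidationError("survival_curve", "survival must have one more entry than mortality")
        if abs(S[0] - 1.0) > 1e-12:
            raise ValidationError("survival_curve", "S(0) must equal 1")
        if np.any(np.diff(S) > 1e-12):
            raise ValidationError("survival_curve", "survival must be nonincreasing")
        if np.any((S < -1e-12) | (S > 1 + 1e-12)):
            raise ValidationError("survival_curve", "survival must lie in [0, 1]")

    @property
    def n_cycles(self) -> int:
        return len(self.annual_mortality)

    def membership_weights(self) -> np.ndarray:
        """Half-cycle person-year weight per cycle: (S(t-1) + S(t)) / 2."""
        S = self.survival
        return (S[:-1] + S[1:]) / 2.0


def interpolate_survival(anchors: SurvivalAnchors) -> np.ndarray:
    """Cumulative survival at years 0..5 from the three registry anchors.

    Years 3 and 4 follow S(t) = s2 * (s5/s2)**((t-2)/3): the constant-hazard
    (geometric) interpolation between the year-2 and year-5 anchors.
    """
    s1, s2, s5 = anchors.s1, anchors.s2, anchors.s5
    t = np.arange(6)
    out = np.empty(6)
    out[0] = 1.0
    out[1] = s1
    out[2:] = s2 * (s5 / s2) ** ((t[2:] - 2) / 3.0)
    return out


def implied_tail_mortality(anchors: SurvivalAnchors) -> float:
    """Constant annual death probability beyond year 5.

    Equals 1 - (s5/s2)**(1/3), i.e. the annual probability implied by the
    constant year 2-5 hazard, unless an explicit override is configured.
    """
    if anchors.tail_annual_mortality_override is not None:
        return float(anchors.tail_annual_mortality_override)
    return 1.0 - (anchors.s5 / anchors.s2) ** (1.0 / 3.0)


def apply_general_population_floor(q_dialysis: np.ndarray, life_table: LifeTable,
                                   start_age: int) -> np.ndarray:
    """Floor dialysis mortality with general-population mortality.

    Cycle t (age start_age + t at its end) uses
    q(t) = max(q_dialysis(t), qx(start_age + t)).
    """
    q_dialysis = np.asarray(q_dialysis, dtype=float)
    T = len(q_dialysis)
    ages = start_age + 1 + np.arange(T)
    qx = np.array([life_table.qx_at(int(a)) for a in ages])
    return np.maximum(q_dialysis, qx)


def build_survival_curve(anchors: SurvivalAnchors,
                         life_table: Optional[LifeTable] = None,
                         start_age: int = 67,
                         horizon_age: int = 100,
                         prevalent_5y: bool = False) -> SurvivalCurve:
    """Assemble the cohort's annual survival curve over the model horizon.

    Incident cohorts follow the interpolated anchor survival for years 1-5
    and the constant tail thereafter.  A prevalent cohort that has already
    completed five years on dialysis faces the tail rate from cycle 1
    (survival conditional on the 5-year anchor).  ``life_table=None`` skips
    the general-population floor.
    """
    if horizon_age > 100:
        raise ValidationError("horizon_age", "must be <= 100")
    T = horizon_age - start_age
    if T < 1:
        raise ValidationError("horizon_age", "must exceed start_age")
    q_tail = implied_tail_mortality(anchors)
    q = np.full(T, q_tail)
    if not prevalent_5y:
        s05 = interpolate_survival(anchors)
        n_anchor = min(5, T)
        q[:n_anchor] = 1.0 - s05[1:n_anchor + 1] / s05[:n_anchor]
    if life_table is not None:
        q = apply_general_population_floor(q, life_table, start_age)
    survival = np.concatenate([[1.0], np.cumprod(1.0 - q)])
    return SurvivalCurve(survival=survival, annual_mortality=q)


def discount_factors(n_cycles: int, rate: float, timing: str = "midcycle") -> np.ndarray:
    """Annual discount factors d(t) for cycles t = 1..n_cycles."""
    if rate < 0.0:
        raise ValidationError("discount_rate", "must be >= 0")
    if timing not in ("midcycle", "endcycle"):
        raise ValidationError("discount_timing", f"unknown timing {timing!r}")
    t = np.arange(1, n_cycles + 1, dtype=float)
    exponent = t - 0.5 if timing == "midcycle" else t
    return (1.0 + rate) ** -exponent


def discounted_life_years(curve: SurvivalCurve, rate: float,
                          timing: str = "midcycle") -> float:
    """Discounted life expectancy by the half-cycle (life-table) sum."""
    w = curve.membership_weights()
    d = discount_factors(curve.n_cycles, rate, timing)
    return float(np.sum(w * d))
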