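# Methods

## Model structure and assumptions

The model is a deterministic two-state (alive/dead) Markov cohort
simulation with 12-month cycles, run separately for an intervention arm
(hemodialysis with the anemia-management decision support system) and a
comparator arm (hemodialysis without it).  Patients enter alive at age 67
and can only transition to death; the horizon ends at age 100 (33 cycles),
beyond which well under 0.1% of the cohort survives.  Clinical events —
hospitalizations, inappropriate ESA administration (ESA at Hb > 12 g/dL)
and severe anemia (Hb < 9 g/dL) — do not form separate states and do not
affect mortality; they attach costs and utility decrements to the alive
state.  Both arms therefore have identical life expectancy by
construction, and every incremental effect flows through costs and
quality weights.  The perspective is the statutory health insurance
payer: the intervention itself costs the payer nothing (it is not
reimbursed), so its value is the sum of induced savings plus monetized
QALY gains.

## Survival

Cohort survival is anchored at registry values S(1) = 0.857,
S(2) = 0.755 and S(5) = 0.474.  Years 3–4 are interpolated assuming a
constant hazard between years 2 and 5,
S(t) = S(2)·(S(5)/S(2))^((t−2)/3), and beyond year 5 mortality is
constant at the implied annual probability 1 − (S(5)/S(2))^(1/3) ≈ 0.1437
(an exponential tail).  The tail probability is overridable
(the one-way analysis spans 0.10–0.20).  In every cycle the
dialysis-specific death probability is floored by the age-specific
general-population probability, q(t) = max(q_dialysis, qx(age)); with the
packaged life table the floor binds only from about age 89 and moves
discounted life expectancy by ~0.02 years.  A prevalent-cohort scenario
(five years on dialysis already) applies the tail rate from cycle 1 at
unchanged entry age.

Accrual uses the life-table (half-cycle) method: cycle t contributes
(S(t−1)+S(t))/2 person-years, and the default discount factor is
(1+r)^−(t−½), consistent with events occurring mid-cycle; an
end-of-cycle exponent (1+r)^−t is available via
`settings.discount_timing`.

### Divergence from the published life-year levels

The published evaluation prints 7.03 undiscounted and 5.71 discounted
life-years.  Exhaustive checking of membership conventions
(start-of-cycle, half-cycle average, end-of-cycle) crossed with discount
exponents (t−1, t−½, t), tail-rate definitions and floor strengths shows
no combination of the stated anchor/interpolation/tail construction that
reproduces both numbers at once: the half-cycle model yields
(6.51, 5.51); the only parameterizations that match both require a tail
probability near 0.108 that nothing in the inputs implies, and leave ~2%
of the cohort alive at 100, contradicting the stated "<0.1%".  This
package implements the stated construction and accepts the lower
absolute levels.  The divergence cancels out of every incremental
quantity: λ is a per-person-year ratio and independent of it, and ΔE, ΔC
and NMB all scale with the same life-expectancy factor, staying within a
few percent of the published values.

## Costs and quality weights

The annual cost of an HD patient (€54,604 in 2017 euros) is inflated to
2024 euros with a configurable CPI factor.  Its default, 1.2375, is
calibrated so the 2024 cost (~€67,572/patient-year) matches the printed
cost per life-year; the official index value can be substituted in the
configuration.  The DRG hospitalization tariff (€4,210.59, 2025 base
rate) is used directly without further adjustment.

Monthly event rates are converted to annual exposure proportions by
multiplying by 12 (capped at one patient-year, with a logged warning) and
valued against full-year quantities.  Per person-year the intervention
arm saves:

* hospitalization: ARR × DRG cost (0.126 × €4,210.59 ≈ €531);
* ESA (default "full" mode): avoided inappropriate administrations,
  rate × (1 − RR) × 12 × annual ESA cost, plus the additional ESA-free
  patient-month proportion × annual ESA cost.  Because the two components
  may overlap, a conservative `esa_free_only` mode keeps only the second;
* hypertension: the ESA-attributable prevalence shift — baseline
  prevalence 0.92 mapped through the odds ratio 2.10 on the odds scale
  (+4 percentage points) — times the ESA-free proportion, valued at the
  annual management cost of atenolol (1.56 packs × €23.31, from 3 × 100 mg
  weekly) plus two outpatient visits (€18.34 each).

Utility on hemodialysis is 0.69; severe anemia carries a 0.03 decrement
applied to the annualized severe-anemia exposure (rate × RR × 12 × 0.03
per person-year), inside the same half-cycle weight as the utility
itself.  A no-quality-of-life-effect scenario removes the decrement from
both arms.  Effect sizes are tier-specific: the comparator may be set to
tier 1 (< 70% of patients in the Hb 10–12 g/dL target), tier 2 (70–80%)
or tier 3 (> 80%), with correspondingly smaller baseline event rates and
weaker relative effects.

## Willingness-to-pay and net monetary benefit

λ is endogenous: lifetime discounted cost over lifetime discounted QALYs
of the comparator arm, with no-treatment (immediate death, zero cost,
zero QALYs) as the reference.  Because costs and utilities are constant
per person-year, λ is invariant to the discount rate.  For tier-2/3
comparisons λ is recomputed from that tier's comparator arm (the
published definition does not qualify the tier; a fixed tier-1 λ can be
passed explicitly).  NMB = λ·ΔE − ΔC, annualized by the comparator's
discounted life expectancy — the discounted divisor is the only choice
consistent with the published annualized figure.

## Sensitivity analysis

One-way analysis re-runs the pipeline at both bounds of each parameter's
published range — including discount rate 0–5%, tail mortality 0.10–0.20,
survival anchors, and the four scenario switches (no QoL effect,
ESA-free-only savings, one-year effect duration, prevalent cohort) — and
ranks NMB interval widths descending (ties alphabetical).

The probabilistic analysis assigns each uncertain input a marginal by
support: beta for probabilities/rates/utilities (method of moments on
mean and SE = CI width/3.92), lognormal for relative risks and the odds
ratio (σ from the log-CI, median at the point value), gamma for the
annual dialysis cost (moments), triangular for the annual ESA cost
(midpoint mode on the printed min/max), uniform for the hospitalization
ARR and the anemia disutility (printed ranges as hard bounds), and a
normal truncated to [0,1] for the ESA-free-month differences (the
truncation is implemented through the truncated-normal inverse CDF,
which is equivalent in distribution to resampling out-of-support draws).
Draws are joined by a Gaussian copula: standard-normal scores correlated
via the Cholesky factor (coefficient 0.5 between the hospitalization ARR
and the active tier's severe-anemia RR), mapped through each marginal's
inverse CDF.  λ is held at its deterministic base-case value across
draws so the threshold acts as a fixed decision rule rather than a
self-referential quantity (per-draw recomputation is available via
`resample_wtp=True`).  Survival anchors are excluded from the default
PSA (their CIs are negligible and the published analysis gives no
indication they were resampled); they can be sampled by passing custom
specs.  Each draw's (ΔE, ΔC) pair is classified on the
cost-effectiveness plane; boundary cases (ΔE = 0 or ΔC = 0) count as
non-southeast, a probability-zero event under continuous draws.  1,000
draws give stable quadrant shares; draws that fail bundle validation are
rejected and logged, and more than 1% rejections abort the run (in
practice none occur under the default ranges).

## Synthetic data

The packaged general-population life table is synthetic: a Gompertz
hazard h(a) = s·e^{s(a−m)} with steepness s = 0.12 and modal age m = 86,
chosen to resemble a national period table at old ages (q(90) ≈ 0.18,
q(95) ≈ 0.30).  It reproduces the structural role of the official table —
a floor that binds only at advanced ages — but not its exact values, so
tests passing with it say nothing about the third decimal of life
expectancy under the official table; users substitute the official CSV
(`age,qx`) for production estimates.  `generate_parameter_bundle`
produces seeded, log-normally jittered parameter sets re-clamped into
each field's support, used to fuzz the validation layer.  `toy_scenario`
provides constant-hazard cohorts whose discounted life-years, QALYs and
costs have closed geometric-series forms; the engine must match them to
1e-9, which pins down the accrual and discounting conventions exactly.

## Numerical choices and edge cases

All computation is double precision; exports round currency to 2 and
life-years/QALYs to 4 decimals.  ICERs are reported only when ΔC and ΔE
share a sign; otherwise the comparison is labelled dominant/dominated.
Equal-width tornado bars order alphabetically.  Annualized exposure
proportions cap at 1.0.  Validation is total: every field of every input
type either satisfies its invariant or raises an error naming the field;
the PSA revalidates every sampled bundle.  Monte-Carlo runs are fully
determined by (parameter set, seed); per-draw CSVs are byte-identical
across reruns.

## Problem sizes

The base case is a 33-cycle deterministic recursion (instantaneous).
The default PSA uses 1,000 draws; test-suite PSAs use 100–1,000 draws
and the microsimulation cross-check uses 100,000 simulated patients,
sizes at which Monte-Carlo error is far below the decision-relevant
differences.

## Known limitations

No transplantation, modality switching, vascular-access events or
transfusion costs; no mortality effect of the intervention (the
underlying evidence showed none); cohort-level expectation only (no
patient-level heterogeneity beyond the microsimulation oracle used for
verification); the CPI factor and the ESA-saving decomposition are
reconstructions calibrated to printed aggregates, not directly published
inputs; tier-2/3 λ handling is a documented interpretation.
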