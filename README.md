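# anemia-cea

A Markov cohort cost-utility model of an AI-based anemia-management
decision support system (the Anemia Control Model, ACM) for adult
in-center hemodialysis (HD) patients, evaluated from the perspective of
the German statutory health insurance.

The package is aimed at health economists and HTA analysts who want a
tested, scriptable re-implementation of the published evaluation: every
input is a validated configuration value, every analysis step (survival
construction, cohort accrual, willingness-to-pay, one-way and
probabilistic sensitivity analysis) is an importable function, and all
results are reproducible from seeds.

## The model

Two health states, alive and dead, with 12-month cycles from cohort entry
(age 67) to age 100.  Annual cohort survival comes from registry anchors
S(1) = 0.857, S(2) = 0.755, S(5) = 0.474, geometric (constant-hazard)
interpolation for years 3–4, a constant annual mortality
q = 1 − (S(5)/S(2))^(1/3) ≈ 0.144 beyond year 5, and a general-population
mortality floor q(t) = max(q_dialysis, qx(age)).  State membership uses
the life-table (half-cycle) method, membership_t = (S(t−1) + S(t))/2,
discounted at (1+r)^−(t−½) with r = 3% in the base case.

Hospitalizations, inappropriate ESA administration (erythropoiesis-
stimulating agents given at Hb > 12 g/dL) and severe anemia (Hb < 9 g/dL)
are within-state modifiers: monthly event rates are annualized
(rate × RR × 12) and valued against annual costs and the severe-anemia
disutility (0.03).  Per person-year the intervention arm saves

* ARR × DRG tariff (0.126 × €4,210.59) from avoided hospitalizations,
* avoided inappropriate ESA use plus the additional ESA-free patient-month
  proportion, both valued at the annual ESA cost (€5,200), and
* an ESA-induced-hypertension component via the odds-ratio prevalence
  shift (0.92 → 0.96 under OR 2.10).

The willingness-to-pay threshold is endogenous — the cost-utility ratio of
HD itself versus no treatment (immediate death) — and the net monetary
benefit is NMB = λ·ΔE − ΔC, annualized by the discounted life expectancy.
One-way sensitivity analysis varies every input over its published range;
the probabilistic sensitivity analysis samples all uncertain inputs from
beta/lognormal/gamma/triangular/uniform/normal marginals joined by a
Gaussian copula with normal-score correlation 0.5 between the
hospitalization ARR and the severe-anemia RR.

## Worked example

```python
from anemia_cea import default_bundle, run_base_case

res = run_base_case(default_bundle())
c = res.comparison
print(f"λ = €{res.wtp:,.0f}/QALY; ΔC = €{c.delta_cost:,.0f}; "
      f"ΔE = {c.delta_qaly:.4f}; NMB = €{c.nmb:,.0f}")
```

prints

```
λ = €100,500/QALY; ΔC = €-31,614; ΔE = 0.0573; NMB = €37,374
```

meaning: statutory health insurance implicitly pays about €100,500 per
QALY for dialysis itself; adding the decision support system saves about
€31,600 per patient lifetime while adding 0.057 QALYs, a dominant result
worth about €37,400 per patient (≈ €6,790 per patient-year, an upper
bound for a value-based subscription fee).  `examples/` contains one
narrative script per capability (base case, survival curve, scenarios,
one-way tornado, probabilistic SA); each prints the numbers it computes
and a line on how to read them.

A thin CLI mirrors the three main outputs:

```bash
anemia-cea run --tier 1 --out results/
anemia-cea psa --n 1000 --seed 42 --out results/
anemia-cea tornado --out results/
```

Custom inputs go in a YAML/JSON file (see
`src/anemia_cea/data/defaults.yaml` for the full schema) passed with
`--config`; runs are reproducible given (config hash, seed) and write a
manifest next to their outputs.

## Caveat on absolute life-years

The published discounted/undiscounted life-year pair is not jointly
reproducible from the stated anchor interpolation and tail assumption
under any standard membership/discounting convention (see
`docs/methods.md`); this package implements the stated methods, which
yield slightly lower absolute life-years and QALYs.  Incremental results
(ΔE, λ, NMB) are insensitive to this divergence.
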