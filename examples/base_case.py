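"""Base-case cost-utility run: both arms, willingness-to-pay, NMB.

Builds the packaged parameter set (tier-1 comparator, 3% discounting),
runs the two-arm Markov cohort to age 100 and prints the headline
economics.  The intervention is cost-saving and QALY-increasing, so it
dominates: NMB = λ·ΔE − ΔC is positive.
"""

from anemia_cea import default_bundle, run_base_case

bundle = default_bundle()
res = run_base_case(bundle)

print("Discount rate: %.0f%%" % (100 * bundle.economics.discount_rate))
for arm in (res.acm, res.no_acm):
    print(f"  {arm.arm_id:7s} lifetime cost €{arm.lifetime_cost:10,.0f}  "
          f"LY {arm.life_years:.2f}  QALYs {arm.qalys:.2f}")
c = res.comparison
print(f"Willingness-to-pay (HD vs no treatment): €{res.wtp:,.0f} per QALY")
print(f"ΔCost €{c.delta_cost:,.0f}  ΔQALY {c.delta_qaly:.4f}  ICER: {c.icer}")
print(f"NMB €{c.nmb:,.0f} per patient  (€{c.nmb_annual:,.0f} per patient-year)")
# Negative ΔCost with positive ΔQALY means the decision support system both
# saves money (fewer hospitalizations, less ESA use) and adds quality of life.
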