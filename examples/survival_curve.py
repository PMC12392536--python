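"""Cohort survival from registry anchors: interpolation, tail, floor.

Shows the annual survival trajectory used by the model: anchors at years
1/2/5, constant-hazard interpolation in between, the implied constant
annual mortality (~14.4%) beyond year 5, and the general-population
mortality floor at advanced ages.
"""

from anemia_cea import (build_survival_curve, default_bundle,
                        discounted_life_years, implied_tail_mortality,
                        load_default_life_table)

bundle = default_bundle()
life_table = load_default_life_table()
curve = build_survival_curve(bundle.anchors, life_table)

print(f"Implied tail annual mortality: {implied_tail_mortality(bundle.anchors):.4f}")
for t in (0, 1, 2, 3, 5, 10, 20, 33):
    print(f"  year {t:2d}  S = {curve.survival[t]:.4f}")
print(f"Alive at age 100: {100 * curve.survival[-1]:.3f}% of the cohort")
for r in (0.0, 0.03, 0.05):
    print(f"Discounted life expectancy at {r:.0%}: "
          f"{discounted_life_years(curve, r):.3f} years")
# Life-years use the life-table (half-cycle) method: membership counts the
# average of start- and end-of-cycle survivors, discounted at mid-cycle.
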