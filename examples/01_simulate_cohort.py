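"""Simulate the default synthetic cohort and inspect its structure.

Draws the 446-patient cohort with the default attrition funnel and prints
the stage counts and the demographic/comorbidity margins the generator is
calibrated to.
"""

from psyprog import CohortConfig, filter_eligible, simulate_cohort
from psyprog.mini_items import MINI_COLUMNS

cohort = simulate_cohort(CohortConfig(seed=0))

print(f"enrolled:             {len(cohort)}")
print(f"completed phase 1:    {cohort['completed_phase1'].sum()}")
print(f"completed phase 2:    {cohort['completed_phase2'].sum()}")
print(f"analysis-eligible:    {len(filter_eligible(cohort))}")
print()
eligible = filter_eligible(cohort)
mini = eligible[MINI_COLUMNS].to_numpy()
print("among the eligible patients:")
print(f"  male:               {eligible['sex_male'].mean():.0%}")
print(f"  mean age:           {eligible['age'].mean():.1f} years")
print(f"  admitted:           {eligible['admitted'].mean():.0%}")
print(f"  any comorbidity:    {mini.any(axis=1).mean():.0%}")
print(f"  current suicidality:{eligible['mini_11'].mean():.0%}")
print(f"  symptomatic remission at week 8: {eligible['remission_sr'].mean():.0%}")

# The funnel counts are exact by construction; the margins drift with the
# small eligible sample but match their configured values at large n.
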