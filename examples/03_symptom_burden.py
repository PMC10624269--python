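"""Bracket the burden of suffering in symptom-days.

The at-most bound adds N x prevalence x duration over all symptoms; the
at-least bound keeps only the longest-duration symptom per condition and
status. The truth lies between, since symptom overlap within days is
unknown.
"""

from palcare import GeneratorSpec, estimate_all_needs, make_scenario, symptom_shares
from palcare.symptoms import estimate_all_burdens

scenario = make_scenario(GeneratorSpec(seed=7))
needs = estimate_all_needs(scenario)
burdens = estimate_all_burdens(scenario, needs)

total_most = sum(b.at_most_days for b in burdens)
total_least = sum(b.at_least_days for b in burdens)
print(f"region symptom-days: at least {total_least/1e6:,.0f}M, "
      f"at most {total_most/1e6:,.0f}M")

b = burdens[0]
shares = symptom_shares(b)
triad = shares["pain"] + shares["fatigue"] + shares["weakness"]
print(f"{b.country}: pain {shares['pain']:.1f}%, fatigue {shares['fatigue']:.1f}%, "
      f"weakness {shares['weakness']:.1f}% (together {triad:.1f}%)")
print("Pain, fatigue and weakness together carry more than half of all")
print("symptom-days — the pattern the coefficient defaults are built to show.")
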