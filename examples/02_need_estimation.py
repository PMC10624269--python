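"""Estimate people in need of palliative care, by country and condition.

Need is deaths (or prevalent non-fatal cases) times the per-condition
need fraction; condition shares say which illnesses generate the need.
"""

from palcare import (
    GeneratorSpec,
    condition_shares,
    estimate_all_needs,
    make_scenario,
    regional_totals,
)

scenario = make_scenario(GeneratorSpec(seed=7))
needs = estimate_all_needs(scenario)

region = regional_totals(needs)
print(f"region total in need: {region.grand_total:,.0f} "
      f"({region.decedent_total:,.0f} decedents, "
      f"{region.nondecedent_total:,.0f} non-decedents)")

hiv_country = needs[0]  # LIC-1, the planted HIV-dominated country
shares = condition_shares(hiv_country)
top3 = sorted(shares.items(), key=lambda kv: -kv[1])[:3]
print(f"{hiv_country.country} condition shares (top 3):")
for code, share in top3:
    print(f"  {code:12s} {share:5.1f}%")
print("Shares are percentages of the country's total need and sum to 100;")
print("an HIV share above 70% mirrors the most HIV-burdened settings.")
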