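"""Reproduce the published regional aggregations from the printed tables.

The bundled reference tables carry the published per-country estimates
for the Eastern Mediterranean Region in 2015; pushing them through the
package's aggregation and normalization operations reproduces every
internally consistent printed derivation.
"""

from palcare import NeedEstimate, fte_per_100k, regional_totals, round_half_up
from palcare.datasets import eamreg_2015_need_table, eamreg_2015_workforce_table

need = eamreg_2015_need_table()
estimates = [
    NeedEstimate(country=r.country,
                 decedents_in_need={"all": r.decedents_thousands * 1e3},
                 nondecedents_in_need={"all": r.nondecedents_thousands * 1e3})
    for r in need.itertuples()
]
region = regional_totals(estimates)
print(f"decedents in need, region:  {region.decedent_total/1e3:,.0f} thousand")
print(f"total in need, region:      "
      f"{round_half_up(region.grand_total/1e6, 1)} million")

wf = eamreg_2015_workforce_table().set_index("country")
for country in ("Afghanistan", "Morocco", "Jordan"):
    v = fte_per_100k(int(wf.loc[country, "fte_doctor"]),
                     int(wf.loc[country, "population"]))
    print(f"{country:12s} doctor FTEs per 100k: {v:.2f}")
print("1,602 thousand decedents and the 3.2 million regional headline come")
print("straight from summing the printed country rows; per-100k values are")
print("100,000 x FTE / population, rounded half-up to two decimals.")
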