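"""Forecast cohort depletion by numerical integration of the Gompertz law.

Restores the worked integration from the Tosnensky life table: starting
from a conditional 1500 first-lactation cows, the published per-lactation
retention factors deplete the cohort until fewer than one cow remains.
Also shows the same forecast driven by fitted Gompertz parameters.
"""

import herdspan as hs

# empirical rates (from the published life table)
result = hs.integrate_cohort(hs.datasets.TOSNO_INTEGRATION_RATES, 1500)
print("lactation  predicted count")
for t, n in zip(result.cohort.t, result.cohort.rounded_counts()):
    print(f"{t:9d} {n:12d}")
print(f"T = {result.T:.2f} lactations, t_max = {result.t_max}, "
      f"remnant = {result.remnant_fraction:.3f}")

# the same herd through its fitted hazard instead of the raw rates
params = hs.fit_gompertz(
    hs.compute_disposal_series(hs.datasets.tosno_cohort())
)
model = hs.integrate_cohort(params, 1500)
print(f"\nmodel-based forecast: T = {model.T:.2f}, t_max = {model.t_max}")

# t_max is the predicted maximum productive life span in this herd: the
# last lactation at which at least one of the 1500 cows is still present.
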