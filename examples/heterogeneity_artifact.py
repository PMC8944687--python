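"""The Strehler-Mildvan correlation as a pure heterogeneity artifact.

All four reference model populations share the same true aging rate
c = 0.15 and differ only in how strongly their subcohorts vary in the
baseline hazard B.  Refitting a Gompertz law to each pooled series yields
apparent aging rates that fall as heterogeneity grows — a negative (B, c)
association with no biological trade-off behind it.
"""

import herdspan as hs

pops = hs.datasets.model_populations()
results, corr = hs.strehler_mildvan_scan(list(pops.values()))

print("population  subcohort B values      apparent B  apparent c")
for (k, spec), ap in zip(pops.items(), results):
    bs = "/".join(f"{s.B:.2f}" for s in spec.subcohorts)
    print(f"{spec.label:>10}  {bs:<22} {ap.params.B:10.2f} {ap.params.c:11.3f}")

print(f"\ncorrelation of apparent (B, c) across populations: {corr:+.2f}")
print("true aging rate of every subcohort: c = 0.150")

# Apparent c drops from 0.15 to ~0.085 while every animal ages at the same
# rate: frail subcohorts (high B) leave the herd early, flattening the
# pooled hazard.  Cross-herd (B, c) scatter of this shape is therefore not
# evidence of a compensation law.
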