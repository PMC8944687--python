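# herdspan

Gompertz life-table analysis and productive-life-span forecasting for
dairy-cow herds.

Dairy cows leave a herd long before their biological life span ends —
culled for udder, fertility, leg and metabolic problems, or dead — and the
herd-level pace of that loss is the most general quantitative indicator of
herd welfare. `herdspan` is a toolkit for analysts who have nothing more
than registration tables (counts of cows at successive lactation numbers,
or binned age-composition reports) and want to estimate survival
parameters, forecast productive life span (PLS), and avoid the classic
pitfall of fitting one hazard law to a heterogeneous population.

## The model

The per-lactation **relative disposal rate** of a cohort,

```
y(t) = ΔN_t / N_t,          ΔN_t = N_t − N_{t+1},
```

is treated as a discrete hazard following the **Gompertz law**

```
y(t) = B · exp(c · t)
```

with `c` the aging rate and `B` the baseline hazard level. Fitting is OLS
of `ln y` on `t` — exactly a spreadsheet exponential trendline, by design.
From a fitted or empirical hazard the package integrates the depletion
recursion `N_{t+1} = N_t (1 − y(t+1))` to forecast the cohort, and reports

- the **viability index** `1/y₁` (reciprocal first-lactation disposal
  rate), a predictor of average PLS: `T = 0.26·(1/y₁) + 1.2`;
- the **average PLS** `T = Σ Δn_t · t` (exit-fraction-weighted mean
  lactation) and the **maximum PLS** `t_max` (last lactation with ≥ 1 cow);
- **apparent Gompertz parameters of mixtures**: pooling subcohorts that
  share `c` but differ in `B` flattens the pooled hazard, so the refitted
  `c` is biased low — the Strehler–Mildvan correlation reproduced as a pure
  heterogeneity artifact;
- per-lactation counts **reconstructed from binned composition tables**
  (bins like 4–5, 6–7, 10+ split along the fitted depletion trend with
  exact bin-sum preservation);
- the **305-d milk-yield model** `y_m(t) = A · exp(−exp(−b t)) · D^t`,
  whose degradation base `D` is a second viability indicator linked to
  longevity by `D = 0.88 + 0.008·t_max` (equivalently `t_max = 125·D − 110`).

## Worked example

```python
import herdspan as hs

cohort = hs.datasets.tosno_cohort()          # counts 5825 … 31, lactations 1–11
disposal = hs.compute_disposal_series(cohort)
params = hs.fit_gompertz(disposal)
print(params.B, params.c, params.r2)         # 0.190 0.120 0.920
print(hs.viability_index(disposal))          # 4.09
print(hs.average_pls(disposal))              # 3.47

forecast = hs.integrate_cohort(hs.datasets.TOSNO_INTEGRATION_RATES, 1500)
print(list(forecast.cohort.rounded_counts()))
# [1500, 1213, 899, 585, 372, 230, 121, 63, 30, 10]
print(forecast.t_max)                        # 10
```

The disposal rate climbs from 0.244 at first lactation to 0.65 at the
tenth; a quarter of heifers never reach a second lactation (`1/y₁ ≈ 4.1`),
the average cow completes about 3.5 lactations, and a conditional cohort
of 1500 first-lactation cows is forecast to be essentially gone after
lactation 10.

The heterogeneity demonstration, run over the four built-in reference
model populations (all with true `c = 0.15`):

```python
results, corr = hs.strehler_mildvan_scan(list(hs.datasets.model_populations().values()))
print([round(r.params.c, 3) for r in results])   # [0.15, 0.127, 0.107, 0.084]
print(round(corr, 2))                            # -1.0
```

Each script in `examples/` is a narrative version of one capability
(life-table fitting, forecasting, the heterogeneity artifact, unbinning,
milk-yield degradation, stochastic simulation); run them with
`python examples/<name>.py`. A thin CLI mirrors the library:
`herdspan fit --input cohort.csv`, `herdspan forecast --params 0.1,0.15
--n1 1500`, `herdspan mixture --spec mix.yaml`, `herdspan unbin`,
`herdspan milkfit`, `herdspan simulate`.

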