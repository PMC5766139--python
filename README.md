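# speiyield

Quantifying how rain-fed crop yields respond to moisture variability.

Winter wheat in humid and semi-humid mid-latitude regions suffers from both
water deficit and water excess over its nine-month growing season
(October–June). `speiyield` implements the complete statistical chain used
to study that response with the Standardized Precipitation
Evapotranspiration Index (SPEI):

1. **Multi-scalar SPEI** from monthly station records: Thornthwaite
   potential evapotranspiration PET from temperature and latitude, climatic
   water balance `D = P − PET`, trailing `k`-month aggregation, a
   three-parameter log-logistic distribution fitted per calendar month by
   L-moments, and the inverse-normal standardization

   `SPEI = W − (C₀ + C₁W + C₂W²)/(1 + d₁W + d₂W² + d₃W³)`, `W = √(−2 ln P)`,

   so that each month's value is in standard-normal units (negative = dry,
   positive = wet).
2. **Trend quantification** with the Mann-Kendall test (tie-corrected
   variance, continuity-corrected Z) and Sen's slope.
3. **Yield–moisture linkage**: growth-stage covariates (S1 sowing/seedling
   Oct–Nov, S2 over-wintering Dec–Feb, S3 late growth Apr–Jun), first-order
   differencing of both yields and SPEI, and Pearson correlation tables
   with 5 % / 1 % significance stars.
4. **Quadratic fixed-effects panel model** on pooled site-year data,

   `Y_it = β_i + α₁·s_it + α₂·s_it² + α₃·t + u_it`,  `u_it = ρ·u_i,t−1 + ε_it`,

   estimated by least squares with site dummies (LSDV), screened for serial
   correlation with a within-site Durbin-Watson test and re-estimated with
   AR(1) errors by iterated Cochrane-Orcutt when needed. The concave
   quadratic yields an optimum moisture level `−α₁/(2α₂)`, loss thresholds
   (the roots of `α₁s + α₂s² = 0`), and a moisture-level → yield-response
   table in kg/ha.

A synthetic-data module generates climate panels (seasonal cycle, warming
trend, gamma monthly precipitation with a monsoon weight profile and a
north-dry/south-wet gradient) and yields drawn from the panel model itself,
so the whole pipeline is testable end to end without external data.

Intended users: agro-climatologists and crop modellers analysing drought /
waterlogging impacts on annual yields from monthly climate panels.

## Worked example

```python
import speiyield as sy

sites = sy.default_sites()                      # 10 stations, 31–35 °N
climate = sy.generate_climate(sites, start_year=1979, n_years=36, seed=7)
spei = sy.compute_spei(climate, scales=[1, 3])
cov = sy.season_covariate(spei[spei.scale_k == 3], "S3",
                          harvest_years=range(1980, 2015))
yields = sy.generate_yields(cov, sy.default_panel_params(sites), seed=8)
fit = sy.fit_panel(yields, cov)
print(f"alpha1={fit.alpha1:.4f}  alpha2={fit.alpha2:.4f}  alpha3={fit.alpha3:.4f}")
print(f"rho={fit.rho:.3f}  dw={fit.dw:.3f}  adj_r2={fit.adj_r2:.3f}  n_obs={fit.n_obs}")
print(f"optimum SPEI = {sy.optimum_spei(fit):.2f}")
print(sy.response_table(fit)[["level", "spei_interval", "response_interval"]]
      .to_string(index=False))
```

prints

```
alpha1=-0.1467  alpha2=-0.1361  alpha3=0.0653
rho=0.398  dw=1.168  adj_r2=0.787  n_obs=350
optimum SPEI = -0.54
           level spei_interval response_interval
 extreme wetting         >=2.0          <=-837.7
moderate wetting    [1.0, 2.0)  (-837.7, -282.8]
  slight wetting    [0.5, 1.0)  (-282.8, -107.4]
          normal   (-0.5, 0.5)    (-107.4, 39.3)
  slight drought  (-1.0, -0.5]      (10.7, 39.5]
moderate drought  (-2.0, -1.0]    (-250.8, 10.7]
 extreme drought        <=-2.0          <=-250.8
```

The fitted slopes recover the coefficients the yields were generated from
(α₁ = −0.1592, α₂ = −0.1297, α₃ = 0.0626, ρ = 0.39) within sampling error.
The low Durbin-Watson statistic (1.17) triggers the AR(1) re-estimation;
`dw` reports the pre-AR(1) diagnostic. The response table reads, e.g.:
under slight wetting the model attributes a yield change between −282.8 and
−107.4 kg/ha relative to neutral moisture (SPEI = 0), while the best
attainable increment sits at the slightly-dry optimum. Wet anomalies cost
more than equally-sized dry ones — the asymmetric response typical of
waterlogging-limited regions.

The same pipeline is available from the shell:

```sh
speiyield simulate --n-years 36 --seed 7 --out-prefix demo
speiyield run demo_climate.csv demo_yield.csv --out-dir out
```

which writes `spei.csv`, `trends.csv`, the two correlation tables,
`panel_fit.json`, `response_table.csv`, `decade_summary.csv` and a
`manifest.json` with input/output hashes for reproducibility.

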