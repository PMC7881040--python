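# vegcarry

Tools for quantifying **vegetation growth carryover (VGC)** — the effect of
the preceding season's (or year's) vegetation state on subsequent growth —
and for weighing it against the immediate and lagged effects of climate.

The package is aimed at terrestrial carbon-cycle and ecological
time-series analysts working with gridded vegetation-index records (NDVI,
LAI), flux-tower or model productivity (GPP), and tree-ring chronologies.
Because the interesting signal is a *conditional* dependence — does last
season's greenness matter once climate is accounted for? — every statistic
here is built around partial correlation and regression decomposition, and
every estimator can be validated on synthetic data whose carryover,
climate sensitivities and trends are known exactly.

## What it computes

**Season delineation.** Per grid cell, the early, peak and late growing
seasons (EGS/PGS/LGS) and the dormancy season (DS) are delineated from the
climatological mean seasonal cycle of the vegetation index: the start and
end of season are the days when the daily rate of change of the cycle is
highest/lowest; the PGS is the two consecutive months of maximum greenness
(April–October); cells peaking outside that window are excluded. A
site-level variant detects the season bounds from the second derivative of
spline-smoothed daily GPP.

**Seasonal carryover profiles.** For a target season, the partial
correlation r_p between seasonal greenness Y and each of five drivers —
preceding-season greenness Y_ps, concurrent temperature TMP and
precipitation PRE, and preceding-season TMP_ps and PRE_ps — with the other
four drivers controlled. For the EGS, Y_ps is the previous year's LGS
greenness (dormant-season greenness is unobservable under snow).

**Trend attribution.** The multi-year linear trend of seasonal greenness
is decomposed into additive driver contributions,

    dY/dt = Σ_X (∂Y/∂X)(dX/dt) + ε,   X ∈ {Y_ps, TMP_ps, PRE_ps, TMP, PRE}

with sensitivities ∂Y/∂X estimated by one joint multiple linear
regression, temperature and precipitation combined into lagged (CLM_ps)
and concurrent (CLM) climate terms, and the residual trend closing the
identity exactly.

**Interannual persistence.** Lead-j partial autocorrelation (j = 1..3) of
annual greenness or tree-ring series, controlling climate of the present
and preceding year and the series at all smaller leads — a measure of how
many years the carryover survives.

**Tree rings.** A Tucson/RWL reader-writer, cubic-smoothing-spline
standardization (50% frequency response at 67% of series length), Tukey
biweight robust-mean chronologies, and the same lead-1..3 analysis grouped
by wood-porosity class.

**Dominance maps and path models.** Per-cell classification of the
strongest driver family (carryover vs concurrent vs preceding climate)
with area-fraction summaries for observation-model comparison, and a
recursive path model of the spring-to-summer vegetation-climate-soil
network, with the soil-moisture/vegetation link oriented by the sign of
their correlation.

All inputs can be generated by `vegcarry.simulate`, which emulates
biweekly greenness curves, a season-chained driver system with prescribed
carryover γ, annual AR(1) series, and raw ring widths — each with a truth
record for scoring recovery.

## Worked example

Simulate a 500-cell, 35-year seasonal system with the default moderate
carryover (γ = 0.4 per season transition), then estimate the peak-season
carryover profile and trend attribution:

```python
from vegcarry import simulate, memory_stats, attribution

cfg = simulate.SeasonalSystemConfig(n_cells=500, n_years=35, seed=42)
data = simulate.simulate_seasonal_system(cfg)

profiles = memory_stats.grid_vgc_profiles(data, season="PGS")
print(memory_stats.sign_frequency_summary(
    profiles[profiles.driver == "ndvi_ps"]).round(1).to_string(index=False))

per_cell = attribution.grid_attribution(data, season="PGS")
print(attribution.summarize_contributions(per_cell).round(4).to_string(index=False))
```

Output:

```
group   n  pct_positive  pct_negative  pct_sig_positive  pct_sig_negative  n_undefined
  all 500          98.8           1.2              67.0               0.0            0

component  mean_contribution  share_pct
      vgc             0.0006    40.0717
   clm_ps             0.0003    20.7558
      clm             0.0006    37.1828
 residual             0.0000     1.9896
    total             0.0015   100.0000
```

The first table says the estimated carryover coefficient is positive in
98.8% of cells and individually significant (p < 0.05) in 67% — the
designed γ = 0.4 is comfortably detectable in a 35-year record. The second
decomposes the mean greenness trend (0.0015 index yr⁻¹, driven here by the
default 0.03 °C yr⁻¹ warming): about 40% propagates through the carryover
term, 37% through concurrent climate and 21% through preceding-season
climate, with a ~2% residual; the four components sum to the observed
trend exactly.

The same workflows are scriptable from the shell:

```sh
vegcarry simulate system --seed 42 --out system.csv
vegcarry vgc seasonal --in system.csv --season PGS --out profile.csv
vegcarry attribute --in system.csv --season PGS --out attribution.csv
vegcarry dominance --in profile.csv --out labels.csv
```

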