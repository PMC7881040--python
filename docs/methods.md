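# Methods

This note documents the statistical models implemented in `vegcarry`,
the assumptions behind them, the synthetic data they are validated on,
and the numerical choices that were genuinely open.

## 1. The estimand: carryover as a conditional dependence

Vegetation growth in one season correlates with growth in the previous
season for two distinct reasons: a real biological/ecological carryover
(carbohydrate reserves, leaf area, canopy structure, soil-moisture
legacies), or a shared climatic driver that is itself autocorrelated.
The package therefore never interprets a raw lag correlation. The
carryover statistic is always a *partial* correlation: the association
between seasonal greenness Y and preceding-season greenness Y_ps after
linearly removing temperature and precipitation of both the present and
the preceding season (and, at interannual leads j > 1, the series at all
smaller leads). The implicit assumptions are those of linear partial
regression: effects are additive and linear over the anomaly range, and
the controlled climate variables capture the relevant abiotic forcing.

Two algebraically equivalent implementations exist side by side —
correlation of OLS residuals, and the inverse-correlation-matrix
formula — and their agreement (to 1e-10 on random instances) is asserted
in the test suite. Significance uses the t statistic with n − 2 − k
degrees of freedom for k controls; the null calibration of this test at
the 5% level is itself an acceptance check, run on 10,000 simulated
null cells of 35 years each (the length of a typical satellite record).

### Seasonal driver sets

For a target season s ∈ {EGS, PGS, LGS}, the five mutually controlled
drivers are Y_ps, TMP_s, PRE_s, TMP_ps, PRE_ps. Two conventions matter:

* **Preceding greenness for the EGS** is the *previous year's LGS*
  value, not the dormancy season's: dormant vegetation has no meaningful
  greenness signal and high-latitude winter retrievals are
  snow-contaminated. Preceding *climate* for the EGS is the dormancy
  season (the immediately preceding season).
* **The dormancy season is attached to the year whose spring it
  precedes.** DS of year t spans from after the EOS of year t − 1 to
  before the SOS of year t. This keeps the dormancy-to-spring legacy a
  within-year pairing.

## 2. Season delineation

Seasons are phenological, not calendar-based. Per cell:

1. The climatological mean cycle is the multi-year mean of each of the
   24 biweekly composites (missing-aware). Biweekly composites are
   max-value composited to months (periods 2k − 1, 2k → month k).
2. The cycle is interpolated to daily resolution with a periodic cubic
   spline (three tiled years, center year evaluated), giving a
   continuous derivative; SOS/EOS are the days of the extreme derivative.
   A cubic spline was chosen because the method needs d/dt of an
   interpolant; any smooth interpolation of a 24-point cycle gives
   essentially the same extrema.
3. PGS is the two consecutive months with the largest summed greenness,
   constrained to April–October; one month when the growing season spans
   three months or fewer. Cells peaking outside April–October are
   excluded, as are cells whose cycle range is below `min_amplitude`
   (default 0.02 index units) or whose maximum stays below `min_ndvi`
   (default 0.1 — a conventional non-vegetated cutoff; the threshold is
   exposed because no canonical value exists).
4. EGS runs from the SOS month to the month before PGS; LGS from the
   month after PGS to the EOS month; DS is the remainder. Every
   `SeasonWindows` instance validates on construction that the four
   month sets partition the 12 months with EGS < PGS < LGS.

Ties in the two-month PGS sum are broken toward the earlier pair. The
site-level GPP variant smooths the daily series with a curvature-penalty
spline (`lam`, default 5000 on daily data — heavy enough to suppress
synoptic variability while keeping seasonal inflections; exposed as
config since no standard value exists) and takes SOS/EOS at the extreme
second derivative.

Detection accuracy is checked against dense numerical differentiation of
the analytic noise-free curve; the acceptance bound (±8 days) is half a
composite period, the intrinsic resolution of the input.

## 3. Trend attribution

The linear trend of Y is decomposed as dY/dt = Σ β_X (dX/dt) + ε-trend,
with the β estimated by a single joint OLS of Y on the five drivers and
each dX/dt the OLS slope of that driver against the year. Because OLS
residuals are orthogonal to the design and the trend operator is linear,
contributions plus residual trend reconstruct the observed trend to
machine precision; the identity is asserted on every cell (tolerance
1e-12, and the residual trend is computed from the residual series, not
as a remainder, so the assertion is informative). Temperature and
precipitation are combined into CLM and CLM_ps for reporting. Percentage
shares are signed, may exceed 100% for opposing terms, and are reported
relative to the observed total trend by default (an `explained` basis is
available); with a zero total trend the shares are undefined but the
absolute contributions are still reported. Rank-deficient designs (e.g.
duplicated drivers) flag the cell rather than returning arbitrary
coefficients. The dependent variable is a parameter — the same operation
runs unchanged on model GPP.

A caveat the tests document deliberately: a trending driver absorbs part
of any exogenous trend in Y through omitted-variable aliasing. The
share-recovery test therefore designs its 75/25 split across driver
families rather than against an exogenous residual trend.

## 4. Tree-ring chronologies

Standardization divides each raw series (≥ 25 years, gap-free, positive)
by a cubic smoothing spline with 50% frequency response at 0.67 of the
series length — the community-standard stiffness. The csaps parameter p
for that cutoff is converted to the curvature-penalty weight
λ = (1 − p)/p; the implementation's frequency response was verified to
be 0.500 at the design wavelength on sinusoids. Two numerical choices
reduce fitting bias without changing the convention:

* **Boundary padding.** Curvature-penalty smoothers are biased near the
  series ends (the natural boundary condition forces zero curvature).
  Each series is padded at both ends by point reflection over one
  smoothing bandwidth (≈ λ^(1/4) years) before fitting; the padding is
  discarded afterwards.
* **Log-domain fitting (default).** Ring-width variability scales with
  ring width, and multiplicative age trends (the negative exponential)
  are nearly linear in log space, so a spline of the same stiffness
  tracks them with far less bias. The spline is fit to log widths and
  the index is raw/exp(fit). Linear-domain fitting is available via
  `domain="linear"`. In log domain the ratio index is exactly invariant
  to rescaling the raw series.

Chronologies are Tukey biweight means per year (tuning constant 9 MADs,
iterated to convergence, median fallback when the MAD vanishes), with
sample depth recorded and years below `min_depth` (default 2) masked.
Chronology-level carryover uses the same lead-1..3 partial
autocorrelation as the satellite analysis, with linear detrending always
applied for comparability (standardized ring indices carry no trend by
construction). The climate covariates controlled for tree-ring series
are annual means — no finer convention exists for chronologies whose
seasonal growth windows differ by species; the covariates are a
parameter.

The Tucson/RWL decadal format is parsed and written natively (stop
marker 999 = 0.01 mm units, −9999 = 0.001 mm); the round trip is
lossless at the format's precision.

## 5. Dominance classification

Per cell, three scores: |r_p| of the carryover term; max over
{TMP, PRE} of |r_p| for concurrent climate; max over {TMP_ps, PRE_ps}
for preceding climate. The cell is labeled by the argmax; ties break by
the fixed priority carryover > concurrent > preceding and are flagged.
The max-combination of a climate family is the default because the
question is whether *any* climate variable beats the carryover; a
root-sum-of-squares mode is provided for sensitivity analysis, and the
scores can equally be |trend contributions| from the attribution step.
Area fractions are weight-normalized over labeled cells (cos-latitude
weights by default when latitudes are available; whether hemispheric
averages should be area-weighted at all is exposed as a switch since
either convention is defensible).

## 6. Recursive path model

The path model is a DAG over observed standardized seasonal variables.
Estimation is equation-wise least squares: each endogenous node on its
parents. For recursive models with observed variables these point
estimates coincide with full-information maximum likelihood; what is
lost is only the likelihood-based global fit machinery (χ², RMSEA,
AGFI), which is out of scope. Global adequacy is summarized instead by
the largest absolute gap between the observed correlation matrix and the
model-implied one, computed as (I − B)⁻¹ Ψ (I − B)⁻ᵀ with Ψ carrying
the observed exogenous correlations and residual variances 1 − r².
Direct/indirect/total effects follow path-tracing: products of edge
coefficients summed over directed paths; total = direct + indirect holds
identically and is asserted against a brute-force path enumeration.

The soil-moisture/vegetation edge cannot be oriented from
contemporaneous data alone, so its direction follows the sign rule:
positive correlation → moisture drives vegetation; negative → vegetation
depletes moisture; |r| below a threshold (default 0.05) → undetermined.
This is a disciplined convention, not a causal discovery method, and is
labeled as such in outputs.

## 7. The synthetic-data generators

The generators define the study conditions under which every estimator
is validated.

**Biweekly greenness** follows a double logistic — baseline 0.1,
amplitude 0.6, green-up inflection day 130, senescence day 280, rates
0.12/0.10 d⁻¹ — a standard smooth unimodal form for mid-latitude
deciduous phenology; interannual variability is one additive anomaly per
year (SD 0.02, typical satellite-scale interannual NDVI variability)
plus an optional linear trend, so anomalies shift the cycle without
deforming it. Ground-truth SOS/EOS are the slope extrema of the
noise-free curve located on a 0.01-day grid.

**The seasonal system** chains the three active seasons within and
across years (EGS ← previous LGS across the calendar boundary):

    NDVI_s = γ_s NDVI_{s−1} + β_T TMP_s + β_P PRE_s
             + β_T' TMP_{s−1} + β_P' PRE_{s−1} + β_SM SM_{s−1} + ε
    SM_s   = a SM_{s−1} − b NDVI_s + c PRE_s + η

Defaults describe a 35-year mid-latitude record: γ = 0.4 per transition
(moderate carryover), β_T = 0.02 index °C⁻¹, β_P = 0.0005 index mm⁻¹,
lagged sensitivities half the concurrent ones, temperature trend
0.03 °C yr⁻¹ (late-20th-century northern warming), seasonal temperature
SD 1 °C, precipitation SD 30 mm, greenness noise SD 0.05, soil-moisture
carryover 0.5 with depletion 0.05 m³ m⁻³ per unit greenness anomaly.
Dormancy-season climate and soil moisture are generated; dormancy
greenness is not. Ten burn-in years are discarded so recorded anomalies
are stationary (|γ| < 1 enforced). Specific validation scenarios (null
system; single-transition γ = 0.5 at unit noise) set the parameters the
scenario prescribes.

**Annual AR(1)** series are initialized from the stationary distribution
(no burn-in); **ring widths** are age-trend × (1 + signal + noise) with
a negative-exponential age trend (0.5 + 2 e^(−0.03 age) mm — juvenile
width ~2.5 mm decaying over ~33 years toward 0.5 mm), an AR(1) common
signal (φ = 0.3, SD 0.2) and tree noise SD 0.1, 20 trees, 100 years,
positive-clipped.

What the generators do **not** emulate — and hence what passing tests do
not demonstrate about real data: sensor artifacts (orbital drift, snow
and cloud contamination), spatially correlated noise between cells,
nonlinear or threshold vegetation responses, drought-induced growth
divergence between wood-anatomy classes, age-dependent climate
sensitivity in trees, and observation error in the climate drivers
themselves. Cross-cell independence in particular makes across-cell
sampling distributions narrower than they would be on real, spatially
autocorrelated grids.

## 8. Problem sizes and determinism

Every generator is deterministic given (config, seed); identical seeds
give bit-identical output. The validation script and acceptance tests
use: 200 cells × 3 seasons for the closure identity; 1000 random
instances (n = 50, ≤ 4 controls) for the dual-route agreement; 10,000
null cells × 35 yr for type-I calibration; a 10⁶-pair brute-force oracle
(10,000 cells × 100 yr) plus 500 estimation cells for carryover
recovery; 200 replicates of 100-yr AR(1) for persistence; three curve
shapes for phenology; 300 cells for dominance; n = 10,000 for the path
model. These sizes put Monte Carlo error well inside each tolerance
while the whole suite runs in about a minute.

## 9. Known limitations

* Listwise deletion is the only missing-data policy; there is no
  imputation, and a single missing month removes the year for all
  statistics that touch it (by design, so sample sizes match across
  drivers within one comparison).
* Partial correlation controls linearly; nonlinear confounding by
  climate is not removed.
* Per-cell significance is reported without any field-significance or
  multiple-testing control across cells.
* The trend decomposition inherits OLS omitted-variable behavior: trends
  not represented by any driver are split between the residual term and
  whichever drivers carry a trend.
* The path-model orientation rule for soil moisture resolves only the
  *dominant* direction of a feedback loop, and the recursive estimator
  cannot represent simultaneous bidirectional coupling.
* Tree-ring handling excludes crossdating, quality control, and
  regional-curve standardization; series with age trends crossing zero
  in the linear fitting domain are dropped rather than repaired.
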