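"""Synthetic inputs with known ground truth.

Four generators cover every input the pipeline consumes:

* :func:`simulate_biweekly_ndvi` — biweekly vegetation-index series built
  from a double-logistic seasonal cycle with interannual anomalies and a
  linear trend, together with the true start/end-of-season days of the
  noise-free curve.
* :func:`simulate_seasonal_system` — a season-chained driver system in
  which each season's greenness responds to the previous season's
  greenness (the carryover gamma), to concurrent and lagged climate, and
  optionally to a soil-moisture state that carries between seasons.
* :func:`simulate_annual_ar` — annual AR(1) anomaly series for the
  interannual-persistence analyses.
* :func:`simulate_ring_widths` — raw ring-width series with a
  negative-exponential age trend, a shared AR(1) growth signal, and
  tree-level noise.

Every generator is deterministic given (config, seed) and emits a truth
record sufficient to score recovery of each parameter the estimators
target.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from vegcarry.core import ACTIVE_SEASONS, SEASONS, SEASONAL_COLUMNS, VegcarryError

#: Days per year used throughout the synthetic calendar (no leap days).
DAYS_PER_YEAR = 365
#: Biweekly composites per year; composite p is centered at day (p - 0.5) * 365/24.
PERIODS_PER_YEAR = 24


def composite_midpoints() -> np.ndarray:
    """Day-of-year centers of the 24 biweekly composites."""
    return (np.arange(1, PERIODS_PER_YEAR + 1) - 0.5) * DAYS_PER_YEAR / PERIODS_PER_YEAR


# ---------------------------------------------------------------------------
# Biweekly vegetation-index curves
# ---------------------------------------------------------------------------

@dataclass
class PhenoCurveParams:
    """Double-logistic seasonal cycle of a vegetation index.

    The noise-free cycle is
    ``v(d) = baseline + amplitude * (S(d; greenup_day, greenup_rate)
    - S(d; senescence_day, senescence_rate))`` with ``S`` the logistic
    function, so greenness rises around ``greenup_day`` and falls around
    ``senescence_day``. A double logistic is the standard smooth unimodal
    form in land-surface phenology; any smooth cycle with well-defined
    slope extrema would do.
    """

    baseline: float = 0.1           # winter index value
    amplitude: float = 0.6          # summer excess over baseline
    greenup_day: float = 130.0      # inflection of the spring rise (DOY)
    senescence_day: float = 280.0   # inflection of the autumn decline (DOY)
    greenup_rate: float = 0.12      # logistic steepness (1/day)
    senescence_rate: float = 0.10   # logistic steepness (1/day)
    anomaly_sd: float = 0.02        # SD of additive year-level anomalies
    trend_per_year: float = 0.0     # additive linear trend (index/yr)

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise VegcarryError("amplitude must be >= 0")
        if self.amplitude > 0 and not self.greenup_day < self.senescence_day:
            raise VegcarryError("greenup_day must precede senescence_day")
        if self.anomaly_sd < 0:
            raise VegcarryError("anomaly_sd must be >= 0")

    def curve(self, day: np.ndarray) -> np.ndarray:
        """Noise-free index value at day-of-year ``day``."""
        d = np.asarray(day, dtype=float)
        up = 1.0 / (1.0 + np.exp(-self.greenup_rate * (d - self.greenup_day)))
        down = 1.0 / (1.0 + np.exp(-self.senescence_rate * (d - self.senescence_day)))
        return self.baseline + self.amplitude * (up - down)


def true_slope_extrema(params: PhenoCurveParams, step: float = 0.01):
    """Days of maximum and minimum slope of the noise-free cycle.

    Located by dense numerical differencing of the analytic curve; with the
    default 0.01-day grid the location error is negligible against the
    composite spacing of ~15 days. Returns (sos_day, eos_day), or
    (nan, nan) when the cycle is flat.
    """
    if params.amplitude == 0:
        return float("nan"), float("nan")
    days = np.arange(1.0, DAYS_PER_YEAR + step, step)
    slope = np.gradient(params.curve(days), days)
    return float(days[np.argmax(slope)]), float(days[np.argmin(slope)])


def simulate_biweekly_ndvi(
    params: PhenoCurveParams,
    n_years: int,
    seed: int,
    n_cells: int = 1,
    start_year: int = 1982,
) -> tuple[pd.DataFrame, dict]:
    """Sample biweekly composites of the seasonal cycle over several years.

    Each year gets one additive anomaly draw (N(0, anomaly_sd)) plus the
    linear trend, shared by all 24 composites of that year, so interannual
    variability shifts the whole curve without deforming it.

    Returns
    -------
    biweekly
        Frame in the ``biweekly`` layout (cells ``cell_0``, ``cell_1``, ...).
    truth
        ``{"sos_day", "eos_day", "phenology_defined", "params"}`` —
        ground-truth slope-extrema days of the noise-free curve.
    """
    rng = np.random.default_rng(seed)
    mids = composite_midpoints()
    base_cycle = params.curve(mids)
    years = np.arange(start_year, start_year + n_years)

    frames = []
    for c in range(n_cells):
        anomalies = rng.normal(0.0, params.anomaly_sd, size=n_years)
        offsets = anomalies + params.trend_per_year * np.arange(n_years)
        values = base_cycle[None, :] + offsets[:, None]
        frames.append(pd.DataFrame({
            "cell_id": f"cell_{c}",
            "year": np.repeat(years, PERIODS_PER_YEAR),
            "period": np.tile(np.arange(1, PERIODS_PER_YEAR + 1), n_years),
            "value": values.ravel(),
        }))
    sos, eos = true_slope_extrema(params)
    truth = {
        "sos_day": sos,
        "eos_day": eos,
        "phenology_defined": params.amplitude > 0,
        "params": asdict(params),
    }
    return pd.concat(frames, ignore_index=True), truth


# ---------------------------------------------------------------------------
# Season-chained driver system
# ---------------------------------------------------------------------------

@dataclass
class SeasonalSystemConfig:
    """Generative model for the seasonal greenness-climate-soil system.

    For each cell, active seasons are generated in within-year order
    EGS -> PGS -> LGS, chained across the year boundary (EGS of year t
    follows LGS of year t-1)::

        NDVI_s = gamma_s * NDVI_{s-1} + beta_t * TMP_s + beta_p * PRE_s
                 + beta_t_lag * TMP_{s-1} + beta_p_lag * PRE_{s-1}
                 + beta_sm * SM_{s-1} + eps,      eps ~ N(0, ndvi_noise_sd)

        SM_s = sm_carryover * SM_{s-1} - sm_depletion * NDVI_s
               + sm_recharge * PRE_s + eta,       eta ~ N(0, sm_noise_sd)

    Climate is exogenous white noise around a seasonal mean plus a linear
    trend. Dormancy-season climate and soil moisture are generated;
    dormancy-season greenness is not (vegetation is dormant and the index
    is unobservable under snow). Anomalies are stationary when every
    |gamma| < 1; a burn-in is discarded before the recorded window.

    Defaults describe a mid-latitude 35-year record: moderate carryover
    (gamma 0.4), greenness gaining ~0.02 index per degree of seasonal
    warmth, weak precipitation control, a 0.03 degC/yr warming trend, and
    greenness noise comparable to observed interannual NDVI variability.
    """

    n_cells: int = 100
    n_years: int = 35
    start_year: int = 1982
    burn_in: int = 10

    # carryover per season transition, keyed by the target season
    gamma: dict = field(default_factory=lambda: {
        "LGS->EGS": 0.4, "EGS->PGS": 0.4, "PGS->LGS": 0.4,
    })

    beta_t: float = 0.02        # index per degC, concurrent temperature
    beta_p: float = 0.0005      # index per mm, concurrent precipitation
    beta_t_lag: float = 0.01    # index per degC, preceding-season temperature
    beta_p_lag: float = 0.00025  # index per mm, preceding-season precipitation
    beta_sm: float = 0.0        # index per m3/m3, preceding-season soil moisture

    tmp_mean: float = 10.0      # degC
    tmp_sd: float = 1.0
    tmp_trend: float = 0.03     # degC per year
    pre_mean: float = 100.0     # mm per season
    pre_sd: float = 30.0
    pre_trend: float = 0.0      # mm per year

    sm_mean: float = 0.25       # m3/m3 baseline around which SM fluctuates
    sm_carryover: float = 0.5
    sm_depletion: float = 0.05  # m3/m3 per unit greenness anomaly
    sm_recharge: float = 0.0005  # m3/m3 per mm precipitation anomaly
    sm_noise_sd: float = 0.02

    ndvi_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for key, g in self.gamma.items():
            if abs(g) >= 1:
                raise VegcarryError(f"|gamma[{key}]| must be < 1 for stationarity")
        if abs(self.sm_carryover) >= 1:
            raise VegcarryError("|sm_carryover| must be < 1")
        for name in ("ndvi_noise_sd", "sm_noise_sd", "tmp_sd", "pre_sd"):
            if getattr(self, name) < 0:
                raise VegcarryError(f"{name} must be >= 0")


@dataclass
class SeasonalSystemData:
    """Arrays of the simulated system plus the truth record.

    ``ndvi`` has shape (n_cells, n_years, 3) over the active seasons in
    order EGS, PGS, LGS; ``tmp``, ``pre`` and ``sm`` have shape
    (n_cells, n_years, 4) with DS last. Values are anomalies around the
    configured means plus trends, i.e. the series the statistics consume.
    """

    ndvi: np.ndarray
    tmp: np.ndarray
    pre: np.ndarray
    sm: np.ndarray
    years: np.ndarray
    cell_ids: list
    truth: dict

    _ACTIVE_IDX = {s: i for i, s in enumerate(ACTIVE_SEASONS)}
    _ALL_IDX = {s: i for i, s in enumerate(SEASONS)}

    def series(self, cell: int, variable: str, season: str) -> np.ndarray:
        """Per-year series of one variable in one season for one cell."""
        if variable == "ndvi":
            return self.ndvi[cell, :, self._ACTIVE_IDX[season]]
        arr = getattr(self, variable)
        return arr[cell, :, self._ALL_IDX[season]]

    def to_frame(self) -> pd.DataFrame:
        """Long ``seasonal`` frame of all four variables."""
        rows = []
        n_cells, n_years, _ = self.ndvi.shape
        for var, arr, seasons in (
            ("ndvi", self.ndvi, ACTIVE_SEASONS),
            ("tmp", self.tmp, SEASONS),
            ("pre", self.pre, SEASONS),
            ("sm", self.sm, SEASONS),
        ):
            for si, season in enumerate(seasons):
                rows.append(pd.DataFrame({
                    "cell_id": np.repeat(self.cell_ids, n_years),
                    "year": np.tile(self.years, n_cells),
                    "season": season,
                    "variable": var,
                    "value": arr[:, :, si].ravel(),
                }))
        return pd.concat(rows, ignore_index=True)[SEASONAL_COLUMNS]


def simulate_seasonal_system(config: SeasonalSystemConfig) -> SeasonalSystemData:
    """Generate the season-chained greenness-climate-soil system.

    All cells share the configured parameters and are driven by independent
    noise, so across-cell statistics are replicates of one process. Burn-in
    years are generated and discarded so the recorded anomalies are
    stationary.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nc, ny = cfg.n_cells, cfg.n_years + cfg.burn_in
    t_idx = np.arange(ny) - cfg.burn_in  # trend reference = first recorded year

    # exogenous climate anomalies (mean removed; trend retained), per season
    tmp = rng.normal(0.0, cfg.tmp_sd, size=(nc, ny, 4)) + cfg.tmp_trend * t_idx[None, :, None]
    pre = rng.normal(0.0, cfg.pre_sd, size=(nc, ny, 4)) + cfg.pre_trend * t_idx[None, :, None]

    eps = rng.normal(0.0, cfg.ndvi_noise_sd, size=(nc, ny, 3))
    eta = rng.normal(0.0, cfg.sm_noise_sd, size=(nc, ny, 4))

    ndvi = np.zeros((nc, ny, 3))
    sm = np.zeros((nc, ny, 4))

    gam = [cfg.gamma["LGS->EGS"], cfg.gamma["EGS->PGS"], cfg.gamma["PGS->LGS"]]
    prev_ndvi = np.zeros(nc)       # LGS of the year before the first burn-in year
    prev_sm = np.zeros(nc)
    prev_tmp = np.zeros(nc)
    prev_pre = np.zeros(nc)
    for t in range(ny):
        for si in range(3):        # EGS, PGS, LGS in order
            x = (
                gam[si] * prev_ndvi
                + cfg.beta_t * tmp[:, t, si] + cfg.beta_p * pre[:, t, si]
                + cfg.beta_t_lag * prev_tmp + cfg.beta_p_lag * prev_pre
                + cfg.beta_sm * prev_sm
                + eps[:, t, si]
            )
            ndvi[:, t, si] = x
            s = (
                cfg.sm_carryover * prev_sm
                - cfg.sm_depletion * x
                + cfg.sm_recharge * pre[:, t, si]
                + eta[:, t, si]
            )
            sm[:, t, si] = s
            prev_ndvi, prev_sm = x, s
            prev_tmp, prev_pre = tmp[:, t, si], pre[:, t, si]
        # dormancy season: climate and soil moisture only, no greenness
        sm[:, t, 3] = (
            cfg.sm_carryover * prev_sm
            + cfg.sm_recharge * pre[:, t, 3]
            + eta[:, t, 3]
        )
        prev_sm = sm[:, t, 3]
        prev_tmp, prev_pre = tmp[:, t, 3], pre[:, t, 3]
        # DS precedes the EGS of the NEXT calendar year; its preceding-season
        # greenness link is broken (dormant vegetation), so prev_ndvi carries
        # the last LGS value across the boundary untouched.

    keep = slice(cfg.burn_in, None)
    years = np.arange(cfg.start_year, cfg.start_year + cfg.n_years)
    truth = {"config": asdict(cfg)}
    return SeasonalSystemData(
        ndvi=ndvi[:, keep, :],
        tmp=tmp[:, keep, :] + cfg.tmp_mean,
        pre=pre[:, keep, :] + cfg.pre_mean,
        sm=sm[:, keep, :] + cfg.sm_mean,
        years=years,
        cell_ids=[f"cell_{i}" for i in range(nc)],
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Annual AR(1) series
# ---------------------------------------------------------------------------

def simulate_annual_ar(
    phi: float,
    n_years: int,
    n_series: int = 1,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, dict]:
    """Stationary AR(1) anomaly series with known lag-1 coefficient.

    Initialized from the stationary distribution, so no burn-in is needed.
    Returns (series array of shape (n_series, n_years), truth record).
    """
    if not abs(phi) < 1:
        raise VegcarryError(f"|phi| must be < 1, got {phi}")
    if noise_sd < 0:
        raise VegcarryError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.empty((n_series, n_years))
    stat_sd = noise_sd / np.sqrt(1.0 - phi**2) if noise_sd > 0 else 0.0
    x[:, 0] = rng.normal(0.0, stat_sd, size=n_series) if stat_sd > 0 else 0.0
    shocks = rng.normal(0.0, noise_sd, size=(n_series, n_years))
    for t in range(1, n_years):
        x[:, t] = phi * x[:, t - 1] + shocks[:, t]
    return x, {"phi": phi, "noise_sd": noise_sd, "seed": seed}


# ---------------------------------------------------------------------------
# Ring widths
# ---------------------------------------------------------------------------

@dataclass
class RingSimConfig:
    """Raw ring-width simulation.

    Widths follow ``width[i, t] = age_trend(t) * (1 + signal_t + noise_it)``
    where the age trend is the negative exponential
    ``w_inf + w0 * exp(-decay * age)`` (juvenile growth declining toward an
    asymptote) and the signal shared by all trees is AR(1). An optional
    outlier spec scales whole trees, for robustness checks.
    """

    n_trees: int = 20
    n_years: int = 100
    start_year: int = 1901
    w0: float = 2.0             # mm, juvenile excess over the asymptote
    decay: float = 0.03         # 1/yr
    w_inf: float = 0.5          # mm, asymptotic width
    signal_phi: float = 0.3     # AR(1) coefficient of the common signal
    signal_sd: float = 0.2      # stationary SD of the common signal
    tree_noise_sd: float = 0.1
    outlier_scale: dict = field(default_factory=dict)  # {tree_index: factor}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 2:
            raise VegcarryError("n_trees must be >= 2")
        if not abs(self.signal_phi) < 1:
            raise VegcarryError("|signal_phi| must be < 1")
        if min(self.w0, self.w_inf) <= 0 or self.decay <= 0:
            raise VegcarryError("age-trend parameters must be positive")


def simulate_ring_widths(config: RingSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate raw ring widths for one site.

    Returns
    -------
    widths
        Frame with columns ``series_id, year, width_mm``.
    truth
        ``{"signal": per-year common signal, "age_trend": per-age curve,
        "config": ...}``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ages = np.arange(1, cfg.n_years + 1)
    age_trend = cfg.w_inf + cfg.w0 * np.exp(-cfg.decay * ages)

    innov_sd = cfg.signal_sd * np.sqrt(1.0 - cfg.signal_phi**2)
    signal, _ = simulate_annual_ar(
        cfg.signal_phi, cfg.n_years, n_series=1,
        seed=rng.integers(2**31), noise_sd=innov_sd if cfg.signal_sd > 0 else 0.0,
    )
    signal = signal[0]

    noise = rng.normal(0.0, cfg.tree_noise_sd, size=(cfg.n_trees, cfg.n_years))
    widths = age_trend[None, :] * (1.0 + signal[None, :] + noise)
    for tree, factor in cfg.outlier_scale.items():
        widths[tree] *= factor
    widths = np.clip(widths, 1e-3, None)  # ring widths are physically positive

    years = np.arange(cfg.start_year, cfg.start_year + cfg.n_years)
    df = pd.DataFrame({
        "series_id": np.repeat([f"TRE{i:03d}" for i in range(cfg.n_trees)], cfg.n_years),
        "year": np.tile(years, cfg.n_trees),
        "width_mm": widths.ravel(),
    })
    truth = {"signal": signal, "age_trend": age_trend, "config": asdict(cfg)}
    return df, truth
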