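"""Climate-controlled memory statistics.

The central quantity throughout is the partial correlation: the
correlation between seasonal (or annual) vegetation growth and one driver
after regressing out the remaining drivers. Applied to the preceding
season's greenness with concurrent and lagged climate as controls, it
estimates the vegetation growth carryover (VGC); applied at annual leads
of 1-3 years with smaller leads controlled, it measures how long the
carryover persists.

Two algebraically equivalent implementations are provided — correlation of
OLS residuals, and the inverse-correlation-matrix (precision) formula —
so each can serve as the other's cross-check. Significance uses the
t statistic with n - 2 - k degrees of freedom for k controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from vegcarry.core import ACTIVE_SEASONS, VegcarryError, validate_seasonal

#: Preceding season of each active season, for climate drivers. DS is
#: attached to the year whose EGS it precedes (it spans the calendar
#: boundary), so all mappings stay within one nominal year.
PRECEDING_SEASON = {"EGS": "DS", "PGS": "EGS", "LGS": "PGS"}

#: Preceding season for greenness: dormancy-season greenness is undefined
#: (dormant vegetation, snow-contaminated index), so the EGS looks back to
#: the previous year's LGS.
PRECEDING_NDVI_SEASON = {"EGS": "LGS", "PGS": "EGS", "LGS": "PGS"}

#: Driver names of the seasonal profile, in reporting order.
PROFILE_DRIVERS = ("ndvi_ps", "tmp", "pre", "tmp_ps", "pre_ps")


@dataclass
class PartialCorrResult:
    """One partial-correlation coefficient with its test.

    ``defined`` is False when either residualized series is (numerically)
    constant, in which case ``r_p`` and ``p_value`` are NaN.
    """

    r_p: float
    p_value: float
    n: int
    controls: list = field(default_factory=list)
    defined: bool = True


@dataclass
class VgcProfile:
    """Per-driver partial correlations for one target season.

    Each of the five drivers (preceding-season greenness, concurrent
    temperature/precipitation, preceding-season temperature/precipitation)
    is tested with the other four as controls.
    """

    season: str
    results: dict  # driver name -> PartialCorrResult


@dataclass
class PacfResult:
    """Lead-j partial autocorrelation with its controlled-covariate ledger."""

    lead: int
    r_p: float
    p_value: float
    n: int
    controls: list = field(default_factory=list)
    defined: bool = True


def linear_detrend(values: np.ndarray, years: np.ndarray | None = None) -> np.ndarray:
    """Residuals of an OLS fit of ``values`` against time (mean-zero output).

    NaNs are preserved in place; the fit uses the non-missing points.
    """
    v = np.asarray(values, dtype=float)
    t = np.arange(len(v), dtype=float) if years is None else np.asarray(years, dtype=float)
    ok = np.isfinite(v)
    if ok.sum() < 3:
        raise VegcarryError(f"need >= 3 points to detrend, got {int(ok.sum())}")
    X = np.column_stack([np.ones(ok.sum()), t[ok]])
    beta, *_ = np.linalg.lstsq(X, v[ok], rcond=None)
    out = np.full_like(v, np.nan)
    out[ok] = v[ok] - X @ beta
    return out


def _listwise(y, x, controls):
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    C = [np.asarray(c, dtype=float) for c in controls]
    for arr in [x, *C]:
        if len(arr) != len(y):
            raise VegcarryError("all series must have equal length")
    ok = np.isfinite(y) & np.isfinite(x)
    for c in C:
        ok &= np.isfinite(c)
    return y[ok], x[ok], [c[ok] for c in C]


def partial_correlation(
    y,
    x,
    controls=(),
    control_names: list | None = None,
    method: str = "residual",
) -> PartialCorrResult:
    """Partial correlation of ``y`` and ``x`` given ``controls``.

    Parameters
    ----------
    y, x
        Equal-length 1-D series; missing values are NaN and removed
        listwise together with the controls.
    controls
        Sequence of series to hold fixed (may be empty, giving the plain
        Pearson correlation).
    method
        ``"residual"`` correlates the OLS residuals of y and x on the
        controls (with intercept); ``"precision"`` reads the coefficient
        off the inverse correlation matrix. The two agree to numerical
        precision and exist as mutual cross-checks.
    """
    yv, xv, C = _listwise(y, x, controls)
    k = len(C)
    n = len(yv)
    if n <= k + 2:
        raise VegcarryError(
            f"sample size {n} too small for {k} controls (need n > k + 2)"
        )
    names = list(control_names) if control_names is not None else [
        f"c{i}" for i in range(k)
    ]

    if method == "residual":
        X = np.column_stack([np.ones(n)] + C)
        ry = yv - X @ np.linalg.lstsq(X, yv, rcond=None)[0]
        rx = xv - X @ np.linalg.lstsq(X, xv, rcond=None)[0]
        sy, sx = np.std(ry), np.std(rx)
        scale = max(np.std(yv), np.std(xv), 1.0)
        if sy <= 1e-12 * scale or sx <= 1e-12 * scale:
            return PartialCorrResult(np.nan, np.nan, n, names, defined=False)
        r = float(np.dot(ry, rx) / (n * sy * sx))
    elif method == "precision":
        M = np.column_stack([yv, xv] + C)
        sd = M.std(axis=0)
        if (sd <= 1e-12 * max(sd.max(), 1.0)).any():
            return PartialCorrResult(np.nan, np.nan, n, names, defined=False)
        R = np.corrcoef(M, rowvar=False)
        P = np.linalg.pinv(R)
        r = float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))
    else:
        raise VegcarryError(f"unknown method {method!r}")

    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrResult(r, p, n, names)


# ---------------------------------------------------------------------------
# Seasonal VGC profiles
# ---------------------------------------------------------------------------

def seasonal_series_table(seasonal: pd.DataFrame) -> pd.DataFrame:
    """Pivot a single-cell (or spatially averaged) seasonal frame.

    Returns a frame indexed by year with one column per (variable, season)
    pair, e.g. ``("ndvi", "PGS")``.
    """
    df = seasonal
    if "cell_id" in df.columns:
        if df["cell_id"].nunique() > 1:
            raise VegcarryError(
                "seasonal_series_table expects one cell (or a spatial mean); "
                "use grid_vgc_profiles for many cells"
            )
        validate_seasonal(df)
    return df.pivot_table(
        index="year", columns=["variable", "season"], values="value",
    )


def _profile_driver_frame(table: pd.DataFrame, season: str) -> pd.DataFrame:
    """Year-indexed frame of y and the five drivers for one target season."""
    if season not in ACTIVE_SEASONS:
        raise VegcarryError(f"target season must be one of {ACTIVE_SEASONS}")
    ps_clim = PRECEDING_SEASON[season]
    ps_ndvi = PRECEDING_NDVI_SEASON[season]
    out = pd.DataFrame(index=table.index)
    out["y"] = table[("ndvi", season)]
    ndvi_ps = table[("ndvi", ps_ndvi)]
    if season == "EGS":
        ndvi_ps = ndvi_ps.shift(1)  # previous year's LGS
    out["ndvi_ps"] = ndvi_ps
    out["tmp"] = table[("tmp", season)]
    out["pre"] = table[("pre", season)]
    out["tmp_ps"] = table[("tmp", ps_clim)]
    out["pre_ps"] = table[("pre", ps_clim)]
    return out


def seasonal_vgc_profile(
    seasonal: pd.DataFrame,
    season: str,
    detrend: bool = False,
    method: str = "residual",
) -> VgcProfile:
    """Five mutually controlled partial correlations for one target season.

    The target series is the season's greenness; the drivers are the
    preceding season's greenness (the carryover term) and temperature and
    precipitation of the present and preceding season. Each driver's
    coefficient controls the other four, so the five results share one
    sample (listwise deletion over complete years).

    Parameters
    ----------
    seasonal
        Single-cell seasonal frame, or an already-pivoted table from
        :func:`seasonal_series_table`.
    season
        Target season: EGS, PGS or LGS. For EGS the preceding greenness is
        the previous year's LGS value.
    detrend
        If True, linearly detrend every series first (the anomaly variant).
    """
    table = seasonal if isinstance(seasonal.columns, pd.MultiIndex) else (
        seasonal_series_table(seasonal)
    )
    frame = _profile_driver_frame(table, season)
    frame = frame.dropna()
    if len(frame) < 10:
        raise VegcarryError(
            f"need >= 10 complete years for a seasonal profile, got {len(frame)}"
        )
    arrays = {c: frame[c].to_numpy() for c in frame.columns}
    if detrend:
        yrs = frame.index.to_numpy(dtype=float)
        arrays = {c: linear_detrend(v, yrs) for c, v in arrays.items()}

    results = {}
    for driver in PROFILE_DRIVERS:
        others = [d for d in PROFILE_DRIVERS if d != driver]
        results[driver] = partial_correlation(
            arrays["y"], arrays[driver],
            controls=[arrays[d] for d in others],
            control_names=others,
            method=method,
        )
    return VgcProfile(season=season, results=results)


def grid_vgc_profiles(
    data,
    season: str,
    detrend: bool = False,
    drivers=PROFILE_DRIVERS,
) -> pd.DataFrame:
    """Seasonal VGC profile for every cell of a simulated (or loaded) grid.

    ``data`` is a :class:`vegcarry.simulate.SeasonalSystemData`; the
    computation runs directly on its arrays. Returns a tidy frame
    (cell_id, season, driver, r_p, p_value, n).
    """
    rows = []
    ps_clim = PRECEDING_SEASON[season]
    ps_ndvi = PRECEDING_NDVI_SEASON[season]
    n_cells = data.ndvi.shape[0]
    yrs = data.years.astype(float)
    for c in range(n_cells):
        y = data.series(c, "ndvi", season)
        ndvi_ps = data.series(c, "ndvi", ps_ndvi)
        if season == "EGS":
            ndvi_ps = np.concatenate([[np.nan], ndvi_ps[:-1]])
        series = {
            "y": y,
            "ndvi_ps": ndvi_ps,
            "tmp": data.series(c, "tmp", season),
            "pre": data.series(c, "pre", season),
            "tmp_ps": data.series(c, "tmp", ps_clim),
            "pre_ps": data.series(c, "pre", ps_clim),
        }
        if detrend:
            series = {k: linear_detrend(v, yrs) for k, v in series.items()}
        for driver in drivers:
            others = [d for d in PROFILE_DRIVERS if d != driver]
            res = partial_correlation(
                series["y"], series[driver],
                controls=[series[d] for d in others],
                control_names=others,
            )
            rows.append((data.cell_ids[c], season, driver, res.r_p, res.p_value, res.n))
    return pd.DataFrame(
        rows, columns=["cell_id", "season", "driver", "r_p", "p_value", "n"]
    )


# ---------------------------------------------------------------------------
# Residual-vs-previous-year analysis
# ---------------------------------------------------------------------------

def residual_driver_correlation(
    residuals: np.ndarray,
    factors: dict,
) -> tuple[dict, float]:
    """Correlate trend-model residuals with previous-year factors.

    After the five-driver trend regression, the residual series holds
    whatever variation the concurrent and immediately-preceding season do
    not explain. Correlating it with greenness and climate of earlier
    seasons of the previous year probes longer legacies.

    Parameters
    ----------
    residuals
        Per-year residual series.
    factors
        Mapping of factor name to an equal-length per-year series (e.g.
        previous-year PGS greenness, previous-year DS precipitation).

    Returns
    -------
    (results, r_squared)
        ``results`` maps each factor to its mutually controlled
        :class:`PartialCorrResult`; ``r_squared`` is the collective
        explained variance of the residuals on all factors jointly.
    """
    if not factors:
        raise VegcarryError("factor list is empty")
    names = list(factors)
    eps = np.asarray(residuals, dtype=float)
    ok = np.isfinite(eps)
    for v in factors.values():
        ok &= np.isfinite(np.asarray(v, dtype=float))
    eps_c = eps[ok]
    fac = {k: np.asarray(v, dtype=float)[ok] for k, v in factors.items()}

    results = {}
    for name in names:
        others = [n for n in names if n != name]
        results[name] = partial_correlation(
            eps_c, fac[name], controls=[fac[n] for n in others],
            control_names=others,
        )
    X = np.column_stack([np.ones(len(eps_c))] + [fac[n] for n in names])
    beta, *_ = np.linalg.lstsq(X, eps_c, rcond=None)
    resid = eps_c - X @ beta
    tss = float(np.sum((eps_c - eps_c.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else np.nan
    return results, r2


# ---------------------------------------------------------------------------
# Interannual lead-1..3 partial autocorrelation
# ---------------------------------------------------------------------------

def lagged_pacf(
    y: np.ndarray,
    climate: dict | None = None,
    max_lead: int = 3,
    detrend: bool = True,
) -> list[PacfResult]:
    """Partial autocorrelation of an annual series at leads 1..max_lead.

    The lead-j coefficient is the partial correlation of ``y_t`` with
    ``y_{t-j}``, controlling the series at every smaller lead 1..j-1 and,
    when climate covariates are supplied, their values in the present and
    the preceding year. All series are linearly detrended first by default
    (for comparability with standardized tree-ring series, which carry no
    trend).

    Parameters
    ----------
    y
        Annual series (greenness anomaly or tree-ring index).
    climate
        Optional mapping name -> equal-length annual series (e.g.
        ``{"tmp": ..., "pre": ...}``).
    max_lead
        Largest lead in years (1..3 in typical use).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 15:
        raise VegcarryError(f"need >= 15 years for lagged PACF, got {n}")
    climate = climate or {}
    if detrend:
        y = linear_detrend(y)
        climate = {k: linear_detrend(np.asarray(v, dtype=float)) for k, v in climate.items()}
    else:
        climate = {k: np.asarray(v, dtype=float) for k, v in climate.items()}

    out = []
    for j in range(1, max_lead + 1):
        # rows t = start..n-1; start leaves room for lead j and climate lag 1
        start = max(j, 1)
        t = np.arange(start, n)
        target = y[t]
        lagged = y[t - j]
        controls, names = [], []
        for i in range(1, j):
            controls.append(y[t - i])
            names.append(f"y_lead{i}")
        for name, series in climate.items():
            controls.append(series[t])
            names.append(f"{name}_t")
            controls.append(series[t - 1])
            names.append(f"{name}_t-1")
        if len(target) <= len(controls) + 2:
            raise VegcarryError(
                f"lead {j}: {len(target)} usable years cannot support "
                f"{len(controls)} controls (need n > k + 2)"
            )
        res = partial_correlation(target, lagged, controls, control_names=names)
        out.append(PacfResult(j, res.r_p, res.p_value, res.n, names, res.defined))
    return out


# ---------------------------------------------------------------------------
# Sign/significance frequency tables
# ---------------------------------------------------------------------------

def sign_frequency_summary(
    results: pd.DataFrame,
    group_col: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tabulate coefficient signs and significance across cells or series.

    Expects columns ``r_p`` and ``p_value`` (one row per cell/series/
    driver). Undefined results (NaN coefficient) are excluded from the
    percentages and counted separately.

    Returns per group: ``n`` (defined results), ``pct_positive``,
    ``pct_negative``, ``pct_sig_positive``, ``pct_sig_negative``,
    ``n_undefined``. Signed percentages sum to 100 within a group.
    """
    if len(results) == 0:
        raise VegcarryError("empty result set")
    df = results.copy()
    if group_col is None:
        df["_group"] = "all"
        group_col = "_group"
    rows = []
    for group, sub in df.groupby(group_col, sort=True):
        defined = sub[sub["r_p"].notna()]
        n = len(defined)
        n_undef = len(sub) - n
        if n == 0:
            rows.append((group, 0, np.nan, np.nan, np.nan, np.nan, n_undef))
            continue
        pos = defined["r_p"] > 0
        sig = defined["p_value"] < alpha
        rows.append((
            group, n,
            100.0 * pos.mean(),
            100.0 * (~pos).mean(),
            100.0 * (pos & sig).mean(),
            100.0 * (~pos & sig).mean(),
            n_undef,
        ))
    return pd.DataFrame(rows, columns=[
        "group", "n", "pct_positive", "pct_negative",
        "pct_sig_positive", "pct_sig_negative", "n_undefined",
    ])
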