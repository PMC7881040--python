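"""Linear-trend attribution by regression decomposition.

The multi-year linear trend of seasonal vegetation growth Y is expressed
as the sum over drivers X of (sensitivity dY/dX) x (driver trend dX/dt)
plus a residual trend::

    dY/dt = b_Yps dYps/dt + b_Tps dTMPps/dt + b_Pps dPREps/dt
            + b_T dTMP/dt + b_P dPRE/dt + eps-trend

with sensitivities b estimated jointly by one multiple linear regression
of Y on the five drivers (preceding-season greenness, preceding-season
temperature and precipitation, concurrent temperature and precipitation).
Because OLS residuals are orthogonal to the design and the trend operator
is linear, the five contributions plus the residual trend reconstruct the
observed trend to machine precision — the closure identity asserted on
every cell.

Temperature and precipitation contributions are combined into lagged
(CLM_ps) and concurrent (CLM) climate terms for reporting; percentage
shares are signed and may exceed 100% when terms oppose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from vegcarry.core import VegcarryError
from vegcarry.memory_stats import PROFILE_DRIVERS, _profile_driver_frame

#: Driver order of the sensitivity regression.
DRIVERS = PROFILE_DRIVERS  # ("ndvi_ps", "tmp", "pre", "tmp_ps", "pre_ps")

#: Absolute tolerance of the closure identity check, in Y-units per year.
CLOSURE_ATOL = 1e-12


def linear_trend(values, years=None, with_stats: bool = False):
    """OLS slope of a per-year series against the year.

    Returns the slope alone, or ``(slope, p_value)`` when ``with_stats``.
    Missing values are dropped; a constant year vector is an error.
    """
    v = np.asarray(values, dtype=float)
    t = np.arange(len(v), dtype=float) if years is None else np.asarray(years, dtype=float)
    ok = np.isfinite(v) & np.isfinite(t)
    if ok.sum() < 3:
        raise VegcarryError(f"need >= 3 points for a trend, got {int(ok.sum())}")
    tv, vv = t[ok], v[ok]
    if np.ptp(tv) == 0:
        raise VegcarryError("year vector is constant")
    res = stats.linregress(tv, vv)
    if with_stats:
        return float(res.slope), float(res.pvalue)
    return float(res.slope)


@dataclass
class SensitivityVector:
    """Joint OLS sensitivities of Y to the five drivers."""

    beta: dict                  # driver -> dY/dX
    intercept: float
    r_squared: float
    n: int
    defined: bool = True
    reason: str = ""


@dataclass
class AttributionResult:
    """Trend decomposition of one cell-season.

    ``contributions`` maps each driver to beta_X * dX/dt (Y-units per
    year); ``clm_ps`` and ``clm`` combine the lagged and concurrent
    temperature + precipitation terms; ``residual_trend`` closes the
    identity against ``total_trend``.
    """

    contributions: dict         # driver -> delta-Y^X
    clm_ps: float
    clm: float
    residual_trend: float
    total_trend: float
    driver_trends: dict         # driver -> dX/dt
    sensitivities: SensitivityVector = None

    @property
    def vgc(self) -> float:
        """Contribution of the carryover (preceding-season greenness) term."""
        return self.contributions["ndvi_ps"]

    def closure_defect(self) -> float:
        """|observed trend - reconstructed trend|; ~0 by construction."""
        recon = sum(self.contributions.values()) + self.residual_trend
        return abs(self.total_trend - recon)


def fit_sensitivities(y, drivers: dict) -> SensitivityVector:
    """Jointly regress Y on the five drivers by OLS.

    Parameters
    ----------
    y
        Per-year target series.
    drivers
        Mapping with keys ``ndvi_ps, tmp, pre, tmp_ps, pre_ps`` of
        equal-length per-year series. Listwise deletion over complete
        years.

    A rank-deficient design (e.g. duplicated drivers) yields a flagged,
    undefined result rather than arbitrary coefficients.
    """
    missing = set(DRIVERS) - set(drivers)
    if missing:
        raise VegcarryError(f"missing drivers {sorted(missing)}")
    yv = np.asarray(y, dtype=float)
    cols = [np.asarray(drivers[d], dtype=float) for d in DRIVERS]
    for c in cols:
        if len(c) != len(yv):
            raise VegcarryError("driver series length mismatch")
    ok = np.isfinite(yv)
    for c in cols:
        ok &= np.isfinite(c)
    n = int(ok.sum())
    if n < 8:
        raise VegcarryError(f"need >= 8 complete years, got {n}")
    X = np.column_stack([np.ones(n)] + [c[ok] for c in cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return SensitivityVector({}, np.nan, np.nan, n, False, "rank-deficient design")
    beta, *_ = np.linalg.lstsq(X, yv[ok], rcond=None)
    fitted = X @ beta
    tss = float(np.sum((yv[ok] - yv[ok].mean()) ** 2))
    r2 = 1.0 - float(np.sum((yv[ok] - fitted) ** 2)) / tss if tss > 0 else np.nan
    return SensitivityVector(
        beta=dict(zip(DRIVERS, beta[1:])),
        intercept=float(beta[0]),
        r_squared=r2,
        n=n,
    )


def decompose_trend(y, drivers: dict, years=None) -> AttributionResult:
    """Decompose the linear trend of Y into per-driver contributions.

    Each contribution is the product of the jointly estimated sensitivity
    and the driver's own linear trend. The residual trend is computed as
    the trend of the OLS residual series; the closure identity
    (contributions + residual = observed trend) is asserted to
    ``CLOSURE_ATOL``.
    """
    sens = fit_sensitivities(y, drivers)
    if not sens.defined:
        raise VegcarryError(f"sensitivity fit failed: {sens.reason}")

    yv = np.asarray(y, dtype=float)
    t = np.arange(len(yv), dtype=float) if years is None else np.asarray(years, dtype=float)
    ok = np.isfinite(yv)
    cols = {d: np.asarray(drivers[d], dtype=float) for d in DRIVERS}
    for c in cols.values():
        ok &= np.isfinite(c)

    total = linear_trend(yv[ok], t[ok])
    driver_trends = {d: linear_trend(cols[d][ok], t[ok]) for d in DRIVERS}
    contributions = {d: sens.beta[d] * driver_trends[d] for d in DRIVERS}

    fitted = sens.intercept + sum(sens.beta[d] * cols[d][ok] for d in DRIVERS)
    residual_trend = linear_trend(yv[ok] - fitted, t[ok])
    defect = abs(total - sum(contributions.values()) - residual_trend)
    if not defect <= max(CLOSURE_ATOL, 1e-9 * max(abs(total), 1e-30)):
        raise AssertionError(
            f"closure identity violated by {defect:.3e} (OLS pathology)"
        )

    return AttributionResult(
        contributions=contributions,
        clm_ps=contributions["tmp_ps"] + contributions["pre_ps"],
        clm=contributions["tmp"] + contributions["pre"],
        residual_trend=residual_trend,
        total_trend=total,
        driver_trends=driver_trends,
        sensitivities=sens,
    )


def attribute_season(table: pd.DataFrame, season: str) -> AttributionResult:
    """Run the decomposition for one target season of a pivoted cell table.

    ``table`` is the year-indexed (variable, season) table from
    :func:`vegcarry.memory_stats.seasonal_series_table`; the driver set is
    identical to the seasonal VGC profile's.
    """
    frame = _profile_driver_frame(table, season).dropna()
    y = frame["y"].to_numpy()
    drivers = {d: frame[d].to_numpy() for d in DRIVERS}
    return decompose_trend(y, drivers, years=frame.index.to_numpy(dtype=float))


def grid_attribution(data, season: str) -> pd.DataFrame:
    """Per-cell attribution over a simulated grid.

    ``data`` is a :class:`vegcarry.simulate.SeasonalSystemData`. Returns a
    tidy frame with one row per cell and the named contribution columns.
    """
    from vegcarry.memory_stats import PRECEDING_NDVI_SEASON, PRECEDING_SEASON

    ps_clim = PRECEDING_SEASON[season]
    ps_ndvi = PRECEDING_NDVI_SEASON[season]
    rows = []
    yrs = data.years.astype(float)
    for c in range(data.ndvi.shape[0]):
        ndvi_ps = data.series(c, "ndvi", ps_ndvi)
        if season == "EGS":
            ndvi_ps = np.concatenate([[np.nan], ndvi_ps[:-1]])
        drivers = {
            "ndvi_ps": ndvi_ps,
            "tmp": data.series(c, "tmp", season),
            "pre": data.series(c, "pre", season),
            "tmp_ps": data.series(c, "tmp", ps_clim),
            "pre_ps": data.series(c, "pre", ps_clim),
        }
        res = decompose_trend(data.series(c, "ndvi", season), drivers, years=yrs)
        rows.append({
            "cell_id": data.cell_ids[c],
            "season": season,
            "vgc": res.vgc,
            "clm_ps": res.clm_ps,
            "clm": res.clm,
            "residual": res.residual_trend,
            "total": res.total_trend,
            **{f"d_{d}": res.contributions[d] for d in DRIVERS},
        })
    return pd.DataFrame(rows)


def summarize_contributions(
    per_cell: pd.DataFrame,
    weights: pd.Series | None = None,
    share_basis: str = "observed",
) -> pd.DataFrame:
    """Area-weighted mean contributions and signed percentage shares.

    Parameters
    ----------
    per_cell
        Frame from :func:`grid_attribution` (columns ``vgc, clm_ps, clm,
        residual, total`` at least).
    weights
        Area weight per ``cell_id``; None = equal weights.
    share_basis
        ``"observed"`` divides by the mean observed trend; ``"explained"``
        divides by the explained (observed minus residual) trend.

    Returns a frame with one row per component: mean contribution and
    percentage share. Shares are undefined (NaN) when the basis trend is
    zero; absolute contributions are always reported.
    """
    if len(per_cell) == 0:
        raise VegcarryError("no valid cells to summarize")
    if weights is None:
        w = np.ones(len(per_cell))
    else:
        w = per_cell["cell_id"].map(weights).to_numpy(dtype=float)
        if not np.isfinite(w).all():
            raise VegcarryError("missing weight for some cells")
    if w.sum() <= 0:
        raise VegcarryError("no positive weight")

    components = ["vgc", "clm_ps", "clm", "residual", "total"]
    means = {c: float(np.average(per_cell[c].to_numpy(), weights=w)) for c in components}
    if share_basis == "observed":
        basis = means["total"]
    elif share_basis == "explained":
        basis = means["total"] - means["residual"]
    else:
        raise VegcarryError(f"unknown share basis {share_basis!r}")
    shares = {
        c: (100.0 * means[c] / basis if basis != 0 else np.nan) for c in components
    }
    return pd.DataFrame({
        "component": components,
        "mean_contribution": [means[c] for c in components],
        "share_pct": [shares[c] for c in components],
    })
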