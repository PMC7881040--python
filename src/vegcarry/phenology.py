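"""Season delineation from the climatological vegetation cycle.

Rather than fixed calendar seasons or temperature thresholds, seasons are
delineated per grid cell from the multi-year mean seasonal cycle of the
vegetation index:

* SOS / EOS — the days when the daily rate of change of the cycle
  (interpolated from the biweekly composites) is highest / lowest;
* PGS — the two consecutive months with maximum summed greenness, no
  earlier than April and no later than October (one month when the
  growing season is three months or shorter);
* EGS — from the month containing SOS up to the month before PGS;
* LGS — from the month after PGS through the month containing EOS;
* DS — all remaining months, spanning the calendar boundary; the DS
  attached to year t runs from after EOS of year t-1 to before SOS of
  year t, so dormancy precedes the spring it is paired with.

Cells whose maximum greenness falls before April or after October, or
whose cycle is too flat for slope detection, are excluded.

A site-level variant detects SOS/EOS from the second derivative of a
spline-smoothed daily productivity series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline

from vegcarry.core import SEASONAL_COLUMNS, VegcarryError, validate_biweekly
from vegcarry.simulate import DAYS_PER_YEAR, composite_midpoints

MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
MONTH_ENDS = np.cumsum(MONTH_LENGTHS)          # day-of-year of each month end
MONTH_STARTS = MONTH_ENDS - MONTH_LENGTHS + 1


class CellExcluded(VegcarryError):
    """Cell fails a phenology inclusion rule (flat cycle, off-window peak)."""


def month_of_day(day: float) -> int:
    """Calendar month (1..12) containing a day-of-year on the 365-day calendar."""
    d = min(max(int(np.ceil(day)), 1), DAYS_PER_YEAR)
    return int(np.searchsorted(MONTH_ENDS, d) + 1)


def climatological_cycle(biweekly: pd.DataFrame, years=None) -> np.ndarray:
    """Multi-year mean of each of the 24 composite periods for one cell.

    Missing composites are ignored period-wise; a period missing in every
    year is an error (the cycle would have a hole).
    """
    validate_biweekly(biweekly)
    df = biweekly if years is None else biweekly[biweekly["year"].isin(years)]
    counts = df.groupby("period")["value"].count()
    if (counts.reindex(range(1, 25), fill_value=0) < 2).any():
        missing = sorted(set(range(1, 25)) - set(counts[counts >= 2].index))
        raise VegcarryError(f"periods {missing} have <2 non-missing years")
    cycle = df.groupby("period")["value"].mean()
    return cycle.reindex(range(1, 25)).to_numpy()


@dataclass
class PhenoDates:
    sos_day: float
    eos_day: float
    defined: bool = True
    reason: str = ""


def detect_sos_eos(cycle: np.ndarray, min_amplitude: float = 0.02) -> PhenoDates:
    """SOS/EOS from the daily rate of change of the 24-point mean cycle.

    The cycle is interpolated to daily resolution with a periodic cubic
    spline (three tiled years, center year evaluated), giving a continuous
    first derivative; SOS is the day of the maximum derivative, EOS the
    day of the minimum.

    Cycles whose range is below ``min_amplitude`` are flagged
    undetectable and should be excluded downstream.
    """
    cycle = np.asarray(cycle, dtype=float)
    if cycle.shape != (24,):
        raise VegcarryError("cycle must have exactly 24 composite values")
    if not np.isfinite(cycle).all():
        raise VegcarryError("cycle contains missing periods")
    if cycle.max() - cycle.min() < min_amplitude:
        return PhenoDates(np.nan, np.nan, False, "flat cycle")

    mids = composite_midpoints()
    x = np.concatenate([mids - DAYS_PER_YEAR, mids, mids + DAYS_PER_YEAR])
    y = np.tile(cycle, 3)
    spline = CubicSpline(x, y)
    days = np.arange(1.0, DAYS_PER_YEAR + 1.0)
    slope = spline(days, 1)
    sos = float(days[np.argmax(slope)])
    eos = float(days[np.argmin(slope)])
    if not sos < eos:
        return PhenoDates(np.nan, np.nan, False, "degenerate cycle (SOS >= EOS)")
    return PhenoDates(sos, eos)


@dataclass
class SeasonWindows:
    """Per-cell assignment of calendar months to the four seasons.

    The month sets are disjoint, cover all 12 months, and the active
    seasons appear in within-year order EGS < PGS < LGS. Validated on
    construction.
    """

    sos_day: float
    eos_day: float
    months: dict          # season -> tuple of months
    cell_id: str | None = None

    def __post_init__(self) -> None:
        all_months = [m for s in ("EGS", "PGS", "LGS", "DS") for m in self.months.get(s, ())]
        if sorted(all_months) != list(range(1, 13)):
            raise VegcarryError(
                f"season windows do not partition the year: {self.months}"
            )
        egs, pgs, lgs = (self.months.get(s, ()) for s in ("EGS", "PGS", "LGS"))
        if not pgs:
            raise VegcarryError("PGS is empty")
        if len(pgs) > 2:
            raise VegcarryError("PGS must have 1 or 2 months")
        if egs and max(egs) >= min(pgs):
            raise VegcarryError("EGS months must precede PGS months")
        if lgs and min(lgs) <= max(pgs):
            raise VegcarryError("LGS months must follow PGS months")

    def season_of(self, month: int) -> str:
        for season, months in self.months.items():
            if month in months:
                return season
        raise VegcarryError(f"month {month} unassigned")


def define_seasons(
    sos_day: float,
    eos_day: float,
    monthly_cycle: np.ndarray,
    cell_id: str | None = None,
    pgs_window: tuple[int, int] = (4, 10),
) -> SeasonWindows:
    """Apply the season-definition rules to one cell.

    Parameters
    ----------
    sos_day, eos_day
        Detected phenology dates (day-of-year).
    monthly_cycle
        12 climatological monthly greenness values, used to place the peak
        growing season.
    pgs_window
        Admissible months for the greenness peak (inclusive); a peak
        outside this window marks the cell as outside the target
        phenological regime.

    Raises
    ------
    CellExcluded
        If the maximum-greenness month falls outside ``pgs_window``.
    """
    monthly_cycle = np.asarray(monthly_cycle, dtype=float)
    if monthly_cycle.shape != (12,):
        raise VegcarryError("monthly cycle must have 12 values")
    if not (np.isfinite(sos_day) and np.isfinite(eos_day)):
        raise CellExcluded(f"cell {cell_id}: undetectable phenology")

    peak_month = int(np.argmax(monthly_cycle) + 1)
    lo, hi = pgs_window
    if not lo <= peak_month <= hi:
        raise CellExcluded(
            f"cell {cell_id}: maximum greenness in month {peak_month}, "
            f"outside months {lo}..{hi}"
        )

    sos_month = month_of_day(sos_day)
    eos_month = month_of_day(eos_day)
    gs_length = eos_month - sos_month + 1

    if gs_length <= 3:
        pgs = (peak_month,)
    else:
        # two consecutive months with maximum summed greenness, both inside
        # the admissible window; ties broken toward the earlier pair
        best, best_sum = None, -np.inf
        for m in range(lo, hi):
            s = monthly_cycle[m - 1] + monthly_cycle[m]
            if s > best_sum + 1e-12:
                best, best_sum = (m, m + 1), s
        pgs = best

    if pgs[0] < sos_month:
        raise VegcarryError(
            f"cell {cell_id}: PGS {pgs} precedes the SOS month {sos_month}"
        )
    if pgs[-1] > eos_month:
        raise VegcarryError(
            f"cell {cell_id}: PGS {pgs} follows the EOS month {eos_month}"
        )

    egs = tuple(range(sos_month, pgs[0]))
    lgs = tuple(range(pgs[-1] + 1, eos_month + 1))
    used = set(egs) | set(pgs) | set(lgs)
    ds = tuple(m for m in range(1, 13) if m not in used)
    return SeasonWindows(
        sos_day=sos_day, eos_day=eos_day, cell_id=cell_id,
        months={"EGS": egs, "PGS": pgs, "LGS": lgs, "DS": ds},
    )


def delineate_cell(
    biweekly: pd.DataFrame,
    cell_id: str | None = None,
    min_ndvi: float = 0.1,
    min_amplitude: float = 0.02,
) -> SeasonWindows:
    """Full per-cell delineation: cycle -> SOS/EOS -> season windows.

    Cells whose climatological growing-season maximum stays below
    ``min_ndvi`` are flagged non-vegetated and excluded.
    """
    cycle = climatological_cycle(biweekly)
    if np.nanmax(cycle) < min_ndvi:
        raise CellExcluded(f"cell {cell_id}: non-vegetated (max index < {min_ndvi})")
    dates = detect_sos_eos(cycle, min_amplitude=min_amplitude)
    if not dates.defined:
        raise CellExcluded(f"cell {cell_id}: {dates.reason}")
    monthly_cycle = cycle.reshape(12, 2).max(axis=1)  # max-value compositing
    return define_seasons(dates.sos_day, dates.eos_day, monthly_cycle, cell_id)


def delineate_grid(biweekly: pd.DataFrame, **kwargs) -> tuple[dict, dict]:
    """Delineate every cell; returns (cell_id -> SeasonWindows, exclusions)."""
    windows, excluded = {}, {}
    for cell_id, sub in biweekly.groupby("cell_id"):
        try:
            windows[cell_id] = delineate_cell(sub, cell_id=cell_id, **kwargs)
        except CellExcluded as exc:
            excluded[cell_id] = str(exc)
    return windows, excluded


def detect_sos_eos_gpp(
    daily: np.ndarray,
    lam: float = 5000.0,
    max_missing: float = 0.2,
    min_amplitude: float = 0.0,
) -> PhenoDates:
    """Site-level SOS/EOS from the second derivative of daily productivity.

    The daily series is smoothed with a smoothing spline (penalty ``lam``
    on integrated squared curvature; the default suppresses synoptic
    noise while keeping the seasonal inflections) and SOS / EOS are the
    days of the maximum / minimum second derivative of the smoothed curve.

    Sites with more than ``max_missing`` of days missing are excluded.
    """
    v = np.asarray(daily, dtype=float)
    n = len(v)
    ok = np.isfinite(v)
    if 1.0 - ok.mean() > max_missing:
        raise CellExcluded(
            f"site excluded: {100 * (1 - ok.mean()):.0f}% of days missing"
        )
    days = np.arange(1.0, n + 1.0)
    if np.nanmax(v) - np.nanmin(v) <= min_amplitude or np.nanstd(v) < 1e-12:
        return PhenoDates(np.nan, np.nan, False, "flat series")
    spline = make_smoothing_spline(days[ok], v[ok], lam=lam)
    d2 = spline(days, 2)
    sos = float(days[np.argmax(d2)])
    eos = float(days[np.argmin(d2)])
    return PhenoDates(sos, eos)


def aggregate_seasonal(
    monthly: pd.DataFrame,
    windows: dict | SeasonWindows,
    sum_variables: tuple = ("pre",),
) -> pd.DataFrame:
    """Aggregate monthly values to seasonal values under per-cell windows.

    Seasonal value = mean of the member months (sum for variables named in
    ``sum_variables``, conventionally precipitation). Dormancy months after
    the EOS month belong to the following year's DS, so the DS attached to
    year t spans from after EOS of year t-1 to before SOS of year t. Years
    with any member month missing give a missing seasonal value.
    """
    if isinstance(windows, SeasonWindows):
        windows = {windows.cell_id if windows.cell_id is not None else c: windows
                   for c in monthly["cell_id"].unique()}
    out = []
    for cell_id, sub in monthly.groupby("cell_id"):
        if cell_id not in windows:
            continue
        w = windows[cell_id]
        eos_month = month_of_day(w.eos_day)
        df = sub.copy()
        df["season"] = df["month"].map(w.season_of)
        late_ds = (df["season"] == "DS") & (df["month"] > eos_month)
        df["season_year"] = df["year"] + late_ds.astype(int)
        for (year, season, variable), grp in df.groupby(
            ["season_year", "season", "variable"]
        ):
            members = w.months[season]
            present = set(grp.loc[grp["value"].notna(), "month"])
            if set(members) - present:
                value = np.nan
            elif variable in sum_variables:
                value = float(grp["value"].sum())
            else:
                value = float(grp["value"].mean())
            out.append((cell_id, year, season, variable, value))
    return pd.DataFrame(out, columns=SEASONAL_COLUMNS)


def windows_to_frame(windows: dict) -> pd.DataFrame:
    """Serialize SeasonWindows per cell as a tidy frame (one row per month)."""
    rows = []
    for cell_id, w in windows.items():
        for season, months in w.months.items():
            for m in months:
                rows.append((cell_id, w.sos_day, w.eos_day, m, season))
    return pd.DataFrame(rows, columns=["cell_id", "sos_doy", "eos_doy", "month", "season"])
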