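"""Shared data model, I/O, compositing, masking, and spatial aggregation.

The common currency of the pipeline is a set of tidy :class:`pandas.DataFrame`
layouts, one per temporal resolution:

``biweekly``
    columns ``cell_id, year, period, value`` with ``period`` in 1..24;
    composites ``2k-1`` and ``2k`` belong to calendar month ``k``.
``monthly``
    columns ``cell_id, year, month, variable, value`` (plus optional
    ``lat``/``lon``); one row per (cell, year, month, variable).
``seasonal``
    columns ``cell_id, year, season, variable, value`` with ``season`` in
    ``{"EGS", "PGS", "LGS", "DS"}`` — early, peak and late growing season
    plus the dormancy season.

Grid cells are addressed by an opaque ``cell_id``; latitude is attached only
where a spatial weight needs it, so the pipeline never assumes a particular
grid resolution.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger("vegcarry")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

#: Within-year season order. DS spans the calendar boundary and precedes the
#: EGS it is paired with (the dormancy-to-spring legacy pairing).
SEASONS = ("EGS", "PGS", "LGS", "DS")

#: Active growing seasons, in within-year order.
ACTIVE_SEASONS = ("EGS", "PGS", "LGS")

BIWEEKLY_COLUMNS = ["cell_id", "year", "period", "value"]
MONTHLY_COLUMNS = ["cell_id", "year", "month", "variable", "value"]
SEASONAL_COLUMNS = ["cell_id", "year", "season", "variable", "value"]


class VegcarryError(ValueError):
    """Malformed input or violated contract anywhere in the pipeline."""


def period_to_month(period: np.ndarray | int) -> np.ndarray | int:
    """Map a biweekly composite index 1..24 to its calendar month 1..12."""
    return (np.asarray(period) + 1) // 2


def validate_biweekly(df: pd.DataFrame) -> pd.DataFrame:
    """Check the biweekly layout; return the frame for chaining."""
    missing = set(BIWEEKLY_COLUMNS) - set(df.columns)
    if missing:
        raise VegcarryError(f"biweekly frame missing columns {sorted(missing)}")
    bad = df[(df["period"] < 1) | (df["period"] > 24)]
    if len(bad):
        row = bad.iloc[0]
        raise VegcarryError(
            f"period {row['period']} out of range 1..24 "
            f"(cell {row['cell_id']}, year {row['year']})"
        )
    dup = df.duplicated(subset=["cell_id", "year", "period"])
    if dup.any():
        row = df[dup].iloc[0]
        raise VegcarryError(
            f"duplicate composite for cell {row['cell_id']}, "
            f"year {row['year']}, period {row['period']}"
        )
    return df


def validate_seasonal(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(SEASONAL_COLUMNS) - set(df.columns)
    if missing:
        raise VegcarryError(f"seasonal frame missing columns {sorted(missing)}")
    bad = set(df["season"].unique()) - set(SEASONS)
    if bad:
        raise VegcarryError(f"unknown seasons {sorted(bad)}")
    return df


def composite_monthly_max(biweekly: pd.DataFrame, variable: str = "ndvi") -> pd.DataFrame:
    """Composite biweekly values to monthly values by taking the maximum.

    Maximum-value compositing suppresses cloud and atmospheric
    contamination, which biases vegetation indices low. Months whose
    composites are all missing stay missing (NaN).

    Parameters
    ----------
    biweekly
        Frame in the ``biweekly`` layout.
    variable
        Name recorded in the output ``variable`` column.

    Returns
    -------
    Frame in the ``monthly`` layout, one row per (cell, year, month),
    value = max over that month's non-missing composites.
    """
    validate_biweekly(biweekly)
    df = biweekly.copy()
    df["month"] = period_to_month(df["period"].to_numpy())
    out = (
        df.groupby(["cell_id", "year", "month"], sort=True)["value"]
        .max()  # NaN-aware: max of all-NaN group is NaN
        .reset_index()
    )
    out["variable"] = variable
    return out[MONTHLY_COLUMNS]


def dominant_cover_mask(fractions: pd.DataFrame, threshold: float = 0.6) -> pd.Series:
    """Label each cell with its dominant vegetation class, if dominant enough.

    A cell is labeled with a class iff that class covers strictly more than
    ``threshold`` of the cell area; otherwise the cell is excluded (NaN),
    which screens out mixed pixels and land-cover conversions.

    Parameters
    ----------
    fractions
        Wide frame indexed by ``cell_id`` with one column per vegetation
        class; values are area fractions in [0, 1] summing to <= 1 per cell.
    threshold
        Dominance threshold in (0, 1]; the conventional choice is 0.6.

    Returns
    -------
    Series indexed by ``cell_id``: class name, or NaN for excluded cells.
    """
    if not 0 < threshold <= 1:
        raise VegcarryError(f"threshold must be in (0, 1], got {threshold}")
    vals = fractions.to_numpy(dtype=float)
    if (vals < 0).any():
        raise VegcarryError("negative cover fractions")
    if (vals.sum(axis=1) > 1 + 1e-9).any():
        raise VegcarryError("cover fractions exceed 1 in at least one cell")
    winner = fractions.idxmax(axis=1)
    dominant = fractions.max(axis=1) > threshold
    return winner.where(dominant).rename("cover_class")


def cos_lat_weights(lat: pd.Series) -> pd.Series:
    """Area weights proportional to cos(latitude), indexed like ``lat``."""
    w = np.cos(np.deg2rad(lat.to_numpy(dtype=float)))
    if (w < 0).any():
        raise VegcarryError("latitude outside [-90, 90]")
    return pd.Series(w, index=lat.index, name="weight")


def area_weighted_mean(
    seasonal: pd.DataFrame,
    weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Spatially average a seasonal field into per-year series.

    Parameters
    ----------
    seasonal
        Frame in the ``seasonal`` layout.
    weights
        Nonnegative area weight per ``cell_id``; ``None`` means equal
        weights (the unweighted hemispheric average).

    Returns
    -------
    Frame with columns ``year, season, variable, value`` where value is
    sum(w_i v_i) / sum(w_i) over cells with non-missing values. Years where
    every cell is missing come out NaN.
    """
    validate_seasonal(seasonal)
    df = seasonal.copy()
    if weights is None:
        df["weight"] = 1.0
    else:
        if (weights < 0).any():
            raise VegcarryError("negative area weights")
        df["weight"] = df["cell_id"].map(weights)
        if df["weight"].isna().any():
            bad = df.loc[df["weight"].isna(), "cell_id"].iloc[0]
            raise VegcarryError(f"no weight for cell {bad}")
    ok = df["value"].notna()
    df["wv"] = df["weight"].where(ok, 0.0) * df["value"].fillna(0.0)
    df["w"] = df["weight"].where(ok, 0.0)
    g = df.groupby(["year", "season", "variable"], sort=True)[["wv", "w"]].sum()
    if (g["w"] == 0).all():
        raise VegcarryError("no positive weight on any non-missing cell")
    out = (g["wv"] / g["w"].replace(0.0, np.nan)).rename("value").reset_index()
    return out


# ---------------------------------------------------------------------------
# I/O: long CSV and CF-style gridded NetCDF
# ---------------------------------------------------------------------------

def read_long_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_long_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
    logger.info("wrote %d records to %s", len(df), path)


def monthly_to_dataset(monthly: pd.DataFrame, cells: pd.DataFrame) -> xr.Dataset:
    """Assemble a CF-style (time, lat, lon) Dataset from a monthly frame.

    ``cells`` maps ``cell_id`` to ``lat``/``lon``; the grid is taken as the
    cross-product of the latitudes and longitudes present.
    """
    df = monthly.merge(cells[["cell_id", "lat", "lon"]], on="cell_id")
    df["time"] = pd.to_datetime(
        dict(year=df["year"], month=df["month"], day=15)
    )
    ds = xr.Dataset()
    for var, sub in df.groupby("variable"):
        da = sub.set_index(["time", "lat", "lon"])["value"].to_xarray()
        ds[var] = da
    ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
    ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
    return ds


def write_netcdf(ds: xr.Dataset, path: str | Path) -> None:
    """Write a NetCDF3-classic file (portable, no compression)."""
    ds.to_netcdf(path, engine="scipy")
    logger.info("wrote dataset %s to %s", dict(ds.sizes), path)


def read_netcdf(path: str | Path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy")


def write_manifest(path: str | Path, *, inputs=None, parameters=None, seed=None) -> None:
    """Write a machine-readable run manifest beside an output file."""
    manifest = {
        "inputs": inputs or {},
        "parameters": parameters or {},
        "seed": seed,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
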