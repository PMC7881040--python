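"""Tree-ring standardization and chronology construction.

Raw ring widths confound the climate/growth signal of interest with a
biological age trend (wide juvenile rings narrowing with age and trunk
diameter). Standardization divides each series by a fitted cubic
smoothing spline whose 50% frequency response sits at a wavelength of
67% of the series length — the dendrochronology-community convention —
removing the low-frequency age trend while preserving interannual and
interdecadal variability. Site chronologies average the tree-level
indices year by year with Tukey's biweight robust mean, which resists
the occasional aberrant tree.

Ring widths are read and written in the Tucson/RWL decadal format used
by public tree-ring archives, with a CSV fallback carrying the same
columns (``series_id, year, width_mm``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from vegcarry.core import VegcarryError, logger
from vegcarry.memory_stats import lagged_pacf, sign_frequency_summary

#: Minimum series length for standardization (archives conventionally
#: require a few decades of record for a usable spline fit).
MIN_SERIES_YEARS = 25

#: Biweight tuning constant, in units of the median absolute deviation.
BIWEIGHT_C = 9.0


# ---------------------------------------------------------------------------
# Tucson/RWL decadal format
# ---------------------------------------------------------------------------

def read_rwl(path) -> pd.DataFrame:
    """Read a Tucson/RWL decadal ring-width file.

    Each line holds a series id, the decade's first year, and up to ten
    integer widths; a series ends at the stop marker, whose value
    declares the precision (999 -> 0.01 mm units, -9999 -> 0.001 mm).

    Returns a frame with columns ``series_id, year, width_mm``.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    precision: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise VegcarryError(f"{path}:{lineno}: malformed row {line!r}")
            sid = parts[0]
            try:
                decade_year = int(parts[1])
                values = [int(v) for v in parts[2:]]
            except ValueError as exc:
                raise VegcarryError(f"{path}:{lineno}: non-numeric field ({exc})")
            if sid in precision:
                raise VegcarryError(
                    f"{path}:{lineno}: data for series {sid} after its stop marker"
                )
            seq = raw.setdefault(sid, [])
            if seq and decade_year <= seq[-1][0]:
                raise VegcarryError(
                    f"{path}:{lineno}: decade {decade_year} out of order for {sid}"
                )
            year = decade_year
            for v in values:
                if v == 999:
                    precision[sid] = 0.01
                    break
                if v == -9999:
                    precision[sid] = 0.001
                    break
                seq.append((year, v))
                year += 1

    rows = []
    for sid, seq in raw.items():
        scale = precision.get(sid, 0.01)
        for year, v in seq:
            rows.append((sid, year, v * scale))
    if not rows:
        raise VegcarryError(f"{path}: no ring-width data found")
    df = pd.DataFrame(rows, columns=["series_id", "year", "width_mm"])
    logger.info("read %d series, %d rings from %s", df["series_id"].nunique(), len(df), path)
    return df


def write_rwl(df: pd.DataFrame, path, precision: float = 0.01) -> None:
    """Write ring widths in Tucson/RWL decadal layout.

    ``precision`` selects the integer unit (0.01 mm with stop marker 999,
    or 0.001 mm with stop marker -9999). Widths are rounded to that unit;
    the reader recovers them exactly.
    """
    if precision == 0.01:
        stop = "999"
    elif precision == 0.001:
        stop = "-9999"
    else:
        raise VegcarryError("precision must be 0.01 or 0.001 mm")
    with open(path, "w") as fh:
        for sid, sub in df.groupby("series_id", sort=True):
            sub = sub.sort_values("year")
            years = sub["year"].to_numpy(dtype=int)
            if (np.diff(years) != 1).any():
                raise VegcarryError(f"series {sid} has year gaps; fill or split first")
            vals = np.round(sub["width_mm"].to_numpy() / precision).astype(int)
            i = 0
            while i < len(years):
                year = years[i]
                row_end = min(len(years), i + (10 - year % 10))
                fields = [f"{v:6d}" for v in vals[i:row_end]]
                if row_end == len(years):
                    fields.append(f"{stop:>6s}")
                fh.write(f"{sid:<8s}{year:4d}" + "".join(fields) + "\n")
                i = row_end


# ---------------------------------------------------------------------------
# Spline standardization
# ---------------------------------------------------------------------------

def _spline_smoothing_param(wavelength: float, response: float = 0.5) -> float:
    """csaps-style parameter p with the given frequency response at ``wavelength``.

    Classic smoothing-spline frequency-response relation for unit sample
    spacing; p weights the data-fidelity term against the curvature
    penalty (p -> 1 interpolates, p -> 0 gives the least-squares line).
    """
    c = np.cos(2.0 * np.pi / wavelength)
    return 1.0 / (1.0 + ((c + 2.0) * (1.0 - response)) / (12.0 * response * (c - 1.0) ** 2))


def spline_detrend(
    widths: np.ndarray,
    stiffness: float = 0.67,
    domain: str = "log",
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize one raw ring-width series by a cubic smoothing spline.

    The spline's 50% frequency response sits at ``stiffness`` times the
    series length. Two numerical refinements reduce fitting bias without
    changing the convention: the series is padded at both ends by point
    reflection over one smoothing bandwidth before fitting (curvature-
    penalty smoothers are otherwise biased at the boundaries), and by
    default the spline is fit to log widths — ring-width variability
    scales with width, and multiplicative age trends are far less curved
    in log space, so the same stiffness tracks them more faithfully.

    Parameters
    ----------
    widths
        Raw widths (mm) on consecutive years, length >= 25.
    stiffness
        Wavelength of the 50% frequency response, as a fraction of the
        series length (default 0.67 — the community convention).
    domain
        ``"log"`` (default) fits the spline to log widths;
        ``"linear"`` fits the widths directly.

    Returns
    -------
    (index, fitted)
        Dimensionless index = raw / fitted (centered near 1), and the
        fitted age curve. A fitted value <= 0 (possible only in the
        linear domain) flags the series as unusable (raises).
    """
    w = np.asarray(widths, dtype=float)
    if len(w) < MIN_SERIES_YEARS:
        raise VegcarryError(
            f"series of {len(w)} years is below the {MIN_SERIES_YEARS}-year minimum"
        )
    if not np.isfinite(w).all():
        raise VegcarryError("missing widths; series must be gap-free")
    if (w <= 0).any():
        raise VegcarryError("ring widths must be positive")
    if domain not in ("log", "linear"):
        raise VegcarryError(f"unknown fitting domain {domain!r}")
    p = _spline_smoothing_param(stiffness * len(w))
    lam = (1.0 - p) / p

    y = np.log(w) if domain == "log" else w
    # pad by point reflection over one smoothing bandwidth (~lam^(1/4))
    k = min(max(2, int(round(lam**0.25))), len(y) - 1)
    padded = np.concatenate([2 * y[0] - y[k:0:-1], y, 2 * y[-1] - y[-2:-k - 2:-1]])
    x = np.arange(len(padded), dtype=float)
    smooth = make_smoothing_spline(x, padded, lam=lam)(x)[k:k + len(y)]
    fitted = np.exp(smooth) if domain == "log" else smooth
    if (fitted <= 0).any():
        raise VegcarryError("fitted growth curve crosses zero; series excluded")
    return w / fitted, fitted


def standardize(df: pd.DataFrame, stiffness: float = 0.67) -> pd.DataFrame:
    """Standardize every series of a ring-width frame.

    Series shorter than the minimum or with a non-positive fitted curve
    are dropped (logged). Returns columns ``series_id, year, index``.
    """
    out = []
    for sid, sub in df.groupby("series_id", sort=True):
        sub = sub.sort_values("year")
        try:
            index, _ = spline_detrend(sub["width_mm"].to_numpy(), stiffness=stiffness)
        except VegcarryError as exc:
            logger.info("series %s skipped: %s", sid, exc)
            continue
        out.append(pd.DataFrame({
            "series_id": sid, "year": sub["year"].to_numpy(), "index": index,
        }))
    if not out:
        raise VegcarryError("no series survived standardization")
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Biweight robust mean chronology
# ---------------------------------------------------------------------------

def tukey_biweight(values: np.ndarray, c: float = BIWEIGHT_C, max_iter: int = 50) -> float:
    """Tukey biweight location of a 1-D sample.

    Iteratively reweights around the current center with weights
    (1 - u^2)^2 for |u| < 1, u = (x - m) / (c * MAD). Falls back to the
    median when the MAD vanishes (over half the sample identical).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        return np.nan
    m = float(np.median(x))
    for _ in range(max_iter):
        mad = float(np.median(np.abs(x - m)))
        if mad <= 0:
            return m
        u = (x - m) / (c * mad)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            return m
        m_new = float(np.sum(w * x) / np.sum(w))
        if abs(m_new - m) < 1e-12:
            return m_new
        m = m_new
    return m


@dataclass
class Chronology:
    """Site-level standardized annual index with per-year sample depth."""

    site_id: str
    index: pd.Series       # year -> biweight mean index
    depth: pd.Series       # year -> number of contributing series

    @property
    def span(self) -> tuple[int, int]:
        years = self.index.dropna().index
        return int(years.min()), int(years.max())


def biweight_mean(
    indices: pd.DataFrame,
    site_id: str = "site",
    min_depth: int = 2,
) -> Chronology:
    """Build a chronology by biweight-averaging tree indices per year.

    Parameters
    ----------
    indices
        Long frame ``series_id, year, index`` (from :func:`standardize`)
        or a wide year x series matrix.
    min_depth
        Years with fewer overlapping series than this come out missing.
    """
    if {"series_id", "year", "index"} <= set(indices.columns):
        wide = indices.pivot_table(index="year", columns="series_id", values="index")
    else:
        wide = indices
    depth = wide.notna().sum(axis=1)
    chron = pd.Series(
        [tukey_biweight(row.to_numpy()) for _, row in wide.iterrows()],
        index=wide.index, name="index", dtype=float,
    )
    chron[depth < min_depth] = np.nan
    if chron.notna().sum() == 0:
        raise VegcarryError(f"no year reaches sample depth {min_depth}")
    return Chronology(site_id=site_id, index=chron, depth=depth.rename("depth"))


# ---------------------------------------------------------------------------
# Interannual carryover of chronologies
# ---------------------------------------------------------------------------

def chronology_vgc(
    chronologies: dict,
    climate: dict | None = None,
    groups: dict | None = None,
    max_lead: int = 3,
) -> pd.DataFrame:
    """Lead-1..3 partial autocorrelation per chronology, tidily tabulated.

    Parameters
    ----------
    chronologies
        Mapping site_id -> :class:`Chronology` (or a plain per-year
        series). Each series is linearly detrended inside the PACF for
        comparability with the greenness analyses.
    climate
        Optional mapping site_id -> {name: annual series} of covariates
        (annual-mean temperature/precipitation) controlled at years t
        and t-1.
    groups
        Optional site_id -> label (e.g. wood-porosity class); missing
        labels become "ungrouped".

    Returns a frame (site_id, group, lead, r_p, p_value, n) suitable for
    :func:`vegcarry.memory_stats.sign_frequency_summary`.
    """
    rows = []
    for site_id, chron in chronologies.items():
        series = chron.index if isinstance(chron, Chronology) else pd.Series(chron)
        y = series.dropna().to_numpy(dtype=float)
        clim = (climate or {}).get(site_id)
        results = lagged_pacf(y, climate=clim, max_lead=max_lead)
        label = (groups or {}).get(site_id, "ungrouped")
        for res in results:
            rows.append((site_id, label, res.lead, res.r_p, res.p_value, res.n))
    if not rows:
        raise VegcarryError("no chronologies supplied")
    return pd.DataFrame(
        rows, columns=["site_id", "group", "lead", "r_p", "p_value", "n"]
    )


def porosity_frequency_table(vgc_table: pd.DataFrame, lead: int = 1) -> pd.DataFrame:
    """Sign/significance frequencies per porosity group at one lead."""
    sub = vgc_table[vgc_table["lead"] == lead]
    return sign_frequency_summary(sub, group_col="group")
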