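"""Dominant-driver classification and area-fraction summaries.

Each cell's interannual greenness variability is attributed to whichever
of three driver families associates with it most strongly: the
carryover of preceding-season growth (VGC), concurrent climate
(temperature or precipitation of the target season), or preceding-season
climate. The default score is the absolute partial correlation from the
seasonal profile; an alternative mode scores on absolute trend
contributions from the attribution step. Climate families collapse their
two members by the maximum |score| (switchable to root-sum-of-squares).

Area fractions of the three labels support observation-versus-model
comparisons: for each model's fraction set, the signed difference from
the observed fractions and the count of models under/over the observed
carryover-dominated share.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from vegcarry.core import VegcarryError
from vegcarry.memory_stats import VgcProfile

#: The three driver families, in tie-break priority order.
LABELS = ("vgc", "concurrent_climate", "preceding_climate")


@dataclass
class DriverLabel:
    label: str
    score: float
    tied: bool = False


def _family_scores(scores: dict, combine: str) -> dict:
    """Collapse the five per-driver scores into the three families."""
    def comb(a, b):
        if combine == "max":
            return max(a, b)
        if combine == "rss":
            return float(np.hypot(a, b))
        raise VegcarryError(f"unknown combine mode {combine!r}")

    return {
        "vgc": scores["ndvi_ps"],
        "concurrent_climate": comb(scores["tmp"], scores["pre"]),
        "preceding_climate": comb(scores["tmp_ps"], scores["pre_ps"]),
    }


def classify_dominant_driver(
    profile: VgcProfile | dict,
    combine: str = "max",
) -> DriverLabel:
    """Label a cell with its strongest driver family.

    Parameters
    ----------
    profile
        A :class:`~vegcarry.memory_stats.VgcProfile`, or a plain mapping
        of the five driver names to scores (e.g. |trend contributions|
        for the attribution-based mode).
    combine
        How the two members of each climate family merge: ``"max"``
        (default) or ``"rss"`` (root sum of squares).

    Ties go to the earlier family in priority order (vgc, concurrent,
    preceding) and are flagged. Any undefined score leaves the cell
    unlabeled (raises).
    """
    if isinstance(profile, VgcProfile):
        scores = {d: abs(r.r_p) for d, r in profile.results.items()}
    else:
        scores = {d: abs(float(v)) for d, v in profile.items()}
    if not all(np.isfinite(v) for v in scores.values()):
        raise VegcarryError("undefined score; cell unlabeled")
    fam = _family_scores(scores, combine)
    best = max(LABELS, key=lambda k: fam[k])
    tied = sum(1 for k in LABELS if fam[k] == fam[best]) > 1
    winner = next(k for k in LABELS if fam[k] == fam[best])  # priority order
    return DriverLabel(label=winner, score=fam[winner], tied=tied)


def classify_grid(
    profiles: pd.DataFrame,
    combine: str = "max",
) -> pd.DataFrame:
    """Classify every cell of a tidy per-cell profile table.

    ``profiles`` is the output of
    :func:`vegcarry.memory_stats.grid_vgc_profiles` (columns ``cell_id,
    driver, r_p``). Cells with any undefined driver stay unlabeled (NaN).
    """
    rows = []
    for cell_id, sub in profiles.groupby("cell_id", sort=False):
        scores = dict(zip(sub["driver"], sub["r_p"]))
        try:
            lab = classify_dominant_driver(scores, combine=combine)
            rows.append((cell_id, lab.label, lab.score, lab.tied))
        except VegcarryError:
            rows.append((cell_id, np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["cell_id", "label", "score", "tied"])


@dataclass
class TernaryFractions:
    """Area share per driver family over labeled cells (sums to 1)."""

    fractions: dict          # label -> fraction
    unlabeled_fraction: float = 0.0

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions).reindex(LABELS).fillna(0.0)


def area_fractions(
    labels: pd.DataFrame,
    weights: pd.Series | None = None,
) -> TernaryFractions:
    """Weighted share of each driver-family label.

    ``labels`` needs columns ``cell_id, label`` (NaN label = unlabeled).
    Fractions are normalized over labeled cells; the unlabeled weight
    share is reported separately.
    """
    df = labels.copy()
    if weights is None:
        df["w"] = 1.0
    else:
        df["w"] = df["cell_id"].map(weights)
        if df["w"].isna().any() or (df["w"] < 0).any():
            raise VegcarryError("missing or negative weight")
    labeled = df[df["label"].notna()]
    if len(labeled) == 0 or labeled["w"].sum() <= 0:
        raise VegcarryError("no labeled cells with positive weight")
    total = labeled["w"].sum()
    fractions = {
        lab: float(labeled.loc[labeled["label"] == lab, "w"].sum() / total)
        for lab in LABELS
    }
    unlabeled = float(df.loc[df["label"].isna(), "w"].sum() / df["w"].sum())
    return TernaryFractions(fractions=fractions, unlabeled_fraction=unlabeled)


def compare_fraction_sets(
    observed: TernaryFractions,
    models: dict,
) -> pd.DataFrame:
    """Compare modeled driver-dominance fractions against the observed set.

    Parameters
    ----------
    observed
        The observation-based fractions.
    models
        Mapping model name -> :class:`TernaryFractions` with the same
        label vocabulary.

    Returns a frame with one row per model (signed difference per label,
    and whether the model's carryover-dominated share falls below the
    observed one) plus an ``ensemble_mean`` row.
    """
    if not models:
        raise VegcarryError("no model fraction sets supplied")
    obs = observed.as_series()
    rows = []
    for name, frac in models.items():
        s = frac.as_series()
        if set(frac.fractions) - set(LABELS):
            raise VegcarryError(f"model {name}: unknown labels")
        rows.append({
            "model": name,
            **{f"{lab}": s[lab] for lab in LABELS},
            **{f"d_{lab}": s[lab] - obs[lab] for lab in LABELS},
            "under_vgc": bool(s["vgc"] < obs["vgc"]),
        })
    out = pd.DataFrame(rows)
    ens = out[[*LABELS]].mean()
    summary = {
        "model": "ensemble_mean",
        **{lab: ens[lab] for lab in LABELS},
        **{f"d_{lab}": ens[lab] - obs[lab] for lab in LABELS},
        "under_vgc": bool(ens["vgc"] < obs["vgc"]),
    }
    return pd.concat([out, pd.DataFrame([summary])], ignore_index=True)
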