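"""Dive classification, dive-shape metrics, activity budgets and PCA.

A dive is *benthic* when its maximum depth reaches within a margin
(default 25 m) of the charted bottom, or exceeds the charted bottom —
bathymetric charts in glacial fjords routinely read shallow, so "deeper
than the chart" is evidence of bottom contact, not of mid-water diving.
Both clauses reduce to the single inequality

    max_depth >= bathymetric_depth - margin .

The *bottom phase* of a dive is the time spent at or below 80% of the
maximum depth; descent is everything before the first bottom entry and
ascent everything after the last exit, so the three fractions always
partition the dive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "classify_dive", "dive_shape", "activity_budget", "monthly_pca",
    "ActivityBudget", "PcaResult", "BENTHIC_MARGIN_M",
]

BENTHIC_MARGIN_M = 25.0
BOTTOM_THRESHOLD = 0.8


def classify_dive(max_depth_m, bathy_depth_m, margin_m: float = BENTHIC_MARGIN_M):
    """Classify dive(s) as "benthic" or "pelagic" against the bathymetry.

    Vectorised; NaN bathymetry yields None (unclassifiable).
    """
    md = np.asarray(max_depth_m, float)
    bd = np.asarray(bathy_depth_m, float)
    if np.any(md[~np.isnan(md)] <= 0):
        raise ValueError("max depth must be positive")
    benthic = md >= bd - margin_m
    out = np.where(benthic, "benthic", "pelagic").astype(object)
    out = np.where(np.isnan(bd), None, out)
    if out.ndim == 0:
        return out[()]
    return out


def dive_shape(profile, bottom_threshold: float = BOTTOM_THRESHOLD):
    """(bottom, descent, ascent) time fractions from a depth profile.

    ``profile`` is an ordered list of (elapsed fraction in [0, 1], depth m)
    with surface start and end.  Crossing times of the bottom threshold
    (``bottom_threshold`` x max depth) are found by linear interpolation;
    the bottom phase runs from the first entry to the last exit, so brief
    excursions above the threshold mid-dive still count as bottom time.
    """
    pts = np.asarray(profile, float)
    if pts.ndim != 2 or pts.shape[0] < 4:
        raise ValueError("profile needs >= 4 (fraction, depth) points")
    t, z = pts[:, 0], pts[:, 1]
    if np.any(np.diff(t) < 0) or t[0] != 0.0 or abs(t[-1] - 1.0) > 1e-9:
        raise ValueError("profile fractions must increase from 0 to 1")
    zmax = z.max()
    if zmax <= 0:
        raise ValueError("profile never leaves the surface")
    level = bottom_threshold * zmax

    # first downward crossing and last upward crossing of the level
    below = z >= level
    first = None
    last = None
    for i in range(len(t)):
        if below[i]:
            if first is None:
                if i == 0:
                    first = t[0]
                else:
                    f = (level - z[i - 1]) / (z[i] - z[i - 1])
                    first = t[i - 1] + f * (t[i] - t[i - 1])
            last = t[i]
    # extend the last exit by interpolation past the final below-level point
    for i in range(len(t) - 1, 0, -1):
        if below[i - 1] and not below[i]:
            f = (z[i - 1] - level) / (z[i - 1] - z[i])
            last = max(last, t[i - 1] + f * (t[i] - t[i - 1]))
            break
    descent = first
    ascent = 1.0 - last
    bottom = last - first
    return float(bottom), float(descent), float(ascent)


@dataclass
class ActivityBudget:
    """Time-weighted activity percentages and haul-out statistics."""

    seal_id: str
    period: str                       # "all" or "YYYY-MM"
    pct_diving: float
    pct_surface: float
    pct_hauled: float
    haulout_durations_min: np.ndarray
    interhaulout_intervals_h: np.ndarray


def activity_budget(summaries: pd.DataFrame, haulouts: pd.DataFrame,
                    seal_id: str = "", by_month: bool = False):
    """Activity budget from 6-h summary records plus haul-out events.

    Percentages are time-weighted means of the summary periods; haul-out
    durations are per-event minutes, and intervals the gaps (h) between
    consecutive events of the same seal.  Returns one
    :class:`ActivityBudget` ("all") or a list per month.
    """
    if summaries.empty:
        raise ValueError("activity budget needs at least one summary period")
    h = haulouts.sort_values("start_time") if len(haulouts) else haulouts
    if len(h):
        starts = h["start_time"].values
        ends = h["end_time"].values
        if (starts[1:] < ends[:-1]).any():
            raise ValueError("overlapping haul-out events")
        durations = (ends - starts) / np.timedelta64(1, "m")
        gaps = (starts[1:] - ends[:-1]) / np.timedelta64(1, "h")
    else:
        durations = np.array([])
        gaps = np.array([])

    def _one(sub: pd.DataFrame, label: str) -> ActivityBudget:
        w = sub["period_hours"].values.astype(float)
        w = w / w.sum()
        if len(h) and label != "all":
            in_month = h["start_time"].dt.to_period("M").astype(str) == label
            dur = durations[in_month.values]
        else:
            dur = durations
        return ActivityBudget(
            seal_id=seal_id, period=label,
            pct_diving=float(np.sum(w * sub["pct_diving"].values)),
            pct_surface=float(np.sum(w * sub["pct_surface"].values)),
            pct_hauled=float(np.sum(w * sub["pct_hauled"].values)),
            haulout_durations_min=np.asarray(dur, float),
            interhaulout_intervals_h=np.asarray(gaps, float),
        )

    if not by_month:
        return _one(summaries, "all")
    return [
        _one(sub, str(period))
        for period, sub in summaries.groupby(
            summaries["period_start"].dt.to_period("M"))
    ]


@dataclass
class PcaResult:
    variables: list
    loadings: np.ndarray          # (n_vars, n_comp), orthonormal columns
    scores: np.ndarray            # (n_rows, n_comp)
    variance_fraction: np.ndarray
    row_index: pd.Index


def monthly_pca(table: pd.DataFrame) -> PcaResult:
    """PCA of a (seal-month x dive variables) table of monthly means.

    Variables are standardized; rows with missing cells are dropped;
    constant variables are dropped with a warning.  Loadings follow the
    sign convention that each component's largest-magnitude element is
    positive.
    """
    numeric = table.select_dtypes("number")
    clean = numeric.dropna(axis=0)
    keep = [c for c in clean.columns if clean[c].std(ddof=0) > 0]
    if len(keep) < len(clean.columns):
        import warnings
        dropped = sorted(set(clean.columns) - set(keep))
        warnings.warn(f"constant variable(s) dropped from PCA: {dropped}")
    clean = clean[keep]
    if clean.shape[0] < 3 or clean.shape[1] < 2:
        raise ValueError("PCA needs >= 3 complete rows and >= 2 variables")
    Z = (clean - clean.mean()) / clean.std(ddof=1)
    U, S, Vt = np.linalg.svd(Z.values, full_matrices=False)
    # sign convention: largest |loading| positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    var = S ** 2
    return PcaResult(
        variables=list(clean.columns),
        loadings=Vt.T,
        scores=U * S,
        variance_fraction=var / var.sum(),
        row_index=clean.index,
    )
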