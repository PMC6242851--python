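"""Core domain types for seal biologging datasets.

Observation streams (GPS fixes, dives, 6-h activity summaries, haul-out
events, CTD casts) are held as pandas DataFrames with documented column
schemas; the environment (bathymetry, coast and tidal-glacier-front
polylines, dated sea-ice fields) is a small dataclass of numpy arrays on a
shared planar grid.  Conventions used throughout the package:

* planar coordinates are kilometres in a local azimuthal-equidistant
  projection centred on the dataset; latitude/longitude live only in the
  raw streams,
* depths (dive depth and bathymetry alike) are metres, positive downward,
* timestamps are timezone-naive UTC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import datetime as _dt

import numpy as np
import pandas as pd

__all__ = [
    "SealMetadata",
    "EnvironmentStack",
    "IceField",
    "SealDataset",
    "ValidationError",
    "FIX_COLUMNS",
    "DIVE_COLUMNS",
    "SUMMARY_COLUMNS",
    "HAULOUT_COLUMNS",
    "CTD_COLUMNS",
    "validate_dataset",
]

#: required columns of each observation stream
FIX_COLUMNS = ["seal_id", "time", "lat", "lon", "source"]
DIVE_COLUMNS = [
    "seal_id", "start_time", "duration_min", "max_depth_m",
    "surface_duration_s", "profile", "lat", "lon",
]
SUMMARY_COLUMNS = [
    "seal_id", "period_start", "period_hours",
    "pct_diving", "pct_surface", "pct_hauled",
]
HAULOUT_COLUMNS = ["seal_id", "start_time", "end_time"]
CTD_COLUMNS = [
    "seal_id", "time", "lat", "lon", "depth_m", "temperature_c", "salinity_psu",
]


class ValidationError(ValueError):
    """A dataset violated one of the documented stream invariants."""


@dataclass
class SealMetadata:
    """Capture record for one instrumented seal."""

    id: str
    sex: str                       # "M" or "F"
    standard_length_cm: float
    girth_cm: float
    body_mass_kg: float
    tag_start: _dt.datetime
    tag_end: _dt.datetime
    start_lat: float
    start_lon: float

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"seal {self.id}: sex must be M or F, got {self.sex!r}")
        for name in ("standard_length_cm", "girth_cm", "body_mass_kg"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"seal {self.id}: {name} must be positive")
        if self.tag_end < self.tag_start:
            raise ValidationError(f"seal {self.id}: tag_end before tag_start")


@dataclass
class IceField:
    """One dated sea-ice state: concentration (%) plus a land-fast mask."""

    date: _dt.date
    concentration: np.ndarray      # (ny, nx), percent in [0, 100]
    landfast: np.ndarray           # (ny, nx) bool


@dataclass
class EnvironmentStack:
    """Static environment layers on one planar-km grid.

    ``bathymetry[j, i]`` is the water depth (m, positive down) at cell
    centre ``(x[i], y[j])``.  Polylines are lists of (N, 2) float arrays in
    the same planar km frame.
    """

    x: np.ndarray                  # (nx,) cell-centre x, km
    y: np.ndarray                  # (ny,) cell-centre y, km
    bathymetry: np.ndarray         # (ny, nx), m positive down
    coastline: list                # list of (N, 2) arrays, km
    glacier_fronts: list           # list of (N, 2) arrays, km
    ice_fields: list = field(default_factory=list)   # list[IceField], dated
    center_lat: float = 79.0       # projection origin
    center_lon: float = 12.0

    @property
    def cell_km(self) -> float:
        return float(self.x[1] - self.x[0])

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.bathymetry = np.asarray(self.bathymetry, float)
        if self.bathymetry.shape != (self.y.size, self.x.size):
            raise ValidationError("bathymetry shape does not match grid axes")
        if np.any(self.bathymetry < 0):
            raise ValidationError("bathymetry must be >= 0 (positive down)")
        if not self.glacier_fronts:
            raise ValidationError("environment needs at least one glacier front")
        for f in self.ice_fields:
            c = f.concentration
            if c.shape != self.bathymetry.shape:
                raise ValidationError("ice field shape does not match bathymetry")
            if np.any((c < 0) | (c > 100)):
                raise ValidationError("ice concentration outside [0, 100]")


@dataclass
class SealDataset:
    """All observation streams for a tagged population plus the environment."""

    metadata: list                 # list[SealMetadata]
    fixes: pd.DataFrame
    dives: pd.DataFrame
    summaries: pd.DataFrame
    haulouts: pd.DataFrame
    ctd: pd.DataFrame
    env: EnvironmentStack

    @property
    def seal_ids(self) -> list:
        return [m.id for m in self.metadata]

    def for_seal(self, seal_id: str):
        """Return the five per-seal streams filtered to one animal."""
        out = []
        for df in (self.fixes, self.dives, self.summaries, self.haulouts, self.ctd):
            out.append(df[df["seal_id"] == seal_id].reset_index(drop=True))
        return tuple(out)


def _require_columns(df: pd.DataFrame, cols, stream: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{stream}: missing mandatory column(s) {missing}")


def _check_sorted_unique(df, time_col, stream):
    """Sort per seal by time and drop duplicate timestamps (keep first)."""
    df = df.sort_values(["seal_id", time_col], kind="stable")
    dup = df.duplicated(["seal_id", time_col])
    n_dup = int(dup.sum())
    df = df[~dup].reset_index(drop=True)
    return df, ([f"{stream}: dropped {n_dup} duplicate timestamp(s)"] if n_dup else [])


def validate_dataset(ds: SealDataset, strict: bool = True) -> list:
    """Check all stream invariants; returns a list of warnings.

    Sorts streams in place (per seal, by time) and collapses duplicate
    timestamps keeping the first record.  Raises :class:`ValidationError`
    for hard violations; soft issues are returned as warning strings.
    """
    warnings: list = []

    ids = [m.id for m in ds.metadata]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate seal ids in metadata")

    _require_columns(ds.fixes, FIX_COLUMNS, "fixes")
    _require_columns(ds.dives, DIVE_COLUMNS, "dives")
    _require_columns(ds.summaries, SUMMARY_COLUMNS, "summaries")
    _require_columns(ds.haulouts, HAULOUT_COLUMNS, "haulouts")
    _require_columns(ds.ctd, CTD_COLUMNS, "ctd")

    ds.fixes, w = _check_sorted_unique(ds.fixes, "time", "fixes")
    warnings += w
    ds.dives, w = _check_sorted_unique(ds.dives, "start_time", "dives")
    warnings += w
    ds.summaries, w = _check_sorted_unique(ds.summaries, "period_start", "summaries")
    warnings += w

    f = ds.fixes
    if len(f):
        bad = f.index[(f["lat"].abs() > 90) | (f["lon"] <= -180) | (f["lon"] > 180)]
        if len(bad):
            raise ValidationError(f"fixes: coordinate out of range at record {bad[0]}")

    d = ds.dives
    if len(d):
        bad = d.index[(d["max_depth_m"] <= 0) | (d["duration_min"] <= 0)]
        if len(bad):
            raise ValidationError(f"dives: non-positive depth/duration at record {bad[0]}")
        for i, prof in d["profile"].items():
            if prof is None or len(prof) == 0:
                continue
            depths = np.asarray([p[1] for p in prof], float)
            md = d.at[i, "max_depth_m"]
            if depths.max() > md + 1e-6 or abs(depths.max() - md) > 0.5:
                raise ValidationError(
                    f"dives: profile max depth inconsistent with max_depth_m at record {i}")

    s = ds.summaries
    if len(s):
        for col in ("pct_diving", "pct_surface", "pct_hauled"):
            if ((s[col] < 0) | (s[col] > 100)).any():
                raise ValidationError(f"summaries: {col} outside [0, 100]")
        tot = s["pct_diving"] + s["pct_surface"] + s["pct_hauled"]
        if (np.abs(tot - 100.0) > 0.5).any():
            raise ValidationError("summaries: activity percentages do not sum to 100 +- 0.5")

    h = ds.haulouts
    if len(h):
        if (h["end_time"] <= h["start_time"]).any():
            raise ValidationError("haulouts: event with end <= start")
        for sid, grp in h.groupby("seal_id"):
            grp = grp.sort_values("start_time")
            if (grp["start_time"].values[1:] < grp["end_time"].values[:-1]).any():
                raise ValidationError(f"haulouts: overlapping events for seal {sid}")

    c = ds.ctd
    if len(c):
        if (c["salinity_psu"] < 0).any():
            raise ValidationError("ctd: negative salinity")
        for (sid, t), grp in c.groupby(["seal_id", "time"]):
            dz = np.diff(grp["depth_m"].values)
            if (dz <= 0).any():
                raise ValidationError(
                    f"ctd: profile depths not strictly increasing (seal {sid} at {t})")

    if strict:
        known = set(ids)
        for name in ("fixes", "dives", "summaries", "haulouts", "ctd"):
            df = getattr(ds, name)
            if len(df):
                unknown = set(df["seal_id"]) - known
                if unknown:
                    warnings.append(f"{name}: records for unknown seal(s) {sorted(unknown)}")
    return warnings
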