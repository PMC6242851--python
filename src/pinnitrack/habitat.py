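"""Habitat covariates and per-seal habitat-use statistics.

For every track location the module extracts distance to the nearest
coastline and tidal glacier front (km, planar), bilinear bathymetric depth
(m) and the sea-ice concentration/category of the nearest-dated ice field.
Monthly summaries are nonparametric bootstrap means with percentile
confidence intervals (10,000 replicates); seasonal trends are ordinary
least-squares regressions of each (optionally log-transformed) variable on
the day-of-tracking index; and the habitat most frequently used is
described by a three-dimensional product-Gaussian kernel density over
(distance to coast, distance to glacier, depth), thresholded at the top
quartile of evaluated density values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import skew
from shapely.geometry import LineString, MultiLineString, Point

from .datatypes import EnvironmentStack
from .geometry import bathymetry_at, ice_category

__all__ = [
    "BootstrapSummary", "TrendResult", "EnvSpaceUD",
    "distance_to_polylines", "extract_covariates",
    "bootstrap_mean_ci", "seasonal_trend", "env_space_ud",
]

BOOTSTRAP_REPS = 10_000


@dataclass
class BootstrapSummary:
    seal_id: str
    month: str
    variable: str
    mean: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class TrendResult:
    seal_id: str
    variable: str
    slope_per_day: float
    p_value: float
    transform: str            # "identity" or "log"
    n: int


@dataclass
class EnvSpaceUD:
    """3-D kernel density over environmental space with a top-quartile mask."""

    axes: tuple               # three 1-D grids: dist_coast, dist_glacier, depth
    density: np.ndarray       # (n, n, n)
    mask: np.ndarray          # density >= 75th percentile of evaluated values
    bandwidth: np.ndarray     # per-dimension


def _as_multiline(lines) -> MultiLineString:
    if isinstance(lines, (LineString, MultiLineString)):
        return lines if isinstance(lines, MultiLineString) else MultiLineString([lines])
    if len(lines) == 0:
        raise ValueError("empty polyline set")
    return MultiLineString([LineString(np.asarray(l, float)) for l in lines])


def distance_to_polylines(points, lines):
    """Minimum Euclidean distance (km) from point(s) to a polyline set."""
    ml = _as_multiline(lines)
    pts = np.atleast_2d(np.asarray(points, float))
    out = np.array([ml.distance(Point(p)) for p in pts])
    if np.ndim(points) == 1:
        return float(out[0])
    return out


def _nearest_ice_field(env: EnvironmentStack, when):
    if not env.ice_fields:
        return None
    when = pd.Timestamp(when).date()
    return min(env.ice_fields, key=lambda f: abs((f.date - when).days))


def extract_covariates(track: pd.DataFrame, env: EnvironmentStack) -> pd.DataFrame:
    """Per-location habitat covariates for a planar track.

    ``track`` needs x_km, y_km and (for ice matching) a time column.
    Locations outside the bathymetry grid are flagged ``missing=True`` and
    carry NaN covariates.
    """
    pts = track[["x_km", "y_km"]].values
    n = len(pts)
    dist_coast = distance_to_polylines(pts, env.coastline)
    dist_glacier = distance_to_polylines(pts, env.glacier_fronts)
    depth = np.full(n, np.nan)
    missing = np.zeros(n, bool)
    inside = (
        (pts[:, 0] >= env.x[0]) & (pts[:, 0] <= env.x[-1])
        & (pts[:, 1] >= env.y[0]) & (pts[:, 1] <= env.y[-1])
    )
    if inside.any():
        depth[inside] = bathymetry_at(env, pts[inside, 0], pts[inside, 1])
    missing[~inside] = True

    ice_conc = np.full(n, np.nan)
    ice_cat = np.empty(n, object)
    ice_cat[:] = None
    if env.ice_fields and "time" in track.columns:
        xi = np.clip(np.searchsorted(env.x, pts[:, 0]), 0, env.x.size - 1)
        yi = np.clip(np.searchsorted(env.y, pts[:, 1]), 0, env.y.size - 1)
        for when, idx in track.groupby(pd.to_datetime(track["time"]).dt.date).groups.items():
            fld = _nearest_ice_field(env, when)
            rows = track.index.get_indexer(idx)
            ice_conc[rows] = fld.concentration[yi[rows], xi[rows]]
            lf = fld.landfast[yi[rows], xi[rows]]
            ice_cat[rows] = ice_category(ice_conc[rows], lf)

    out = track.copy()
    out["dist_coast_km"] = dist_coast
    out["dist_glacier_km"] = dist_glacier
    out["depth_m"] = depth
    out["ice_concentration"] = ice_conc
    out["ice_category"] = ice_cat
    out["missing"] = missing
    return out


def bootstrap_mean_ci(values, reps: int = BOOTSTRAP_REPS, level: float = 0.95,
                      seed: int = 0, seal_id: str = "", month: str = "",
                      variable: str = "") -> BootstrapSummary:
    """Percentile bootstrap CI for the mean (deterministic under ``seed``)."""
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("bootstrap needs at least two observations")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(reps, v.size))
    means = v[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return BootstrapSummary(seal_id=seal_id, month=month, variable=variable,
                            mean=float(v.mean()), ci_low=float(lo),
                            ci_high=float(hi), n=int(v.size))


def seasonal_trend(values, day_index, seal_id: str = "", variable: str = "",
                   transform: str = "auto") -> TrendResult:
    """OLS trend of a variable on the day-of-tracking index.

    ``transform="auto"`` log-transforms strictly positive, right-skewed
    (skewness > 1) responses; the slope is reported on the fitted scale.
    """
    y = np.asarray(values, float)
    d = np.asarray(day_index, float)
    ok = ~(np.isnan(y) | np.isnan(d))
    y, d = y[ok], d[ok]
    if y.size < 10 or (d.max() - d.min()) < 30:
        raise ValueError("trend test needs >= 10 observations spanning >= 30 days")
    if np.ptp(d) == 0:
        raise ValueError("degenerate design: day index has zero variance")
    used = "identity"
    if transform == "log" or (
            transform == "auto" and np.all(y > 0) and skew(y) > 1.0):
        y = np.log(y)
        used = "log"
    X = sm.add_constant(d)
    res = sm.OLS(y, X).fit()
    return TrendResult(seal_id=seal_id, variable=variable,
                       slope_per_day=float(res.params[1]),
                       p_value=float(res.pvalues[1]),
                       transform=used, n=int(y.size))


def _silverman_bandwidth(x):
    n = x.size
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25])) / 1.349
    scale = min(sd, iqr) if iqr > 0 else sd
    # Silverman's plug-in for a 3-D product kernel
    return scale * (4.0 / (3 + 2)) ** (1.0 / (3 + 4)) * n ** (-1.0 / (3 + 4))


def env_space_ud(covariates: pd.DataFrame, grid_size: int = 32) -> EnvSpaceUD:
    """3-D kernel UD over (dist_coast, dist_glacier, depth).

    Product-Gaussian kernel with per-dimension Silverman bandwidths,
    evaluated on a ``grid_size``^3 lattice spanning the data range plus one
    bandwidth; the mask marks cells at or above the 75th percentile of
    evaluated density values ("top 25%" of the UD values).
    """
    cols = ["dist_coast_km", "dist_glacier_km", "depth_m"]
    data = covariates[cols].dropna().values
    if len(data) < 50:
        raise ValueError("environmental-space UD needs >= 50 complete locations")
    bw = np.empty(3)
    axes = []
    for j in range(3):
        col = data[:, j]
        if np.ptp(col) == 0:
            import warnings
            warnings.warn(f"covariate {cols[j]} has zero variance; axis collapsed")
            bw[j] = 1.0
            axes.append(np.array([col[0]]))
            continue
        bw[j] = max(_silverman_bandwidth(col), 1e-9)
        axes.append(np.linspace(col.min() - bw[j], col.max() + bw[j], grid_size))

    # product-Gaussian density evaluated dimension-wise then combined
    k0 = np.exp(-0.5 * ((axes[0][:, None] - data[:, 0]) / bw[0]) ** 2) / bw[0]
    k1 = np.exp(-0.5 * ((axes[1][:, None] - data[:, 1]) / bw[1]) ** 2) / bw[1]
    k2 = np.exp(-0.5 * ((axes[2][:, None] - data[:, 2]) / bw[2]) ** 2) / bw[2]
    dens = np.einsum("ai,bi,ci->abc", k0, k1, k2)
    dens /= len(data) * (2.0 * np.pi) ** 1.5
    thresh = np.percentile(dens, 75.0)
    return EnvSpaceUD(axes=tuple(axes), density=dens, mask=dens >= thresh,
                      bandwidth=bw)
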