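"""Planar projection, grid lookups and sea-ice categories.

All spatial analysis runs in a local azimuthal-equidistant projection
(spherical Earth, R = 6371 km) centred on the dataset: azimuths and
great-circle distances from the centre are preserved, which is the right
compromise for fjord-scale (tens of km) telemetry where the quantities of
interest are metric distances and 500-m grid cells.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .datatypes import EnvironmentStack

EARTH_RADIUS_KM = 6371.0

ICE_CATEGORIES = ("<=10", "10-40", "40-90", ">90", "landfast")

__all__ = [
    "project_to_plane",
    "plane_to_lonlat",
    "bathymetry_at",
    "ice_category",
    "ICE_CATEGORIES",
]


def project_to_plane(lat, lon, center_lat, center_lon):
    """Forward azimuthal-equidistant projection, degrees -> planar km.

    Returns ``(x, y)`` with x east and y north of the centre.  Exact for a
    spherical Earth; vectorised over arrays.
    """
    lat = np.radians(np.asarray(lat, float))
    lon = np.radians(np.asarray(lon, float))
    lat0 = np.radians(center_lat)
    lon0 = np.radians(center_lon)
    dlon = lon - lon0
    cos_c = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(dlon)
    cos_c = np.clip(cos_c, -1.0, 1.0)
    c = np.arccos(cos_c)
    # k = c / sin(c), with the removable singularity at c = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(dlon)
    y = EARTH_RADIUS_KM * k * (
        np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(dlon)
    )
    return x, y


def plane_to_lonlat(x, y, center_lat, center_lon):
    """Inverse azimuthal-equidistant projection, planar km -> (lat, lon) degrees."""
    x = np.asarray(x, float) / EARTH_RADIUS_KM
    y = np.asarray(y, float) / EARTH_RADIUS_KM
    lat0 = np.radians(center_lat)
    lon0 = np.radians(center_lon)
    c = np.hypot(x, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        sin_c = np.sin(c)
        cos_c = np.cos(c)
        safe_c = np.where(c > 1e-12, c, 1.0)
        lat = np.arcsin(
            np.where(
                c > 1e-12,
                cos_c * np.sin(lat0) + y * sin_c * np.cos(lat0) / safe_c,
                np.sin(lat0),
            )
        )
        lon = lon0 + np.arctan2(
            x * sin_c, safe_c * np.cos(lat0) * cos_c - y * np.sin(lat0) * sin_c
        )
    return np.degrees(lat), np.degrees(lon)


def _interpolator(env: EnvironmentStack) -> RegularGridInterpolator:
    # cached per environment instance
    interp = getattr(env, "_bathy_interp", None)
    if interp is None:
        interp = RegularGridInterpolator(
            (env.y, env.x), env.bathymetry, method="linear", bounds_error=True
        )
        env._bathy_interp = interp
    return interp


def bathymetry_at(env: EnvironmentStack, x, y):
    """Bilinear bathymetric depth (m, positive down) at planar km point(s).

    Exact at cell centres and on any affine depth surface.  Raises
    ``ValueError`` for queries outside the grid extent; never extrapolates.
    """
    pts = np.column_stack([np.atleast_1d(np.asarray(y, float)),
                           np.atleast_1d(np.asarray(x, float))])
    out = _interpolator(env)(pts)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out[0])
    return out


def ice_category(concentration, landfast=False):
    """Bin sea-ice concentration (%) into the reporting categories.

    Bins are half-open above 10: [0, 10], (10, 40], (40, 90], (90, 100];
    a set land-fast flag dominates the concentration.  Vectorised; returns
    a string for scalar input, an object array otherwise.
    """
    conc = np.asarray(concentration, float)
    if np.any((conc < 0) | (conc > 100)):
        raise ValueError("ice concentration outside [0, 100]")
    lf = np.broadcast_to(np.asarray(landfast, bool), conc.shape)
    cat = np.empty(conc.shape, dtype=object)
    cat[...] = "<=10"
    cat[conc > 10] = "10-40"
    cat[conc > 40] = "40-90"
    cat[conc > 90] = ">90"
    cat[lf] = "landfast"
    if cat.ndim == 0:
        return str(cat[()])
    return cat
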