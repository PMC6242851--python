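"""Water-mass assignment for dives from seal-borne CTD profiles.

Temperature and salinity are assigned to the surface (1.5 m) and maximum
depth of each dive by a three-way weighted average over nearby CTD
profiles: each candidate profile is interpolated in depth to the target,
then weighted by Gaussian kernels in time gap, horizontal distance and
depth gap, and the K highest-weight profiles are averaged.  The resulting
(T, S) pairs are classified into the six regional water-mass classes of
the west-Svalbard fjord system:

    WCW      winter-cooled water        T < -0.5            any S
    LW       local water                -0.5 <= T < 1       any S
    GW       modified glacial water     T >= 1              S < 34
    IntW     intermediate water         T >= 1              34 <= S < 34.65
    TransAW  transformed Atlantic       1 <= T < 3          S >= 34.65
    AW       Atlantic water             T >= 3              S >= 34.65

These boxes partition the finite (T, S) plane: every pair maps to exactly
one class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WATER_MASS_CLASSES", "WeightParams", "DiveWaterMass",
    "classify_water_mass", "assign_ts", "assign_dataset", "same_mass_fraction",
]

WATER_MASS_CLASSES = ("WCW", "LW", "GW", "IntW", "TransAW", "AW")

SURFACE_DEPTH_M = 1.5


@dataclass(frozen=True)
class WeightParams:
    """Kernel scales of the three-way weighted average."""

    tau_h: float = 48.0       # time scale
    rho_km: float = 25.0      # horizontal distance scale
    zeta_m: float = 10.0      # depth-extrapolation scale
    k_profiles: int = 10      # number of highest-weight profiles averaged
    window_days: float = 10.0 # candidate profiles within this time gap


@dataclass
class DiveWaterMass:
    dive_index: int
    surface_t: float
    surface_s: float
    surface_class: str
    bottom_t: float
    bottom_s: float
    bottom_class: str
    same_class: bool
    total_weight: float


def classify_water_mass(temperature_c, salinity_psu):
    """Water-mass class for finite (T, S); vectorised."""
    T = np.asarray(temperature_c, float)
    S = np.asarray(salinity_psu, float)
    if not (np.all(np.isfinite(T)) and np.all(np.isfinite(S))):
        raise ValueError("non-finite temperature or salinity")
    if np.any(S < 0):
        raise ValueError("negative salinity")
    out = np.empty(T.shape, dtype=object)
    out[...] = "AW"
    # evaluated coldest-first; every pair matches exactly one box
    out[np.broadcast_to(T < 3.0, T.shape)] = "TransAW"
    out[np.broadcast_to((T >= 1.0) & (S < 34.65), T.shape)] = "IntW"
    out[np.broadcast_to((T >= 1.0) & (S < 34.0), T.shape)] = "GW"
    out[np.broadcast_to(T < 1.0, T.shape)] = "LW"
    out[np.broadcast_to(T < -0.5, T.shape)] = "WCW"
    if out.ndim == 0:
        return str(out[()])
    return out


def _interp_profile(depths, values, z, zeta_m):
    """Linear interpolation in depth; shallow extrapolation uses the deepest
    sample and reports the gap (None when the gap exceeds 3 zeta)."""
    if z <= depths[-1]:
        dz = 0.0
        v = np.interp(z, depths, values)
    else:
        dz = z - depths[-1]
        if dz > 3.0 * zeta_m:
            return None, None
        v = values[-1]
    return float(v), float(dz)


def assign_ts(dive_row, profiles: pd.DataFrame,
              params: WeightParams = WeightParams()):
    """Assign (T, S, class) at the surface and maximum depth of one dive.

    ``dive_row`` needs start_time, max_depth_m, x_km, y_km;  ``profiles``
    is a long-format CTD table with time, x_km, y_km, depth_m,
    temperature_c, salinity_psu (typically one seal's casts).  Returns a
    :class:`DiveWaterMass` or None when no profile is eligible.
    """
    t_dive = pd.Timestamp(dive_row["start_time"])
    window = pd.Timedelta(days=params.window_days)
    cand = profiles[(profiles["time"] >= t_dive - window)
                    & (profiles["time"] <= t_dive + window)]
    if cand.empty:
        return None

    results = {}
    for z_target, tag in ((SURFACE_DEPTH_M, "surface"),
                          (float(dive_row["max_depth_m"]), "bottom")):
        entries = []
        for when, grp in cand.groupby("time"):
            grp = grp.sort_values("depth_m")
            depths = grp["depth_m"].values
            tvals = grp["temperature_c"].values
            svals = grp["salinity_psu"].values
            t_i, dz = _interp_profile(depths, tvals, z_target, params.zeta_m)
            if t_i is None:
                continue
            s_i, _ = _interp_profile(depths, svals, z_target, params.zeta_m)
            dt_h = abs((when - t_dive).total_seconds()) / 3600.0
            dx = np.hypot(grp["x_km"].iloc[0] - dive_row["x_km"],
                          grp["y_km"].iloc[0] - dive_row["y_km"])
            w = (np.exp(-dt_h ** 2 / (2.0 * params.tau_h ** 2))
                 * np.exp(-dx ** 2 / (2.0 * params.rho_km ** 2))
                 * np.exp(-dz ** 2 / (2.0 * params.zeta_m ** 2)))
            entries.append((w, t_i, s_i))
        if not entries:
            return None
        entries.sort(key=lambda e: -e[0])
        top = entries[: params.k_profiles]
        wsum = sum(e[0] for e in top)
        if wsum <= 0:
            return None
        T = sum(e[0] * e[1] for e in top) / wsum
        S = sum(e[0] * e[2] for e in top) / wsum
        results[tag] = (T, S, classify_water_mass(T, S), wsum)

    st, ss, scl, w1 = results["surface"]
    bt, bs, bcl, w2 = results["bottom"]
    return DiveWaterMass(
        dive_index=int(dive_row.name) if dive_row.name is not None else -1,
        surface_t=st, surface_s=ss, surface_class=scl,
        bottom_t=bt, bottom_s=bs, bottom_class=bcl,
        same_class=scl == bcl, total_weight=float(w1 + w2),
    )


def assign_dataset(dives: pd.DataFrame, profiles: pd.DataFrame,
                   params: WeightParams = WeightParams()) -> pd.DataFrame:
    """Batch assignment over a dive table (same semantics as
    :func:`assign_ts` per dive); unassignable dives are dropped.

    Profiles are pre-grouped once, so this is the route for whole-seal
    tables.
    """
    casts = []
    for when, grp in profiles.groupby("time"):
        grp = grp.sort_values("depth_m")
        casts.append((pd.Timestamp(when), float(grp["x_km"].iloc[0]),
                      float(grp["y_km"].iloc[0]), grp["depth_m"].values,
                      grp["temperature_c"].values, grp["salinity_psu"].values))
    casts.sort(key=lambda c: c[0])
    cast_times = np.array([c[0].value for c in casts], dtype=np.int64)
    window_ns = np.int64(params.window_days * 86400 * 1e9)

    rows = []
    for idx, dive in dives.iterrows():
        t_dive = pd.Timestamp(dive["start_time"]).value
        lo = np.searchsorted(cast_times, t_dive - window_ns, side="left")
        hi = np.searchsorted(cast_times, t_dive + window_ns, side="right")
        if lo >= hi:
            continue
        ok = True
        results = {}
        for z_target, tag in ((SURFACE_DEPTH_M, "surface"),
                              (float(dive["max_depth_m"]), "bottom")):
            entries = []
            for c in casts[lo:hi]:
                when, cx, cy, depths, tvals, svals = c
                t_i, dz = _interp_profile(depths, tvals, z_target, params.zeta_m)
                if t_i is None:
                    continue
                s_i, _ = _interp_profile(depths, svals, z_target, params.zeta_m)
                dt_h = abs(when.value - t_dive) / 3.6e12
                dx = np.hypot(cx - dive["x_km"], cy - dive["y_km"])
                w = (np.exp(-dt_h ** 2 / (2.0 * params.tau_h ** 2))
                     * np.exp(-dx ** 2 / (2.0 * params.rho_km ** 2))
                     * np.exp(-dz ** 2 / (2.0 * params.zeta_m ** 2)))
                entries.append((w, t_i, s_i))
            if not entries:
                ok = False
                break
            entries.sort(key=lambda e: -e[0])
            top = entries[: params.k_profiles]
            wsum = sum(e[0] for e in top)
            if wsum <= 0:
                ok = False
                break
            T = sum(e[0] * e[1] for e in top) / wsum
            S = sum(e[0] * e[2] for e in top) / wsum
            results[tag] = (T, S, classify_water_mass(T, S), wsum)
        if not ok:
            continue
        st, ss, scl, w1 = results["surface"]
        bt, bs, bcl, w2 = results["bottom"]
        rows.append({
            "dive_index": idx,
            "surface_t": st, "surface_s": ss, "surface_class": scl,
            "bottom_t": bt, "bottom_s": bs, "bottom_class": bcl,
            "same_class": scl == bcl, "total_weight": w1 + w2,
        })
    return pd.DataFrame(rows, columns=[
        "dive_index", "surface_t", "surface_s", "surface_class",
        "bottom_t", "bottom_s", "bottom_class", "same_class", "total_weight"])


def same_mass_fraction(assigned: pd.DataFrame) -> float:
    """Percent of assigned dives with identical surface and bottom class."""
    if assigned.empty:
        raise ValueError("no assigned dives")
    return float(100.0 * assigned["same_class"].mean())
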