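"""Seeded generator of fjord environments and seal biologging datasets.

The generator emulates the statistical structure the downstream pipeline
assumes, at the tag's observed data rates (about 15 GPS fixes, 18 dives and
2 CTD casts per seal-day):

* a fjord-like environment: a wiggly north-south coastline with a shallow
  shore shelf, bathymetry deepening monotonically offshore, two tidal
  glacier fronts on the coast, and monthly sea-ice fields with a winter
  maximum plus a near-shore land-fast band;
* per-seal 3-state semi-Markov movement (travelling / foraging / hauled
  out) with state-specific gamma step lengths and von Mises headings;
  foraging bouts are attracted to bout targets drawn around the seal's
  habitat preference centre (distance to glacier front along the coast,
  preferred bottom depth), with a per-seal spread that makes the animal a
  habitat specialist (small spread) or generalist (large spread);
* benthic/pelagic dive mixtures tied to the local bathymetry, U/V-shaped
  depth profiles, 6-h activity summaries consistent with the state
  sequence, haul-out events, and two-layer seasonal CTD profiles whose
  layer properties traverse all six regional water-mass classes over the
  year.

All randomness flows from one ``numpy`` PCG64 generator per seal, derived
from the master seed via ``SeedSequence``, so datasets are reproducible
across platforms.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import EnvironmentStack, IceField, SealDataset, SealMetadata
from .geometry import plane_to_lonlat
from .morphometrics import estimate_body_mass

__all__ = [
    "SealProfile", "SimConfig", "water_column_ts",
    "simulate_environment", "simulate_seal", "simulate_population",
    "STATE_TRAVEL", "STATE_FORAGE", "STATE_HAULOUT", "STATE_NAMES",
]

STATE_TRAVEL, STATE_FORAGE, STATE_HAULOUT = 0, 1, 2
STATE_NAMES = ("travelling", "foraging", "haulout")

GPS_ERROR_KM = 0.036     # nominal GPS accuracy, 36 m


class GenerationError(RuntimeError):
    pass


@dataclass
class SealProfile:
    """Behavioural parameters of one simulated seal."""

    id: str
    sex: str = "F"
    # habitat preference: distance (km) of foraging targets from the home
    # glacier front measured along the coast, and preferred bottom depth (m)
    pref_glacier_km: float = 8.0
    pref_depth_m: float = 40.0
    spread_glacier_km: float = 1.0    # small -> specialist, large -> generalist
    spread_depth_m: float = 8.0
    home_glacier: int = 0             # index into env.glacier_fronts
    # semi-Markov dwell means, hours, per (travel, forage, haulout)
    dwell_means_h: tuple = (8.0, 36.0, 6.0)
    benthic_fraction: float = 0.8
    # per-state hourly step length gamma (mean, sd) in km
    step_mean_km: tuple = (2.0, 0.35, 0.0)
    step_sd_km: tuple = (0.9, 0.25, 0.0)
    turn_concentration: tuple = (4.0, 1.5, 0.0)

    def __post_init__(self):
        if not 0.0 <= self.benthic_fraction <= 1.0:
            raise ValueError("benthic_fraction must be in [0, 1]")
        if self.spread_glacier_km <= 0 or self.spread_depth_m <= 0:
            raise ValueError("preference spreads must be positive")
        if any(d < 0 for d in self.dwell_means_h):
            raise ValueError("dwell means must be >= 0")


@dataclass
class SimConfig:
    """Population- and environment-level simulation settings."""

    n_seals: int = 4
    duration_days: int = 60
    fix_rate_per_day: float = 15.0
    dive_rate_per_day: float = 18.0
    ctd_rate_per_day: float = 2.0
    seed: int = 0
    start_date: _dt.datetime = field(
        default_factory=lambda: _dt.datetime(2011, 7, 19))
    # environment shape
    cell_km: float = 0.5
    x_range_km: tuple = (-4.0, 60.0)
    y_range_km: tuple = (-44.0, 44.0)
    depth_slope_m_per_km: float = 6.0
    shore_shelf_km: float = 0.3
    glacier_y_km: tuple = (25.0, -20.0)
    center_lat: float = 79.0
    center_lon: float = 12.0
    # specialist / generalist spreads used by simulate_population
    specialist_spread_km: float = 0.6
    generalist_spread_km: float = 9.0

    def __post_init__(self):
        for name in ("fix_rate_per_day", "dive_rate_per_day", "ctd_rate_per_day"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.x_range_km[1] - self.x_range_km[0] < 10 * self.cell_km \
                or self.y_range_km[1] - self.y_range_km[0] < 10 * self.cell_km:
            raise ValueError("degenerate environment extent")


# ------------------------------------------------------------ environment

def _coast_x(y, config: SimConfig):
    """Coastline x-position (km) as a smooth function of the along-shore y."""
    return 0.8 * np.sin(np.asarray(y, float) / 9.0)


def _depth_m(x, y, config: SimConfig):
    """Analytic bathymetry: shore shelf then a monotone offshore ramp."""
    off = np.asarray(x, float) - _coast_x(y, config) - config.shore_shelf_km
    relief = 1.0 + 0.15 * np.sin(np.asarray(y, float) / 7.0)
    return np.maximum(0.0, off) * config.depth_slope_m_per_km * relief


def _ice_concentration(month: int) -> float:
    """Seasonal peak ice concentration (%), maximal in late winter."""
    # phase such that Feb-Mar peak, Jul-Aug minimum
    return 50.0 * (1.0 + np.cos(2.0 * np.pi * (month - 2.5) / 12.0))


def simulate_environment(config: SimConfig, seed=None) -> EnvironmentStack:
    """Build the fjord environment for a configuration (deterministic given
    config and seed; the seed only perturbs the ice fields slightly)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    x = np.arange(config.x_range_km[0] + config.cell_km / 2,
                  config.x_range_km[1], config.cell_km)
    y = np.arange(config.y_range_km[0] + config.cell_km / 2,
                  config.y_range_km[1], config.cell_km)
    xx, yy = np.meshgrid(x, y)
    bathy = _depth_m(xx, yy, config)

    coast_y = np.linspace(y[0], y[-1], 200)
    coastline = [np.column_stack([_coast_x(coast_y, config), coast_y])]
    fronts = []
    for gy in config.glacier_y_km:
        fy = np.linspace(gy - 1.5, gy + 1.5, 7)
        fronts.append(np.column_stack([_coast_x(fy, config), fy]))

    ice_fields = []
    date = config.start_date.date().replace(day=15)
    n_months = int(np.ceil(config.duration_days / 30.0)) + 1
    for k in range(n_months):
        month = (date.month - 1 + k) % 12 + 1
        year = date.year + (date.month - 1 + k) // 12
        peak = _ice_concentration(month)
        coastward = np.clip(1.0 - (xx - _coast_x(yy, config)) / 70.0, 0.0, 1.0)
        conc = np.clip(peak * coastward + rng.normal(0.0, 1.0, xx.shape), 0.0, 100.0)
        landfast = (peak > 60.0) & ((xx - _coast_x(yy, config)) < 2.0) & (bathy > 0)
        ice_fields.append(IceField(date=_dt.date(year, month, 15),
                                   concentration=conc, landfast=landfast))

    return EnvironmentStack(
        x=x, y=y, bathymetry=bathy, coastline=coastline, glacier_fronts=fronts,
        ice_fields=ice_fields,
        center_lat=config.center_lat, center_lon=config.center_lon,
    )


# ----------------------------------------------------------- water column

# calendar month -> ((surface T, surface S), (deep T, deep S)); the layer
# properties traverse all six regional water-mass boxes over the year:
# modified Glacial and Intermediate Water in summer, Atlantic Water at depth
# in autumn, Local / Transformed Atlantic Water in early winter, and
# Winter-Cooled Water at the surface in late winter.
_SEASON_TS = {
    1: ((0.0, 34.2), (2.0, 34.8)),    # LW over TransAW
    2: ((-1.2, 34.4), (2.0, 34.8)),   # WCW over TransAW
    3: ((-1.2, 34.4), (2.0, 34.8)),
    4: ((-0.8, 34.3), (3.2, 34.8)),   # WCW over AW
    5: ((-0.5, 34.2), (3.2, 34.8)),   # LW over AW
    6: ((0.5, 34.0), (3.2, 34.8)),
    7: ((2.5, 33.3), (1.5, 34.3)),    # GW over IntW
    8: ((2.8, 33.2), (1.5, 34.3)),
    9: ((2.5, 33.4), (1.6, 34.3)),
    10: ((1.2, 34.2), (3.5, 34.9)),   # IntW over AW
    11: ((0.3, 34.1), (3.5, 34.9)),   # LW over AW
    12: ((0.0, 34.2), (2.0, 34.8)),
}

PYCNOCLINE_M = 40.0
PYCNOCLINE_WIDTH_M = 8.0


def water_column_ts(month: int, depth_m):
    """Two-layer seasonal temperature/salinity at a given month and depth.

    Returns ``(T, S)``; smooth tanh transition across the pycnocline.
    """
    (t0, s0), (t1, s1) = _SEASON_TS[int(month)]
    z = np.asarray(depth_m, float)
    w = 0.5 * (1.0 + np.tanh((z - PYCNOCLINE_M) / PYCNOCLINE_WIDTH_M))
    return t0 + (t1 - t0) * w, s0 + (s1 - s0) * w


# ------------------------------------------------------------- seal track

def _sample_state_sequence(profile: SealProfile, n_hours: int, rng):
    """Semi-Markov state sequence on an hourly grid (exponential dwells)."""
    travel_h, forage_h, haul_h = profile.dwell_means_h
    allow_haul = haul_h > 0
    seq = np.empty(n_hours, dtype=np.int64)
    state = STATE_FORAGE
    t = 0
    while t < n_hours:
        mean = profile.dwell_means_h[state]
        dwell = max(1, int(round(rng.exponential(mean if mean > 0 else 1.0))))
        seq[t:t + dwell] = state
        t += dwell
        u = rng.random()
        if state == STATE_TRAVEL:
            state = STATE_FORAGE if (u < 0.8 or not allow_haul) else STATE_HAULOUT
        elif state == STATE_FORAGE:
            state = STATE_TRAVEL if (u < 0.6 or not allow_haul) else STATE_HAULOUT
        else:
            state = STATE_FORAGE if u < 0.7 else STATE_TRAVEL
    return seq


def _glacier_anchor(env: EnvironmentStack, profile: SealProfile):
    front = env.glacier_fronts[profile.home_glacier % len(env.glacier_fronts)]
    return front[len(front) // 2]


def _bout_target(profile: SealProfile, env, config: SimConfig, rng):
    """Draw one foraging-bout target in environmental space and map it to a
    planar point: an along-coast offset from the home glacier plus the
    offshore offset that realises the preferred bottom depth."""
    gx, gy = _glacier_anchor(env, profile)
    d_g = rng.normal(profile.pref_glacier_km, profile.spread_glacier_km)
    side = 1.0 if profile.pref_glacier_km + d_g >= 0 else -1.0
    y_t = gy + np.sign(d_g if d_g != 0 else 1.0) * abs(d_g) * side
    y_t = float(np.clip(y_t, config.y_range_km[0] + 2, config.y_range_km[1] - 2))
    depth_t = max(5.0, rng.normal(profile.pref_depth_m, profile.spread_depth_m))
    relief = 1.0 + 0.15 * np.sin(y_t / 7.0)
    off = config.shore_shelf_km + depth_t / (config.depth_slope_m_per_km * relief)
    x_t = float(np.clip(_coast_x(y_t, config) + off,
                        config.x_range_km[0] + 1, config.x_range_km[1] - 2))
    return np.array([x_t, y_t]), d_g, depth_t


def _simulate_track(profile, env, config: SimConfig, rng):
    """Hourly positions + states; returns (times_h, xy, states, targets)."""
    n_hours = config.duration_days * 24
    states = _sample_state_sequence(profile, n_hours, rng)
    xy = np.empty((n_hours, 2))
    pos, _, _ = _bout_target(profile, env, config, rng)
    heading = rng.uniform(-np.pi, np.pi)
    target = pos.copy()
    targets = []

    def on_sea(p):
        return (config.x_range_km[0] + 0.5 < p[0] < config.x_range_km[1] - 0.5
                and config.y_range_km[0] + 0.5 < p[1] < config.y_range_km[1] - 0.5
                and _depth_m(p[0], p[1], config) > 1.0)

    if not on_sea(pos):
        raise GenerationError(
            f"seal {profile.id}: preference centre unreachable in environment")

    for t in range(n_hours):
        s = states[t]
        if t > 0 and s == STATE_FORAGE and states[t - 1] != STATE_FORAGE:
            target, d_g, depth_t = _bout_target(profile, env, config, rng)
            targets.append((t, target[0], target[1], d_g, depth_t))
        if s == STATE_HAULOUT:
            xy[t] = pos
            continue
        mean, sd = profile.step_mean_km[s], profile.step_sd_km[s]
        shape = (mean / sd) ** 2
        scale = sd ** 2 / mean
        for _attempt in range(25):
            step = rng.gamma(shape, scale)
            if s == STATE_TRAVEL:
                cand_heading = heading + rng.vonmises(0.0, profile.turn_concentration[s])
            else:
                delta = target - pos
                dist = np.hypot(*delta)
                if dist > 1.0:
                    cand_heading = (np.arctan2(delta[1], delta[0])
                                    + rng.vonmises(0.0, profile.turn_concentration[s]))
                    step = min(step * 3.0, 0.6 * dist + step)
                else:
                    cand_heading = rng.uniform(-np.pi, np.pi)
            cand = pos + step * np.array([np.cos(cand_heading), np.sin(cand_heading)])
            if on_sea(cand):
                pos, heading = cand, cand_heading
                break
        xy[t] = pos

    times_h = np.arange(n_hours, dtype=float)
    return times_h, xy, states, targets


# ----------------------------------------------------------- observations

def _interp_track(times_h, xy, t):
    x = np.interp(t, times_h, xy[:, 0])
    y = np.interp(t, times_h, xy[:, 1])
    return x, y


def _make_profile_points(max_depth, bottom_frac, rng):
    """Dive depth profile as (elapsed fraction, depth) points; the maximum
    profile depth equals max_depth exactly."""
    td = (1.0 - bottom_frac) * 0.55     # descent end
    ta = td + bottom_frac               # ascent start
    pts = [
        (0.0, 0.0),
        (td / 2.0, 0.55 * max_depth),
        (td, max_depth),
        ((td + ta) / 2.0, (0.86 + 0.1 * rng.random()) * max_depth),
        (ta, 0.97 * max_depth),
        (1.0 - (1.0 - ta) / 2.0, 0.5 * max_depth),
        (1.0, 0.0),
    ]
    return [(round(f, 4), round(d, 2)) for f, d in pts]


def simulate_seal(profile: SealProfile, env: EnvironmentStack,
                  config: SimConfig, seed):
    """Simulate all observation streams for one seal.

    Returns ``(streams, truth)`` where ``streams`` is a dict of DataFrames
    (fixes, dives, summaries, haulouts, ctd) and ``truth`` holds the hidden
    quantities used by tests: hourly states and positions, foraging-bout
    targets, and per-dive benthic labels.
    """
    rng = np.random.default_rng(seed)
    t0 = config.start_date
    times_h, xy, states, targets = _simulate_track(profile, env, config, rng)
    n_hours = times_h.size

    def to_latlon(x, y):
        return plane_to_lonlat(x, y, env.center_lat, env.center_lon)

    # --- GPS fixes
    fix_times = []
    for day in range(config.duration_days):
        n = rng.poisson(config.fix_rate_per_day)
        fix_times.extend(day * 24.0 + np.sort(rng.uniform(0.0, 24.0, n)))
    fix_times = np.asarray(sorted(set(np.round(fix_times, 4))))
    fx, fy = _interp_track(times_h, xy, fix_times)
    fx = fx + rng.normal(0.0, GPS_ERROR_KM, fx.size)
    fy = fy + rng.normal(0.0, GPS_ERROR_KM, fy.size)
    lat, lon = to_latlon(fx, fy)
    fixes = pd.DataFrame({
        "seal_id": profile.id,
        "time": [t0 + _dt.timedelta(hours=float(h)) for h in fix_times],
        "lat": lat, "lon": lon, "source": "gps",
    })

    # --- haul-out events from state runs
    events = []
    in_haul = False
    for t in range(n_hours + 1):
        s = states[t] if t < n_hours else -1
        if s == STATE_HAULOUT and not in_haul:
            start = t
            in_haul = True
        elif s != STATE_HAULOUT and in_haul:
            events.append((start, t))
            in_haul = False
    haulouts = pd.DataFrame({
        "seal_id": profile.id,
        "start_time": [t0 + _dt.timedelta(hours=a) for a, _ in events],
        "end_time": [t0 + _dt.timedelta(hours=b) for _, b in events],
    })

    # --- dives
    dive_rows, benthic_truth = [], []
    hourly_rate = config.dive_rate_per_day / 24.0
    for t in range(n_hours):
        if states[t] == STATE_HAULOUT:
            continue
        for _ in range(rng.poisson(hourly_rate)):
            off = rng.uniform(0.0, 1.0)
            dx, dy = _interp_track(times_h, xy, t + off)
            bathy = float(_depth_m(dx, dy, config))
            if bathy < 3.0:
                continue
            benthic = rng.random() < profile.benthic_fraction
            if not benthic and bathy - 30.0 <= 3.0:
                benthic = True          # too shallow for a clear pelagic dive
            if benthic:
                if rng.random() < 0.2:
                    max_depth = bathy + rng.uniform(0.0, 10.0)
                else:
                    max_depth = max(1.0, bathy - rng.uniform(0.0, 15.0))
                bottom = rng.uniform(0.45, 0.75)
            else:
                max_depth = rng.uniform(3.0, bathy - 30.0)
                bottom = rng.uniform(0.08, 0.25)
            duration = float(np.clip(rng.normal(6.6, 1.5), 1.0, 24.0))
            dlat, dlon = to_latlon(dx, dy)
            dive_rows.append({
                "seal_id": profile.id,
                "start_time": t0 + _dt.timedelta(hours=t + off),
                "duration_min": duration,
                "max_depth_m": round(max_depth, 2),
                "surface_duration_s": float(np.clip(rng.normal(90.0, 20.0), 20.0, 300.0)),
                "profile": _make_profile_points(round(max_depth, 2), bottom, rng),
                "lat": float(dlat), "lon": float(dlon),
            })
            benthic_truth.append(benthic)
    dives = pd.DataFrame(dive_rows) if dive_rows else pd.DataFrame(
        {c: pd.Series(dtype=object) for c in
         ["seal_id", "start_time", "duration_min", "max_depth_m",
          "surface_duration_s", "profile", "lat", "lon"]})
    if len(dives):
        dives = dives.sort_values("start_time").reset_index(drop=True)
        benthic_truth = list(pd.Series(benthic_truth)[dives.index])

    # --- 6-h activity summaries consistent with the state sequence
    rows = []
    for p0 in range(0, n_hours, 6):
        chunk = states[p0:p0 + 6]
        pct_haul = 100.0 * np.mean(chunk == STATE_HAULOUT)
        q = float(np.clip(rng.normal(0.78, 0.02), 0.55, 0.95))
        pct_dive = q * (100.0 - pct_haul)
        rows.append({
            "seal_id": profile.id,
            "period_start": t0 + _dt.timedelta(hours=p0),
            "period_hours": 6,
            "pct_diving": round(pct_dive, 3),
            "pct_surface": round(100.0 - pct_haul - pct_dive, 3),
            "pct_hauled": round(pct_haul, 3),
        })
    summaries = pd.DataFrame(rows)

    # --- CTD casts with two-layer seasonal T/S
    ctd_rows = []
    n_casts = rng.poisson(config.ctd_rate_per_day * config.duration_days)
    cast_times = np.sort(rng.uniform(0.0, n_hours, n_casts))
    for h in cast_times:
        cx, cy = _interp_track(times_h, xy, h)
        bathy = float(_depth_m(cx, cy, config))
        when = t0 + _dt.timedelta(hours=float(h))
        depths = np.arange(1.0, max(bathy, 12.0) + 1e-9, 4.0)
        T, S = water_column_ts(when.month, depths)
        T = T + rng.normal(0.0, 0.03, depths.size)
        S = np.maximum(0.0, S + rng.normal(0.0, 0.02, depths.size))
        clat, clon = to_latlon(cx, cy)
        for z, t_c, s_c in zip(depths, T, S):
            ctd_rows.append({
                "seal_id": profile.id, "time": when,
                "lat": float(clat), "lon": float(clon),
                "depth_m": float(z), "temperature_c": float(t_c),
                "salinity_psu": float(s_c),
            })
    ctd = pd.DataFrame(ctd_rows) if ctd_rows else pd.DataFrame(
        {c: pd.Series(dtype=object) for c in
         ["seal_id", "time", "lat", "lon", "depth_m", "temperature_c",
          "salinity_psu"]})

    truth = {
        "states": states, "times_h": times_h, "xy": xy,
        "bout_targets": pd.DataFrame(
            targets, columns=["hour", "x", "y", "dist_glacier_km", "depth_m"]),
        "dive_benthic": np.asarray(benthic_truth, bool),
    }
    streams = {"fixes": fixes, "dives": dives, "summaries": summaries,
               "haulouts": haulouts, "ctd": ctd}
    return streams, truth


def simulate_population(config: SimConfig):
    """Simulate a labelled specialist/generalist population.

    Even-indexed seals are habitat specialists (small glacier-distance
    spread), odd-indexed seals generalists (large spread).  Returns
    ``(SealDataset, truth)`` with ``truth["specialist"]`` mapping seal id to
    its label and per-seal hidden state/target tables under
    ``truth["seals"]``.
    """
    if config.n_seals < 2:
        raise ValueError("need at least two seals (similarity indices compare seals)")
    ss = np.random.SeedSequence(config.seed)
    env_seed, *seal_seeds = ss.spawn(config.n_seals + 1)
    env = simulate_environment(config, seed=env_seed.generate_state(1)[0] % (2**31))

    meta, frames = [], {k: [] for k in ("fixes", "dives", "summaries", "haulouts", "ctd")}
    truth = {"specialist": {}, "seals": {}}
    rng_meta = np.random.default_rng(ss.generate_state(1)[0] % (2**31))
    for i in range(config.n_seals):
        sid = f"S{i + 1:02d}"
        specialist = i % 2 == 0
        spread = (config.specialist_spread_km if specialist
                  else config.generalist_spread_km)
        profile = SealProfile(
            id=sid,
            sex="F" if i % 2 == 0 else "M",
            pref_glacier_km=float(rng_meta.uniform(4.0, 14.0)),
            pref_depth_m=float(rng_meta.uniform(25.0, 60.0)),
            spread_glacier_km=spread,
            spread_depth_m=4.0 if specialist else 20.0,
            home_glacier=i % 2,
            benthic_fraction=float(rng_meta.uniform(0.55, 0.95)),
        )
        streams, seal_truth = simulate_seal(
            profile, env, config, seal_seeds[i].generate_state(1)[0] % (2**31))
        length = float(rng_meta.uniform(180.0, 215.0))
        girth = float(rng_meta.uniform(158.0, 186.0))
        meta.append(SealMetadata(
            id=sid, sex=profile.sex,
            standard_length_cm=round(length, 0), girth_cm=round(girth, 0),
            body_mass_kg=round(estimate_body_mass(length, girth), 0),
            tag_start=config.start_date,
            tag_end=config.start_date + _dt.timedelta(days=config.duration_days),
            start_lat=float(streams["fixes"]["lat"].iloc[0]),
            start_lon=float(streams["fixes"]["lon"].iloc[0]),
        ))
        for k in frames:
            frames[k].append(streams[k])
        truth["specialist"][sid] = specialist
        truth["seals"][sid] = seal_truth
        truth["seals"][sid]["profile"] = profile

    ds = SealDataset(
        metadata=meta,
        **{k: pd.concat(v, ignore_index=True) for k, v in frames.items()},
        env=env,
    )
    return ds, truth
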