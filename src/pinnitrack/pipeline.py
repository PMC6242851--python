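"""End-to-end orchestration: simulate/load -> track -> home range ->
habitat -> specialization -> dives -> water mass.

Every stage is a pure function of (inputs, parameters, seed); the run
manifest records a config hash and an md5 checksum per output file, so
re-running the same configuration reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import SealDataset
from .dives import activity_budget, classify_dive, dive_shape, monthly_pca
from .geometry import bathymetry_at, project_to_plane
from .habitat import (bootstrap_mean_ci, env_space_ud, extract_covariates,
                      seasonal_trend)
from .home_range import monthly_home_ranges
from .io import read_dataset, write_dataset
from .specialization import (extract_foraging_areas, fit_hmm, label_states,
                             similarity_indices)
from .synthetic import SimConfig, simulate_population
from .track import CtcrwModel
from .water_mass import WeightParams, assign_dataset, same_mass_fraction

__all__ = ["RunConfig", "run_pipeline", "prepare_dataset", "stage_tracks",
           "stage_home_range", "stage_habitat", "stage_specialization",
           "stage_dives", "stage_water_mass"]


class PipelineError(RuntimeError):
    def __init__(self, stage, seal_id, original):
        super().__init__(f"stage '{stage}' failed for seal {seal_id}: {original}")
        self.stage = stage
        self.seal_id = seal_id


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    mode: str = "synthetic"               # "synthetic" or "files"
    input_dir: str | None = None
    output_dir: str = "pinnitrack_run"
    seed: int = 42
    sim: dict = field(default_factory=dict)          # SimConfig overrides
    track_error_sd_m: float = 36.0
    track_restarts: int = 5
    hmm_restarts: int = 2
    min_pts: int = 5
    bootstrap_reps: int = 10_000
    benthic_margin_m: float = 25.0
    water_mass: dict = field(default_factory=dict)   # WeightParams overrides

    _KNOWN = None

    def __post_init__(self):
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "files" and not self.input_dir:
            raise ValueError("files mode requires input_dir")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self):
        return dataclasses.asdict(self)


def _child_seed(master: int, stage: str, extra: str = "") -> int:
    h = hashlib.md5(f"{master}:{stage}:{extra}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def _hours_since(times, t0):
    return (pd.to_datetime(times) - t0).dt.total_seconds().values / 3600.0


def prepare_dataset(config: RunConfig):
    """Stage 0: simulate or load the dataset; returns (dataset, truth|None)."""
    if config.mode == "synthetic":
        sim = SimConfig(seed=config.seed, **config.sim)
        ds, truth = simulate_population(sim)
        return ds, truth
    ds, _warnings = read_dataset(config.input_dir)
    return ds, None


def stage_tracks(ds: SealDataset, config: RunConfig):
    """Fit one CTCRW per seal and predict hourly and 2-hourly positions.

    Returns {seal_id: {"fit", "t0", "hourly", "two_hourly"}} where the
    prediction frames carry time, x_km, y_km, sd_km, hauled.
    """
    env = ds.env
    out = {}
    for sid in ds.seal_ids:
        fixes, _, _, haul, _ = ds.for_seal(sid)
        if len(fixes) < 10:
            continue
        t0 = fixes["time"].iloc[0].floor("h")
        th = _hours_since(fixes["time"], t0)
        x, y = project_to_plane(fixes["lat"].values, fixes["lon"].values,
                                env.center_lat, env.center_lon)
        intervals = [
            (float(a), float(b))
            for a, b in zip(_hours_since(haul["start_time"], t0),
                            _hours_since(haul["end_time"], t0))
        ] if len(haul) else []
        try:
            model = CtcrwModel(error_sd_m=config.track_error_sd_m,
                               n_restarts=config.track_restarts,
                               seed=_child_seed(config.seed, "track", sid))
            model.fit(th, np.column_stack([x, y]), intervals)
        except Exception as exc:          # pragma: no cover - surfaced as stage error
            raise PipelineError("track", sid, exc) from exc
        end = float(np.floor(th[-1]))
        hourly_t = np.arange(0.0, end + 1e-9, 1.0)
        two_t = np.arange(0.0, end + 1e-9, 2.0)

        def frame(tgrid):
            pred = model.predict(tgrid)
            pred.insert(0, "time", t0 + pd.to_timedelta(pred["time_h"], unit="h"))
            return pred

        out[sid] = {"fit": model, "t0": t0, "hourly": frame(hourly_t),
                    "two_hourly": frame(two_t)}
    return out


def stage_home_range(tracks, config: RunConfig) -> pd.DataFrame:
    rows = []
    for sid, tr in tracks.items():
        df = tr["hourly"].rename(columns={})[["time", "x_km", "y_km"]]
        results, excluded = monthly_home_ranges(df, seal_id=sid)
        for r in results:
            rows.append({"seal_id": r.seal_id, "period": r.period,
                         "area_50_km2": r.area_50_km2,
                         "area_95_km2": r.area_95_km2,
                         "n_locations": r.n_locations})
    return pd.DataFrame(rows)


def stage_habitat(ds: SealDataset, tracks, config: RunConfig):
    """Covariates, bootstrap monthly summaries, seasonal trends, env UD."""
    env = ds.env
    summaries, trends, env_uds, covs = [], [], {}, {}
    for sid, tr in tracks.items():
        cov = extract_covariates(tr["hourly"], env)
        cov = cov[~cov["missing"]]
        covs[sid] = cov
        day0 = cov["time"].iloc[0].normalize()
        day_idx = (cov["time"] - day0).dt.total_seconds() / 86400.0 + 1.0
        for var in ("dist_coast_km", "dist_glacier_km", "depth_m"):
            groups = [("all", cov)] + [
                (str(p), g) for p, g in cov.groupby(cov["time"].dt.to_period("M"))]
            for label, grp in groups:
                if len(grp) < 2:
                    continue
                s = bootstrap_mean_ci(
                    grp[var].values, reps=config.bootstrap_reps,
                    seed=_child_seed(config.seed, "boot", f"{sid}:{label}:{var}"),
                    seal_id=sid, month=label, variable=var)
                summaries.append(dataclasses.asdict(s))
            try:
                t = seasonal_trend(cov[var].values, day_idx.values,
                                   seal_id=sid, variable=var)
                trends.append(dataclasses.asdict(t))
            except ValueError:
                pass
        if len(cov) >= 50:
            env_uds[sid] = env_space_ud(cov)
    return pd.DataFrame(summaries), pd.DataFrame(trends), env_uds, covs


def _steps_angles(xy):
    d = np.diff(xy, axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    headings = np.arctan2(d[:, 1], d[:, 0])
    turns = np.full(steps.size, np.nan)
    dh = np.diff(headings)
    turns[1:] = (dh + np.pi) % (2 * np.pi) - np.pi
    ok = np.concatenate([[False], (steps[:-1] > 1e-9)]) & (steps > 1e-9)
    turns[~ok] = np.nan
    return steps, turns


def _activity_covariates(two_hourly, summaries):
    """Map each 2-h position to its 6-h summary's diving/hauled proportions."""
    s = summaries.sort_values("period_start")
    idx = np.searchsorted(s["period_start"].values,
                          two_hourly["time"].values, side="right") - 1
    idx = np.clip(idx, 0, len(s) - 1)
    return np.column_stack([
        s["pct_diving"].values[idx] / 100.0,
        s["pct_hauled"].values[idx] / 100.0,
    ])


def stage_specialization(ds: SealDataset, tracks, config: RunConfig):
    """HMM decoding, 3-day foraging areas with covariates, similarity indices."""
    env = ds.env
    areas_rows = []
    for sid, tr in tracks.items():
        two = tr["two_hourly"]
        _, _, summ, _, _ = ds.for_seal(sid)
        if summ.empty or len(two) < 30:
            continue
        xy = two[["x_km", "y_km"]].values
        steps, angles = _steps_angles(xy)
        cov = _activity_covariates(two.iloc[1:], summ)
        try:
            model = fit_hmm(steps, angles, cov,
                            n_restarts=config.hmm_restarts,
                            seed=_child_seed(config.seed, "hmm", sid))
        except Exception as exc:
            raise PipelineError("specialization", sid, exc) from exc
        states = model.decode()
        labels = label_states(model, states, cov[:, 1], steps)
        named = np.array([labels[s] for s in states], object)
        t_mid = two["time_h"].values[1:]
        areas = extract_foraging_areas(t_mid, xy[1:], named,
                                       min_pts=config.min_pts)
        for _, row in areas.iterrows():
            areas_rows.append({"seal_id": sid, **row.to_dict()})

    areas_df = pd.DataFrame(
        areas_rows, columns=["seal_id", "interval_start_h", "x_km", "y_km"])
    if len(areas_df):
        cov_df = extract_covariates(areas_df, env)
        areas_df = cov_df.drop(columns=["ice_concentration", "ice_category",
                                        "missing"])
    indices = []
    for var in ("dist_coast_km", "dist_glacier_km", "depth_m"):
        if var not in areas_df.columns or areas_df["seal_id"].nunique() < 2:
            continue
        for res in similarity_indices(areas_df, var):
            indices.append({"seal_id": res.seal_id, "variable": res.variable,
                            "mean_index": res.mean_index,
                            "n_pairs": len(res.pair_indices)})
    return areas_df, pd.DataFrame(indices)


def stage_dives(ds: SealDataset, tracks, config: RunConfig):
    """Per-dive classification + shape, activity budgets, monthly PCA."""
    env = ds.env
    dive_rows, budgets = [], []
    for sid in ds.seal_ids:
        _, dives, summ, haul, _ = ds.for_seal(sid)
        for idx, dive in dives.iterrows():
            x, y = project_to_plane(dive["lat"], dive["lon"],
                                    env.center_lat, env.center_lon)
            try:
                bathy = bathymetry_at(env, float(x), float(y))
            except ValueError:
                continue
            cls = classify_dive(dive["max_depth_m"], bathy,
                                margin_m=config.benthic_margin_m)
            try:
                bottom, descent, ascent = dive_shape(dive["profile"])
            except ValueError:
                continue
            dive_rows.append({
                "seal_id": sid, "start_time": dive["start_time"],
                "max_depth_m": dive["max_depth_m"],
                "duration_min": dive["duration_min"],
                "surface_duration_s": dive["surface_duration_s"],
                "bathy_depth_m": bathy, "dive_class": cls,
                "bottom_frac": bottom, "descent_frac": descent,
                "ascent_frac": ascent,
            })
        if len(summ):
            b = activity_budget(summ, haul, seal_id=sid)
            budgets.append({
                "seal_id": sid, "period": b.period,
                "pct_diving": b.pct_diving, "pct_surface": b.pct_surface,
                "pct_hauled": b.pct_hauled,
                "mean_haulout_min": (float(np.mean(b.haulout_durations_min))
                                     if b.haulout_durations_min.size else np.nan),
                "mean_interhaulout_h": (float(np.mean(b.interhaulout_intervals_h))
                                        if b.interhaulout_intervals_h.size else np.nan),
            })
    dive_df = pd.DataFrame(dive_rows)
    budget_df = pd.DataFrame(budgets)

    pca = None
    if len(dive_df):
        monthly = dive_df.assign(month=dive_df["start_time"].dt.to_period("M"))
        table = monthly.groupby(["seal_id", "month"]).agg(
            dive_duration=("duration_min", "mean"),
            dive_depth=("max_depth_m", "mean"),
            surface_duration=("surface_duration_s", "mean"),
            prop_benthic=("dive_class", lambda c: np.mean(c == "benthic")),
            bottom_frac=("bottom_frac", "mean"),
            ascent_frac=("ascent_frac", "mean"),
            descent_frac=("descent_frac", "mean"),
        )
        if table.shape[0] >= 3:
            pca = monthly_pca(table)
    return dive_df, budget_df, pca


def stage_water_mass(ds: SealDataset, tracks, config: RunConfig):
    env = ds.env
    params = WeightParams(**config.water_mass)
    assigned_all, fractions = [], []
    for sid in ds.seal_ids:
        _, dives, _, _, ctd = ds.for_seal(sid)
        if dives.empty or ctd.empty:
            continue
        x, y = project_to_plane(dives["lat"].values, dives["lon"].values,
                                env.center_lat, env.center_lon)
        d = dives.assign(x_km=x, y_km=y)
        px, py = project_to_plane(ctd["lat"].values, ctd["lon"].values,
                                  env.center_lat, env.center_lon)
        p = ctd.assign(x_km=px, y_km=py)
        assigned = assign_dataset(d, p, params)
        if assigned.empty:
            continue
        assigned.insert(0, "seal_id", sid)
        assigned["month"] = d.loc[assigned["dive_index"],
                                  "start_time"].dt.to_period("M").astype(str).values
        assigned_all.append(assigned)
        fractions.append({"seal_id": sid, "period": "all",
                          "same_mass_pct": same_mass_fraction(assigned)})
        for m, grp in assigned.groupby("month"):
            fractions.append({"seal_id": sid, "period": m,
                              "same_mass_pct": same_mass_fraction(grp)})
    assigned_df = (pd.concat(assigned_all, ignore_index=True)
                   if assigned_all else pd.DataFrame())
    return assigned_df, pd.DataFrame(fractions)


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig):
    """Execute all stages; writes CSV outputs plus a run manifest.

    Returns (manifest dict, results dict).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.md5(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
        "outputs": {},
    }
    results = {}

    def _write(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False, float_format="%.6f")
        manifest["outputs"][name] = _md5(path)

    def _stage(name, fn):
        t0 = time.perf_counter()
        res = fn()
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        return res

    ds, truth = _stage("data", lambda: prepare_dataset(config))
    if config.mode == "synthetic":
        # canonicalise through serialization so synthetic and files mode
        # analyse byte-identical inputs
        write_dataset(ds, out / "data")
        ds, _ = read_dataset(out / "data")
    results["dataset"], results["truth"] = ds, truth

    tracks = _stage("track", lambda: stage_tracks(ds, config))
    results["tracks"] = tracks
    for sid, tr in tracks.items():
        _write(tr["hourly"], f"track_hourly_{sid}.csv")

    hr = _stage("home_range", lambda: stage_home_range(tracks, config))
    results["home_range"] = hr
    _write(hr, "home_ranges.csv")

    hab_sum, hab_tr, env_uds, covs = _stage(
        "habitat", lambda: stage_habitat(ds, tracks, config))
    results["habitat_summaries"], results["habitat_trends"] = hab_sum, hab_tr
    results["env_uds"], results["covariates"] = env_uds, covs
    _write(hab_sum, "habitat_summaries.csv")
    _write(hab_tr, "habitat_trends.csv")

    areas, indices = _stage(
        "specialization", lambda: stage_specialization(ds, tracks, config))
    results["foraging_areas"], results["similarity"] = areas, indices
    _write(areas, "foraging_areas.csv")
    _write(indices, "similarity_indices.csv")

    dive_df, budget_df, pca = _stage(
        "dives", lambda: stage_dives(ds, tracks, config))
    results["dive_metrics"], results["activity_budget"] = dive_df, budget_df
    results["pca"] = pca
    _write(dive_df, "dive_metrics.csv")
    _write(budget_df, "activity_budget.csv")

    wm, frac = _stage("water_mass", lambda: stage_water_mass(ds, tracks, config))
    results["water_mass"], results["same_mass"] = wm, frac
    _write(wm, "water_mass.csv")
    _write(frac, "same_mass_fraction.csv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest, results
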