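"""Dataset readers and writers.

On-disk layout of a dataset directory::

    metadata.csv     fixes.csv  dives.csv  summaries.csv  haulouts.csv  ctd.csv
    bathymetry.asc   coastline.geojson  glacier_fronts.geojson
    ice_YYYY-MM-DD.asc  landfast_YYYY-MM-DD.asc   (one pair per ice date)
    environment.json (projection centre, grid metadata)

Streams are plain CSV with the headers documented in
:mod:`pinnitrack.datatypes`; dive profiles are serialised in a single
column as ``frac:depth|frac:depth|...``.  Grids use the 6-line-header ESRI
ASCII format; polylines are GeoJSON (Multi)LineStrings in planar km.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CTD_COLUMNS, DIVE_COLUMNS, FIX_COLUMNS, HAULOUT_COLUMNS, SUMMARY_COLUMNS,
    EnvironmentStack, IceField, SealDataset, SealMetadata, ValidationError,
    validate_dataset,
)

__all__ = [
    "read_dataset", "write_dataset",
    "read_ascii_grid", "write_ascii_grid",
    "read_polylines_geojson", "write_polylines_geojson",
]

_TIME_COLS = {
    "fixes": ["time"], "dives": ["start_time"], "summaries": ["period_start"],
    "haulouts": ["start_time", "end_time"], "ctd": ["time"],
}


# ---------------------------------------------------------------- profiles

def encode_profile(profile) -> str:
    if profile is None or len(profile) == 0:
        return ""
    return "|".join(f"{f:.4f}:{d:.2f}" for f, d in profile)


def decode_profile(text):
    if not isinstance(text, str) or text == "":
        return []
    out = []
    for tok in text.split("|"):
        f, d = tok.split(":")
        out.append((float(f), float(d)))
    return out


# ------------------------------------------------------------------ grids

def write_ascii_grid(path, x, y, values, nodata=-9999.0) -> None:
    """Write a regular grid as ESRI ASCII (cell-centre registration)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    values = np.asarray(values, float)
    cell = x[1] - x[0]
    if abs((y[1] - y[0]) - cell) > 1e-9:
        raise ValueError("ASCII grids require square cells")
    with open(path, "w") as fh:
        fh.write(f"ncols {x.size}\n")
        fh.write(f"nrows {y.size}\n")
        fh.write(f"xllcenter {x[0]:.6f}\n")
        fh.write(f"yllcenter {y[0]:.6f}\n")
        fh.write(f"cellsize {cell:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        # rows from north (max y) to south, per the format
        for row in values[::-1]:
            fh.write(" ".join(f"{v:.4f}" for v in row) + "\n")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (x, y, values) cell-centre arrays."""
    header = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    if "xllcenter" in header:
        x0, y0 = header["xllcenter"], header["yllcenter"]
    else:  # corner registration
        x0 = header["xllcorner"] + cell / 2.0
        y0 = header["yllcorner"] + cell / 2.0
    data = np.loadtxt(lines[6:6 + nrows].__iter__())
    data = np.atleast_2d(data)[::-1]          # back to south-to-north rows
    if data.shape != (nrows, ncols):
        raise ValidationError(f"{path}: grid body does not match header")
    x = x0 + cell * np.arange(ncols)
    y = y0 + cell * np.arange(nrows)
    return x, y, data


# -------------------------------------------------------------- polylines

def write_polylines_geojson(path, lines) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {},
            "geometry": {
                "type": "LineString",
                "coordinates": [[float(p[0]), float(p[1])] for p in line],
            },
        }
        for line in lines
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_polylines_geojson(path):
    with open(path) as fh:
        gj = json.load(fh)
    lines = []
    for feat in gj.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") == "LineString":
            lines.append(np.asarray(geom["coordinates"], float))
        elif geom.get("type") == "MultiLineString":
            lines.extend(np.asarray(c, float) for c in geom["coordinates"])
        else:
            raise ValidationError(f"{path}: unsupported geometry {geom.get('type')}")
    return lines


# ---------------------------------------------------------------- dataset

def write_dataset(ds: SealDataset, directory) -> None:
    """Serialise a full dataset to a directory (created if absent)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    meta = pd.DataFrame(
        {
            "id": [m.id for m in ds.metadata],
            "sex": [m.sex for m in ds.metadata],
            "standard_length_cm": [m.standard_length_cm for m in ds.metadata],
            "girth_cm": [m.girth_cm for m in ds.metadata],
            "body_mass_kg": [m.body_mass_kg for m in ds.metadata],
            "tag_start": [m.tag_start.isoformat() for m in ds.metadata],
            "tag_end": [m.tag_end.isoformat() for m in ds.metadata],
            "start_lat": [m.start_lat for m in ds.metadata],
            "start_lon": [m.start_lon for m in ds.metadata],
        }
    )
    meta.to_csv(directory / "metadata.csv", index=False)

    for name, cols in (
        ("fixes", FIX_COLUMNS), ("dives", DIVE_COLUMNS),
        ("summaries", SUMMARY_COLUMNS), ("haulouts", HAULOUT_COLUMNS),
        ("ctd", CTD_COLUMNS),
    ):
        df = getattr(ds, name).copy()
        if name == "dives" and len(df):
            df["profile"] = df["profile"].map(encode_profile)
        for col in _TIME_COLS[name]:
            if len(df):
                df[col] = pd.to_datetime(df[col]).dt.strftime(
                    "%Y-%m-%dT%H:%M:%S.%f")
        df.to_csv(directory / f"{name}.csv", index=False, columns=cols,
                  float_format="%.6f")

    env = ds.env
    write_ascii_grid(directory / "bathymetry.asc", env.x, env.y, env.bathymetry)
    write_polylines_geojson(directory / "coastline.geojson", env.coastline)
    write_polylines_geojson(directory / "glacier_fronts.geojson", env.glacier_fronts)
    for fld in env.ice_fields:
        tag = fld.date.isoformat()
        write_ascii_grid(directory / f"ice_{tag}.asc", env.x, env.y, fld.concentration)
        write_ascii_grid(directory / f"landfast_{tag}.asc", env.x, env.y,
                         fld.landfast.astype(float))
    with open(directory / "environment.json", "w") as fh:
        json.dump(
            {
                "center_lat": env.center_lat,
                "center_lon": env.center_lon,
                "ice_dates": [f.date.isoformat() for f in env.ice_fields],
            },
            fh,
        )


def _read_stream(directory: Path, name: str, cols) -> pd.DataFrame:
    path = directory / f"{name}.csv"
    if not path.exists():
        raise ValidationError(f"missing stream file {path.name}")
    df = pd.read_csv(path, dtype={"seal_id": str})
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing mandatory column(s) {missing}")
    for col in _TIME_COLS[name]:
        df[col] = pd.to_datetime(df[col])
    if name == "dives":
        df["profile"] = df["profile"].map(decode_profile)
    return df


def read_dataset(directory, validate: bool = True):
    """Load a dataset directory; returns ``(SealDataset, warnings)``.

    All stream invariants are checked on read (see
    :func:`pinnitrack.datatypes.validate_dataset`); streams come back
    time-sorted per seal with duplicate timestamps collapsed.
    """
    directory = Path(directory)
    meta_df = pd.read_csv(directory / "metadata.csv", dtype={"id": str})
    metadata = [
        SealMetadata(
            id=r["id"], sex=r["sex"],
            standard_length_cm=r["standard_length_cm"], girth_cm=r["girth_cm"],
            body_mass_kg=r["body_mass_kg"],
            tag_start=_dt.datetime.fromisoformat(r["tag_start"]),
            tag_end=_dt.datetime.fromisoformat(r["tag_end"]),
            start_lat=r["start_lat"], start_lon=r["start_lon"],
        )
        for _, r in meta_df.iterrows()
    ]

    with open(directory / "environment.json") as fh:
        env_meta = json.load(fh)
    x, y, bathy = read_ascii_grid(directory / "bathymetry.asc")
    coast = read_polylines_geojson(directory / "coastline.geojson")
    fronts = read_polylines_geojson(directory / "glacier_fronts.geojson")
    ice_fields = []
    for tag in env_meta.get("ice_dates", []):
        _, _, conc = read_ascii_grid(directory / f"ice_{tag}.asc")
        _, _, lf = read_ascii_grid(directory / f"landfast_{tag}.asc")
        ice_fields.append(IceField(date=_dt.date.fromisoformat(tag),
                                   concentration=conc, landfast=lf > 0.5))
    env = EnvironmentStack(
        x=x, y=y, bathymetry=bathy, coastline=coast, glacier_fronts=fronts,
        ice_fields=ice_fields,
        center_lat=env_meta["center_lat"], center_lon=env_meta["center_lon"],
    )

    ds = SealDataset(
        metadata=metadata,
        fixes=_read_stream(directory, "fixes", FIX_COLUMNS),
        dives=_read_stream(directory, "dives", DIVE_COLUMNS),
        summaries=_read_stream(directory, "summaries", SUMMARY_COLUMNS),
        haulouts=_read_stream(directory, "haulouts", HAULOUT_COLUMNS),
        ctd=_read_stream(directory, "ctd", CTD_COLUMNS),
        env=env,
    )
    warnings = validate_dataset(ds) if validate else []
    return ds, warnings
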