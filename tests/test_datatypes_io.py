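import datetime as dt

import numpy as np
import pandas as pd
import pytest

from pinnitrack.datatypes import (SealDataset, SealMetadata, ValidationError,
                                  validate_dataset)
from pinnitrack.io import (read_ascii_grid, read_dataset, read_polylines_geojson,
                           write_ascii_grid, write_dataset,
                           write_polylines_geojson)


def _empty_streams():
    from pinnitrack.datatypes import (CTD_COLUMNS, DIVE_COLUMNS, FIX_COLUMNS,
                                      HAULOUT_COLUMNS, SUMMARY_COLUMNS)
    mk = lambda cols: pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
    return (mk(FIX_COLUMNS), mk(DIVE_COLUMNS), mk(SUMMARY_COLUMNS),
            mk(HAULOUT_COLUMNS), mk(CTD_COLUMNS))


def _one_seal_meta():
    return SealMetadata(
        id="F310", sex="F", standard_length_cm=198, girth_cm=171,
        body_mass_kg=310, tag_start=dt.datetime(2011, 7, 25),
        tag_end=dt.datetime(2012, 3, 22), start_lat=79.19, start_lon=12.14)


def test_single_fix_round_trips_unchanged(tmp_path, small_env):
    fixes, dives, summ, haul, ctd = _empty_streams()
    fixes = pd.DataFrame({
        "seal_id": ["F310"], "time": [pd.Timestamp("2011-07-25 12:00:00")],
        "lat": [80.0], "lon": [12.0], "source": ["gps"]})
    ds = SealDataset(metadata=[_one_seal_meta()], fixes=fixes, dives=dives,
                     summaries=summ, haulouts=haul, ctd=ctd, env=small_env)
    write_dataset(ds, tmp_path / "d")
    back, warnings = read_dataset(tmp_path / "d")
    assert warnings == []
    assert len(back.dives) == 0          # empty dive file reads cleanly
    assert len(back.fixes) == 1
    row = back.fixes.iloc[0]
    assert row["lat"] == pytest.approx(80.0, abs=1e-6)
    assert row["lon"] == pytest.approx(12.0, abs=1e-6)
    assert row["time"] == pd.Timestamp("2011-07-25 12:00:00")


def test_synthetic_population_round_trip_and_validation(tmp_path, small_population):
    ds, _ = small_population
    assert validate_dataset(ds) == []
    write_dataset(ds, tmp_path / "pop")
    back, warnings = read_dataset(tmp_path / "pop")
    assert warnings == []
    assert back.seal_ids == ds.seal_ids
    for name in ("fixes", "dives", "summaries", "haulouts", "ctd"):
        assert len(getattr(back, name)) == len(getattr(ds, name)), name
    np.testing.assert_allclose(back.fixes["lat"].values,
                               ds.fixes["lat"].values, atol=1e-6)
    np.testing.assert_allclose(back.env.bathymetry, ds.env.bathymetry,
                               atol=1e-4)


def test_missing_column_raises_named_format_error(tmp_path, small_population):
    ds, _ = small_population
    write_dataset(ds, tmp_path / "broken")
    path = tmp_path / "broken" / "fixes.csv"
    df = pd.read_csv(path).drop(columns=["lat"])
    df.to_csv(path, index=False)
    with pytest.raises(ValidationError, match="lat"):
        read_dataset(tmp_path / "broken")


def test_out_of_range_coordinate_is_rejected(small_env):
    fixes, dives, summ, haul, ctd = _empty_streams()
    fixes = pd.DataFrame({
        "seal_id": ["F310", "F310"],
        "time": pd.to_datetime(["2011-07-25", "2011-07-26"]),
        "lat": [80.0, 95.0], "lon": [12.0, 12.0], "source": "gps"})
    ds = SealDataset(metadata=[_one_seal_meta()], fixes=fixes, dives=dives,
                     summaries=summ, haulouts=haul, ctd=ctd, env=small_env)
    with pytest.raises(ValidationError, match="coordinate"):
        validate_dataset(ds)


def test_duplicate_timestamps_collapse_keeping_first(small_env):
    fixes, dives, summ, haul, ctd = _empty_streams()
    t = pd.Timestamp("2011-07-25 06:00:00")
    fixes = pd.DataFrame({
        "seal_id": ["F310"] * 3, "time": [t, t, t + pd.Timedelta("1h")],
        "lat": [79.0, 79.5, 79.1], "lon": [12.0, 12.5, 12.1], "source": "gps"})
    ds = SealDataset(metadata=[_one_seal_meta()], fixes=fixes, dives=dives,
                     summaries=summ, haulouts=haul, ctd=ctd, env=small_env)
    warnings = validate_dataset(ds)
    assert any("duplicate" in w for w in warnings)
    assert len(ds.fixes) == 2
    assert ds.fixes.iloc[0]["lat"] == 79.0


def test_ascii_grid_round_trip(tmp_path):
    x = np.arange(5) * 0.5
    y = np.arange(4) * 0.5
    vals = np.arange(20, dtype=float).reshape(4, 5) * 1.25
    write_ascii_grid(tmp_path / "g.asc", x, y, vals)
    x2, y2, v2 = read_ascii_grid(tmp_path / "g.asc")
    np.testing.assert_allclose(x2, x)
    np.testing.assert_allclose(y2, y)
    np.testing.assert_allclose(v2, vals, atol=1e-4)


def test_geojson_polyline_round_trip(tmp_path):
    lines = [np.array([[0.0, 0.0], [1.5, 2.5], [3.0, 1.0]]),
             np.array([[-2.0, 4.0], [0.0, 5.0]])]
    write_polylines_geojson(tmp_path / "l.geojson", lines)
    back = read_polylines_geojson(tmp_path / "l.geojson")
    assert len(back) == 2
    for a, b in zip(lines, back):
        np.testing.assert_allclose(a, b)


def test_metadata_invariants():
    with pytest.raises(ValidationError):
        SealMetadata(id="X", sex="Q", standard_length_cm=198, girth_cm=171,
                     body_mass_kg=310, tag_start=dt.datetime(2011, 7, 25),
                     tag_end=dt.datetime(2012, 3, 22), start_lat=0, start_lon=0)
    with pytest.raises(ValidationError):
        SealMetadata(id="X", sex="F", standard_length_cm=-1, girth_cm=171,
                     body_mass_kg=310, tag_start=dt.datetime(2011, 7, 25),
                     tag_end=dt.datetime(2012, 3, 22), start_lat=0, start_lon=0)
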