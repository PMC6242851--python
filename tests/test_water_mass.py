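import numpy as np
import pandas as pd
import pytest

from pinnitrack.water_mass import (WeightParams, assign_dataset, assign_ts,
                                   classify_water_mass, same_mass_fraction)


@pytest.mark.parametrize("T, S, expected", [
    (4.0, 35.0, "AW"), (-1.0, 34.2, "WCW"), (1.5, 33.5, "GW"),
    (2.0, 34.8, "TransAW"), (2.0, 34.3, "IntW"), (0.0, 34.0, "LW"),
    (3.0, 34.65, "AW"), (1.0, 34.65, "TransAW"), (1.0, 34.0, "IntW"),
    (-0.5, 30.0, "LW"), (4.0, 33.0, "GW"),
])
def test_printed_thresholds(T, S, expected):
    assert classify_water_mass(T, S) == expected


def test_partition_property_and_boundaries(rng):
    T = rng.uniform(-3.0, 10.0, 100_000)
    S = rng.uniform(28.0, 36.0, 100_000)
    classes = classify_water_mass(T, S)
    assert set(np.unique(classes)) <= {"AW", "TransAW", "IntW", "GW", "LW", "WCW"}
    assert not (classes == None).any()  # noqa: E711
    # every threshold tested a hair either side
    eps = 1e-9
    for T0 in (-0.5, 1.0, 3.0):
        for S0 in (34.0, 34.65):
            for dT in (-eps, 0.0, eps):
                for dS in (-eps, 0.0, eps):
                    c = classify_water_mass(T0 + dT, S0 + dS)
                    assert c in ("AW", "TransAW", "IntW", "GW", "LW", "WCW")


def test_non_finite_rejected():
    with pytest.raises(ValueError):
        classify_water_mass(np.nan, 34.0)
    with pytest.raises(ValueError):
        classify_water_mass(2.0, -1.0)


def _cast(time, x, y, depths, T, S):
    return pd.DataFrame({
        "time": pd.Timestamp(time), "x_km": x, "y_km": y,
        "depth_m": depths, "temperature_c": T, "salinity_psu": S})


def test_single_colocated_profile_is_identity():
    prof = _cast("2011-08-01", 0.0, 0.0, [1.0, 20.0, 50.0, 100.0],
                 [2.0, 2.0, 4.0, 4.0], [33.0, 33.0, 35.0, 35.0])
    dive = pd.Series({"start_time": pd.Timestamp("2011-08-01"),
                      "max_depth_m": 100.0, "x_km": 0.0, "y_km": 0.0}, name=0)
    res = assign_ts(dive, prof)
    assert res.surface_t == pytest.approx(2.0)
    assert res.bottom_t == pytest.approx(4.0)
    assert res.surface_class == "GW"
    assert res.bottom_class == "AW"
    assert not res.same_class


def test_symmetric_profiles_average():
    p1 = _cast("2011-08-01 00:00", 5.0, 0.0, [1.0, 100.0], [2.0, 2.0],
               [34.0, 34.0])
    p2 = _cast("2011-08-03 00:00", -5.0, 0.0, [1.0, 100.0], [4.0, 4.0],
               [34.0, 34.0])
    dive = pd.Series({"start_time": pd.Timestamp("2011-08-02 00:00"),
                      "max_depth_m": 50.0, "x_km": 0.0, "y_km": 0.0}, name=0)
    res = assign_ts(dive, pd.concat([p1, p2], ignore_index=True))
    assert res.bottom_t == pytest.approx(3.0)


def test_profile_order_invariance():
    p1 = _cast("2011-08-01 00:00", 2.0, 1.0, [1.0, 80.0], [1.5, 3.5],
               [33.5, 34.8])
    p2 = _cast("2011-08-02 12:00", -3.0, 2.0, [1.0, 80.0], [2.5, 3.0],
               [33.8, 34.7])
    dive = pd.Series({"start_time": pd.Timestamp("2011-08-02 00:00"),
                      "max_depth_m": 60.0, "x_km": 0.0, "y_km": 0.0}, name=0)
    a = assign_ts(dive, pd.concat([p1, p2], ignore_index=True))
    b = assign_ts(dive, pd.concat([p2, p1], ignore_index=True))
    assert a.bottom_t == pytest.approx(b.bottom_t)
    assert a.surface_s == pytest.approx(b.surface_s)


def test_shrinking_kernels_converge_to_nearest_profile():
    near = _cast("2011-08-02 01:00", 0.5, 0.0, [1.0, 80.0], [2.0, 2.0],
                 [34.0, 34.0])
    far = _cast("2011-08-05 00:00", 20.0, 0.0, [1.0, 80.0], [4.0, 4.0],
                [35.0, 35.0])
    dive = pd.Series({"start_time": pd.Timestamp("2011-08-02 00:00"),
                      "max_depth_m": 50.0, "x_km": 0.0, "y_km": 0.0}, name=0)
    profs = pd.concat([near, far], ignore_index=True)
    tight = WeightParams(tau_h=0.5, rho_km=0.5, zeta_m=10.0)
    res = assign_ts(dive, profs, tight)
    assert res.bottom_t == pytest.approx(2.0, abs=1e-6)


def test_no_eligible_profile_returns_none():
    prof = _cast("2011-01-01", 0.0, 0.0, [1.0, 50.0], [2.0, 2.0], [34.0, 34.0])
    dive = pd.Series({"start_time": pd.Timestamp("2011-08-01"),
                      "max_depth_m": 50.0, "x_km": 0.0, "y_km": 0.0}, name=0)
    assert assign_ts(dive, prof) is None


def test_depth_extrapolation_limit():
    shallow = _cast("2011-08-01", 0.0, 0.0, [1.0, 20.0], [2.0, 2.0],
                    [34.0, 34.0])
    dive = pd.Series({"start_time": pd.Timestamp("2011-08-01"),
                      "max_depth_m": 100.0, "x_km": 0.0, "y_km": 0.0}, name=0)
    # 80 m past the deepest sample >> 3 * zeta: excluded -> unassignable
    assert assign_ts(dive, shallow, WeightParams(zeta_m=10.0)) is None


def test_two_layer_ocean_dives(rng):
    # AW below 50 m, GW above; dives crossing the interface change class
    times = pd.date_range("2011-08-01", periods=8, freq="12h")
    profs = pd.concat([
        _cast(t, rng.uniform(-2, 2), rng.uniform(-2, 2),
              [1.0, 40.0, 60.0, 120.0],
              [2.0, 2.0, 4.0, 4.0], [33.0, 33.0, 35.0, 35.0])
        for t in times], ignore_index=True)
    dives = pd.DataFrame({
        "start_time": pd.date_range("2011-08-02", periods=20, freq="3h"),
        "max_depth_m": 100.0,
        "x_km": rng.uniform(-2, 2, 20), "y_km": rng.uniform(-2, 2, 20)})
    assigned = assign_dataset(dives, profs)
    assert len(assigned) == 20
    assert (assigned["surface_class"] == "GW").all()
    assert (assigned["bottom_class"] == "AW").all()
    assert same_mass_fraction(assigned) == 0.0


def test_same_mass_fraction_is_a_recount(rng):
    n = 200
    assigned = pd.DataFrame({
        "same_class": rng.random(n) < 0.7,
    })
    expected = 100.0 * assigned["same_class"].sum() / n
    assert same_mass_fraction(assigned) == pytest.approx(expected)
    with pytest.raises(ValueError):
        same_mass_fraction(assigned.iloc[:0])


def test_assign_dataset_matches_per_dive_assign(rng):
    times = pd.date_range("2011-08-01", periods=5, freq="1D")
    profs = pd.concat([
        _cast(t, rng.uniform(-5, 5), rng.uniform(-5, 5),
              [1.0, 30.0, 90.0], [2.0, 1.0, 3.5], [33.5, 34.2, 34.8])
        for t in times], ignore_index=True)
    dives = pd.DataFrame({
        "start_time": pd.date_range("2011-08-02", periods=10, freq="7h"),
        "max_depth_m": rng.uniform(10, 80, 10),
        "x_km": rng.uniform(-5, 5, 10), "y_km": rng.uniform(-5, 5, 10)})
    batch = assign_dataset(dives, profs)
    for _, row in batch.iterrows():
        single = assign_ts(dives.loc[row["dive_index"]], profs)
        assert single.bottom_t == pytest.approx(row["bottom_t"])
        assert single.surface_class == row["surface_class"]
        assert single.total_weight == pytest.approx(row["total_weight"])
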