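import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from pinnitrack.habitat import (bootstrap_mean_ci, distance_to_polylines,
                                env_space_ud, extract_covariates,
                                seasonal_trend)


def _segment_distance(p, a, b):
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return np.linalg.norm(p - (a + t * ab))


def brute_force_distance(p, lines):
    best = np.inf
    for line in lines:
        for a, b in zip(line[:-1], line[1:]):
            best = min(best, _segment_distance(np.asarray(p, float), a, b))
    return best


def test_distance_basics():
    seg = [np.array([[-1.0, 0.0], [1.0, 0.0]])]
    assert distance_to_polylines([1.0, 0.0], seg) == 0.0       # on a vertex
    assert distance_to_polylines([0.0, 1.0], seg) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        distance_to_polylines([0.0, 0.0], [])


def test_distance_matches_brute_force_oracle():
    rng = np.random.default_rng(12)
    lines = [rng.normal(0, 5, (rng.integers(2, 8), 2)) for _ in range(4)]
    pts = rng.normal(0, 6, (1000, 2))
    fast = distance_to_polylines(pts, lines)
    slow = np.array([brute_force_distance(p, lines) for p in pts])
    np.testing.assert_allclose(fast, slow, atol=1e-9)


def test_distance_to_discretized_circle():
    theta = np.linspace(0, 2 * np.pi, 721)
    r = 5.0
    circle = [np.column_stack([r * np.cos(theta), r * np.sin(theta)])]
    step = 2 * np.pi * r / 720
    rng = np.random.default_rng(13)
    pts = rng.uniform(-8, 8, (200, 2))
    d = distance_to_polylines(pts, circle)
    analytic = np.abs(np.hypot(pts[:, 0], pts[:, 1]) - r)
    np.testing.assert_allclose(d, analytic, atol=step)


def test_extract_covariates_at_glacier_vertex(small_env):
    v = small_env.glacier_fronts[0][0]
    track = pd.DataFrame({"x_km": [v[0]], "y_km": [v[1]],
                          "time": [pd.Timestamp("2011-08-01")]})
    cov = extract_covariates(track, small_env)
    assert cov["dist_glacier_km"].iloc[0] == pytest.approx(0.0, abs=1e-9)
    assert not cov["missing"].iloc[0]


def test_extract_covariates_depth_matches_preference(small_env, small_config):
    from pinnitrack.synthetic import SealProfile, simulate_seal
    profile = SealProfile(id="X", pref_depth_m=30.0, spread_depth_m=2.0,
                          spread_glacier_km=0.5,
                          dwell_means_h=(4.0, 48.0, 0.0))
    _, truth = simulate_seal(profile, small_env, small_config, seed=2)
    forage = truth["states"] == 1
    track = pd.DataFrame({"x_km": truth["xy"][forage, 0],
                          "y_km": truth["xy"][forage, 1]})
    cov = extract_covariates(track, small_env)
    assert abs(cov["depth_m"].mean() - 30.0) <= 10.0


def test_extract_covariates_flags_outside_grid(small_env):
    track = pd.DataFrame({"x_km": [1e6], "y_km": [0.0]})
    cov = extract_covariates(track, small_env)
    assert cov["missing"].iloc[0]
    assert np.isnan(cov["depth_m"].iloc[0])


def test_bootstrap_constant_vector_collapses():
    s = bootstrap_mean_ci(np.full(20, 7.0), reps=200, seed=0)
    assert s.ci_low == s.mean == s.ci_high == 7.0


def test_bootstrap_scale_equivariance():
    v = np.random.default_rng(1).normal(3.0, 1.0, 50)
    a = bootstrap_mean_ci(v, reps=2000, seed=5)
    b = bootstrap_mean_ci(10.0 * v, reps=2000, seed=5)
    assert b.mean == pytest.approx(10 * a.mean)
    assert b.ci_low == pytest.approx(10 * a.ci_low)
    assert b.ci_high == pytest.approx(10 * a.ci_high)


def test_bootstrap_needs_two_values():
    with pytest.raises(ValueError):
        bootstrap_mean_ci([1.0], reps=10, seed=0)


def test_bootstrap_ci_width_scales_as_inverse_sqrt_n():
    rng = np.random.default_rng(2)
    ns = np.array([50, 100, 200, 400, 800])
    widths = []
    for n in ns:
        w = []
        for k in range(4):
            s = bootstrap_mean_ci(rng.normal(0, 1, n), reps=1500, seed=k)
            w.append(s.ci_high - s.ci_low)
        widths.append(np.mean(w))
    slope = np.polyfit(np.log(ns), np.log(widths), 1)[0]
    assert -0.6 < slope < -0.4


def test_trend_recovers_exact_line():
    d = np.arange(1.0, 61.0)
    res = seasonal_trend(2.0 * d, d, transform="identity")
    assert res.slope_per_day == pytest.approx(2.0, abs=1e-10)
    assert res.p_value < 1e-10


def test_trend_invariant_to_constant_shift():
    rng = np.random.default_rng(3)
    d = np.arange(1.0, 41.0)
    y = 0.3 * d + rng.normal(0, 1, 40)
    a = seasonal_trend(y, d, transform="identity")
    b = seasonal_trend(y + 100.0, d, transform="identity")
    assert a.slope_per_day == pytest.approx(b.slope_per_day)
    assert a.p_value == pytest.approx(b.p_value)


def test_trend_matches_closed_form_ols():
    rng = np.random.default_rng(4)
    d = np.sort(rng.uniform(1, 90, 50))
    y = rng.normal(0, 1, 50)
    res = seasonal_trend(y, d, transform="identity")
    slope = np.sum((d - d.mean()) * (y - y.mean())) / np.sum((d - d.mean()) ** 2)
    assert res.slope_per_day == pytest.approx(slope, abs=1e-12)


def test_trend_preconditions():
    with pytest.raises(ValueError):
        seasonal_trend([1, 2, 3], [1, 2, 3])


def test_env_ud_integrates_to_one_and_masks_top_quartile(rng):
    df = pd.DataFrame({
        "dist_coast_km": rng.normal(2.0, 0.5, 400).clip(0),
        "dist_glacier_km": rng.normal(8.0, 1.0, 400).clip(0),
        "depth_m": rng.normal(40.0, 5.0, 400).clip(1),
    })
    ud = env_space_ud(df)
    vol = np.prod([np.diff(a).mean() for a in ud.axes])
    assert ud.density.sum() * vol == pytest.approx(1.0, abs=0.02)
    assert ud.mask.mean() == pytest.approx(0.25, abs=0.02)


def test_env_ud_single_cluster_is_connected_and_contains_mode(rng):
    df = pd.DataFrame({
        "dist_coast_km": rng.normal(3.0, 0.3, 300),
        "dist_glacier_km": rng.normal(5.0, 0.3, 300),
        "depth_m": rng.normal(30.0, 2.0, 300),
    })
    ud = env_space_ud(df)
    labels, n = ndimage.label(ud.mask)
    modal = np.unravel_index(np.argmax(ud.density), ud.density.shape)
    assert ud.mask[modal]
    # the modal component dominates the mask (outlier points may add tiny
    # satellite bumps just above the value threshold)
    sizes = np.bincount(labels.ravel())[1:]
    assert sizes[labels[modal] - 1] >= 0.95 * ud.mask.sum()


def test_env_ud_two_separated_clusters_both_masked(rng):
    half = 200
    a = np.column_stack([rng.normal(2, 0.2, half), rng.normal(2, 0.2, half),
                         rng.normal(20, 1, half)])
    b = a + np.array([20.0, 20.0, 100.0])
    df = pd.DataFrame(np.vstack([a, b]),
                      columns=["dist_coast_km", "dist_glacier_km", "depth_m"])
    ud = env_space_ud(df)

    def cell_of(point):
        return tuple(int(np.argmin(np.abs(ax - p)))
                     for ax, p in zip(ud.axes, point))

    assert ud.mask[cell_of(a.mean(axis=0))]
    assert ud.mask[cell_of(b.mean(axis=0))]


def test_env_ud_needs_enough_locations():
    df = pd.DataFrame({"dist_coast_km": [1.0] * 10,
                       "dist_glacier_km": [1.0] * 10, "depth_m": [1.0] * 10})
    with pytest.raises(ValueError):
        env_space_ud(df)
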