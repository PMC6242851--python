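import itertools

import numpy as np
import pandas as pd
import pytest

from pinnitrack.specialization import (MovementHMM, fit_hmm, knee_epsilon,
                                       label_states, select_foraging_area,
                                       similarity_indices)


def _random_params(model, n_cov, seed):
    rng = np.random.default_rng(seed)
    vec = rng.normal(0.0, 0.5, 15 + 6 * (n_cov + 1))
    return model._unpack(vec, n_cov)


def simulate_hmm_series(T, seed):
    """Data from a known 3-state model (travel / forage / haulout)."""
    rng = np.random.default_rng(seed)
    means, sds = [4.0, 0.7, 0.001], [2.0, 0.5, 0.001]
    zp = [0.0, 0.0, 0.9]
    kappa, mu = [3.0, 0.5, 0.1], [0.0, np.pi, 0.0]
    G = np.array([[0.90, 0.08, 0.02], [0.10, 0.85, 0.05], [0.10, 0.10, 0.80]])
    cov = np.zeros((T, 2))
    steps = np.zeros(T)
    angles = np.zeros(T)
    states = np.zeros(T, dtype=int)
    s = 0
    for t in range(T):
        if t:
            s = rng.choice(3, p=G[s])
        states[t] = s
        cov[t, 0] = (0.7, 0.8, 0.1)[s] + rng.normal(0, 0.05)
        cov[t, 1] = (0.0, 0.0, 0.9)[s] + rng.normal(0, 0.05)
        if rng.random() < zp[s]:
            steps[t] = 0.0
        else:
            m, sd = means[s], sds[s]
            steps[t] = rng.gamma((m / sd) ** 2, sd ** 2 / m)
        angles[t] = rng.vonmises(mu[s], kappa[s])
    angles[steps <= 1e-9] = np.nan
    return steps, angles, cov, states


def brute_force_loglik(model, params, steps, angles, cov):
    """Exhaustive sum over all 3^T state paths."""
    b = model.emission_probs(params, steps, angles)
    G = model.transition_matrices(params, cov[1:])
    T = len(steps)
    total = 0.0
    for path in itertools.product(range(3), repeat=T):
        p = params.delta[path[0]] * b[0, path[0]]
        for t in range(1, T):
            p *= G[t - 1, path[t - 1], path[t]] * b[t, path[t]]
        total += p
    return np.log(total)


def test_forward_matches_exhaustive_enumeration():
    T = 8
    steps, angles, cov, _ = simulate_hmm_series(T, seed=1)
    model = MovementHMM()
    covz = (cov - cov.mean(axis=0)) / cov.std(axis=0)
    for seed in (0, 1, 2):
        params = _random_params(model, 2, seed)
        ll = model.loglik(params, steps, angles, covz)
        oracle = brute_force_loglik(model, params, steps, angles, covz)
        assert ll == pytest.approx(oracle, abs=1e-8)


def test_identical_emissions_collapse_to_single_state():
    T = 60
    steps, angles, cov, _ = simulate_hmm_series(T, seed=2)
    model = MovementHMM()
    params = _random_params(model, 2, seed=3)
    for attr in ("step_mean", "step_sd", "zero_prob", "angle_mean",
                 "angle_kappa"):
        arr = getattr(params, attr)
        arr[:] = arr[0]
    covz = (cov - cov.mean(axis=0)) / cov.std(axis=0)
    ll = model.loglik(params, steps, angles, covz)
    b = model.emission_probs(params, steps, angles)
    single = float(np.sum(np.log(b[:, 0])))
    assert ll == pytest.approx(single, abs=1e-6)


def test_viterbi_recovers_states_on_moderate_series():
    steps, angles, cov, states = simulate_hmm_series(600, seed=5)
    model = fit_hmm(steps, angles, cov, n_restarts=2, seed=5)
    decoded = model.decode()
    labels = label_states(model, decoded, cov[:, 1], steps)
    names = {0: "travelling", 1: "foraging", 2: "haulout"}
    truth = np.array([names[s] for s in states])
    got = np.array([labels[s] for s in decoded])
    assert np.mean(got == truth) >= 0.9


def test_label_states_permutation_invariant():
    steps, angles, cov, states = simulate_hmm_series(300, seed=6)
    model = MovementHMM()
    params = _random_params(model, 2, seed=0)
    decoded = states.copy()
    labels = label_states(model, decoded, cov[:, 1], steps)
    # permute the state indices and relabel
    perm = np.array([2, 0, 1])
    permuted = perm[decoded]
    labels_p = label_states(model, permuted, cov[:, 1], steps)
    for s in range(3):
        assert labels[s] == labels_p[perm[s]]


def test_label_states_degenerate_hauled_covariate_warns():
    steps = np.array([1.0, 2.0, 0.5, 3.0] * 10)
    states = np.array([0, 1, 2, 0] * 10)
    model = MovementHMM()
    with pytest.warns(UserWarning, match="hauled"):
        labels = label_states(model, states, np.zeros(40), steps)
    assert sorted(labels.values()) == ["foraging", "haulout", "travelling"]


def test_all_zero_steps_rejected():
    with pytest.raises(ValueError):
        fit_hmm(np.zeros(100), np.full(100, np.nan), np.zeros((100, 2)))


# --------------------------------------------------------- foraging areas

def test_two_blob_case_selects_dominant_blob():
    rng = np.random.default_rng(2)
    big = rng.normal([0.0, 0.0], 0.1, (20, 2))
    small = rng.normal([10.0, 10.0], 0.1, (10, 2))
    pts = np.vstack([big, small])
    area = select_foraging_area(pts, min_pts=5)
    assert area is not None
    assert np.linalg.norm(area - big.mean(axis=0)) < 0.5


def test_too_few_points_yields_none():
    assert select_foraging_area(np.zeros((4, 2))) is None


def _dbscan_oracle(pts, eps, min_pts):
    """Brute-force density-reachability clustering."""
    n = len(pts)
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    neighbours = [set(np.where(d[i] <= eps)[0]) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbours])
    # connected components over core points
    comp = -np.ones(n, dtype=int)
    cid = 0
    for i in range(n):
        if not core[i] or comp[i] >= 0:
            continue
        stack = [i]
        comp[i] = cid
        while stack:
            j = stack.pop()
            for k in neighbours[j]:
                if core[k] and comp[k] < 0:
                    comp[k] = cid
                    stack.append(k)
        cid += 1
    return core, comp, neighbours


def test_dbscan_labels_match_density_reachability_oracle():
    from sklearn.cluster import DBSCAN
    rng = np.random.default_rng(7)
    for trial in range(200):
        pts = rng.uniform(0, 4, (30, 2))
        eps = rng.uniform(0.2, 1.0)
        labels = DBSCAN(eps=eps, min_samples=5).fit_predict(pts)
        core, comp, neighbours = _dbscan_oracle(pts, eps, 5)
        for i in range(30):
            if labels[i] == -1:
                # noise: not core and no core neighbour
                assert not core[i]
                assert not any(core[j] for j in neighbours[i])
            elif core[i]:
                # core partition must match exactly (up to label names)
                same = [j for j in range(30) if core[j] and comp[j] == comp[i]]
                sk_same = [j for j in same if labels[j] == labels[i]]
                assert sk_same == same
            else:
                # border point: attached to a cluster with a core neighbour
                assert any(core[j] and labels[j] == labels[i]
                           for j in neighbours[i])


def test_knee_epsilon_separates_scales():
    rng = np.random.default_rng(8)
    tight = rng.normal(0, 0.05, (30, 2))
    spread = rng.uniform(-5, 5, (10, 2))
    eps = knee_epsilon(np.vstack([tight, spread]), min_pts=5)
    assert 0.01 < eps < 5.0


# --------------------------------------------------------- similarity

def test_similarity_hand_enumerated_case():
    areas = pd.DataFrame({"seal_id": ["A", "A", "B", "B", "B"],
                          "v": [10.0, 12.0, 10.0, 11.0, 30.0]})
    res = {r.seal_id: r for r in similarity_indices(areas, "v")}
    # cross differences {0,1,20,2,1,18}; d = 2 -> 3 of 6 strictly smaller
    assert res["A"].pair_indices[0] == pytest.approx(0.5)


def test_similarity_zero_and_maximal_pairs():
    areas = pd.DataFrame({"seal_id": ["A", "A", "B", "B"],
                          "v": [5.0, 5.0, 5.2, 5.3]})
    res = {r.seal_id: r for r in similarity_indices(areas, "v")}
    assert res["A"].pair_indices[0] == 0.0           # d = 0: nothing smaller
    areas2 = pd.DataFrame({"seal_id": ["A", "A", "B", "B"],
                           "v": [0.0, 100.0, 49.0, 51.0]})
    res2 = {r.seal_id: r for r in similarity_indices(areas2, "v")}
    assert res2["A"].pair_indices[0] == 1.0


def test_similarity_invariance_under_affine_maps():
    rng = np.random.default_rng(9)
    areas = pd.DataFrame({
        "seal_id": np.repeat(["A", "B", "C"], 6),
        "v": rng.normal(10, 3, 18),
    })
    base = {r.seal_id: r.pair_indices for r in similarity_indices(areas, "v")}
    shifted = areas.assign(v=areas["v"] + 42.0)
    scaled = areas.assign(v=areas["v"] * 3.7)
    for variant in (shifted, scaled):
        out = {r.seal_id: r.pair_indices
               for r in similarity_indices(variant, "v")}
        for sid in base:
            np.testing.assert_allclose(out[sid], base[sid])
    for r in similarity_indices(areas, "v"):
        assert np.all((r.pair_indices >= 0) & (r.pair_indices <= 1))


def test_similarity_needs_two_seals():
    areas = pd.DataFrame({"seal_id": ["A", "A"], "v": [1.0, 2.0]})
    with pytest.raises(ValueError):
        similarity_indices(areas, "v")
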