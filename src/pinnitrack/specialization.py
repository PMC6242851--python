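"""Individual-specialization machinery: movement HMM, 3-day foraging areas
and pairwise environmental similarity indices.

A 3-state hidden Markov model (travelling / foraging / hauled out) is fit
to 2-hourly track positions: step lengths get zero-inflated gamma
emissions, turning angles von Mises emissions, and the state transition
probabilities depend on standardized activity covariates (proportion of
time diving and hauled out) through a multinomial logit.  The likelihood
is maximised directly (forward algorithm with scaling, numba-compiled)
from multiple restarts, as in the movement-ecology HMM tools this module
mirrors.

Foraging locations (Viterbi-decoded) are grouped into 3-day intervals; in
each interval a density cluster (DBSCAN, with the epsilon neighbourhood
chosen from the changepoint of the sorted k-nearest-neighbour mean
distances) picks the dominant foraging patch, and the member location
closest to the patch centroid becomes the interval's "foraging area".

The similarity index then compares, for each unordered pair of a seal's
foraging areas, the absolute difference of an environmental value (e.g.
distance to the glacier front) with the cross-differences between that
seal's areas and every other seal's areas: the index is the proportion of
cross-differences strictly smaller than the pair's difference.  Indices
near 0 mean the seal reuses environmentally similar sites (specialist);
near 1, sites as different from each other as from everyone else's
(generalist).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "MovementHMM", "fit_hmm", "label_states",
    "select_foraging_area", "extract_foraging_areas",
    "SimilarityResult", "similarity_indices", "knee_epsilon",
]

_ZERO_STEP = 1e-9


# ------------------------------------------------------------ numba cores

@njit(cache=True)
def _forward_scaled(delta, gammas, b):
    """Scaled forward algorithm.  gammas: (T-1, N, N); b: (T, N)."""
    T, N = b.shape
    alpha = delta * b[0]
    c = alpha.sum()
    if c <= 0:
        return -np.inf
    ll = np.log(c)
    alpha = alpha / c
    for t in range(1, T):
        new = np.zeros(N)
        for j in range(N):
            s = 0.0
            for i in range(N):
                s += alpha[i] * gammas[t - 1, i, j]
            new[j] = s * b[t, j]
        c = new.sum()
        if c <= 0:
            return -np.inf
        ll += np.log(c)
        alpha = new / c
    return ll


@njit(cache=True)
def _viterbi(delta, gammas, b):
    T, N = b.shape
    logb = np.log(b + 1e-300)
    loggam = np.log(gammas + 1e-300)
    v = np.log(delta + 1e-300) + logb[0]
    back = np.zeros((T, N), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(N)
        for j in range(N):
            best, arg = -np.inf, 0
            for i in range(N):
                s = v[i] + loggam[t - 1, i, j]
                if s > best:
                    best, arg = s, i
            new[j] = best + logb[t, j]
            back[t, j] = arg
        v = new
    path = np.zeros(T, dtype=np.int64)
    path[-1] = np.argmax(v)
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


# --------------------------------------------------------------- the HMM

def _gamma_logpdf(x, shape, rate):
    from scipy.special import gammaln
    return shape * np.log(rate) + (shape - 1.0) * np.log(x) - rate * x \
        - gammaln(shape)


def _vonmises_logpdf(x, mu, kappa):
    from scipy.special import i0e
    # log I0(kappa) = log i0e(kappa) + kappa  (overflow-safe)
    return kappa * np.cos(x - mu) - np.log(2.0 * np.pi) \
        - (np.log(i0e(kappa)) + kappa)


@dataclass
class HmmParams:
    """Unpacked parameters of the 3-state movement HMM."""

    step_mean: np.ndarray       # (N,) km
    step_sd: np.ndarray         # (N,)
    zero_prob: np.ndarray       # (N,) mass at step == 0
    angle_mean: np.ndarray      # (N,) radians
    angle_kappa: np.ndarray     # (N,)
    beta: np.ndarray            # (N*(N-1), 1 + n_cov) transition logits
    delta: np.ndarray = field(default_factory=lambda: np.full(3, 1 / 3))


class MovementHMM:
    """Covariate-driven 3-state HMM fitted by direct likelihood maximisation.

    Parameters are estimated by numerically maximising the forward-algorithm
    likelihood from ``n_restarts`` perturbed initialisations (deterministic
    under ``seed``).  Fitted attributes: ``params_``, ``log_likelihood_``,
    ``converged_``, ``covariate_mean_``, ``covariate_sd_``.
    """

    N_STATES = 3

    def __init__(self, n_restarts: int = 3, seed: int = 0, max_iter: int = 400):
        self.n_restarts = n_restarts
        self.seed = seed
        self.max_iter = max_iter

    # -- parameter packing ------------------------------------------------
    def _pack(self, p: HmmParams):
        return np.concatenate([
            np.log(p.step_mean), np.log(p.step_sd),
            np.log(p.zero_prob / (1.0 - p.zero_prob)),
            p.angle_mean, np.log(p.angle_kappa),
            p.beta.ravel(),
        ])

    def _unpack(self, vec, n_cov):
        N = self.N_STATES
        i = 0
        step_mean = np.exp(np.clip(vec[i:i + N], -12, 6)); i += N
        step_sd = np.exp(np.clip(vec[i:i + N], -12, 6)); i += N
        zero_prob = 1.0 / (1.0 + np.exp(-np.clip(vec[i:i + N], -30, 30))); i += N
        angle_mean = vec[i:i + N]; i += N
        angle_kappa = np.exp(np.clip(vec[i:i + N], -8, 6)); i += N
        beta = vec[i:].reshape(N * (N - 1), n_cov + 1)
        return HmmParams(step_mean, step_sd, zero_prob, angle_mean,
                         angle_kappa, beta)

    # -- model pieces -----------------------------------------------------
    def transition_matrices(self, params: HmmParams, covariates):
        """Per-interval transition matrices from the multinomial logit.

        Row i of each matrix: diagonal gets weight 1, off-diagonal (i -> j)
        weight exp(beta_ij . [1, covs]); rows normalised (sum to 1 at any
        covariate value).
        """
        X = np.column_stack([np.ones(len(covariates)), covariates])
        eta = X @ params.beta.T                      # (T, N*(N-1))
        N = self.N_STATES
        T = len(covariates)
        G = np.empty((T, N, N))
        k = 0
        for i in range(N):
            row = np.ones((T, N))
            for j in range(N):
                if j == i:
                    continue
                row[:, j] = np.exp(np.clip(eta[:, k], -30, 30))
                k += 1
            G[:, i, :] = row / row.sum(axis=1, keepdims=True)
        return G

    def emission_probs(self, params: HmmParams, steps, angles):
        """Per-time emission likelihoods b[t, state]."""
        T = len(steps)
        N = self.N_STATES
        b = np.empty((T, N))
        is_zero = steps <= _ZERO_STEP
        pos = ~is_zero
        ang_ok = ~np.isnan(angles)
        shape = (params.step_mean / params.step_sd) ** 2
        rate = params.step_mean / params.step_sd ** 2
        for s in range(N):
            col = np.empty(T)
            col[is_zero] = params.zero_prob[s]
            if pos.any():
                col[pos] = (1.0 - params.zero_prob[s]) * np.exp(
                    _gamma_logpdf(steps[pos], shape[s], rate[s]))
            if ang_ok.any():
                col[ang_ok] *= np.exp(_vonmises_logpdf(
                    angles[ang_ok], params.angle_mean[s], params.angle_kappa[s]))
            b[:, s] = col
        return np.maximum(b, 1e-300)

    def loglik(self, params: HmmParams, steps, angles, covariates):
        b = self.emission_probs(params, steps, angles)
        G = self.transition_matrices(params, covariates[1:])
        return float(_forward_scaled(params.delta, G, b))

    # -- fitting ----------------------------------------------------------
    def _initial_params(self, steps, n_cov, rng, perturb):
        pos = steps[steps > _ZERO_STEP]
        if pos.size == 0:
            raise ValueError("all steps are zero; emissions degenerate")
        q = np.quantile(pos, [0.35, 0.85])
        step_mean = np.array([q[1], q[0], max(pos.min() * 0.5, 1e-4)])
        step_sd = step_mean * 0.8
        zero_prob = np.array([0.01, 0.01, 0.5])
        angle_mean = np.array([0.0, np.pi, 0.0])
        angle_kappa = np.array([1.0, 0.7, 0.5])
        beta = np.zeros((self.N_STATES * 2, n_cov + 1))
        beta[:, 0] = -2.0
        p = HmmParams(step_mean, step_sd, zero_prob, angle_mean, angle_kappa, beta)
        vec = self._pack(p)
        if perturb:
            vec = vec + rng.normal(0.0, 0.3, vec.size)
        return vec

    def fit(self, steps, angles, covariates):
        """Fit to step lengths (km), turning angles (radians, NaN where
        undefined) and a (T, k) covariate matrix.

        Covariates are standardized internally (mean 0, sd 1); the fitted
        transition coefficients live on the standardized scale.
        """
        steps = np.asarray(steps, float)
        angles = np.asarray(angles, float)
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != steps.size:
            cov = cov.T
        if steps.size < 20:
            raise ValueError("HMM needs a reasonably long sequence")
        self.covariate_mean_ = cov.mean(axis=0)
        sd = cov.std(axis=0)
        self.covariate_sd_ = np.where(sd > 0, sd, 1.0)
        covz = (cov - self.covariate_mean_) / self.covariate_sd_
        n_cov = covz.shape[1]

        rng = np.random.default_rng(self.seed)
        best = None
        for r in range(self.n_restarts):
            x0 = self._initial_params(steps, n_cov, rng, perturb=r > 0)

            def nll(vec):
                p = self._unpack(vec, n_cov)
                ll = self.loglik(p, steps, angles, covz)
                return -ll if np.isfinite(ll) else 1e12

            res = minimize(nll, x0, method="L-BFGS-B",
                           options={"maxiter": self.max_iter, "ftol": 1e-9})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
            raise RuntimeError("HMM likelihood maximisation failed")
        self.params_ = self._unpack(best.x, n_cov)
        self.log_likelihood_ = -float(best.fun)
        self.converged_ = bool(best.success)
        self._train = (steps, angles, covz)
        return self

    def decode(self, steps=None, angles=None, covariates=None):
        """Viterbi state path (training data by default)."""
        if steps is None:
            steps, angles, covz = self._train
        else:
            covz = (np.atleast_2d(np.asarray(covariates, float))
                    - self.covariate_mean_) / self.covariate_sd_
            steps = np.asarray(steps, float)
            angles = np.asarray(angles, float)
        b = self.emission_probs(self.params_, steps, angles)
        G = self.transition_matrices(self.params_, covz[1:])
        return _viterbi(self.params_.delta, G, b)


def fit_hmm(steps, angles, covariates, n_restarts: int = 3,
            seed: int = 0) -> MovementHMM:
    """Functional wrapper: fit a :class:`MovementHMM` and return it."""
    return MovementHMM(n_restarts=n_restarts, seed=seed).fit(
        steps, angles, covariates)


def label_states(model: MovementHMM, states, hauled_covariate, steps):
    """Map HMM state indices to behavioural labels.

    The haul-out state has the highest mean hauled-out covariate along the
    decoded path; of the remaining two, foraging has the smaller mean step.
    Returns a dict ``{state_index: label}``.
    """
    states = np.asarray(states)
    hauled = np.asarray(hauled_covariate, float)
    steps = np.asarray(steps, float)
    N = model.N_STATES
    mean_haul = np.array([
        hauled[states == s].mean() if (states == s).any() else -np.inf
        for s in range(N)])
    if np.all(mean_haul[np.isfinite(mean_haul)] == 0):
        import warnings
        warnings.warn("hauled covariate is identically zero; "
                      "haul-out label assigned by argmax tie-break")
    haul_state = int(np.argmax(mean_haul))
    rest = [s for s in range(N) if s != haul_state]
    mean_step = np.array([
        steps[states == s].mean() if (states == s).any() else np.inf
        for s in rest])
    forage_state = rest[int(np.argmin(mean_step))]
    travel_state = [s for s in rest if s != forage_state][0]
    return {travel_state: "travelling", forage_state: "foraging",
            haul_state: "haulout"}


# ----------------------------------------------------- foraging areas

def knee_epsilon(points, min_pts: int = 5):
    """DBSCAN epsilon from the changepoint of sorted kNN mean distances.

    Each point's mean distance to its (min_pts - 1) nearest neighbours is
    computed, the values sorted ascending, and a single Gaussian
    mean-change changepoint located; epsilon is the value at the change.
    Falls back to the median when no significant change exists.
    """
    pts = np.asarray(points, float)
    k = min_pts - 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
    dist, _ = nn.kneighbors(pts)
    means = np.sort(dist[:, 1:].mean(axis=1))
    n = means.size
    if n < 4:
        return float(np.median(means))
    # at-most-one-change in mean, Gaussian cost, MBIC-style penalty
    css = np.cumsum(means)
    css2 = np.cumsum(means ** 2)
    sse0 = css2[-1] - css[-1] ** 2 / n
    best_k, best_sse = None, np.inf
    for kk in range(2, n - 1):
        left = css2[kk - 1] - css[kk - 1] ** 2 / kk
        rn = n - kk
        rsum = css[-1] - css[kk - 1]
        right = (css2[-1] - css2[kk - 1]) - rsum ** 2 / rn
        if left + right < best_sse:
            best_sse, best_k = left + right, kk
    if best_k is None or best_sse <= 0:
        return float(np.median(means))
    stat = n * np.log(max(sse0, 1e-300) / max(best_sse, 1e-300))
    if stat <= 3.0 * np.log(n):
        return float(np.median(means))
    return float(means[best_k])


def select_foraging_area(points, min_pts: int = 5):
    """One representative foraging location from a 3-day point set.

    Runs DBSCAN with the knee-selected epsilon, takes the largest cluster,
    and returns the member point closest to the cluster centroid (None when
    there are fewer than ``min_pts`` points or everything is noise).
    """
    pts = np.asarray(points, float)
    if len(pts) < min_pts:
        return None
    eps = knee_epsilon(pts, min_pts)
    if eps <= 0:
        eps = 1e-6
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(pts)
    good = labels >= 0
    if not good.any():
        return None
    counts = np.bincount(labels[good])
    biggest = int(np.argmax(counts))
    members = pts[labels == biggest]
    centroid = members.mean(axis=0)
    idx = int(np.argmin(np.sum((members - centroid) ** 2, axis=1)))
    return members[idx]


def extract_foraging_areas(times_h, xy, state_labels, interval_h: float = 72.0,
                           min_pts: int = 5) -> pd.DataFrame:
    """Per-3-day-interval foraging areas from a decoded 2-hourly track.

    ``state_labels`` is the per-position behavioural label sequence;
    positions labelled "foraging" are clustered within each interval.
    Returns a DataFrame (interval, x_km, y_km), at most one row per
    interval.
    """
    t = np.asarray(times_h, float)
    xy = np.asarray(xy, float)
    labels = np.asarray(state_labels, object)
    rows = []
    for b0 in np.arange(t.min(), t.max() + 1e-9, interval_h):
        sel = (t >= b0) & (t < b0 + interval_h) & (labels == "foraging")
        if sel.sum() < min_pts:
            continue
        area = select_foraging_area(xy[sel], min_pts=min_pts)
        if area is None:
            continue
        rows.append({"interval_start_h": float(b0),
                     "x_km": float(area[0]), "y_km": float(area[1])})
    return pd.DataFrame(rows, columns=["interval_start_h", "x_km", "y_km"])


# ----------------------------------------------------- similarity index

@dataclass
class SimilarityResult:
    seal_id: str
    variable: str
    pair_indices: np.ndarray     # one value per unordered within-seal pair
    mean_index: float


def similarity_indices(areas: pd.DataFrame, variable: str,
                       include_within_other: bool = False):
    """Pairwise environmental similarity index per seal (0 = specialist,
    1 = generalist).

    ``areas`` needs columns seal_id and ``variable``.  For each unordered
    pair of a focal seal's areas, the index is the proportion of reference
    differences strictly smaller than the pair's absolute difference; the
    reference set is the cross-differences between the focal seal's areas
    and all other seals' areas (optionally also the within-pair differences
    of the other seals).
    """
    if areas["seal_id"].nunique() < 2:
        raise ValueError("similarity indices need at least two seals")
    out = []
    for sid, grp in areas.groupby("seal_id"):
        vals = grp[variable].dropna().values
        if vals.size < 2:
            continue
        other = areas[areas["seal_id"] != sid]
        ref = np.abs(vals[:, None] - other[variable].dropna().values[None, :]).ravel()
        if include_within_other:
            extra = []
            for _, og in other.groupby("seal_id"):
                ov = og[variable].dropna().values
                extra.extend(abs(a - b) for a, b in combinations(ov, 2))
            ref = np.concatenate([ref, np.asarray(extra, float)])
        if ref.size == 0:
            raise ValueError(f"empty reference set for seal {sid}")
        idx = np.array([
            np.mean(ref < abs(a - b)) for a, b in combinations(vals, 2)])
        out.append(SimilarityResult(seal_id=sid, variable=variable,
                                    pair_indices=idx,
                                    mean_index=float(idx.mean())))
    return out
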