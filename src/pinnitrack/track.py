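"""Continuous-time correlated random walk (CTCRW) track model.

The model is the integrated Ornstein-Uhlenbeck velocity process: per planar
axis, velocity follows ``dv = -beta v dt + sigma dW`` and position is its
integral, observed at GPS fix times with independent Gaussian measurement
error (36 m by default).  beta (1/h) sets how quickly velocity
decorrelates, sigma (km/h^{3/2}) its diffusion scale; the stationary speed
scale per axis is ``sigma / sqrt(2 beta)``.

The exact discrete-time transition over a gap of length ``d`` is

    x' = x + v (1 - e^{-beta d}) / beta,     v' = v e^{-beta d}

with process covariance (per axis)

    Var(x') = (sigma^2/beta^2) (d - 2(1-e^{-bd})/b + (1-e^{-2bd})/(2b))
    Cov(x', v') = sigma^2 (1 - e^{-bd})^2 / (2 b^2)
    Var(v') = sigma^2 (1 - e^{-2bd}) / (2 b)

so the likelihood is computed exactly by a Kalman filter, and positions at
arbitrary times by the fixed-interval (RTS) smoother.  Reported haul-out
intervals act as a stopping model: within them the transition pins velocity
to zero and position constant, which keeps the hauled seal stationary in
both the filter and the smoother.

Both planar axes share (beta, sigma) and are conditionally independent, so
one 2-state filter propagates the two axes simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "CtcrwFit", "CtcrwModel", "fit_ctcrw", "predict_positions",
    "simulate_ctcrw_track", "TrackFitError",
]

_SIGMA_FLOOR = 1e-6
_JITTER = 1e-12


class TrackFitError(RuntimeError):
    """CTCRW fitting failed; carries the best parameters found so far."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class CtcrwFit:
    """Fitted CTCRW parameters for one seal."""

    beta: float            # velocity autocorrelation, 1/h
    sigma: float           # velocity diffusion scale, km/h^1.5
    error_sd_m: float
    log_likelihood: float
    converged: bool
    n_fixes: int


def _q11_bracket(b, d):
    """d - 2(1-e^{-bd})/b + (1-e^{-2bd})/(2b), cancellation-safe.

    The direct formula loses all precision for small b*d (the bracket is
    O(b^2 d^3) from terms of size d); a series expansion takes over there.
    """
    bd = b * d
    if np.ndim(bd) == 0:
        if bd < 1e-3:
            return b ** 2 * d ** 3 / 3.0 - b ** 3 * d ** 4 / 4.0 \
                + 7.0 * b ** 4 * d ** 5 / 60.0
        return d + 2.0 * np.expm1(-bd) / b - np.expm1(-2.0 * bd) / (2.0 * b)
    small = bd < 1e-3
    series = b ** 2 * d ** 3 / 3.0 - b ** 3 * d ** 4 / 4.0 \
        + 7.0 * b ** 4 * d ** 5 / 60.0
    direct = d + 2.0 * np.expm1(-bd) / b - np.expm1(-2.0 * bd) / (2.0 * b)
    return np.where(small, series, direct)


def _iou_matrices(beta, sigma, d):
    """Transition F and process covariance Q over a gap d (hours)."""
    b = beta
    one_me = -np.expm1(-b * d)            # 1 - e^{-bd}, accurate for small bd
    e = 1.0 - one_me
    F = np.array([[1.0, one_me / b], [0.0, e]])
    q11 = (sigma ** 2 / b ** 2) * _q11_bracket(b, d)
    q12 = sigma ** 2 * one_me ** 2 / (2.0 * b ** 2)
    q22 = -sigma ** 2 * np.expm1(-2.0 * b * d) / (2.0 * b)
    Q = np.array([[q11, q12], [q12, q22]])
    return F, Q


_F_HAUL = np.array([[1.0, 0.0], [0.0, 0.0]])
_Q_HAUL = np.eye(2) * _JITTER


def _build_grid(obs_t, extra_t, haulouts):
    """Union time grid with per-segment hauled flags and obs indices."""
    times = set(np.round(np.asarray(obs_t, float), 9))
    times.update(np.round(np.asarray(extra_t, float), 9))
    for a, b in haulouts:
        times.add(round(float(a), 9))
        times.add(round(float(b), 9))
    grid = np.array(sorted(times))
    mids = (grid[:-1] + grid[1:]) / 2.0
    hauled_seg = np.zeros(mids.size, bool)
    for a, b in haulouts:
        hauled_seg |= (mids > a) & (mids < b)
    obs_idx = {round(float(t), 9): k for k, t in enumerate(np.round(obs_t, 9))}
    return grid, hauled_seg, obs_idx


def _filter_loglik(beta, sigma, dts, hauled_seg, obs_slot, zx, zy, r_var):
    """Scalar-form Kalman log-likelihood (fast path used by the optimiser).

    ``dts`` are inter-grid gaps (h), ``obs_slot[k]`` the observation index
    at grid node k or -1.  Exactly equivalent to the matrix filter.
    """
    b = beta
    one_me = -np.expm1(-b * dts)
    e1 = 1.0 - one_me
    f12 = one_me / b
    q11 = (sigma ** 2 / b ** 2) * _q11_bracket(b, dts)
    q12 = sigma ** 2 * one_me ** 2 / (2.0 * b ** 2)
    q22 = -sigma ** 2 * np.expm1(-2.0 * b * dts) / (2.0 * b)
    # haul-out segments: velocity zeroed, position frozen
    f12 = np.where(hauled_seg, 0.0, f12)
    e1 = np.where(hauled_seg, 0.0, e1)
    q11 = np.where(hauled_seg, _JITTER, q11)
    q12 = np.where(hauled_seg, 0.0, q12)
    q22 = np.where(hauled_seg, _JITTER, q22)

    mx_p, my_p = zx[0], zy[0]
    mx_v = my_v = 0.0
    p11, p12, p22 = 1.0e4, 0.0, max(sigma ** 2 / (2.0 * b), 1e-8)
    ll = 0.0
    log2pi = np.log(2.0 * np.pi)
    n = dts.size + 1
    for k in range(n):
        if k > 0:
            a, c = f12[k - 1], e1[k - 1]
            mx_p, mx_v = mx_p + a * mx_v, c * mx_v
            my_p, my_v = my_p + a * my_v, c * my_v
            t11 = p11 + 2.0 * a * p12 + a * a * p22 + q11[k - 1]
            t12 = c * (p12 + a * p22) + q12[k - 1]
            t22 = c * c * p22 + q22[k - 1]
            p11, p12, p22 = t11, t12, t22
        j = obs_slot[k]
        if j >= 0:
            S = p11 + r_var
            if not (S > 0.0) or not np.isfinite(S):
                return -np.inf
            vx = zx[j] - mx_p
            vy = zy[j] - my_p
            k1, k2 = p11 / S, p12 / S
            mx_p += k1 * vx
            mx_v += k2 * vx
            my_p += k1 * vy
            my_v += k2 * vy
            p22 -= k2 * p12
            p12 -= k1 * p12
            p11 -= k1 * p11
            ll += -0.5 * (2.0 * (log2pi + np.log(S)) + (vx * vx + vy * vy) / S)
    return ll


def _kalman(beta, sigma, grid, hauled_seg, obs_idx, obs_xy, r_var,
            smooth=False):
    """Shared-parameter two-axis Kalman filter (and optional RTS smoother).

    Returns (loglik, means, covs) where means is (n, 2, 2): state
    (position, velocity) per axis; covs is the per-axis 2x2 covariance
    (identical for both axes).
    """
    n = grid.size
    m = np.zeros((2, 2))            # state x axes
    # diffuse-ish init centred on the first fix
    first = obs_xy[0]
    m[0, :] = first
    P = np.diag([1.0e4, np.maximum(sigma ** 2 / (2 * beta), 1e-8)])
    ll = 0.0
    ms = np.empty((n, 2, 2))
    Ps = np.empty((n, 2, 2))
    Fs = np.empty((n, 2, 2))
    mp = np.empty((n, 2, 2))
    Pp = np.empty((n, 2, 2))

    Fs[0] = np.eye(2)
    for k in range(n):
        if k > 0:
            d = grid[k] - grid[k - 1]
            if hauled_seg[k - 1]:
                F, Q = _F_HAUL, _Q_HAUL
            else:
                F, Q = _iou_matrices(beta, sigma, d)
            m = F @ m
            P = F @ P @ F.T + Q
            Fs[k] = F
        mp[k], Pp[k] = m, P

        idx = obs_idx.get(round(float(grid[k]), 9))
        if idx is not None:
            # H = [1, 0] on each axis; shared scalar innovation variance
            r = max(r_var, _JITTER)
            S = max(P[0, 0], 0.0) + r
            v = obs_xy[idx] - m[0, :]
            K = P[:, 0] / S
            m = m + np.outer(K, v)
            # Joseph form keeps P positive semi-definite even when the
            # measurement noise is orders of magnitude below the state scale
            IKH = np.eye(2)
            IKH[:, 0] -= K
            P = IKH @ P @ IKH.T + r * np.outer(K, K)
            P = (P + P.T) / 2.0
            ll += -0.5 * (2.0 * np.log(2.0 * np.pi * S) + (v @ v) / S)
        ms[k], Ps[k] = m, P

    if not smooth:
        return ll, ms, Ps
    # RTS smoother
    for k in range(n - 2, -1, -1):
        Ppred = Pp[k + 1] + np.eye(2) * _JITTER
        J = Ps[k] @ Fs[k + 1].T @ np.linalg.inv(Ppred)
        ms[k] = ms[k] + J @ (ms[k + 1] - mp[k + 1])
        Ps[k] = Ps[k] + J @ (Ps[k + 1] - Pp[k + 1]) @ J.T
    return ll, ms, Ps


def _prepare(times_h, xy, haulouts):
    t = np.asarray(times_h, float)
    xy = np.asarray(xy, float)
    order = np.argsort(t, kind="stable")
    t, xy = t[order], xy[order]
    keep = np.concatenate([[True], np.diff(t) > 1e-9])
    return t[keep], xy[keep]


class CtcrwModel:
    """CTCRW fitted by exact maximum likelihood.

    Parameters
    ----------
    error_sd_m : float
        GPS measurement error standard deviation per axis, metres.
    n_restarts : int
        Random restarts around the moment-based initialisation.
    seed : int
        Seed for the restart perturbations (fitting is deterministic).
    """

    def __init__(self, error_sd_m: float = 36.0, n_restarts: int = 5,
                 seed: int = 0, tol: float = 1e-6):
        self.error_sd_m = error_sd_m
        self.n_restarts = n_restarts
        self.seed = seed
        self.tol = tol

    def fit(self, times_h, xy, haulouts=()):
        """Fit (beta, sigma) to fixes at ``times_h`` (hours) / ``xy`` (km).

        ``haulouts`` is a sequence of (start_h, end_h) intervals during
        which the seal is pinned in place.
        """
        t, z = _prepare(times_h, xy, haulouts)
        if t.size < 10:
            raise TrackFitError(f"need >= 10 distinct fixes, got {t.size}")
        if t[-1] - t[0] <= 24.0:
            raise TrackFitError("fixes must span more than 24 h")
        grid, hauled_seg, obs_idx = _build_grid(t, [], haulouts)
        r_var = (self.error_sd_m / 1000.0) ** 2
        dts = np.diff(grid)
        obs_slot = np.full(grid.size, -1, dtype=np.int64)
        for k, g in enumerate(grid):
            obs_slot[k] = obs_idx.get(round(float(g), 9), -1)
        zx, zy = z[:, 0], z[:, 1]

        # moment-based initial guess from empirical hourly velocities
        dt = np.diff(t)
        vel = np.linalg.norm(np.diff(z, axis=0), axis=1) / np.maximum(dt, 1e-3)
        v_scale = max(np.median(vel) / np.sqrt(2.0), 1e-3)
        beta0, sigma0 = 1.0, v_scale * np.sqrt(2.0)

        def nll(p):
            beta = np.exp(np.clip(p[0], -8.0, 6.0))
            sigma = max(np.exp(np.clip(p[1], -14.0, 6.0)), _SIGMA_FLOOR)
            ll = _filter_loglik(beta, sigma, dts, hauled_seg, obs_slot,
                                zx, zy, r_var)
            return -ll if np.isfinite(ll) else 1e12

        rng = np.random.default_rng(self.seed)
        best = None
        x0s = [np.array([np.log(beta0), np.log(sigma0)])]
        x0s += [x0s[0] + rng.normal(0.0, 1.0, 2) for _ in range(self.n_restarts - 1)]
        for x0 in x0s:
            res = minimize(nll, x0, method="Nelder-Mead",
                           options={"xatol": 1e-5, "fatol": self.tol, "maxiter": 400})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise TrackFitError("CTCRW likelihood maximisation failed", best)

        self.fit_ = CtcrwFit(
            beta=float(np.exp(best.x[0])),
            sigma=float(max(np.exp(best.x[1]), _SIGMA_FLOOR)),
            error_sd_m=self.error_sd_m,
            log_likelihood=float(-best.fun),
            converged=bool(best.success),
            n_fixes=int(t.size),
        )
        self._obs = (t, z)
        self._haulouts = [(float(a), float(b)) for a, b in haulouts]
        return self

    def predict(self, times_h) -> pd.DataFrame:
        """Smoothed positions at the requested times (hours).

        Returns a DataFrame with time_h, x_km, y_km, sd_km (per-axis
        posterior sd) and a hauled flag.  Times must lie within
        [first fix - 6 h, last fix + 6 h].
        """
        if not hasattr(self, "fit_"):
            raise RuntimeError("model is not fitted")
        t_obs, z = self._obs
        req = np.atleast_1d(np.asarray(times_h, float))
        lo, hi = t_obs[0] - 6.0, t_obs[-1] + 6.0
        bad = req[(req < lo) | (req > hi)]
        if bad.size:
            raise ValueError(f"prediction times outside [{lo}, {hi}] h: {bad[:5]}")
        grid, hauled_seg, obs_idx = _build_grid(t_obs, req, self._haulouts)
        r_var = (self.fit_.error_sd_m / 1000.0) ** 2
        r_var = max(r_var, _JITTER)
        _, ms, Ps = _kalman(self.fit_.beta, self.fit_.sigma, grid, hauled_seg,
                            obs_idx, z, r_var, smooth=True)
        pos = {round(float(g), 9): k for k, g in enumerate(grid)}
        rows = np.array([pos[round(float(tt), 9)] for tt in req])
        hauled = np.zeros(req.size, bool)
        for a, b in self._haulouts:
            hauled |= (req >= a) & (req <= b)
        return pd.DataFrame({
            "time_h": req,
            "x_km": ms[rows, 0, 0],
            "y_km": ms[rows, 0, 1],
            "sd_km": np.sqrt(np.maximum(Ps[rows, 0, 0], 0.0)),
            "hauled": hauled,
        })


def fit_ctcrw(times_h, xy, haulouts=(), error_sd_m: float = 36.0,
              n_restarts: int = 5, seed: int = 0) -> CtcrwModel:
    """Functional wrapper: fit a :class:`CtcrwModel` and return it."""
    return CtcrwModel(error_sd_m=error_sd_m, n_restarts=n_restarts,
                      seed=seed).fit(times_h, xy, haulouts)


def predict_positions(model: CtcrwModel, times_h) -> pd.DataFrame:
    return model.predict(times_h)


def simulate_ctcrw_track(beta, sigma, times_h, seed=0, error_sd_m=36.0,
                         start_xy=(0.0, 0.0)):
    """Simulate fixes from the exact CTCRW discretisation (for recovery
    tests and calibration studies).  Returns (true_xy, observed_xy)."""
    rng = np.random.default_rng(seed)
    t = np.asarray(times_h, float)
    n = t.size
    state = np.zeros((2, 2))
    state[0, :] = start_xy
    # stationary velocity draw
    state[1, :] = rng.normal(0.0, sigma / np.sqrt(2.0 * beta), 2)
    out = np.empty((n, 2))
    out[0] = state[0]
    for k in range(1, n):
        F, Q = _iou_matrices(beta, sigma, t[k] - t[k - 1])
        L = np.linalg.cholesky(Q + np.eye(2) * 1e-15)
        state = F @ state + L @ rng.normal(size=(2, 2))
        out[k] = state[0]
    obs = out + rng.normal(0.0, error_sd_m / 1000.0, out.shape)
    return out, obs
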