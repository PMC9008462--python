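"""Per-trajectory statistics, windowed instantaneous velocity, and
maximum-likelihood diffusion estimation with localization error.

For a trajectory of N measured positions {p_i} at times {t_i}:

    d_net  = ||p_N - p_1||                       net displacement, um
    d_max  = max_{i,j} ||p_i - p_j||             maximum displacement, um
    s_net  = d_net / (t_N - t_1)                 net speed, um/s
    s_mean = mean_i ||p_{i+1} - p_i|| / dt_i     mean curvilinear speed, um/s
    r_lin  = s_net / s_mean                      linearity of forward
                                                 progression, in [0, 1]

The diffusion constant is the maximizer of the Gaussian increment
likelihood with per-localization static error: each per-axis increment
d_i = x_{i+1} - x_i has variance ``2 D dt_i + s_i^2 + s_{i+1}^2``.  By
default increments are treated as independent (the -s^2 covariance between
consecutive increments is neglected); ``covariance="tridiagonal"`` uses the
full banded covariance instead.  Confidence intervals come from the
profile likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial.distance import pdist

__all__ = ["TrajectoryStats", "VelocityProfile", "compute_track_stats",
           "instantaneous_velocity", "estimate_diffusion", "stats_table"]


@dataclass
class TrajectoryStats:
    d_net: float
    d_max: float
    s_net: float
    s_mean: float
    r_lin: float
    n_localizations: int
    duration_s: float
    D: Optional[float] = None
    D_ci: Optional[tuple[float, float]] = None


def compute_track_stats(xy_um: np.ndarray, t_s: np.ndarray,
                        max_gap_s: float | None = None) -> TrajectoryStats:
    """The six trajectory statistics (diffusion filled in separately).

    ``max_gap_s``: increments spanning longer than this (blink gaps bridged
    by the linker) are excluded from the mean curvilinear speed so that
    bridged dark periods do not dilute it; displacement statistics always
    use the true time differences.
    """
    xy = np.asarray(xy_um, float).reshape(-1, 2)
    t = np.asarray(t_s, float)
    if len(xy) < 2:
        raise ValueError("need >= 2 localizations")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    d_net = float(np.hypot(*(xy[-1] - xy[0])))
    d_max = float(pdist(xy).max())
    duration = float(t[-1] - t[0])
    s_net = d_net / duration
    step = np.hypot(*np.diff(xy, axis=0).T)
    speeds = step / dt
    if max_gap_s is not None:
        keep = dt <= max_gap_s
        speeds = speeds[keep] if keep.any() else speeds
    s_mean = float(np.mean(speeds))
    r_lin = s_net / s_mean if s_mean > 0 else 0.0
    return TrajectoryStats(d_net=d_net, d_max=d_max, s_net=s_net,
                           s_mean=s_mean, r_lin=float(r_lin),
                           n_localizations=len(xy), duration_s=duration)


@dataclass
class VelocityProfile:
    """Windowed velocity estimate at every localization of a track."""

    frames: np.ndarray
    t_s: np.ndarray
    vx: np.ndarray          # um/s
    vy: np.ndarray
    speed: np.ndarray
    support: np.ndarray     # points in each window

    def __len__(self):
        return len(self.frames)


def instantaneous_velocity(xy_um: np.ndarray, t_s: np.ndarray,
                           frames: np.ndarray | None = None,
                           window: int = 7,
                           min_support: int = 4) -> VelocityProfile:
    """Sliding-window linear-fit velocity at each localization.

    At every localization, x(t) and y(t) over the ``window`` localizations
    centered there are fit by least squares; the fitted slopes are the
    velocity components.  Near the ends the window truncates down to
    ``min_support`` points (the support is recorded); tracks shorter than
    ``min_support`` yield an empty profile.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    xy = np.asarray(xy_um, float).reshape(-1, 2)
    t = np.asarray(t_s, float)
    n = len(xy)
    if frames is None:
        frames = np.arange(n)
    if n < min_support:
        e = np.array([])
        return VelocityProfile(e.astype(int), e, e, e, e, e.astype(int))
    half = window // 2
    vx = np.empty(n)
    vy = np.empty(n)
    support = np.empty(n, dtype=int)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        while hi - lo < min_support:  # extend a truncated end window
            if lo > 0:
                lo -= 1
            elif hi < n:
                hi += 1
        tw = t[lo:hi]
        tc = tw - tw.mean()
        denom = float(np.sum(tc * tc))
        vx[i] = float(np.sum(tc * xy[lo:hi, 0])) / denom
        vy[i] = float(np.sum(tc * xy[lo:hi, 1])) / denom
        support[i] = hi - lo
    return VelocityProfile(np.asarray(frames), t, vx, vy,
                           np.hypot(vx, vy), support)


# ---------------------------------------------------------------------------
# Diffusion MLE with static localization error


def _nll_independent(D, d, dt, var_loc):
    v = 2.0 * D * dt + var_loc
    return 0.5 * float(np.sum(np.log(2 * math.pi * v) + d * d / v))


def _nll_tridiagonal(D, d, dt, sig2):
    """Exact Gaussian NLL with the -sigma^2 increment covariance band."""
    from scipy.linalg import cholesky_banded, solve_banded
    n = len(d)
    diag = 2.0 * D * dt + sig2[:-1] + sig2[1:]
    off = -sig2[1:-1]
    ab = np.zeros((2, n))
    ab[0, 1:] = off
    ab[1, :] = diag
    try:
        L = cholesky_banded(ab, lower=False)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * float(np.sum(np.log(L[1])))
    x = solve_banded((1, 1), _band_to_full_ab(ab), d)
    return 0.5 * (logdet + float(d @ x) + n * math.log(2 * math.pi))


def _band_to_full_ab(ab_upper):
    n = ab_upper.shape[1]
    full = np.zeros((3, n))
    full[0, 1:] = ab_upper[0, 1:]
    full[1] = ab_upper[1]
    full[2, :-1] = ab_upper[0, 1:]
    return full


def estimate_diffusion(xy_um: np.ndarray, t_s: np.ndarray,
                       precision_um: np.ndarray | float = 0.0,
                       covariance: str = "independent",
                       d_max: float = 50.0):
    """MLE of the diffusion constant (um^2/s) with 95% profile-likelihood CI.

    Both axes contribute increments.  ``precision_um`` is the per-
    localization static error (scalar or per-point per-axis array of shape
    (n,) or (n, 2)).  Returns ``(D_hat, (lo, hi))``; a track with zero
    increments and zero error returns ``(0.0, (0.0, 0.0))``.
    """
    xy = np.asarray(xy_um, float).reshape(-1, 2)
    t = np.asarray(t_s, float)
    n = len(xy)
    if n < 11:
        raise ValueError("need >= 10 increments")
    prec = np.asarray(precision_um, float)
    if prec.ndim == 0:
        prec = np.full((n, 2), float(prec))
    elif prec.ndim == 1:
        prec = np.stack([prec, prec], axis=1)
    dt = np.diff(t)

    def total_nll(D):
        s = 0.0
        for ax in range(2):
            d = np.diff(xy[:, ax])
            sig2 = prec[:, ax] ** 2
            if covariance == "tridiagonal":
                s += _nll_tridiagonal(D, d, dt, sig2)
            else:
                s += _nll_independent(D, d, dt, sig2[:-1] + sig2[1:])
        return s

    if np.allclose(np.diff(xy, axis=0), 0) and np.allclose(prec, 0):
        return 0.0, (0.0, 0.0)
    if np.allclose(prec, 0):
        lo_bound = 1e-12
    else:
        lo_bound = 0.0
    res = optimize.minimize_scalar(total_nll, bounds=(lo_bound, d_max),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    d_hat = float(res.x)
    if d_hat < 1e-9:
        d_hat = 0.0 if total_nll(0.0 + 1e-15) <= res.fun + 1e-9 else d_hat
    # 95% profile-likelihood interval: nll(D) - nll(D_hat) = 1.92
    nll_min = total_nll(max(d_hat, lo_bound))
    target = nll_min + 1.92

    def shifted(D):
        return total_nll(D) - target

    lo = 0.0
    if d_hat > lo_bound and shifted(lo_bound) > 0:
        lo = float(optimize.brentq(shifted, lo_bound, max(d_hat, 1e-12)))
    hi = d_max
    if shifted(d_max) > 0:
        hi = float(optimize.brentq(shifted, max(d_hat, lo_bound), d_max))
    return d_hat, (lo, hi)


def velocity_table(tracks: pd.DataFrame, window: int = 7) -> pd.DataFrame:
    """Windowed instantaneous velocity for every localization of every
    track: track_id, frame, vx, vy, speed, support."""
    rows = []
    for tid, sub in tracks.groupby("track_id"):
        sub = sub.sort_values("frame")
        vp = instantaneous_velocity(sub[["x_um", "y_um"]].to_numpy(),
                                    sub["t_s"].to_numpy(),
                                    frames=sub["frame"].to_numpy(),
                                    window=window)
        for i in range(len(vp)):
            rows.append((tid, int(vp.frames[i]), vp.vx[i], vp.vy[i],
                         vp.speed[i], int(vp.support[i])))
    return pd.DataFrame(rows, columns=["track_id", "frame", "vx_um_s",
                                       "vy_um_s", "speed_um_s", "support"])


def stats_table(tracks: pd.DataFrame, max_gap_s: float | None = None,
                estimate_d: bool = True) -> pd.DataFrame:
    """One row of trajectory statistics per track in a linked table.

    ``tracks`` needs columns track_id, frame, t_s (or frame times are
    derived from frame index), x_um, y_um, optionally precision columns.
    """
    rows = []
    for tid, sub in tracks.groupby("track_id"):
        sub = sub.sort_values("frame")
        xy = sub[["x_um", "y_um"]].to_numpy()
        t = sub["t_s"].to_numpy()
        st = compute_track_stats(xy, t, max_gap_s=max_gap_s)
        d_hat, ci = (None, (None, None))
        if estimate_d and len(sub) >= 11:
            prec = 0.0
            if {"precision_x_um", "precision_y_um"} <= set(sub.columns):
                prec = sub[["precision_x_um", "precision_y_um"]].to_numpy()
            d_hat, ci = estimate_diffusion(xy, t, prec)
        rows.append({"track_id": tid, "n_localizations": st.n_localizations,
                     "duration_s": st.duration_s, "d_net_um": st.d_net,
                     "d_max_um": st.d_max, "s_net_um_s": st.s_net,
                     "s_mean_um_s": st.s_mean, "r_lin": st.r_lin,
                     "D_um2_s": d_hat, "D_ci_lo": ci[0], "D_ci_hi": ci[1]})
    return pd.DataFrame(rows)
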