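"""Spot detection and sub-pixel localization.

Candidate emitters are enhanced with a difference-of-Gaussians (DoG)
bandpass, picked as strict local maxima above threshold, and refined by
maximum-likelihood fitting of a pixel-integrated symmetric Gaussian PSF
under a Poisson photon-counting model.  Each accepted localization carries
a CRLB-based precision (square root of the inverse Fisher information at
the optimum) and a fit-quality statistic (Poisson deviance: twice the
log-likelihood ratio of the saturated model to the fit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import erf

from .camera import CameraModel

__all__ = ["DetectionConfig", "Localization", "dog_filter", "find_candidates",
           "fit_spot_mle", "filter_localizations", "detect_movie",
           "count_fixed_stack"]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable knobs of the detection stage.

    ``candidate_threshold`` is in DoG-response units; when ``None`` it is
    set per frame to ``threshold_nsigma`` robust standard deviations of the
    response (1.4826 * MAD).  ``max_fit_quality`` bounds the Poisson
    deviance of an acceptable fit; note that EM excess noise roughly doubles
    the deviance expected for an ideal Poisson detector.
    """

    dog_sigma_small: float = 1.0
    dog_sigma_large: float = 2.0
    candidate_threshold: Optional[float] = None
    threshold_nsigma: float = 5.0
    fit_window: int = 9
    psf_sigma: float = 1.3
    min_photons: float = 100.0
    max_fit_quality: float = 500.0
    merge_radius_px: float = 2.0

    def __post_init__(self):
        if not self.dog_sigma_small < self.dog_sigma_large:
            raise ValueError("dog_sigma_small must be < dog_sigma_large")
        if self.fit_window < 5 or self.fit_window % 2 == 0:
            raise ValueError("fit_window must be odd and >= 5")


@dataclass
class Localization:
    """One fitted emitter in one frame (pixel units internally)."""

    frame: int
    x_px: float
    y_px: float
    photons: float
    background: float
    precision_x_px: float
    precision_y_px: float
    fit_quality: float
    accepted: bool = True
    reject_reason: str = ""


def dog_filter(image: np.ndarray, sigma_small: float,
               sigma_large: float) -> np.ndarray:
    """Difference-of-Gaussians bandpass; mirror boundaries, DC-free."""
    img = np.asarray(image, float)
    return (ndimage.gaussian_filter(img, sigma_small, mode="mirror")
            - ndimage.gaussian_filter(img, sigma_large, mode="mirror"))


def find_candidates(response: np.ndarray, threshold: float):
    """Strict 8-neighbourhood local maxima with response above threshold.

    Plateaus (exact ties) keep only the smallest (row, col).  Returns an
    ``(n, 2)`` int array of (row, col) pixel positions.
    """
    r = np.asarray(response, float)
    footprint = np.ones((3, 3), bool)
    maxf = ndimage.maximum_filter(r, footprint=footprint, mode="mirror")
    is_max = (r >= maxf) & (r > threshold)
    ys, xs = np.nonzero(is_max)
    out = []
    for y, x in zip(ys, xs):
        # strictness + deterministic plateau tie-break to smallest (row, col)
        nb = r[max(0, y - 1):y + 2, max(0, x - 1):x + 2]
        ties = np.argwhere(nb == r[y, x])
        ty, tx = ties[0]
        if (max(0, y - 1) + ty, max(0, x - 1) + tx) == (y, x):
            out.append((y, x))
    return np.asarray(out, dtype=int).reshape(-1, 2)


# ---------------------------------------------------------------------------
# Integrated-Gaussian Poisson MLE


def _pixel_profiles(n: int, c: float, sigma: float):
    """Integrated 1D Gaussian over pixels 0..n-1 and its derivative in c."""
    s = math.sqrt(2.0) * sigma
    edges = np.arange(n + 1)
    e = erf((edges - c) / s)
    prof = 0.5 * (e[1:] - e[:-1])
    g = np.exp(-((edges - c) / s) ** 2) / (s * math.sqrt(math.pi))
    dprof = g[:-1] - g[1:]
    return prof, dprof


def _model_and_grads(theta, shape, sigma):
    x, y, n_ph, bg = theta
    h, w = shape
    ex, dex = _pixel_profiles(w, x, sigma)
    ey, dey = _pixel_profiles(h, y, sigma)
    P = np.outer(ey, ex)
    mu = n_ph * P + bg
    dmu_dx = n_ph * np.outer(ey, dex)
    dmu_dy = n_ph * np.outer(dey, ex)
    return mu, (dmu_dx, dmu_dy, P, np.ones_like(P))


def _nll_and_grad(theta, data, sigma):
    mu, grads = _model_and_grads(theta, data.shape, sigma)
    mu = np.maximum(mu, 1e-12)
    nll = float(np.sum(mu - data * np.log(mu)))
    ratio = 1.0 - data / mu
    g = np.array([float(np.sum(ratio * d)) for d in grads])
    return nll, g


def _crlb(theta, shape, sigma):
    """Per-parameter CRLB standard deviations from the Fisher information."""
    mu, grads = _model_and_grads(theta, shape, sigma)
    mu = np.maximum(mu, 1e-12)
    J = np.stack([g.ravel() for g in grads])
    fisher = (J / mu.ravel()) @ J.T
    try:
        cov = np.linalg.inv(fisher)
        d = np.diag(cov)
        if np.any(d <= 0):
            raise np.linalg.LinAlgError
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        return np.full(4, np.nan)


def _deviance(data, mu):
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(data > 0, data * np.log(data / mu), 0.0)
    return float(2.0 * np.sum(mu - data + term))


def fit_spot_mle(window: np.ndarray, psf_sigma: float,
                 initial_center: tuple[float, float] | None = None,
                 frame: int = 0, max_iter: int = 50) -> Localization:
    """Fit one spot in a photon-unit window by Poisson maximum likelihood.

    Parameters are (x, y, photons, background) of a pixel-integrated
    symmetric Gaussian; ``initial_center`` is (x, y) in window pixel units
    (defaults to the window center).  Non-convergence or a degenerate
    Fisher information yields a rejected record.
    """
    data = np.asarray(window, float)
    h, w = data.shape
    border = np.concatenate([data[0], data[-1], data[1:-1, 0], data[1:-1, -1]])
    bg0 = max(float(np.median(border)), 1e-3)
    n0 = max(float(data.sum() - bg0 * data.size), 10.0)
    if initial_center is None:
        # background-subtracted centroid
        excess = np.maximum(data - bg0, 0.0)
        tot = excess.sum()
        if tot > 0:
            ys, xs = np.mgrid[0:h, 0:w]
            initial_center = (float(((xs + 0.5) * excess).sum() / tot),
                              float(((ys + 0.5) * excess).sum() / tot))
        else:
            initial_center = (w / 2.0, h / 2.0)
    x0, y0 = initial_center
    theta0 = np.array([x0, y0, n0, bg0])
    theta, converged = _fisher_scoring(theta0, data, psf_sigma, max_iter)
    if not converged:
        # damped-Newton failure: fall back to a quasi-Newton line search
        bounds = [(0.0, float(w)), (0.0, float(h)), (1e-3, None),
                  (0.0, None)]
        res = optimize.minimize(
            _nll_and_grad, theta0, args=(data, psf_sigma), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 3 * max_iter, "ftol": 1e-11, "gtol": 1e-7})
        theta = res.x
        converged = res.success or res.status == 1
    x, y, n_ph, bg = theta
    mu, _ = _model_and_grads(theta, data.shape, psf_sigma)
    quality = _deviance(data, mu)
    crlb = _crlb(theta, data.shape, psf_sigma)
    loc = Localization(frame=frame, x_px=float(x), y_px=float(y),
                       photons=float(n_ph), background=float(bg),
                       precision_x_px=float(crlb[0]),
                       precision_y_px=float(crlb[1]),
                       fit_quality=quality)
    if not converged:
        loc.accepted = False
        loc.reject_reason = "no convergence"
    elif not np.isfinite(crlb[:2]).all():
        loc.accepted = False
        loc.reject_reason = "degenerate Fisher information"
    return loc


def _fisher_scoring(theta0, data, sigma, max_iter, tol_px=1e-4):
    """Damped Fisher-scoring ascent of the Poisson log-likelihood.

    The expected information matrix is positive definite wherever the
    model is non-degenerate, so the scoring step is an ascent direction;
    a simple backtracking line search plus positivity/box clamps make the
    iteration robust.  Converged when the position moves < ``tol_px``.
    """
    h, w = data.shape
    theta = np.asarray(theta0, float).copy()
    nll, grad = _nll_and_grad(theta, data, sigma)
    for _ in range(max_iter):
        mu, grads = _model_and_grads(theta, data.shape, sigma)
        mu = np.maximum(mu, 1e-12)
        J = np.stack([g.ravel() for g in grads])
        fisher = (J / mu.ravel()) @ J.T
        try:
            step = np.linalg.solve(fisher + 1e-9 * np.eye(4), -grad)
        except np.linalg.LinAlgError:
            return theta, False
        scale = 1.0
        for _ in range(8):
            cand = theta + scale * step
            cand[0] = np.clip(cand[0], 0.0, w)
            cand[1] = np.clip(cand[1], 0.0, h)
            cand[2] = max(cand[2], 1e-3)
            cand[3] = max(cand[3], 0.0)
            cand_nll, cand_grad = _nll_and_grad(cand, data, sigma)
            if cand_nll <= nll + 1e-12:
                break
            scale *= 0.5
        else:
            return theta, False
        moved = max(abs(cand[0] - theta[0]), abs(cand[1] - theta[1]))
        theta, nll, grad = cand, cand_nll, cand_grad
        if moved < tol_px:
            return theta, True
    return theta, False


def filter_localizations(locs: Sequence[Localization],
                         config: DetectionConfig) -> list[Localization]:
    """Intensity and fit-quality gate; rejection reasons are recorded."""
    out = []
    for loc in locs:
        if not loc.accepted:
            out.append(loc)
            continue
        reasons = []
        if loc.photons < config.min_photons:
            reasons.append(f"photons {loc.photons:.0f} < {config.min_photons}")
        if loc.fit_quality > config.max_fit_quality:
            reasons.append(
                f"fit_quality {loc.fit_quality:.0f} > {config.max_fit_quality}")
        if reasons:
            out.append(replace_accept(loc, False, "; ".join(reasons)))
        else:
            out.append(loc)
    return out


def replace_accept(loc: Localization, accepted: bool,
                   reason: str) -> Localization:
    loc.accepted = accepted
    loc.reject_reason = reason
    return loc


def _auto_threshold(response: np.ndarray, nsigma: float) -> float:
    med = np.median(response)
    mad = np.median(np.abs(response - med))
    return float(med + nsigma * 1.4826 * mad)


def _merge_duplicates(locs: list[Localization],
                      radius: float) -> list[Localization]:
    """Greedy merge of fits closer than ``radius`` px; keep higher photons."""
    locs = sorted(locs, key=lambda l: -l.photons)
    kept: list[Localization] = []
    for loc in locs:
        if any((loc.x_px - k.x_px) ** 2 + (loc.y_px - k.y_px) ** 2
               < radius ** 2 for k in kept):
            continue
        kept.append(loc)
    return kept


def detect_frame(photon_image: np.ndarray, config: DetectionConfig,
                 frame: int = 0) -> list[Localization]:
    """Full detection chain on one photon-unit frame."""
    resp = dog_filter(photon_image, config.dog_sigma_small,
                      config.dog_sigma_large)
    thr = (config.candidate_threshold if config.candidate_threshold is not None
           else _auto_threshold(resp, config.threshold_nsigma))
    cands = find_candidates(resp, thr)
    half = config.fit_window // 2
    h, w = photon_image.shape
    locs = []
    for (cy, cx) in cands:
        y0 = int(np.clip(cy - half, 0, h - config.fit_window))
        x0 = int(np.clip(cx - half, 0, w - config.fit_window))
        win = photon_image[y0:y0 + config.fit_window,
                           x0:x0 + config.fit_window]
        loc = fit_spot_mle(win, config.psf_sigma,
                           (cx - x0 + 0.5, cy - y0 + 0.5), frame=frame)
        loc.x_px += x0
        loc.y_px += y0
        locs.append(loc)
    locs = _merge_duplicates(locs, config.merge_radius_px)
    return filter_localizations(locs, config)


def detect_movie(photon_movie: np.ndarray, camera: CameraModel,
                 config: DetectionConfig | None = None,
                 keep_rejected: bool = False,
                 chunk_frames: int = 256) -> pd.DataFrame:
    """Detect and localize spots in every frame of a photon-unit movie.

    The DoG bandpass and maxima search run on frame chunks (the filters
    are separable, so filtering a ``(t, y, x)`` block with zero temporal
    sigma equals filtering each frame); the candidate threshold, when
    automatic, is estimated once per movie from the first chunk's response
    statistics (the background is temporally stationary).  Returns the
    localization table (one row per fitted spot) with pixel and um
    coordinates, photons, background, CRLB precisions, fit quality and
    accept/reject bookkeeping.
    """
    config = config or DetectionConfig()
    rows = []
    thr = config.candidate_threshold
    half = config.fit_window // 2
    n_frames, h, w = photon_movie.shape
    footprint = np.ones((1, 3, 3), bool)
    for start in range(0, n_frames, chunk_frames):
        block = np.asarray(photon_movie[start:start + chunk_frames], float)
        resp = (ndimage.gaussian_filter(
                    block, (0, config.dog_sigma_small, config.dog_sigma_small),
                    mode="mirror")
                - ndimage.gaussian_filter(
                    block, (0, config.dog_sigma_large, config.dog_sigma_large),
                    mode="mirror"))
        if thr is None:
            sample = resp[:: max(1, len(resp) // 32)]
            med = np.median(sample)
            mad = np.median(np.abs(sample - med))
            thr = float(med + config.threshold_nsigma * 1.4826 * mad)
        maxf = ndimage.maximum_filter(resp, footprint=footprint,
                                      mode="mirror")
        ts, ys, xs = np.nonzero((resp >= maxf) & (resp > thr))
        for t, cy, cx in zip(ts, ys, xs):
            r = resp[t]
            nb = r[max(0, cy - 1):cy + 2, max(0, cx - 1):cx + 2]
            ties = np.argwhere(nb == r[cy, cx])
            ty, tx = ties[0]
            if (max(0, cy - 1) + ty, max(0, cx - 1) + tx) != (cy, cx):
                continue
            y0 = int(np.clip(cy - half, 0, h - config.fit_window))
            x0 = int(np.clip(cx - half, 0, w - config.fit_window))
            win = block[t, y0:y0 + config.fit_window,
                        x0:x0 + config.fit_window]
            loc = fit_spot_mle(win, config.psf_sigma,
                               (cx - x0 + 0.5, cy - y0 + 0.5),
                               frame=start + int(t))
            loc.x_px += x0
            loc.y_px += y0
            rows.append(loc)
    # per-frame duplicate merge + quality gate
    merged = []
    rows.sort(key=lambda l: l.frame)
    frame_groups: dict[int, list[Localization]] = {}
    for loc in rows:
        frame_groups.setdefault(loc.frame, []).append(loc)
    for f in sorted(frame_groups):
        locs = _merge_duplicates(frame_groups[f], config.merge_radius_px)
        for loc in filter_localizations(locs, config):
            if loc.accepted or keep_rejected:
                merged.append(loc)
    rows = merged
    px = camera.pixel_size_um
    df = pd.DataFrame([{
        "frame": l.frame, "x_px": l.x_px, "y_px": l.y_px,
        "x_um": l.x_px * px, "y_um": l.y_px * px,
        "photons": l.photons, "background": l.background,
        "precision_x_um": l.precision_x_px * px,
        "precision_y_um": l.precision_y_px * px,
        "fit_quality": l.fit_quality, "accepted": l.accepted,
        "reject_reason": l.reject_reason} for l in rows])
    if df.empty:
        df = pd.DataFrame(columns=[
            "frame", "x_px", "y_px", "x_um", "y_um", "photons", "background",
            "precision_x_um", "precision_y_um", "fit_quality", "accepted",
            "reject_reason"])
    return df


def count_fixed_stack(stack: np.ndarray, camera: CameraModel,
                      config: DetectionConfig | None = None):
    """Count discrete quantum dots in a fixed-cell z-stack.

    Maximum-intensity projection over z, DoG bandpass, local-maxima
    detection above a robust threshold, and duplicate suppression within
    the merge radius.  Returns ``(count, positions_um)`` with positions as
    an ``(n, 2)`` array of (x, y) in um.
    """
    # max-projection over z pushes the noise floor into the heavier tail of
    # the per-slice noise maxima, so the robust threshold sits higher than
    # for single frames
    config = config or DetectionConfig(psf_sigma=1.0, min_photons=0.0,
                                       threshold_nsigma=7.0)
    stack = np.asarray(stack, float)
    proj = stack.max(axis=0) if stack.ndim == 3 else stack
    if proj.max() >= 65535:
        import warnings
        warnings.warn("saturated projection; counts may be unreliable")
    resp = dog_filter(proj, config.dog_sigma_small, config.dog_sigma_large)
    thr = (config.candidate_threshold if config.candidate_threshold is not None
           else _auto_threshold(resp, config.threshold_nsigma))
    cands = find_candidates(resp, thr)
    # local intensity gate: projected peak must rise above local background
    kept = []
    half = 3
    h, w = proj.shape
    for (cy, cx) in cands:
        y0, y1 = max(0, cy - half), min(h, cy + half + 1)
        x0, x1 = max(0, cx - half), min(w, cx + half + 1)
        patch = proj[y0:y1, x0:x1]
        local_bg = np.median(patch)
        if proj[cy, cx] - local_bg > thr:
            kept.append((cy, cx))
    merged = []
    for (cy, cx) in sorted(kept, key=lambda rc: -resp[rc[0], rc[1]]):
        if any((cy - a) ** 2 + (cx - b) ** 2 < config.merge_radius_px ** 2
               for a, b in merged):
            continue
        merged.append((cy, cx))
    pos = np.array([[ (cx + 0.5) * camera.pixel_size_um,
                      (cy + 0.5) * camera.pixel_size_um]
                    for cy, cx in merged]).reshape(-1, 2)
    return len(merged), pos
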