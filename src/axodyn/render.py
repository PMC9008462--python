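"""Forward model: ground-truth emitters -> EMCCD frames.

Emitters are rendered as integrated 2D Gaussians (error-function pixel
integration).  Each pixel value then passes through the camera chain

    expected photons -> Poisson shot noise -> EM excess noise
    -> divide by gain (photons/ADU) -> + offset -> + Gaussian read noise

and is quantized to 16-bit unsigned ADU.  EM excess noise is applied as a
variance inflation: zero-mean Gaussian noise of variance
``(F - 1) * expected`` added on top of the Poisson draw, which reproduces
the factor-``F`` variance of an EM register without simulating the full
gain cascade.

Coordinates are continuous um, x right / y down; pixel ``(0, 0)`` spans
``[0, 1) x [0, 1)`` px, so a position in um maps to pixel units by plain
division by the pixel size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .camera import CameraModel
from .motion import GroundTruthTrack

__all__ = ["render_movie", "render_frame", "render_fixed_field",
           "gaussian_spot", "FixedFieldTruth"]


def gaussian_spot(shape, x_px, y_px, sigma_px, photons):
    """Expected photon image of one emitter: integrated symmetric Gaussian.

    ``x_px``/``y_px`` are column/row center positions in pixel units under
    the half-open pixel convention (pixel centers at k + 0.5).
    """
    h, w = shape
    xs = np.arange(w)
    ys = np.arange(h)
    s = math.sqrt(2.0) * sigma_px
    ex = 0.5 * (erf((xs + 1 - x_px) / s) - erf((xs - x_px) / s))
    ey = 0.5 * (erf((ys + 1 - y_px) / s) - erf((ys - y_px) / s))
    return photons * np.outer(ey, ex)


def _camera_chain(expected_photons, camera: CameraModel,
                  rng: np.random.Generator):
    """Apply shot noise, EM excess noise, gain, offset, read noise -> ADU.

    The EM excess-noise term (zero-mean, variance ``(F-1) * mu`` electrons)
    and the read noise are both Gaussian, so they are folded into a single
    draw with per-pixel standard deviation
    ``sqrt((F-1) * mu / gain^2 + read_noise^2)`` ADU.
    """
    expected = np.asarray(expected_photons, dtype=np.float32)
    adu = rng.poisson(expected).astype(np.float32)
    adu /= camera.gain
    adu += camera.offset
    var_adu = camera.read_noise ** 2 + (
        (camera.em_excess_noise - 1.0) / camera.gain ** 2) * expected
    if np.any(var_adu > 0):
        adu += rng.standard_normal(adu.shape, dtype=np.float32) \
            * np.sqrt(var_adu, dtype=np.float32)
    return np.clip(np.rint(adu), 0, 65535).astype(np.uint16)


def render_frame(positions_px, photons, camera: CameraModel, psf_sigma_px,
                 bg_photons, rng, shape=None, patch_radius: int = 8):
    """One ADU frame from a list of emitter positions (pixel units).

    Emitters are stamped on local patches (``patch_radius`` px around the
    center) for speed; the expected image is exact within the patch and the
    integrated-Gaussian tail outside it is below 1e-8 of the flux at the
    default radius.
    """
    shape = camera.roi if shape is None else shape
    expected = np.full(shape, float(bg_photons))
    h, w = shape
    for (x, y), n_ph in zip(positions_px, np.broadcast_to(photons, (len(positions_px),))):
        r = patch_radius
        cx, cy = int(x), int(y)
        x0, x1 = max(0, cx - r), min(w, cx + r + 1)
        y0, y1 = max(0, cy - r), min(h, cy + r + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        expected[y0:y1, x0:x1] += gaussian_spot(
            (y1 - y0, x1 - x0), x - x0, y - y0, psf_sigma_px, n_ph)
    return _camera_chain(expected, camera, rng)


def render_movie(tracks, camera: CameraModel, rng,
                 psf_sigma_px: float = 1.3, photons_per_frame: float = 400.0,
                 bg_photons_px: float = 5.0, n_frames: int | None = None,
                 shape=None):
    """Render ground-truth tracks into a 16-bit ADU movie.

    Returns ``(movie, truth_table)`` where ``movie`` is a
    ``(n_frames, h, w)`` uint16 array and ``truth_table`` a pandas DataFrame
    with one row per (track, frame) including visibility and phase labels.
    Only frames where a track exists and its blinking mask is on contribute
    photons.  Deterministic for a fixed generator state.
    """
    import pandas as pd

    if photons_per_frame <= 0:
        raise ValueError("photon budget must be > 0")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    shape = camera.roi if shape is None else shape
    if n_frames is None:
        n_frames = int(max(t.frames[-1] for t in tracks)) + 1 if tracks else 0

    # per-frame emitter lists
    per_frame = [[] for _ in range(n_frames)]
    rows = []
    for tr in tracks:
        for i, f in enumerate(tr.frames):
            if f >= n_frames:
                break
            x_px = tr.xy_um[i, 0] / camera.pixel_size_um
            y_px = tr.xy_um[i, 1] / camera.pixel_size_um
            vis = bool(tr.visible[i])
            if vis:
                per_frame[f].append((x_px, y_px))
            rows.append((tr.track_id, int(f), tr.t_s[i], tr.xy_um[i, 0],
                         tr.xy_um[i, 1], vis, str(tr.phase[i]),
                         tr.motion_class,
                         -1 if tr.partner_id is None else tr.partner_id))
    movie = np.empty((n_frames, *shape), dtype=np.uint16)
    for f in range(n_frames):
        movie[f] = render_frame(per_frame[f], photons_per_frame, camera,
                                psf_sigma_px, bg_photons_px, rng, shape=shape)
    truth = pd.DataFrame(rows, columns=[
        "track_id", "frame", "t_s", "x_um", "y_um", "visible", "phase",
        "motion_class", "partner_id"])
    return movie, truth


@dataclass
class FixedFieldTruth:
    """Truth table of a rendered fixed-cell field."""
    x_um: np.ndarray
    y_um: np.ndarray
    z_um: np.ndarray

    @property
    def count(self) -> int:
        return len(self.x_um)


def render_fixed_field(n_spots: int, field_um, camera: CameraModel, rng,
                       n_slices: int = 20, z_step_um: float = 0.25,
                       psf_sigma_px: float = 1.0, psf_sigma_z_um: float = 0.4,
                       photons_total: float = 2000.0,
                       bg_photons_px: float = 5.0,
                       min_separation_um: float = 1.0):
    """Render a fixed-cell z-stack of discrete quantum dots with known count.

    Spots are placed uniformly with a minimum pairwise separation (rejection
    sampling); each spot's photons are spread over z with a Gaussian axial
    envelope, so it appears in a contiguous subset of slices.  Returns
    ``(stack, truth)`` with ``stack`` of shape ``(n_slices, h, w)`` uint16.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    w_um, h_um = field_um
    if n_spots * math.pi * min_separation_um ** 2 > 2.0 * w_um * h_um:
        raise ValueError("spot density too high for the minimum separation")
    margin = 1.0
    xs, ys = [], []
    attempts = 0
    while len(xs) < n_spots:
        attempts += 1
        if attempts > 200 * max(n_spots, 1):
            raise ValueError("could not place spots at the requested "
                             "density with this minimum separation")
        x = rng.uniform(margin, w_um - margin)
        y = rng.uniform(margin, h_um - margin)
        if all((x - a) ** 2 + (y - b) ** 2 >= min_separation_um ** 2
               for a, b in zip(xs, ys)):
            xs.append(x)
            ys.append(y)
    z_extent = n_slices * z_step_um
    zs = rng.uniform(0.25 * z_extent, 0.75 * z_extent, size=n_spots)

    h_px = int(round(h_um / camera.pixel_size_um))
    w_px = int(round(w_um / camera.pixel_size_um))
    z_centers = (np.arange(n_slices) + 0.5) * z_step_um
    stack = np.empty((n_slices, h_px, w_px), dtype=np.uint16)
    xs_a, ys_a = np.asarray(xs), np.asarray(ys)
    for k, zc in enumerate(z_centers):
        if n_spots:
            weight = np.exp(-0.5 * ((zc - zs) / psf_sigma_z_um) ** 2)
            weight *= z_step_um / (psf_sigma_z_um * math.sqrt(2 * math.pi))
            pos = np.column_stack([xs_a / camera.pixel_size_um,
                                   ys_a / camera.pixel_size_um])
            stack[k] = render_frame(pos, photons_total * weight, camera,
                                    psf_sigma_px, bg_photons_px, rng,
                                    shape=(h_px, w_px))
        else:
            stack[k] = render_frame([], 0.0, camera, psf_sigma_px,
                                    bg_photons_px, rng, shape=(h_px, w_px))
    truth = FixedFieldTruth(xs_a, np.asarray(ys), zs)
    return stack, truth
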