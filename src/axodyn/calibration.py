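"""EMCCD calibration: ADU -> photons conversion and flat-field correction.

Gain and offset are estimated by the mean-variance (photon-transfer)
method: for a photon flux mu the sensor delivers

    mean_ADU = mu / gain + offset
    var_ADU  = F * mu / gain**2 + read_noise**2

with F the EM excess-noise factor, so per-pixel variance is linear in
(mean - offset) with slope F / gain.  The offset and read noise come from a
dark stack; the slope from >= 2 illuminated static stacks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .camera import CameraModel

__all__ = ["CalibrationResult", "estimate_gain_offset", "gain_calibrate",
           "flat_field_correct"]


@dataclass
class CalibrationResult:
    """Camera calibration: gain (photons/ADU), offset and read noise (ADU).

    ``gain`` is ``None`` when only a dark stack was supplied.
    ``flat_reference`` is a unit-mean per-pixel sensitivity field used for
    flat-field correction, or ``None``.
    """

    offset: float
    read_noise: float
    gain: Optional[float] = None
    em_excess_noise: float = 2.0
    flat_reference: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.gain is not None and self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.flat_reference is not None:
            if np.any(self.flat_reference <= 0):
                raise ValueError("flat reference must be strictly positive")


def estimate_gain_offset(stacks: Sequence[np.ndarray],
                         dark_stack: np.ndarray,
                         em_excess_noise: float = 2.0) -> CalibrationResult:
    """Photon-transfer calibration from static stacks at several fluxes.

    Parameters
    ----------
    stacks : sequence of (n_frames, h, w) arrays
        Temporally static illuminated calibration stacks; an empty sequence
        yields an offset/read-noise-only result with ``gain=None``.
    dark_stack : (n_frames, h, w) array
        Frames with the shutter closed.
    em_excess_noise : float
        Excess-noise factor F folded out of the slope; set 1.0 for a
        conventional (non-EM) readout or when F should be absorbed into the
        gain.
    """
    dark = np.asarray(dark_stack, float)
    offset = float(dark.mean())
    read_noise = float(dark.std())
    if len(stacks) == 0:
        return CalibrationResult(offset=offset, read_noise=read_noise,
                                 gain=None, em_excess_noise=em_excess_noise)
    means, variances = [], []
    for st in stacks:
        a = np.asarray(st, float)
        if a.ndim != 3 or a.shape[0] < 2:
            raise ValueError("each calibration stack needs >= 2 frames")
        # per-pixel temporal statistics, pooled over the field
        m = a.mean(axis=0) - offset
        v = a.var(axis=0, ddof=1) - read_noise ** 2
        means.append(m.ravel())
        variances.append(v.ravel())
    x = np.concatenate(means)
    y = np.concatenate(variances)
    if np.ptp(x) <= 0 or np.allclose(y, 0):
        raise ValueError("degenerate calibration stacks (no variance)")
    if len(stacks) < 2 and np.ptp([m.mean() for m in means]) == 0:
        raise ValueError("need >= 2 distinct illumination levels")
    slope = float(np.polyfit(x, y, 1)[0])  # = F / gain
    if slope <= 0:
        raise ValueError("non-positive mean-variance slope")
    gain = em_excess_noise / slope
    return CalibrationResult(offset=offset, read_noise=read_noise, gain=gain,
                             em_excess_noise=em_excess_noise)


def gain_calibrate(movie: np.ndarray, calib: CalibrationResult,
                   clip_negative: bool = True,
                   meta: Optional[dict] = None) -> np.ndarray:
    """Convert an ADU movie to photon units: ``(ADU - offset) * gain``.

    By default values falling below zero after offset subtraction are
    clipped to 0, since downstream Poisson-likelihood fitting needs
    non-negative data; pass ``clip_negative=False`` to keep the affine map
    exact (e.g. for flux-conservation checks, where clipping would bias
    low-background sums upward).

    When the movie's metadata dict is supplied, its ``units`` key guards
    against calibrating twice (arrays carry no unit information, so the
    guard only works through the metadata channel); the dict is updated
    to ``units: photons`` in place.
    """
    if calib.gain is None:
        raise ValueError("calibration has no gain (dark-stack only)")
    if meta is not None:
        if meta.get("units") == "photons":
            raise ValueError("movie is already in photon units; "
                             "refusing to gain-calibrate twice")
        meta["units"] = "photons"
    movie = np.asarray(movie)
    # float32 is ample: photon counts are O(1e3) with shot-noise-limited
    # precision, and it halves the memory traffic of long movies
    dtype = movie.dtype if movie.dtype in (np.float32, np.float64) \
        else np.float32
    out = movie.astype(dtype, copy=True)
    out -= calib.offset
    out *= calib.gain
    return np.maximum(out, 0.0, out=out) if clip_negative else out


def flat_field_correct(image: np.ndarray,
                       reference: np.ndarray) -> np.ndarray:
    """Divide an image by its unit-mean normalized reference field.

    The reference (same optics/exposure, no sample) is rescaled to mean 1
    before division so the corrected image keeps its intensity scale.
    """
    img = np.asarray(image, float)
    ref = np.asarray(reference, float)
    if img.shape[-2:] != ref.shape:
        raise ValueError(
            f"shape mismatch: image {img.shape[-2:]} vs reference {ref.shape}")
    bad = int(np.count_nonzero(ref <= 0))
    if bad:
        raise ValueError(f"reference has {bad} non-positive pixel(s)")
    return img / (ref / ref.mean())
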