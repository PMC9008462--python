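"""EMCCD camera model: geometry, timing, and the photon -> ADU chain.

The conversion convention throughout the package is

    photons = (ADU - offset) * gain

so ``gain`` is expressed in photons/ADU (values near 0.13 are typical for an
EM-amplified sensor read out at high EM gain).  Electron multiplication adds
excess noise, modelled as a multiplicative inflation of the shot-noise
variance by ``em_excess_noise`` (2.0 for an ideal EM register).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class CameraModel:
    """Acquisition parameters of a single-channel EMCCD time-lapse.

    Parameters
    ----------
    pixel_size_um : float
        Lateral size of one pixel in sample space, micrometres.
    frame_interval_s : float
        Time between consecutive frames, seconds.
    gain : float
        Photon conversion factor, photons per ADU.
    offset : float
        Constant camera offset (bias), ADU.
    read_noise : float
        RMS read noise, ADU.
    em_excess_noise : float
        Variance inflation factor of the EM register (1 = none, 2 = ideal
        high-gain EM multiplication).
    roi : tuple of int
        Frame shape ``(height, width)`` in pixels.
    """

    pixel_size_um: float = 0.127
    frame_interval_s: float = 1.0 / 17.0
    gain: float = 0.13
    offset: float = 100.0
    read_noise: float = 0.65
    em_excess_noise: float = 2.0
    roi: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.read_noise < 0:
            raise ValueError("read_noise must be >= 0")
        if self.em_excess_noise < 1:
            raise ValueError("em_excess_noise must be >= 1")

    @property
    def fps(self) -> float:
        return 1.0 / self.frame_interval_s

    def um_to_px(self, um: float) -> float:
        return um / self.pixel_size_um

    def px_to_um(self, px: float) -> float:
        return px * self.pixel_size_um


#: Camera used for fixed-cell z-stack imaging (lower magnification).
FIXED_CELL_CAMERA = CameraModel(pixel_size_um=0.195, frame_interval_s=1.0,
                                roi=(400, 400))
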