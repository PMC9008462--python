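"""High-level simulation facade: preset -> ground-truth tracks / movies.

Places tracks inside the chamber region a preset prescribes, applies
blinking, and optionally renders movies in a local strip of the field of
view sized to the trajectory (so a long transport run fits in memory).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .camera import CameraModel
from .geometry import ChamberGeometry
from .motion import (AxonPath, BlinkModel, GroundTruthTrack, apply_blinking,
                     simulate_pair, simulate_trajectory)
from .presets import SimulationPreset, get_preset
from .render import render_movie

__all__ = ["simulate_preset_tracks", "truth_to_table", "render_track_movie"]


def _start_arcs(preset: SimulationPreset, geometry: ChamberGeometry,
                n: int, total_time: float, rng) -> np.ndarray:
    """Start positions such that tracks mostly stay inside their region."""
    lo, hi = geometry.region_interval(preset.region)
    if preset.motion.motion_class in ("AT", "AT_pair"):
        p = preset.motion
        frac = p.active_dur_mean / (p.active_dur_mean + p.pause_dur_mean) \
            if p.pause_dur_mean else 1.0
        expected_travel = p.active_speed_mean * frac * total_time
        hi_eff = max(lo + 1.0, hi - expected_travel * 1.3)
    else:
        hi_eff = hi - preset.motion.confinement_length
    return rng.uniform(lo, max(hi_eff, lo + 1.0), size=n)


def simulate_preset_tracks(preset: str | SimulationPreset,
                           rng: np.random.Generator | int,
                           geometry: ChamberGeometry | None = None,
                           camera: CameraModel | None = None,
                           n_tracks: int | None = None,
                           total_time_s: float | None = None,
                           blinking: bool = True):
    """Generate ground-truth tracks for a named scenario.

    Returns ``(tracks, path, geometry)``; the path is the straight
    device-spanning axon the tracks move along.
    """
    preset = get_preset(preset) if isinstance(preset, str) else preset
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    geometry = geometry or ChamberGeometry()
    camera = camera or CameraModel()
    n = n_tracks if n_tracks is not None else preset.n_tracks
    total = total_time_s if total_time_s is not None else preset.total_time_s
    path = geometry.default_path()
    starts = _start_arcs(preset, geometry, n, total, rng)
    tracks: list[GroundTruthTrack] = []
    if preset.motion.motion_class == "AT_pair":
        for k in range(0, n - n % 2, 2):
            leader, follower = simulate_pair(
                preset.motion, path, camera, rng, total_time=total,
                start_arc_um=float(starts[k]), track_ids=(k, k + 1))
            tracks += [leader, follower]
    else:
        for k in range(n):
            tracks.append(simulate_trajectory(
                preset.motion, path, camera, rng, total_time=total,
                start_arc_um=float(starts[k]), track_id=k))
    if blinking:
        for tr in tracks:
            apply_blinking(tr, preset.blink, rng)
    return tracks, path, geometry


def truth_to_table(tracks: list[GroundTruthTrack]) -> pd.DataFrame:
    """Ground-truth tracks as the canonical truth CSV table."""
    rows = []
    for tr in tracks:
        for i in range(len(tr)):
            rows.append((tr.track_id, int(tr.frames[i]), float(tr.t_s[i]),
                         float(tr.xy_um[i, 0]), float(tr.xy_um[i, 1]),
                         float(tr.arc_um[i]), bool(tr.visible[i]),
                         str(tr.phase[i]), tr.motion_class,
                         -1 if tr.partner_id is None else tr.partner_id))
    return pd.DataFrame(rows, columns=[
        "track_id", "frame", "t_s", "x_um", "y_um", "arc_um", "visible",
        "phase", "motion_class", "partner_id"])


def render_track_movie(tracks, camera: CameraModel, rng,
                       margin_um: float = 3.0, max_px: int = 4096,
                       **render_kwargs):
    """Render tracks into a movie cropped to their bounding box.

    Track coordinates are shifted so the bounding box (plus margin) starts
    at the origin; the applied offset is returned so detections can be
    mapped back to device coordinates.  Returns
    ``(movie, truth_table, origin_um)``.
    """
    all_xy = np.vstack([t.xy_um for t in tracks])
    lo = all_xy.min(axis=0) - margin_um
    hi = all_xy.max(axis=0) + margin_um
    size_px = np.ceil((hi - lo) / camera.pixel_size_um).astype(int)
    size_px = np.minimum(np.maximum(size_px, 24), max_px)
    shifted = []
    for t in tracks:
        s = GroundTruthTrack(
            track_id=t.track_id, frames=t.frames, t_s=t.t_s,
            xy_um=t.xy_um - lo, arc_um=t.arc_um, phase=t.phase,
            motion_class=t.motion_class, params=t.params,
            visible=t.visible, partner_id=t.partner_id,
            truncated=t.truncated)
        shifted.append(s)
    movie, truth = render_movie(shifted, camera, rng,
                                shape=(int(size_px[1]), int(size_px[0])),
                                **render_kwargs)
    return movie, truth, lo
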