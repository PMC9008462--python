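"""Ground-truthed motion simulation for quantum-dot-labelled axonal cargo.

Three motion classes are generated, mirroring what is seen in live axons:

``AT``
    Active (motor-driven) transport: sustained runs at a roughly constant
    speed toward the soma, interspersed with pauses during which the cargo
    stays confined to the track.
``B&F``
    Back-and-forth motion: one-dimensional diffusion confined to a short
    (3-7 um) elongated domain of the axon.
``S``
    Stationary: sub-diffraction jiggle around a fixed point.

Pairs of co-transported cargoes (``AT_pair``) share phase boundaries and run
speeds and stay within 2 um of each other at all times.

Phase durations are drawn from gamma distributions moment-matched to a
requested (mean, SD) after shifting by a duration floor equal to the shortest
phase an analysis at video rate can resolve; see ``sample_phase_sequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .camera import CameraModel

__all__ = [
    "MotionParams",
    "BlinkModel",
    "GroundTruthTrack",
    "AxonPath",
    "sample_phase_sequence",
    "simulate_trajectory",
    "simulate_pair",
    "apply_blinking",
    "PHASE_DURATION_FLOOR_S",
]

#: Shortest phase that a window-based segmentation at video rate can resolve;
#: generated phase durations never fall below it (see sample_phase_sequence).
PHASE_DURATION_FLOOR_S = 0.5

ACTIVE = "active"
PAUSED = "paused"

MOTION_CLASSES = ("AT", "B&F", "S", "AT_pair")


@dataclass(frozen=True)
class MotionParams:
    """Kinetic parameters of one motion class.

    All durations are seconds, speeds um/s, lengths um.  ``active_*`` and
    ``pause_*`` parameterize the alternating run/pause renewal process of
    active transport; ``confinement_length`` and ``bf_diffusion`` the
    confined diffusion of back-and-forth motion; ``pair_coupling_*`` the
    tether between members of a co-transported pair.
    """

    motion_class: str = "AT"
    active_speed_mean: float = 1.5
    active_speed_sd: float = 0.45
    active_dur_mean: float = 7.0
    active_dur_sd: float = 6.4
    pause_dur_mean: float = 5.0
    pause_dur_sd: float = 9.0
    pause_jitter_sd: float = 0.05
    confinement_length: float = 5.0
    bf_diffusion: float = 0.1
    pair_coupling_rest: float = 0.5
    pair_coupling_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.motion_class not in MOTION_CLASSES:
            raise ValueError(f"unknown motion_class {self.motion_class!r}")
        if self.active_speed_mean <= 0:
            raise ValueError("active_speed_mean must be > 0")
        if self.active_dur_mean <= 0:
            raise ValueError("active_dur_mean must be > 0")
        if self.pause_dur_mean < 0:
            raise ValueError("pause_dur_mean must be >= 0")
        if min(self.active_speed_sd, self.active_dur_sd,
               self.pause_dur_sd, self.pause_jitter_sd) < 0:
            raise ValueError("spread parameters must be >= 0")
        if not (0 < self.confinement_length <= 20):
            raise ValueError("confinement_length must be in (0, 20] um")
        if self.bf_diffusion <= 0:
            raise ValueError("bf_diffusion must be > 0")


@dataclass(frozen=True)
class BlinkModel:
    """Two-state (emitting/dark) Markov blinking of a single quantum dot.

    ``p_off`` is the per-frame probability of an emitting dot going dark,
    ``p_on`` the per-frame probability of recovery; dark dwells are therefore
    geometric with mean ``1 / p_on`` frames.
    """

    p_off: float = 0.05
    p_on: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_off <= 1.0 and 0.0 <= self.p_on <= 1.0):
            raise ValueError("blink probabilities must lie in [0, 1]")


class AxonPath:
    """Arc-length-parameterized polyline along an axon, in um.

    Oriented from the distal end (arc 0) toward the soma, so active
    transport moves toward increasing arc coordinate.
    """

    def __init__(self, vertices: Sequence[Sequence[float]]):
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
            raise ValueError("path needs >= 2 vertices of shape (n, 2)")
        seg = np.diff(v, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(seglen <= 0):
            raise ValueError("degenerate path segment")
        self.vertices = v
        self._cum = np.concatenate([[0.0], np.cumsum(seglen)])

    @classmethod
    def straight(cls, length_um: float, origin=(0.0, 0.0),
                 direction=(1.0, 0.0)) -> "AxonPath":
        d = np.asarray(direction, float)
        d = d / np.hypot(*d)
        o = np.asarray(origin, float)
        return cls([o, o + d * length_um])

    @property
    def length(self) -> float:
        return float(self._cum[-1])

    def point_at(self, arc):
        """Map arc coordinate(s) (um) to 2D point(s); clamps to the ends."""
        s = np.clip(np.atleast_1d(np.asarray(arc, float)), 0.0, self.length)
        idx = np.clip(np.searchsorted(self._cum, s, side="right") - 1,
                      0, len(self._cum) - 2)
        seg = self.vertices[idx + 1] - self.vertices[idx]
        seglen = self._cum[idx + 1] - self._cum[idx]
        frac = (s - self._cum[idx]) / seglen
        pts = self.vertices[idx] + frac[:, None] * seg
        return pts if np.ndim(arc) else pts[0]

    def arc_of_point(self, xy) -> float:
        """Arc coordinate of the projection of ``xy`` onto the path."""
        p = np.asarray(xy, float)
        best, best_d2 = 0.0, np.inf
        for i in range(len(self.vertices) - 1):
            a, b = self.vertices[i], self.vertices[i + 1]
            ab = b - a
            t = float(np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0))
            q = a + t * ab
            d2 = float(np.sum((p - q) ** 2))
            if d2 < best_d2:
                best_d2 = d2
                best = self._cum[i] + t * np.hypot(*ab)
        return float(best)


@dataclass
class GroundTruthTrack:
    """Truth channel of one simulated cargo: positions, phases, visibility."""

    track_id: int
    frames: np.ndarray          # frame indices
    t_s: np.ndarray             # frame times, s
    xy_um: np.ndarray           # (n, 2) true positions, um
    arc_um: np.ndarray          # arc coordinate along the axon path, um
    phase: np.ndarray           # per-frame label: "active" | "paused"
    motion_class: str
    params: MotionParams
    visible: np.ndarray = None  # per-frame emitting flag (blinking)
    partner_id: Optional[int] = None
    truncated: bool = False     # ran off the end of the path

    def __post_init__(self):
        if self.visible is None:
            self.visible = np.ones(len(self.frames), dtype=bool)
        if not np.all(np.isfinite(self.xy_um)):
            raise ValueError("non-finite truth positions")

    def __len__(self) -> int:
        return len(self.frames)

    def phase_intervals(self):
        """Contiguous (label, first_frame, last_frame) blocks of the track."""
        out = []
        start = 0
        for i in range(1, len(self.phase) + 1):
            if i == len(self.phase) or self.phase[i] != self.phase[start]:
                out.append((str(self.phase[start]),
                            int(self.frames[start]), int(self.frames[i - 1])))
                start = i
        return out


def _gamma_shifted(mean: float, sd: float, floor: float,
                   rng: np.random.Generator) -> float:
    """Draw a duration >= floor with overall mean ``mean`` and SD ``sd``.

    The draw is ``floor + Gamma(k, theta)`` with the gamma moment-matched to
    (mean - floor, sd).  ``sd == 0`` gives the deterministic value ``mean``.
    """
    if mean <= floor:
        raise ValueError(
            f"duration mean {mean} must exceed the floor {floor}")
    if sd == 0:
        return mean
    m = mean - floor
    shape = (m / sd) ** 2
    scale = sd * sd / m
    return floor + float(rng.gamma(shape, scale))


def sample_phase_sequence(params: MotionParams, total_time: float,
                          rng: np.random.Generator | int,
                          duration_floor: float = PHASE_DURATION_FLOOR_S,
                          equilibrium_start: bool = True):
    """Alternating (label, duration) phases covering exactly ``total_time``.

    Durations are gamma-distributed with a floor (see module docstring);
    the last phase is truncated so durations sum exactly to
    ``total_time``.  With ``equilibrium_start`` (default) the renewal
    process is burned in before the observation window opens, so a track
    begins in an active or paused phase with the equilibrium (time-
    weighted) probabilities — the natural model for cargo picked up
    mid-transport; without it the first phase is always active.
    ``pause_dur_mean == 0`` degenerates to a single active phase spanning
    the whole track.
    """
    if total_time <= 0:
        raise ValueError("total_time must be > 0")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if params.pause_dur_mean == 0.0:
        return [(ACTIVE, float(total_time))]
    burn = (4.0 * (params.active_dur_mean + params.pause_dur_mean)
            if equilibrium_start else 0.0)
    horizon = burn + total_time
    phases = []
    t = 0.0
    label = ACTIVE
    while t < horizon:
        if label == ACTIVE:
            dur = _gamma_shifted(params.active_dur_mean,
                                 params.active_dur_sd, duration_floor, rng)
        else:
            dur = _gamma_shifted(params.pause_dur_mean,
                                 params.pause_dur_sd, duration_floor, rng)
        phases.append((label, float(dur)))
        t += dur
        label = PAUSED if label == ACTIVE else ACTIVE
    # clip the burn-in interval off the front, truncate the back
    out = []
    start = burn
    t = 0.0
    for label, dur in phases:
        lo = max(t, start)
        hi = min(t + dur, horizon)
        if hi > lo:
            out.append((label, float(hi - lo)))
        t += dur
    return out


def _draw_speed(params: MotionParams, rng: np.random.Generator) -> float:
    """Per-phase run speed: normal truncated to positive values."""
    for _ in range(100):
        s = rng.normal(params.active_speed_mean, params.active_speed_sd)
        if s > 0.05:
            return float(s)
    return params.active_speed_mean


def _frame_times(total_time: float, camera: CameraModel):
    n = int(math.floor(total_time / camera.frame_interval_s)) + 1
    frames = np.arange(n)
    return frames, frames * camera.frame_interval_s


def simulate_trajectory(params: MotionParams, path: AxonPath,
                        camera: CameraModel,
                        rng: np.random.Generator | int,
                        total_time: float = 120.0,
                        start_arc_um: float = 0.0,
                        track_id: int = 0) -> GroundTruthTrack:
    """Simulate one ground-truth track sampled at frame times.

    Active transport advances the arc coordinate at a piecewise-constant
    per-phase run speed; pauses freeze it (plus isotropic positional jitter
    of SD ``pause_jitter_sd``).  Back-and-forth motion is 1D diffusion
    reflected inside ``confinement_length``; stationary cargo only jitters.
    A track that reaches the end of the path is truncated there and flagged.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    frames, t_s = _frame_times(total_time, camera)
    n = len(frames)
    cls = params.motion_class

    if cls in ("AT", "AT_pair"):
        phases = sample_phase_sequence(params, total_time, rng)
        arc, phase_lbl, speeds = _integrate_at(params, phases, t_s, rng,
                                               start_arc_um)
    elif cls == "B&F":
        arc = _reflected_walk(params, t_s, rng, start_arc_um)
        phase_lbl = np.full(n, PAUSED, dtype=object)
    elif cls == "S":
        arc = np.full(n, start_arc_um)
        phase_lbl = np.full(n, PAUSED, dtype=object)
    else:  # pragma: no cover - guarded by MotionParams
        raise ValueError(cls)

    truncated = bool(np.any(arc > path.length))
    keep = n
    if truncated:
        keep = int(np.argmax(arc > path.length))
        keep = max(keep, 2)
    xy = path.point_at(arc[:keep])
    jitter_mask = (phase_lbl[:keep] == PAUSED)
    if params.pause_jitter_sd > 0:
        jit = rng.normal(0.0, params.pause_jitter_sd, size=(keep, 2))
        xy = xy + jit * jitter_mask[:, None]
    return GroundTruthTrack(
        track_id=track_id, frames=frames[:keep], t_s=t_s[:keep],
        xy_um=xy, arc_um=arc[:keep], phase=np.asarray(phase_lbl[:keep]),
        motion_class=cls, params=params, truncated=truncated)


def _integrate_at(params, phases, t_s, rng, start_arc):
    """Arc coordinate and per-frame labels for a run/pause phase sequence."""
    n = len(t_s)
    arc = np.empty(n)
    labels = np.empty(n, dtype=object)
    # phase boundaries in time
    bounds = np.cumsum([0.0] + [d for _, d in phases])
    speeds = [(_draw_speed(params, rng) if lbl == ACTIVE else 0.0)
              for lbl, _ in phases]
    # position at each phase boundary
    pos_b = np.concatenate(
        [[start_arc],
         start_arc + np.cumsum([s * d for s, (_, d) in zip(speeds, phases)])])
    idx = np.clip(np.searchsorted(bounds, t_s, side="right") - 1,
                  0, len(phases) - 1)
    for i in range(n):
        k = idx[i]
        arc[i] = pos_b[k] + speeds[k] * (t_s[i] - bounds[k])
        labels[i] = phases[k][0]
    return arc, labels, speeds


def _reflected_walk(params, t_s, rng, start_arc):
    """1D Brownian steps reflected inside the confinement domain."""
    L = params.confinement_length
    dt = np.diff(t_s)
    steps = rng.normal(0.0, np.sqrt(2.0 * params.bf_diffusion * dt))
    lo = start_arc
    x = np.empty(len(t_s))
    x[0] = start_arc + rng.uniform(0, L)
    for i, s in enumerate(steps):
        y = x[i] + s
        # reflect into [lo, lo + L]
        y = (y - lo) % (2 * L)
        y = 2 * L - y if y > L else y
        x[i + 1] = lo + y
    return x


def simulate_pair(params: MotionParams, path: AxonPath, camera: CameraModel,
                  rng: np.random.Generator | int,
                  total_time: float = 60.0, start_arc_um: float = 0.0,
                  track_ids=(0, 1)):
    """Two co-transported cargoes sharing phases, tethered along the path.

    The leader is an active-transport track; the follower trails it by a
    fluctuating along-path offset (Ornstein-Uhlenbeck around
    ``pair_coupling_rest`` with stationary SD ``pair_coupling_sd``), hard-
    bounded so the inter-distance never reaches 2 um.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if params.pair_coupling_rest + 4 * params.pair_coupling_sd >= 2.0:
        raise ValueError("coupling parameters imply inter-distance >= 2 um")
    leader = simulate_trajectory(
        replace(params, motion_class="AT_pair"), path, camera, rng,
        total_time=total_time, start_arc_um=start_arc_um,
        track_id=track_ids[0])
    n = len(leader)
    dt = camera.frame_interval_s
    tau = 1.0  # tether relaxation time, s
    rho = math.exp(-dt / tau)
    sd_step = params.pair_coupling_sd * math.sqrt(max(1e-12, 1 - rho * rho))
    off = np.empty(n)
    off[0] = params.pair_coupling_rest
    for i in range(1, n):
        off[i] = (params.pair_coupling_rest
                  + rho * (off[i - 1] - params.pair_coupling_rest)
                  + rng.normal(0.0, sd_step))
    off = np.clip(off, 0.05, 1.95)
    arc_f = np.maximum(leader.arc_um - off, 0.0)
    xy_f = path.point_at(arc_f)
    jit_mask = (leader.phase == PAUSED)
    if params.pause_jitter_sd > 0:
        xy_f = xy_f + (rng.normal(0.0, params.pause_jitter_sd, size=(n, 2))
                       * jit_mask[:, None])
    follower = GroundTruthTrack(
        track_id=track_ids[1], frames=leader.frames.copy(),
        t_s=leader.t_s.copy(), xy_um=xy_f, arc_um=arc_f,
        phase=leader.phase.copy(), motion_class="AT_pair", params=params,
        partner_id=track_ids[0], truncated=leader.truncated)
    leader.partner_id = track_ids[1]
    return leader, follower


def apply_blinking(track: GroundTruthTrack, blink: BlinkModel,
                   rng: np.random.Generator | int) -> np.ndarray:
    """Per-frame visibility mask from the two-state blinking chain.

    The dot starts in the emitting state; dark dwells are geometric with
    mean ``1 / p_on`` frames.  The mask is stored on the track and returned.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n = len(track)
    mask = np.ones(n, dtype=bool)
    on = True
    for i in range(n):
        mask[i] = on
        if on:
            if rng.random() < blink.p_off:
                on = False
        else:
            if rng.random() < blink.p_on:
                on = True
    track.visible = mask
    return mask
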