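"""Motion-class taxonomy and active/pause phase segmentation.

Whole trajectories are classified into the motion taxonomy seen in live
axons (stationary S, confined back-and-forth B&F, active transport AT).
Active-transport trajectories are then segmented into alternating active
and paused phases by two-threshold hysteresis on the window-smoothed
instantaneous speed: the cargo enters the active state when the smoothed
speed rises above ``v_on`` and leaves it when the speed falls below
``v_off`` (``v_off < v_on``, suppressing chatter around a single
threshold).  Raw hysteresis switches are refined in two steps — first to
the crossing of the adaptive mid-speed between the adjacent blocks, then
by a local segmented-regression changepoint fit on the positions — so
entry and exit delays of the smoothing window cancel and phase durations
are unbiased.  Phases shorter than the per-label minimum durations are
merged into their neighbours.

An active (paused) phase is "interior" when it is bounded by phases of the
opposite label on both sides, i.e. its start and end are both observed;
only interior phases enter duration statistics that require known
endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .metrics import TrajectoryStats, VelocityProfile

__all__ = ["SegmentationConfig", "Phase", "classify_motion",
           "segment_phases", "phase_kinetics", "phases_table"]

ACTIVE = "active"
PAUSED = "paused"


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds of the taxonomy and of phase segmentation (um/s, s, um)."""

    v_on: float = 0.6
    v_off: float = 0.4
    # a pause at the 0.5-s resolution floor spans 8 frames = 7 intervals
    # = 0.41 s of measured duration; the pause minimum sits one frame below
    # that so boundary jitter cannot erase genuine floor pauses
    min_phase_duration_s: float = 0.35
    min_active_duration_s: float | None = 0.35
    #: fill blink gaps by linear interpolation onto the full frame grid
    #: before computing the segmentation speed (gaps inside short pauses
    #: otherwise delete exactly the low-speed samples that reveal them)
    interpolate_gaps: bool = True
    # taxonomy thresholds
    stationary_dmax_um: float = 0.5
    at_dnet_um: float = 5.0
    bf_dmax_range_um: tuple[float, float] = (2.0, 10.0)
    bf_rlin_max: float = 0.2
    bf_min_reversals: int = 3

    def __post_init__(self):
        if not 0 < self.v_off < self.v_on:
            raise ValueError("need 0 < v_off < v_on")
        if self.min_phase_duration_s < 0:
            raise ValueError("min_phase_duration_s must be >= 0")


@dataclass
class Phase:
    """One active or paused sub-trajectory with its kinetic summary."""

    track_id: int
    phase_id: int
    label: str
    start_frame: int
    end_frame: int
    start_t_s: float
    end_t_s: float
    duration_s: float
    net_disp_um: float
    net_speed_um_s: float
    interior: bool = False
    #: per-phase diffusion constant (um^2/s), filled in for phases with
    #: enough increments; None otherwise
    D_um2_s: Optional[float] = None


def _principal_axis_reversals(xy: np.ndarray, vp: VelocityProfile) -> int:
    """Sign reversals of the velocity along the principal axis of motion."""
    centered = xy - xy.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]
    v_along = vp.vx * axis[0] + vp.vy * axis[1]
    # ignore near-zero velocities when counting sign changes
    sig = v_along[np.abs(v_along) > 0.05]
    if len(sig) < 2:
        return 0
    return int(np.sum(np.sign(sig[1:]) != np.sign(sig[:-1])))


def classify_motion(stats: TrajectoryStats, vp: VelocityProfile,
                    xy_um: np.ndarray | None = None,
                    config: SegmentationConfig | None = None) -> str:
    """Assign one taxonomy label: "S", "AT", "B&F" or "unclassified".

    Decision order S -> AT -> B&F: stationary cargo has a tiny maximum
    displacement; active transport a large net displacement with sustained
    directed runs; back-and-forth motion a confined extent (a few um), low
    linearity and repeated direction reversals.
    """
    config = config or SegmentationConfig()
    if stats.d_max < config.stationary_dmax_um:
        return "S"
    sustained = len(vp) > 0 and np.any(vp.speed >= config.v_on)
    if stats.d_net >= config.at_dnet_um and sustained:
        return "AT"
    lo, hi = config.bf_dmax_range_um
    if (lo <= stats.d_max <= hi and stats.r_lin < config.bf_rlin_max
            and xy_um is not None
            and _principal_axis_reversals(np.asarray(xy_um), vp)
            >= config.bf_min_reversals):
        return "B&F"
    return "unclassified"


def _hysteresis_states(speed: np.ndarray, v_on: float,
                       v_off: float) -> np.ndarray:
    v_mid = 0.5 * (v_on + v_off)
    state = np.empty(len(speed), dtype=bool)  # True = active
    cur = speed[0] >= v_mid
    for i, s in enumerate(speed):
        if cur and s <= v_off:
            cur = False
        elif not cur and s >= v_on:
            cur = True
        state[i] = cur
    return state


def _refine_block_boundaries(blocks, speed: np.ndarray):
    """Move each block boundary to the adaptive mid-speed crossing.

    Hysteresis commits a switch only once the smoothed speed passes the far
    threshold, i.e. systematically late, and by an amount that depends on
    the run speed of the adjacent active phase.  For each boundary the
    crossing of ``(median speed of left block + median speed of right
    block) / 2`` is found instead, which is symmetric about the true
    transition regardless of the per-phase run speed.
    """
    def core_speed(b):
        lo, hi = b[0], b[1]
        # central third of the block, away from both transition ramps
        m = max(1, (hi - lo + 1) // 3)
        mid = (lo + hi) // 2
        return float(np.median(speed[max(lo, mid - m):min(hi, mid + m) + 1]))

    for k in range(1, len(blocks)):
        left, right = blocks[k - 1], blocks[k]
        c = 0.5 * (core_speed(left) + core_speed(right))
        b = right[0]
        lo_lim = left[0] + 1
        hi_lim = right[1]
        if right[2] == PAUSED:   # pause starts where speed drops below c
            while b - 1 >= lo_lim and speed[b - 1] < c:
                b -= 1
            while b < hi_lim and speed[b] >= c:
                b += 1
        else:                    # active starts where speed rises above c
            while b - 1 >= lo_lim and speed[b - 1] >= c:
                b -= 1
            while b < hi_lim and speed[b] < c:
                b += 1
        left[1] = b - 1
        right[0] = b
    return blocks


def _changepoint_refine(blocks, xy: np.ndarray, t_s: np.ndarray,
                        halfwidth: int = 8):
    """Final boundary placement by local segmented regression.

    Threshold crossings of a window-smoothed speed are biased by the
    smoothing ramp and by speed noise; the motion changepoint itself is
    not.  For each active/pause boundary, candidate cut indices within
    ``halfwidth`` frames are scored by the residual sum of squares of a
    piecewise model — linear position over the run side, constant position
    over the pause side — and the minimizer becomes the boundary.

    Both models are fit on flanking data only — the run line on run-side
    points at least 3 frames away from the current boundary, the pause
    plateau on pause-side points likewise — and held fixed while scanning
    cuts.  Refitting per cut would bias the boundary toward the more
    flexible (line) model, which can absorb ambiguous plateau points at
    almost no residual cost and thereby trims short pauses.
    """
    margin = 3

    def fit_line(idx):
        tt = t_s[idx]
        tc = tt - tt.mean()
        denom = float(tc @ tc)
        coefs = []
        for ax in range(2):
            y = xy[idx, ax]
            slope = float(tc @ y) / denom if denom > 0 else 0.0
            coefs.append((y.mean(), slope, tt.mean()))
        return coefs

    def line_residuals(coefs, idx):
        res = np.zeros(len(idx))
        for ax, (mean_y, slope, mean_t) in enumerate(coefs):
            pred = mean_y + slope * (t_s[idx] - mean_t)
            res += (xy[idx, ax] - pred) ** 2
        return res

    for k in range(1, len(blocks)):
        left, right = blocks[k - 1], blocks[k]
        b = right[0]
        lo = max(left[0] + 1, b - halfwidth)
        hi = min(right[1], b + halfwidth)
        if hi <= lo:
            continue
        if left[2] == ACTIVE:
            run_idx = np.arange(max(left[0], b - halfwidth - 4), b - margin)
            pause_idx = np.arange(b + margin, min(right[1], b + halfwidth + 4) + 1)
        else:
            pause_idx = np.arange(max(left[0], b - halfwidth - 4), b - margin)
            run_idx = np.arange(b + margin, min(right[1], b + halfwidth + 4) + 1)
        if len(run_idx) < 4 or len(pause_idx) < 2:
            continue
        line = fit_line(run_idx)
        plateau = xy[pause_idx].mean(axis=0)
        n_pts = len(t_s)
        # candidate cuts (right-block start) and contested points
        scan = np.arange(lo, hi + 1)
        pts = np.arange(max(lo - 1, 0), min(hi + 2, n_pts))
        res_line = line_residuals(line, pts)
        res_plat = np.sum((xy[pts] - plateau) ** 2, axis=1)
        best_b, best_sse = b, np.inf
        for cut in scan:
            if left[2] == ACTIVE:   # run before cut, plateau from cut on
                sse = res_line[pts < cut].sum() + res_plat[pts >= cut].sum()
            else:
                sse = res_plat[pts < cut].sum() + res_line[pts >= cut].sum()
            if sse < best_sse - 1e-15:
                best_sse, best_b = sse, cut
        left[1] = best_b - 1
        right[0] = best_b
    return blocks


def interpolate_gaps(frames: np.ndarray, t_s: np.ndarray,
                     xy_um: np.ndarray):
    """Resample a gapped track onto its full frame grid by linear
    interpolation; returns ``(frames, t_s, xy)`` (no-op when gapless)."""
    frames = np.asarray(frames, int)
    if len(frames) < 2 or frames[-1] - frames[0] + 1 == len(frames):
        return frames, np.asarray(t_s, float), np.asarray(xy_um, float)
    full = np.arange(frames[0], frames[-1] + 1)
    t_full = np.interp(full, frames, t_s)
    xy_full = np.column_stack([np.interp(full, frames, xy_um[:, 0]),
                               np.interp(full, frames, xy_um[:, 1])])
    return full, t_full, xy_full


def _blocks(labels: np.ndarray):
    """Contiguous (start, end_inclusive, value) runs of a label array."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append([start, i - 1, labels[start]])
            start = i
    return out


def _merge_short(blocks, t_s, min_dur, min_active_dur=None):
    """Merge too-short blocks into a neighbour, repeatedly.

    ``min_dur`` applies to paused blocks, ``min_active_dur`` (default:
    same) to active ones: a genuine motor run must be evidenced by more
    consecutive high-speed windows than a pause at the resolution floor,
    since speed noise during long pauses produces brief spurious
    above-threshold excursions but sub-threshold dips during runs are rare.
    """
    if min_active_dur is None:
        min_active_dur = min_dur

    def dur(b):
        return t_s[b[1]] - t_s[b[0]]

    def deficit(b):
        lim = min_active_dur if b[2] == ACTIVE else min_dur
        return dur(b) - lim

    blocks = [list(b) for b in blocks]
    while len(blocks) > 1:
        defs = [deficit(b) for b in blocks]
        k = int(np.argmin(defs))
        if defs[k] >= 0:
            break
        # absorb into the longer adjacent block
        if k == 0:
            j = 1
        elif k == len(blocks) - 1:
            j = k - 1
        else:
            j = k - 1 if dur(blocks[k - 1]) >= dur(blocks[k + 1]) else k + 1
        lo = min(blocks[k][0], blocks[j][0])
        hi = max(blocks[k][1], blocks[j][1])
        blocks[j][0], blocks[j][1] = lo, hi
        del blocks[k]
        # re-fuse equal-label neighbours created by the merge
        i = 1
        while i < len(blocks):
            if blocks[i][2] == blocks[i - 1][2]:
                blocks[i - 1][1] = blocks[i][1]
                del blocks[i]
            else:
                i += 1
    return blocks


def segment_phases(xy_um: np.ndarray, t_s: np.ndarray,
                   vp: VelocityProfile, frames: np.ndarray | None = None,
                   track_id: int = 0,
                   config: SegmentationConfig | None = None) -> list[Phase]:
    """Segment one trajectory into alternating active/paused phases.

    The phases tile the trajectory exactly (each localization belongs to
    one phase; a phase's interval runs from its first to its last
    localization time, and consecutive phases share a boundary
    localization's timestamp).  A track too short for a velocity profile
    becomes a single phase labelled by its mean speed.
    """
    config = config or SegmentationConfig()
    xy = np.asarray(xy_um, float).reshape(-1, 2)
    t = np.asarray(t_s, float)
    n = len(xy)
    if frames is None:
        frames = np.arange(n)
    if len(vp) < n or n < 4:
        mean_speed = (np.hypot(*(xy[-1] - xy[0])) / (t[-1] - t[0])
                      if n >= 2 and t[-1] > t[0] else 0.0)
        label = ACTIVE if mean_speed >= config.v_on else PAUSED
        return [_make_phase(track_id, 0, label, 0, n - 1, frames, t, xy,
                            interior=False)]
    state = _hysteresis_states(vp.speed, config.v_on, config.v_off)
    labels = np.where(state, ACTIVE, PAUSED)
    blocks = _refine_block_boundaries(_blocks(labels), vp.speed)
    blocks = _changepoint_refine(blocks, xy, t)
    blocks = _merge_short(blocks, t, config.min_phase_duration_s,
                          config.min_active_duration_s)
    phases = []
    for k, (lo, hi, lbl) in enumerate(blocks):
        interior = 0 < k < len(blocks) - 1
        phases.append(_make_phase(track_id, k, str(lbl), lo, hi, frames, t,
                                  xy, interior))
    return phases


def _make_phase(track_id, phase_id, label, lo, hi, frames, t, xy, interior):
    dur = float(t[hi] - t[lo]) if hi > lo else 0.0
    disp = float(np.hypot(*(xy[hi] - xy[lo])))
    return Phase(track_id=track_id, phase_id=phase_id, label=label,
                 start_frame=int(frames[lo]), end_frame=int(frames[hi]),
                 start_t_s=float(t[lo]), end_t_s=float(t[hi]),
                 duration_s=dur, net_disp_um=disp,
                 net_speed_um_s=disp / dur if dur > 0 else 0.0,
                 interior=interior)


def phase_kinetics(phases: list[Phase]) -> dict:
    """Aggregate phase kinetics, separately for interior-only and all phases.

    Returns a dict with, per label, mean duration / net displacement / net
    speed and n, keyed ``{label}_{quantity}`` under ``"interior"`` and
    ``"all"``; pause net displacement is included for confinement QC.
    """
    out = {}
    for scope, items in (("interior", [p for p in phases if p.interior]),
                         ("all", phases)):
        agg = {}
        for label in (ACTIVE, PAUSED):
            sel = [p for p in items if p.label == label]
            agg[f"{label}_n"] = len(sel)
            for attr, name in (("duration_s", "duration_s"),
                               ("net_disp_um", "net_disp_um"),
                               ("net_speed_um_s", "net_speed_um_s")):
                vals = [getattr(p, attr) for p in sel]
                agg[f"{label}_{name}_mean"] = (float(np.mean(vals))
                                               if vals else np.nan)
        out[scope] = agg
    return out


_PHASE_COLUMNS = ["track_id", "phase_id", "label", "start_frame",
                  "end_frame", "duration_s", "net_disp_um",
                  "net_speed_um_s", "interior", "D_um2_s"]


def phases_table(phases: list[Phase]) -> pd.DataFrame:
    """Phases as a flat table (one row per phase)."""
    if not phases:
        return pd.DataFrame(columns=_PHASE_COLUMNS)
    return pd.DataFrame([{
        "track_id": p.track_id, "phase_id": p.phase_id, "label": p.label,
        "start_frame": p.start_frame, "end_frame": p.end_frame,
        "duration_s": p.duration_s, "net_disp_um": p.net_disp_um,
        "net_speed_um_s": p.net_speed_um_s, "interior": p.interior,
        "D_um2_s": p.D_um2_s}
        for p in phases])
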