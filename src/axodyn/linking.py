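"""Blinking-aware trajectory linking.

Frame-to-frame association is a linear assignment problem on an augmented
square cost matrix (the standard LAP construction): the upper-left block
holds link costs (squared displacement, um^2) with links beyond
``max_link_distance`` forbidden; the upper-right diagonal carries death
costs and the lower-left diagonal birth costs, both derived from the
quantum-dot blinking model as ``-log`` of the per-frame off/on
probabilities (plus a detection-failure allowance); the lower-right block
is the transposed feasible-link block, completing the square matrix.

A second gap-closing pass joins track ends to later track starts across
dark (blinked-off) periods of up to ``max_gap`` frames, with the allowed
bridging distance growing with the gap length (a sqrt term for diffusion
plus a linear term for transport).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .motion import BlinkModel

__all__ = ["LinkConfig", "build_cost_matrix", "solve_assignment",
           "link_movie"]

_FORBIDDEN = np.inf


@dataclass(frozen=True)
class LinkConfig:
    """Linking knobs.

    ``max_link_distance`` is the largest frame-to-frame displacement (um)
    considered a link.  Birth/death costs default to ``-log`` of blink
    probabilities inflated by ``p_miss`` (the chance of a detection
    failure).  Gap closing joins an end to a start ``g`` frames later if
    their distance is below
    ``max_link_distance * sqrt(g) + gap_speed * g * dt``.
    """

    max_link_distance: float = 0.5
    p_miss: float = 0.05
    max_gap: int = 12
    gap_speed_um_s: float = 2.0
    frame_interval_s: float = 1.0 / 17.0
    min_track_length: int = 10

    def birth_death_costs(self, blink: BlinkModel | None = None):
        blink = blink or BlinkModel()
        death = -math.log(min(blink.p_off + self.p_miss, 0.999))
        birth = -math.log(min(blink.p_on + self.p_miss, 0.999))
        return birth, death


def build_cost_matrix(xy_a: np.ndarray, xy_b: np.ndarray,
                      config: LinkConfig,
                      blink: BlinkModel | None = None) -> np.ndarray:
    """Augmented (n+m) x (n+m) LAP cost matrix for two frames.

    ``xy_a``/``xy_b`` are (n, 2) / (m, 2) positions in um.
    """
    a = np.asarray(xy_a, float).reshape(-1, 2)
    b = np.asarray(xy_b, float).reshape(-1, 2)
    n, m = len(a), len(b)
    birth, death = config.birth_death_costs(blink)
    link = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=2)
    link[link > config.max_link_distance ** 2] = _FORBIDDEN
    cost = np.full((n + m, n + m), _FORBIDDEN)
    cost[:n, :m] = link
    cost[np.arange(n), m + np.arange(n)] = death
    cost[n + np.arange(m), np.arange(m)] = birth
    # lower-right: transpose of feasible links (standard completion block)
    lr = link.T.copy()
    lr[np.isfinite(lr)] = 0.0
    cost[n:, m:] = lr
    return cost


def solve_assignment(cost: np.ndarray):
    """Minimum-cost perfect matching of a square matrix with forbidden
    (infinite) entries.  Returns (row_ind, col_ind); raises on infeasible
    matrices.  scipy's Jonker-Volgenant solver is deterministic, giving
    stable tie-breaking."""
    cost = np.asarray(cost, float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError("cost matrix must be square")
    try:
        rows, cols = linear_sum_assignment(cost)
    except ValueError as e:
        raise ValueError(f"infeasible assignment problem: {e}") from None
    if not np.isfinite(cost[rows, cols]).all():
        raise ValueError("infeasible assignment problem (forbidden entries)")
    return rows, cols


def _frame_to_frame(locs: pd.DataFrame, config: LinkConfig,
                    blink: BlinkModel | None):
    """First pass: per-frame LAP linking; returns a track id per row."""
    locs = locs.sort_values(["frame", "x_um", "y_um"], kind="stable")
    idx_by_frame = {f: sub.index.to_numpy()
                    for f, sub in locs.groupby("frame")}
    frames = sorted(idx_by_frame)
    track_of = pd.Series(-1, index=locs.index, dtype=int)
    next_id = 0
    prev_idx = np.array([], dtype=int)
    prev_frame = None
    for f in frames:
        cur_idx = idx_by_frame[f]
        if prev_frame is not None and f == prev_frame + 1 and len(prev_idx):
            a = locs.loc[prev_idx, ["x_um", "y_um"]].to_numpy()
            b = locs.loc[cur_idx, ["x_um", "y_um"]].to_numpy()
            cost = build_cost_matrix(a, b, config, blink)
            rows, cols = solve_assignment(cost)
            n, m = len(a), len(b)
            assigned = np.full(m, False)
            for r, c in zip(rows, cols):
                if r < n and c < m:
                    track_of[cur_idx[c]] = track_of[prev_idx[r]]
                    assigned[c] = True
            for j in range(m):
                if not assigned[j]:
                    track_of[cur_idx[j]] = next_id
                    next_id += 1
        else:
            for j in cur_idx:
                track_of[j] = next_id
                next_id += 1
        prev_idx = cur_idx
        prev_frame = f
    return track_of, next_id


def _gap_close(locs: pd.DataFrame, track_of: pd.Series, n_tracks: int,
               config: LinkConfig, blink: BlinkModel | None):
    """Second pass: LAP joining track ends to later starts across gaps."""
    birth, death = config.birth_death_costs(blink)
    segs = []
    for tid, sub in locs.groupby(track_of):
        sub = sub.sort_values("frame")
        segs.append({
            "tid": tid,
            "start_f": int(sub["frame"].iloc[0]),
            "end_f": int(sub["frame"].iloc[-1]),
            "start_xy": sub[["x_um", "y_um"]].iloc[0].to_numpy(),
            "end_xy": sub[["x_um", "y_um"]].iloc[-1].to_numpy()})
    segs.sort(key=lambda s: (s["start_f"], s["tid"]))
    k = len(segs)
    if k < 2:
        return track_of
    cost = np.full((2 * k, 2 * k), _FORBIDDEN)
    dt = config.frame_interval_s
    for i, si in enumerate(segs):
        for j, sj in enumerate(segs):
            g = sj["start_f"] - si["end_f"]
            if i == j or g < 2 or g - 1 > config.max_gap:
                continue
            d = float(np.hypot(*(sj["start_xy"] - si["end_xy"])))
            allowed = (config.max_link_distance * math.sqrt(g)
                       + config.gap_speed_um_s * g * dt)
            if d <= allowed:
                cost[i, j] = d * d + 0.01 * (g - 1)
    # terminal death / birth alternatives
    cost[np.arange(k), k + np.arange(k)] = birth + death
    cost[k + np.arange(k), np.arange(k)] = birth + death
    lr = cost[:k, :k].T.copy()
    lr[np.isfinite(lr)] = 0.0
    cost[k:, k:] = lr
    rows, cols = solve_assignment(cost)
    # union segments along accepted end->start joins
    parent = {s["tid"]: s["tid"] for s in segs}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for r, c in zip(rows, cols):
        if r < k and c < k:
            parent[find(segs[c]["tid"])] = find(segs[r]["tid"])
    return track_of.map(lambda t: find(t))


def link_movie(locs: pd.DataFrame, config: LinkConfig | None = None,
               blink: BlinkModel | None = None,
               camera=None) -> pd.DataFrame:
    """Link a localization table into trajectories.

    Expects accepted localizations with ``frame``, ``x_um``, ``y_um`` (and
    optionally photons / precisions, which are carried through).  Returns
    the same rows plus a ``track_id`` column, with tracks shorter than
    ``min_track_length`` localizations dropped and ids renumbered in order
    of first appearance (stable for fixed input).
    """
    config = config or LinkConfig()
    if camera is not None:
        config = LinkConfig(**{**config.__dict__,
                               "frame_interval_s": camera.frame_interval_s})
    if "accepted" in locs.columns:
        locs = locs[locs["accepted"]].copy()
    else:
        locs = locs.copy()
    if locs.empty:
        out = locs.copy()
        out["track_id"] = pd.Series(dtype=int)
        return out
    track_of, n_tracks = _frame_to_frame(locs, config, blink)
    track_of = _gap_close(locs, track_of, n_tracks, config, blink)
    out = locs.copy()
    out["track_id"] = track_of
    sizes = out.groupby("track_id")["frame"].size()
    keep = sizes[sizes >= config.min_track_length].index
    out = out[out["track_id"].isin(keep)].copy()
    # renumber by first appearance (frame, then x) for stable ids
    firsts = (out.groupby("track_id")
              .agg(f0=("frame", "min"), x0=("x_um", "min"))
              .sort_values(["f0", "x0"]))
    remap = {old: new for new, old in enumerate(firsts.index)}
    out["track_id"] = out["track_id"].map(remap)
    return out.sort_values(["track_id", "frame"]).reset_index(drop=True)
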