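"""Truth-matched evaluation of detection and linking.

Used by the test-suite and the acceptance harness to score recovered
localizations/trajectories against the generator's truth channel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["match_localizations", "detection_scores", "track_scores"]


def match_localizations(locs: pd.DataFrame, truth: pd.DataFrame,
                        tol_um: float = 0.3) -> pd.DataFrame:
    """Greedy nearest-neighbour match of localizations to visible truth.

    Returns ``locs`` plus a ``truth_id`` column (-1 where unmatched).
    Matching is per frame, closest pair first, one-to-one, within
    ``tol_um``.
    """
    truth_vis = truth[truth["visible"]]
    out = locs.copy()
    out["truth_id"] = -1
    for frame, sub in out.groupby("frame"):
        tv = truth_vis[truth_vis["frame"] == frame]
        if tv.empty:
            continue
        cand = []
        for i, row in sub.iterrows():
            d = np.hypot(tv["x_um"] - row["x_um"], tv["y_um"] - row["y_um"])
            for j, dist in zip(tv.index, d):
                if dist <= tol_um:
                    cand.append((dist, i, j))
        used_i, used_j = set(), set()
        for dist, i, j in sorted(cand):
            if i in used_i or j in used_j:
                continue
            out.at[i, "truth_id"] = int(truth_vis.at[j, "track_id"])
            used_i.add(i)
            used_j.add(j)
    return out


def detection_scores(locs: pd.DataFrame, truth: pd.DataFrame,
                     tol_um: float = 0.3) -> dict:
    """Recall/precision of per-frame detection against visible truth."""
    matched = match_localizations(locs, truth, tol_um)
    tp = int((matched["truth_id"] >= 0).sum())
    n_det = len(matched)
    n_truth = int(truth["visible"].sum())
    return {"recall": tp / n_truth if n_truth else np.nan,
            "precision": tp / n_det if n_det else np.nan,
            "n_detections": n_det, "n_truth": n_truth}


def track_scores(tracks: pd.DataFrame, truth: pd.DataFrame,
                 tol_um: float = 0.3) -> dict:
    """Purity and completeness of linked trajectories vs ground truth.

    Purity: fraction of a track's matched localizations that belong to its
    majority truth track, averaged over tracks (localization-weighted).
    Completeness: fraction of a truth track's visible frames recovered by
    its best-covering track, averaged over truth tracks.
    """
    matched = match_localizations(tracks, truth, tol_um)
    pure_num = pure_den = 0
    for tid, sub in matched.groupby("track_id"):
        ids = sub["truth_id"][sub["truth_id"] >= 0]
        if ids.empty:
            continue
        pure_num += int((ids == ids.mode().iloc[0]).sum())
        pure_den += len(ids)
    comp_vals = []
    for gid, tsub in truth[truth["visible"]].groupby("track_id"):
        hits = matched[matched["truth_id"] == gid]
        if hits.empty:
            comp_vals.append(0.0)
            continue
        best = hits.groupby("track_id")["frame"].size().max()
        comp_vals.append(best / len(tsub))
    return {"purity": pure_num / pure_den if pure_den else np.nan,
            "completeness": float(np.mean(comp_vals)) if comp_vals else np.nan}
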