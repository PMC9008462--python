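"""Region-stratified analysis: spatial context, 200-um transport
histograms, regional kinetic summaries, and coordinated-pair detection.

Localizations are mapped to an along-axon arc coordinate and labelled with
the chamber region they fall in (axonal compartment, microchannel =
distal axon, cell-body-compartment axon = proximal axon, soma).  A
trajectory's region is the one containing the majority of its
localizations.  Regional summaries mirror the study's comparative grid:
active speed, active duration and paused duration per region (interior
phases only), plus trajectory-level net speed and linearity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .geometry import ChamberGeometry, REGION_LABELS
from .motion import AxonPath
from .segmentation import Phase

__all__ = ["assign_region", "assign_track_regions", "spatial_histogram",
           "summarize_by_region", "detect_pairs", "compare_groups",
           "PairRecord"]


def assign_region(locs: pd.DataFrame, geometry: ChamberGeometry,
                  path: AxonPath | None = None) -> pd.DataFrame:
    """Attach ``arc_um``, ``distance_um`` and ``region`` columns.

    If the table has no ``arc_um`` column, positions are projected onto the
    axon path.  Distances are along-path arc distances from the ligand
    addition point.  Boundary points follow the half-open interval rule of
    the geometry, so each localization gets exactly one label.
    """
    out = locs.copy()
    if "arc_um" not in out.columns:
        path = path or geometry.default_path()
        out["arc_um"] = [path.arc_of_point(p)
                         for p in out[["x_um", "y_um"]].to_numpy()]
    out["distance_um"] = geometry.distance_from_source(out["arc_um"].to_numpy())
    out["region"] = geometry.region_of_arc(out["arc_um"].to_numpy())
    return out


def assign_track_regions(locs: pd.DataFrame) -> pd.Series:
    """Majority region per track (ties broken toward the soma-ward label)."""
    order = {lbl: i for i, lbl in enumerate(REGION_LABELS)}

    def majority(sub):
        counts = sub.value_counts()
        top = counts[counts == counts.max()]
        return max(top.index, key=lambda l: order.get(l, -1))

    return locs.groupby("track_id")["region"].agg(majority)


def spatial_histogram(locs: pd.DataFrame, bin_um: float = 200.0,
                      max_um: float | None = None,
                      replicate_col: str = "replicate",
                      geometry: ChamberGeometry | None = None) -> pd.DataFrame:
    """Mean +/- SEM counts per 200-um distance bin across replicates.

    Bins are fixed-width and left-closed ``[k*bin, (k+1)*bin)`` starting at
    the ligand addition point.  ``locs`` needs ``distance_um`` and a
    replicate id column; with a single replicate the SEM is NaN (flagged by
    ``n_replicates``).  When a geometry is supplied, each bin is annotated
    with whether it overlaps the microchannel span.
    """
    if replicate_col not in locs.columns:
        locs = locs.assign(**{replicate_col: 0})
    d = locs["distance_um"].to_numpy()
    if max_um is None:
        max_um = (np.floor(d.max() / bin_um) + 1) * bin_um if len(d) else bin_um
    edges = np.arange(0.0, max_um + bin_um, bin_um)
    reps = sorted(locs[replicate_col].unique())
    counts = np.zeros((len(reps), len(edges) - 1))
    for i, rep in enumerate(reps):
        dd = locs.loc[locs[replicate_col] == rep, "distance_um"].to_numpy()
        counts[i], _ = np.histogram(dd, bins=edges)
    mean = counts.mean(axis=0)
    sem = (counts.std(axis=0, ddof=1) / np.sqrt(len(reps))
           if len(reps) > 1 else np.full(len(mean), np.nan))
    out = pd.DataFrame({
        "bin_start_um": edges[:-1], "bin_end_um": edges[1:],
        "mean_count": mean, "sem": sem, "n_replicates": len(reps)})
    if geometry is not None:
        lo, hi = geometry.region_interval("microchannel")
        lo -= geometry.source_arc_um
        hi -= geometry.source_arc_um
        out["overlaps_microchannel"] = ((out["bin_start_um"] < hi)
                                        & (out["bin_end_um"] > lo))
    return out


def summarize_by_region(phases: list[Phase] | pd.DataFrame,
                        track_stats: pd.DataFrame,
                        track_regions: pd.Series) -> pd.DataFrame:
    """Regional kinetic grid: per region, interior-phase kinetics + n.

    Emits one row per (region, quantity) with mean, SEM (= SD / sqrt(n))
    and n; quantities are active net speed, active duration, paused
    duration (interior phases only, i.e. phases with observed endpoints)
    and trajectory-level net speed and linearity.  Regions with no data
    appear with n = 0.
    """
    if isinstance(phases, list):
        from .segmentation import phases_table
        phases = phases_table(phases)
    region_of = track_regions.to_dict()
    rows = []
    region_order = ["microchannel", "CBc_axon", "soma", "Ac"]
    for region in region_order:
        tids = [t for t, r in region_of.items() if r == region]
        ph = phases[phases["track_id"].isin(tids)] if len(phases) else phases
        inter = ph[ph["interior"]] if len(ph) else ph
        quantities = {
            "active_speed_um_s": inter.loc[inter["label"] == "active",
                                           "net_speed_um_s"],
            "active_duration_s": inter.loc[inter["label"] == "active",
                                           "duration_s"],
            "paused_duration_s": inter.loc[inter["label"] == "paused",
                                           "duration_s"],
            "paused_disp_um": inter.loc[inter["label"] == "paused",
                                        "net_disp_um"],
        }
        ts = track_stats[track_stats["track_id"].isin(tids)]
        quantities["s_net_um_s"] = ts["s_net_um_s"]
        quantities["r_lin"] = ts["r_lin"]
        for name, vals in quantities.items():
            vals = np.asarray(vals, float)
            n = len(vals)
            rows.append({
                "region": region, "quantity": name, "n": n,
                "mean": float(np.mean(vals)) if n else np.nan,
                "sem": float(np.std(vals, ddof=1) / np.sqrt(n))
                       if n > 1 else np.nan})
    return pd.DataFrame(rows)


@dataclass
class PairRecord:
    """Two co-temporal tracks travelling within pairing distance."""

    track_a: int
    track_b: int
    overlap_s: float
    mean_distance_um: float
    max_distance_um: float
    co_travel_um: float
    frames: np.ndarray
    distance_um: np.ndarray


def detect_pairs(tracks: pd.DataFrame, max_mean_distance_um: float = 2.0,
                 min_overlap_s: float = 5.0,
                 frame_interval_s: float = 1.0 / 17.0) -> list[PairRecord]:
    """Find coordinated pairs: co-temporal tracks staying < 2 um apart.

    The pairing criterion is a mean inter-distance below
    ``max_mean_distance_um`` sustained over at least ``min_overlap_s`` of
    shared frames; the full inter-distance series, its max, and the
    co-travelled distance (mean of the two members' path lengths over the
    overlap) are recorded.  Triplets appear as all of their pairwise
    records.
    """
    ids = sorted(tracks["track_id"].unique())
    by_id = {t: tracks[tracks["track_id"] == t].set_index("frame")
             for t in ids}
    out = []
    for a, b in combinations(ids, 2):
        common = by_id[a].index.intersection(by_id[b].index)
        if len(common) * frame_interval_s < min_overlap_s:
            continue
        pa = by_id[a].loc[common, ["x_um", "y_um"]].to_numpy()
        pb = by_id[b].loc[common, ["x_um", "y_um"]].to_numpy()
        dist = np.hypot(*(pa - pb).T)
        if dist.mean() >= max_mean_distance_um:
            continue
        step = lambda p: float(np.sum(np.hypot(*np.diff(p, axis=0).T)))
        out.append(PairRecord(
            track_a=int(a), track_b=int(b),
            overlap_s=float(len(common) * frame_interval_s),
            mean_distance_um=float(dist.mean()),
            max_distance_um=float(dist.max()),
            co_travel_um=0.5 * (step(pa) + step(pb)),
            frames=np.asarray(common, dtype=int), distance_um=dist))
    return out


def compare_groups(*groups, labels=None, alpha: float = 0.05,
                   correction: str = "bonferroni") -> dict:
    """Welch tests / one-way ANOVA with multiple-comparison adjustment.

    Two groups: Welch two-sample t test.  k > 2 groups: one-way ANOVA plus
    Bonferroni-adjusted pairwise Welch tests.  Degenerate (zero-variance,
    identical) groups short-circuit to p = 1.  Returns a report dict with
    per-group n / mean / SEM and the test statistics.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 observations per group")
    labels = labels or [f"group{i}" for i in range(len(arrays))]
    report = {"groups": [
        {"label": l, "n": len(a), "mean": float(a.mean()),
         "sem": float(a.std(ddof=1) / np.sqrt(len(a)))}
        for l, a in zip(labels, arrays)], "alpha": alpha}

    def welch(a, b):
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            return (0.0, 1.0) if a[0] == b[0] else (np.inf, 0.0)
        t, p = sstats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)

    if len(arrays) == 2:
        t, p = welch(*arrays)
        report.update(test="welch_t", statistic=t, p=p,
                      significant=bool(p < alpha))
        return report
    if all(np.ptp(a) == 0 for a in arrays) and \
            len({a[0] for a in arrays}) == 1:
        f, p = 0.0, 1.0
    else:
        f, p = sstats.f_oneway(*arrays)
    report.update(test="anova", statistic=float(f), p=float(p),
                  significant=bool(p < alpha))
    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    posthoc = []
    for (i, a), (j, b) in combinations(enumerate(arrays), 2):
        t, praw = welch(a, b)
        padj = min(1.0, praw * n_pairs) if correction == "bonferroni" else praw
        posthoc.append({"pair": (labels[i], labels[j]), "statistic": t,
                        "p_raw": praw, "p_adj": padj,
                        "significant": bool(padj < alpha)})
    report["posthoc"] = posthoc
    return report
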