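"""End-to-end orchestration: simulate -> (render -> calibrate -> detect ->
link) -> metrics -> segment -> regional analysis, with a run manifest.

Every random draw flows from the single top-level seed; identical
config + seed give byte-identical CSV outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationResult, gain_calibrate
from .config import PipelineConfig, config_hash, dump_config
from .detection import detect_movie
from .evaluate import track_scores
from .io import write_movie, write_table
from .linking import link_movie
from .metrics import instantaneous_velocity, stats_table
from .regional import (assign_region, assign_track_regions, detect_pairs,
                       spatial_histogram, summarize_by_region)
from .segmentation import classify_motion, phases_table, segment_phases
from .simulate import render_track_movie, simulate_preset_tracks, truth_to_table
from .metrics import compute_track_stats

__all__ = ["run_pipeline", "segment_tracks", "analyze_tracks"]


class StageError(RuntimeError):
    def __init__(self, stage, err):
        super().__init__(f"stage '{stage}' failed: {err}")
        self.stage = stage


def segment_tracks(tracks: pd.DataFrame, seg_config, link_config=None):
    """Classify every track and segment the AT ones into phases.

    Returns ``(stats_df, phases_df)`` where ``stats_df`` carries a
    ``motion_class`` column.
    """
    max_gap_s = None
    if link_config is not None:
        max_gap_s = (link_config.max_gap + 1) * link_config.frame_interval_s
    stats = stats_table(tracks, max_gap_s=max_gap_s, estimate_d=True)
    classes = {}
    all_phases = []
    for tid, sub in tracks.groupby("track_id"):
        sub = sub.sort_values("frame")
        xy = sub[["x_um", "y_um"]].to_numpy()
        t = sub["t_s"].to_numpy()
        frames = sub["frame"].to_numpy()
        if getattr(seg_config, "interpolate_gaps", True):
            from .segmentation import interpolate_gaps
            frames, t, xy = interpolate_gaps(frames, t, xy)
        vp = instantaneous_velocity(xy, t, frames=frames)
        st = compute_track_stats(xy, t, max_gap_s=max_gap_s)
        cls = classify_motion(st, vp, xy_um=xy, config=seg_config)
        classes[tid] = cls
        if cls == "AT":
            phases = segment_phases(xy, t, vp, frames=frames, track_id=tid,
                                    config=seg_config)
            # per-phase diffusion constant where the phase has support
            from .metrics import estimate_diffusion
            idx_of = {f: i for i, f in enumerate(frames)}
            for p in phases:
                lo = idx_of.get(p.start_frame)
                hi = idx_of.get(p.end_frame)
                if lo is None or hi is None or hi - lo < 11:
                    continue
                try:
                    p.D_um2_s, _ = estimate_diffusion(
                        xy[lo:hi + 1], t[lo:hi + 1], 0.0)
                except ValueError:
                    pass
            all_phases.extend(phases)
    stats["motion_class"] = stats["track_id"].map(classes)
    return stats, phases_table(all_phases)


def analyze_tracks(tracks: pd.DataFrame, stats: pd.DataFrame,
                   phases: pd.DataFrame, geometry, path=None,
                   frame_interval_s: float = 1.0 / 17.0):
    """Regional stratification: labels, histogram, summary grid, pairs."""
    labelled = assign_region(tracks, geometry, path)
    track_regions = assign_track_regions(labelled)
    hist = spatial_histogram(labelled, geometry=geometry)
    summary = summarize_by_region(phases, stats, track_regions)
    pairs = detect_pairs(tracks, frame_interval_s=frame_interval_s)
    pairs_df = pd.DataFrame([{
        "track_a": p.track_a, "track_b": p.track_b,
        "overlap_s": p.overlap_s, "mean_distance_um": p.mean_distance_um,
        "max_distance_um": p.max_distance_um,
        "co_travel_um": p.co_travel_um} for p in pairs])
    return labelled, track_regions, hist, summary, pairs_df


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the configured pipeline and write all outputs to ``out_dir``.

    With ``simulation.render`` false the truth positions (visible frames
    only) stand in for the imaging chain and flow directly into linking;
    with it true, movies are rendered, calibrated, detected and linked.
    Returns a manifest dict (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sim = config.simulation

    try:
        tracks_gt, path, geometry = simulate_preset_tracks(
            sim.preset, rng, geometry=config.geometry, camera=config.camera,
            n_tracks=sim.n_tracks, total_time_s=sim.total_time_s,
            blinking=sim.blinking)
        truth = truth_to_table(tracks_gt)
        write_table(out / "truth.csv", truth)
    except Exception as e:
        raise StageError("simulate", e)

    if sim.render:
        try:
            movie, truth_local, origin = render_track_movie(
                tracks_gt, config.camera, rng,
                psf_sigma_px=sim.psf_sigma_px,
                photons_per_frame=sim.photons_per_frame,
                bg_photons_px=sim.bg_photons_px)
            write_movie(out / "movie.tif", movie, config.camera,
                        extra_meta={"origin_x_um": origin[0],
                                    "origin_y_um": origin[1]})
        except Exception as e:
            raise StageError("render", e)
        try:
            calib = CalibrationResult(offset=config.camera.offset,
                                      read_noise=config.camera.read_noise,
                                      gain=config.camera.gain)
            photons = gain_calibrate(movie, calib)
            locs = detect_movie(photons, config.camera, config.detection)
        except Exception as e:
            raise StageError("detect", e)
        try:
            linked = link_movie(locs, config.linking, config.blink,
                                camera=config.camera)
            # back to device coordinates for regional analysis
            linked["x_um"] += origin[0]
            linked["y_um"] += origin[1]
            linked["t_s"] = linked["frame"] * config.camera.frame_interval_s
        except Exception as e:
            raise StageError("link", e)
    else:
        vis = truth[truth["visible"]].copy()
        linked = vis.rename(columns={})[
            ["track_id", "frame", "t_s", "x_um", "y_um"]].copy()
    write_table(out / "tracks.csv", linked)

    try:
        from .metrics import velocity_table
        write_table(out / "velocity.csv", velocity_table(linked))
        stats, phases = segment_tracks(linked, config.segmentation,
                                       config.linking)
        write_table(out / "track_stats.csv", stats)
        write_table(out / "phases.csv", phases)
    except Exception as e:
        raise StageError("segment", e)

    try:
        labelled, track_regions, hist, summary, pairs_df = analyze_tracks(
            linked, stats, phases, geometry, path,
            frame_interval_s=config.camera.frame_interval_s)
        write_table(out / "histogram.csv", hist)
        write_table(out / "regional_summary.csv", summary)
        write_table(out / "pairs.csv", pairs_df)
    except Exception as e:
        raise StageError("regional", e)

    manifest = {
        "axodyn_version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "preset": sim.preset,
        "n_tracks_simulated": len(tracks_gt),
        "n_tracks_linked": int(linked["track_id"].nunique()),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "config.yaml").write_text(dump_config(config))
    return manifest
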