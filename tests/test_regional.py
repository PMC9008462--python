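"""Region assignment, spatial histograms, regional kinetic summaries,
pair detection, and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from axodyn.camera import CameraModel
from axodyn.geometry import ChamberGeometry
from axodyn.metrics import stats_table
from axodyn.motion import AxonPath, MotionParams, simulate_pair
from axodyn.presets import KINETICS
from axodyn.regional import (assign_region, assign_track_regions,
                             compare_groups, detect_pairs, spatial_histogram,
                             summarize_by_region)
from axodyn.simulate import simulate_preset_tracks, truth_to_table


@pytest.fixture
def geometry():
    return ChamberGeometry()


class TestAssignRegion:
    def test_known_points(self, geometry):
        # Ac [0,100), microchannel [100,550), CBc [550,1550), soma [1550,1600)
        locs = pd.DataFrame({"arc_um": [50.0, 300.0, 600.0, 1560.0],
                             "track_id": [0, 1, 2, 3]})
        out = assign_region(locs, geometry)
        assert list(out["region"]) == ["Ac", "microchannel", "CBc_axon",
                                       "soma"]

    def test_boundary_point_follows_half_open_rule(self, geometry):
        locs = pd.DataFrame({"arc_um": [100.0, 550.0]})
        out1 = assign_region(locs, geometry)
        out2 = assign_region(locs, geometry)
        assert list(out1["region"]) == ["microchannel", "CBc_axon"]
        assert list(out1["region"]) == list(out2["region"])

    def test_every_point_gets_exactly_one_label(self, geometry, rng):
        locs = pd.DataFrame({"arc_um": rng.uniform(-50, 1700, 500)})
        out = assign_region(locs, geometry)
        assert out["region"].notna().all()
        inside = out[(out["arc_um"] >= 0) & (out["arc_um"] < 1600)]
        assert not (inside["region"] == "outside").any()
        outside = out[out["arc_um"] < 0]
        assert (outside["region"] == "outside").all()

    def test_positions_projected_onto_path(self, geometry):
        path = geometry.default_path()
        locs = pd.DataFrame({"x_um": [200.0], "y_um": [5.5],
                             "track_id": [0]})
        out = assign_region(locs, geometry, path)
        assert out["region"].iloc[0] == "microchannel"
        assert out["arc_um"].iloc[0] == pytest.approx(200.0, abs=0.01)


class TestSpatialHistogram:
    def test_single_bin_occupancy(self):
        locs = pd.DataFrame({"distance_um": np.full(30, 50.0)})
        h = spatial_histogram(locs)
        assert h["mean_count"].iloc[0] == 30
        assert h["mean_count"].iloc[1:].sum() == 0

    def test_counts_conserved(self, rng):
        locs = pd.DataFrame({
            "distance_um": rng.uniform(0, 900, 400),
            "replicate": rng.integers(0, 4, 400)})
        h = spatial_histogram(locs)
        per_rep = locs.groupby("replicate").size().mean()
        assert h["mean_count"].sum() == pytest.approx(per_rep)

    def test_uniform_fill_matches_multinomial(self):
        rng = np.random.default_rng(1)
        n = 5000
        locs = pd.DataFrame({"distance_um": rng.uniform(0, 1000, n)})
        h = spatial_histogram(locs, max_um=1000.0)
        expect = n / 5
        chi = sstats.chisquare(h["mean_count"].to_numpy()[:5])
        assert chi.pvalue > 0.01
        assert np.allclose(h["mean_count"][:5], expect, rtol=0.1)

    def test_sem_across_replicates(self):
        locs = pd.DataFrame({
            "distance_um": [50.0] * 4,
            "replicate": [0, 0, 1, 1]})
        h = spatial_histogram(locs)
        assert h["mean_count"].iloc[0] == 2.0
        assert h["sem"].iloc[0] == 0.0
        assert (h["n_replicates"] == 2).all()

    def test_single_replicate_flags_undefined_sem(self):
        locs = pd.DataFrame({"distance_um": [10.0, 20.0]})
        h = spatial_histogram(locs)
        assert np.isnan(h["sem"]).all()

    def test_dynein_blocked_preset_stays_in_axonal_compartment(self):
        tracks, path, geometry = simulate_preset_tracks(
            "ehna", 3, n_tracks=6, total_time_s=60.0)
        truth = truth_to_table(tracks)
        truth["distance_um"] = geometry.distance_from_source(
            truth["arc_um"].to_numpy())
        h = spatial_histogram(truth)
        beyond_channel = h[h["bin_start_um"] >= 600.0]
        assert beyond_channel["mean_count"].sum() == 0


class TestSummarizeByRegion:
    def test_distal_preset_net_speed_matches_renewal_rate(self, camera):
        """Trajectory net speed under run/pause alternation approaches
        s_a T_a / (T_a + T_p) ~ 0.88 um/s for the distal kinetics."""
        p = KINETICS["distal"]
        expected = (p.active_speed_mean * p.active_dur_mean
                    / (p.active_dur_mean + p.pause_dur_mean))
        tracks, path, geometry = simulate_preset_tracks(
            "distal", 7, n_tracks=30, total_time_s=120.0)
        rng = np.random.default_rng(0)
        tab = truth_to_table(tracks)
        tab["x_um"] += rng.normal(0, 0.02, len(tab))
        tab["y_um"] += rng.normal(0, 0.02, len(tab))
        stats = stats_table(tab, estimate_d=False)
        assert stats["s_net_um_s"].mean() == pytest.approx(expected,
                                                           rel=0.10)

    def test_grid_shape_and_empty_cells(self, geometry):
        phases = pd.DataFrame(columns=["track_id", "phase_id", "label",
                                       "start_frame", "end_frame",
                                       "duration_s", "net_disp_um",
                                       "net_speed_um_s", "interior"])
        stats = pd.DataFrame({"track_id": [0], "s_net_um_s": [1.0],
                              "r_lin": [0.5]})
        regions = pd.Series({0: "microchannel"})
        out = summarize_by_region(phases, stats, regions)
        assert set(out["region"]) == {"microchannel", "CBc_axon", "soma",
                                      "Ac"}
        empty = out[(out["region"] == "soma")
                    & (out["quantity"] == "active_speed_um_s")]
        assert int(empty["n"].iloc[0]) == 0

    def test_majority_region_assignment(self):
        locs = pd.DataFrame({
            "track_id": [1] * 3 + [2] * 3,
            "region": ["microchannel", "microchannel", "CBc_axon",
                       "CBc_axon", "CBc_axon", "soma"]})
        regions = assign_track_regions(locs)
        assert regions[1] == "microchannel"
        assert regions[2] == "CBc_axon"


class TestDetectPairs:
    def test_distant_tracks_not_paired(self):
        frames = np.arange(200)
        t1 = pd.DataFrame({"track_id": 0, "frame": frames,
                           "x_um": frames * 0.05, "y_um": 0.0})
        t2 = pd.DataFrame({"track_id": 1, "frame": frames,
                           "x_um": frames * 0.05, "y_um": 50.0})
        assert detect_pairs(pd.concat([t1, t2])) == []

    def test_simulated_pair_detected_within_two_um(self, camera):
        p = KINETICS["proximal"]
        from dataclasses import replace
        p = replace(p, motion_class="AT_pair")
        lead, follow = simulate_pair(p, AxonPath.straight(500.0), camera,
                                     np.random.default_rng(4),
                                     total_time=60.0)
        tab = truth_to_table([lead, follow])
        pairs = detect_pairs(tab)
        assert len(pairs) == 1
        assert pairs[0].max_distance_um < 2.0
        # coordinated transport covers tens of um over a minute
        assert pairs[0].co_travel_um > 50.0
        assert pairs[0].overlap_s > 40.0

    def test_short_overlap_ignored(self):
        f1 = np.arange(30)
        t1 = pd.DataFrame({"track_id": 0, "frame": f1, "x_um": 0.0,
                           "y_um": 0.0})
        t2 = pd.DataFrame({"track_id": 1, "frame": f1 + 25, "x_um": 0.1,
                           "y_um": 0.0})
        assert detect_pairs(pd.concat([t1, t2]), min_overlap_s=5.0) == []


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        a = [1.0, 2.0, 3.0, 4.0]
        rep = compare_groups(a, list(a))
        assert rep["p"] > 0.99
        assert not rep["significant"]

    def test_one_sd_shift_detected(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 50)
        rep = compare_groups(a, b)
        assert rep["significant"]
        assert rep["p"] < 0.001

    def test_three_group_anova_with_posthoc(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 40) for m in (0.0, 0.0, 1.5)]
        rep = compare_groups(*groups, labels=["a", "b", "c"])
        assert rep["test"] == "anova"
        assert rep["significant"]
        sig = {tuple(p["pair"]): p["significant"] for p in rep["posthoc"]}
        assert not sig[("a", "b")]
        assert sig[("a", "c")] and sig[("b", "c")]

    def test_type_one_error_near_alpha(self):
        """Under the null, the ANOVA rejects at ~ the nominal 5% rate."""
        rng = np.random.default_rng(4)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            g = [rng.normal(0, 1, 15) for _ in range(3)]
            f, p = sstats.f_oneway(*g)
            rejections += p < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.015)

    def test_degenerate_variance_fast_path(self):
        rep = compare_groups([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert rep["p"] == 1.0
        rep2 = compare_groups([2.0, 2.0], [3.0, 3.0])
        assert rep2["p"] == 0.0

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])
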