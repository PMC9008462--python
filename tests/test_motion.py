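"""Ground-truth motion generator: phase renewal process, motion classes,
pair coupling, and blinking."""

import numpy as np
import pytest
from scipy import stats as sstats

from axodyn.camera import CameraModel
from axodyn.motion import (PHASE_DURATION_FLOOR_S, AxonPath, BlinkModel,
                           MotionParams, apply_blinking,
                           sample_phase_sequence, simulate_pair,
                           simulate_trajectory)
from axodyn.presets import KINETICS


class TestPhaseSequence:
    def test_durations_tile_total_time(self, rng):
        phases = sample_phase_sequence(KINETICS["distal"], 120.0, rng)
        assert sum(d for _, d in phases) == pytest.approx(120.0)
        labels = [l for l, _ in phases]
        assert all(a != b for a, b in zip(labels, labels[1:]))

    def test_equilibrium_start_label_frequencies(self):
        # a track picked up mid-transport starts active with probability
        # T_a / (T_a + T_p)
        p = KINETICS["proximal"]
        expect = p.active_dur_mean / (p.active_dur_mean + p.pause_dur_mean)
        first = [sample_phase_sequence(p, 60.0, s)[0][0] == "active"
                 for s in range(800)]
        assert np.mean(first) == pytest.approx(expect, abs=0.06)

    def test_non_equilibrium_start_is_active(self, rng):
        phases = sample_phase_sequence(KINETICS["distal"], 120.0, rng,
                                       equilibrium_start=False)
        assert phases[0][0] == "active"

    def test_mean_phase_count_matches_renewal_expectation(self):
        # renewal theory: E[phases in T] ~ 2 T / (T_a + T_p); for the distal
        # kinetics the mean cycle is 7.218 + 5.285 = 12.5 s, so a 120-s track
        # holds ~9.6 cycles ~ 19 phases on average
        p = KINETICS["distal"]
        expected = 2 * 120.0 / (p.active_dur_mean + p.pause_dur_mean)
        counts = [len(sample_phase_sequence(p, 120.0, seed))
                  for seed in range(1000)]
        assert np.mean(counts) == pytest.approx(expected, rel=0.10)

    def test_zero_pause_mean_gives_single_active_phase(self, rng):
        p = MotionParams(pause_dur_mean=0.0)
        assert sample_phase_sequence(p, 50.0, rng) == [("active", 50.0)]

    def test_fixed_seed_reproducible(self):
        a = sample_phase_sequence(KINETICS["proximal"], 60.0, 7)
        b = sample_phase_sequence(KINETICS["proximal"], 60.0, 7)
        assert a == b

    def test_nonpositive_mean_rejected(self, rng):
        with pytest.raises(ValueError):
            MotionParams(active_dur_mean=-1.0)
        with pytest.raises(ValueError):
            sample_phase_sequence(KINETICS["distal"], -5.0, rng)

    def test_durations_respect_floor(self, rng):
        phases = sample_phase_sequence(KINETICS["proximal"], 300.0, rng)
        # all phases except the two clipped by the observation window
        # (burn-in boundary and end truncation) are at or above the floor
        assert all(d >= PHASE_DURATION_FLOOR_S for _, d in phases[1:-1])


class TestSimulateTrajectory:
    def test_stationary_with_zero_jitter_is_constant(self, rng, camera):
        p = MotionParams(motion_class="S", pause_jitter_sd=0.0)
        tr = simulate_trajectory(p, AxonPath.straight(100.0), camera, rng,
                                 total_time=5.0, start_arc_um=30.0)
        assert np.allclose(tr.xy_um, tr.xy_um[0])

    def test_single_run_kinematics(self, rng, camera):
        # one active phase at exactly 1.5 um/s for 10 s -> 15 um net
        p = MotionParams(active_speed_mean=1.5, active_speed_sd=0.0,
                         pause_dur_mean=0.0, pause_jitter_sd=0.0)
        tr = simulate_trajectory(p, AxonPath.straight(100.0), camera, rng,
                                 total_time=10.0)
        assert tr.t_s[-1] == pytest.approx(10.0)
        net = np.hypot(*(tr.xy_um[-1] - tr.xy_um[0]))
        assert net == pytest.approx(15.0, abs=1e-9)

    def test_confined_walk_stays_inside_and_fills_domain(self, camera):
        # final positions of many independent walks, each run far beyond the
        # mixing time L^2 / 2D, are uniform on the confinement domain
        p = MotionParams(motion_class="B&F", confinement_length=5.0,
                         bf_diffusion=0.5, pause_jitter_sd=0.0)
        path = AxonPath.straight(100.0)
        finals = []
        for seed in range(200):
            tr = simulate_trajectory(p, path, camera, seed,
                                     total_time=60.0, start_arc_um=10.0)
            assert tr.arc_um.min() >= 10.0 - 1e-9
            assert tr.arc_um.max() <= 15.0 + 1e-9
            finals.append(tr.arc_um[-1])
        stat = sstats.kstest(finals, sstats.uniform(10.0, 5.0).cdf)
        assert stat.pvalue > 0.01

    def test_runs_off_path_end_is_truncated_and_flagged(self, rng, camera):
        p = MotionParams(active_speed_mean=2.0, active_speed_sd=0.0,
                         pause_dur_mean=0.0)
        tr = simulate_trajectory(p, AxonPath.straight(10.0), camera, rng,
                                 total_time=60.0)
        assert tr.truncated
        assert tr.t_s[-1] < 60.0

    def test_phase_labels_alternate_in_blocks(self, rng, camera):
        tr = simulate_trajectory(KINETICS["proximal"],
                                 AxonPath.straight(1000.0), camera, rng,
                                 total_time=60.0)
        labels = [l for l, _, _ in tr.phase_intervals()]
        assert all(a != b for a, b in zip(labels, labels[1:]))


class TestSimulatePair:
    def test_zero_coupling_sd_keeps_constant_separation(self, rng, camera):
        p = MotionParams(motion_class="AT_pair", pair_coupling_rest=0.5,
                         pair_coupling_sd=0.0, pause_jitter_sd=0.0)
        lead, follow = simulate_pair(p, AxonPath.straight(500.0), camera,
                                     rng, total_time=20.0)
        sep = np.hypot(*(lead.xy_um - follow.xy_um).T)
        # constant except where the follower hits the path start
        assert np.allclose(sep[5:], 0.5, atol=1e-9)

    def test_default_coupling_never_reaches_two_um(self, camera):
        p = KINETICS["proximal"]
        from dataclasses import replace
        p = replace(p, motion_class="AT_pair")
        for seed in range(10):
            lead, follow = simulate_pair(p, AxonPath.straight(500.0), camera,
                                         seed, total_time=40.0)
            sep = np.hypot(*(lead.xy_um - follow.xy_um).T)
            assert sep.max() < 2.0

    def test_pair_shares_phase_boundaries(self, rng, camera):
        p = MotionParams(motion_class="AT_pair")
        lead, follow = simulate_pair(p, AxonPath.straight(500.0), camera,
                                     rng, total_time=30.0)
        assert np.array_equal(lead.phase, follow.phase)
        assert lead.partner_id == follow.track_id

    def test_excessive_coupling_rejected(self, rng, camera):
        p = MotionParams(motion_class="AT_pair", pair_coupling_rest=1.8,
                         pair_coupling_sd=0.3)
        with pytest.raises(ValueError, match="2 um"):
            simulate_pair(p, AxonPath.straight(500.0), camera, rng)


class TestBlinking:
    def _long_track(self, camera, total_time):
        p = MotionParams(motion_class="S")
        return simulate_trajectory(p, AxonPath.straight(10.0), camera,
                                   np.random.default_rng(0),
                                   total_time=total_time, start_arc_um=5.0)

    def test_zero_off_probability_always_visible(self, rng, camera):
        tr = self._long_track(camera, 30.0)
        mask = apply_blinking(tr, BlinkModel(p_off=0.0, p_on=0.5), rng)
        assert mask.all()

    def test_dark_dwells_are_geometric(self, camera):
        # p_on = 0.5 -> geometric dark dwells with mean 2 frames
        tr = self._long_track(camera, 6000.0)
        mask = apply_blinking(tr, BlinkModel(p_off=0.2, p_on=0.5),
                              np.random.default_rng(99))
        # extract dark dwell lengths
        dark = ~mask
        dwells = []
        run = 0
        for d in dark:
            if d:
                run += 1
            elif run:
                dwells.append(run)
                run = 0
        dwells = np.array(dwells)
        assert len(dwells) > 3000
        assert dwells.mean() == pytest.approx(2.0, rel=0.05)
        # chi-square against Geometric(0.5) on pooled tail
        kmax = 8
        obs = np.array([(dwells == k).sum() for k in range(1, kmax)]
                       + [(dwells >= kmax).sum()])
        pmf = np.array([0.5 ** k for k in range(1, kmax)]
                       + [0.5 ** (kmax - 1)])
        chi = sstats.chisquare(obs, pmf * len(dwells))
        assert chi.pvalue > 0.01

    def test_fixed_seed_reproducible_mask(self, camera):
        tr = self._long_track(camera, 30.0)
        m1 = apply_blinking(tr, BlinkModel(), np.random.default_rng(5))
        m2 = apply_blinking(tr, BlinkModel(), np.random.default_rng(5))
        assert np.array_equal(m1, m2)


def test_at_long_run_net_speed_matches_renewal_rate(camera):
    """Long-run net speed converges to s_a * T_a / (T_a + T_p)."""
    p = KINETICS["proximal"]
    expected = (p.active_speed_mean * p.active_dur_mean
                / (p.active_dur_mean + p.pause_dur_mean))
    path = AxonPath.straight(100000.0)
    speeds = []
    for seed in range(30):
        tr = simulate_trajectory(p, path, camera, seed, total_time=1000.0)
        speeds.append(np.hypot(*(tr.xy_um[-1] - tr.xy_um[0])) / tr.t_s[-1])
    assert np.mean(speeds) == pytest.approx(expected, rel=0.02)
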