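"""Tests of the peri-personal-space network: dynamics, plasticity, decoding."""

import warnings

import numpy as np
import pandas as pd
import pytest

from perispace.network import (
    LateralKernel,
    NetworkConfig,
    PPSNetwork,
    StimulusSpec,
    build_network,
    decode_rt,
    default_config,
    external_input,
    run_session,
    session_schedule,
)
from perispace.network.model import _grid_axes


@pytest.fixture
def cfg():
    return default_config()


class TestBuild:
    def test_grid_coverage(self, cfg):
        assert cfg.grid.tactile_extent == (20.0, 20.0)
        assert cfg.grid.visual_extent == (400.0, 400.0)
        net = build_network(cfg)
        assert net.w_tactile.shape == (41, 41)
        assert np.allclose(net.w_tactile, net.w_tactile_basal)
        # basal visual weights are maximal at the body and decay with distance
        assert net.w_visual.max() == pytest.approx(cfg.feedforward.w0_visual)
        assert net.w_visual[-1, 0] < 0.1 * net.w_visual.max()

    def test_state_at_rest(self, cfg):
        net = build_network(cfg)
        assert np.all(net.q_tactile == 0) and net.q_multi == 0
        assert net.z_multi < 0.05

    def test_feedback_mirrors_basal_pattern(self, cfg):
        net = build_network(cfg)
        ratio = net.b_visual / net.w_visual_basal
        assert np.allclose(ratio, ratio.flat[0])

    def test_zero_amplitude_kernel_is_identically_zero(self):
        k = LateralKernel(exc_amp=0.0, exc_sigma=1.0, inh_amp=0.0, inh_sigma=4.0)
        assert np.all(k.kernel_2d() == 0)

    def test_mexican_hat_shape(self):
        k = LateralKernel()
        m = k.kernel_2d(radius=12)
        c = m.shape[0] // 2
        assert m[c, c] > 0            # near excitation
        assert m[c, c + 8] < 0        # far inhibition

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            LateralKernel(exc_amp=0.5, inh_amp=1.0)
        with pytest.raises(ValueError):
            NetworkConfig(tactile=default_config().tactile.__class__(tau=2.0))

    def test_yaml_round_trip(self, cfg, tmp_path):
        path = tmp_path / "net.yaml"
        cfg.to_yaml(path)
        back = NetworkConfig.from_yaml(path)
        assert back == cfg


class TestExternalInput:
    def test_peak_on_receptive_field_centre(self, cfg):
        stim = StimulusSpec(modality="visual", amplitude=20.0, sigma=5.0,
                            position=100.0)
        e = external_input(stim, cfg.grid, 10.0, rf_sigma=8.0)
        depth, lateral = _grid_axes(cfg.grid, "visual")
        i, j = np.unravel_index(np.argmax(e), e.shape)
        assert depth[i] == 100.0 and lateral[j] == 0.0
        assert e.max() == pytest.approx(20.0)

    def test_zero_before_onset_and_after_offset(self, cfg):
        stim = StimulusSpec(modality="tactile", onset=100.0, offset=200.0)
        assert not external_input(stim, cfg.grid, 50.0, 0.5).any()
        assert not external_input(stim, cfg.grid, 200.0, 0.5).any()
        assert external_input(stim, cfg.grid, 150.0, 0.5).any()

    def test_looming_position(self):
        stim = StimulusSpec(modality="visual", start_distance=200.0,
                            velocity=75.0, onset=0.0)
        assert stim.distance_at(1000.0) == pytest.approx(125.0)  # 200 - 75*1
        assert stim.distance_at(1e6) == 0.0  # clamped at the body

    def test_outside_space_warns_and_zeros(self, cfg):
        stim = StimulusSpec(modality="visual", position=900.0, sigma=5.0)
        with pytest.warns(UserWarning):
            e = external_input(stim, cfg.grid, 0.0, rf_sigma=8.0)
        assert not e.any()


class TestDynamics:
    def _quiet_config(self):
        # no lateral coupling, no feedback: isolates the membrane equation
        c = default_config()
        c.lateral_tactile.exc_amp = 0.0
        c.lateral_tactile.inh_amp = 0.0
        c.lateral_visual.exc_amp = 0.0
        c.lateral_visual.inh_amp = 0.0
        c.feedback.b0_tactile = 0.0
        c.feedback.b0_visual = 0.0
        return c

    def test_state_converges_to_constant_input(self):
        net = PPSNetwork(self._quiet_config())
        e = np.full((41, 41), 7.3)
        for _ in range(400):  # 20 tau
            net.step(e, np.zeros((41, 41)), learn=False)
        assert np.allclose(net.q_tactile, 7.3, atol=1e-6)

    def test_activation_midpoint_at_theta(self):
        net = PPSNetwork(self._quiet_config())
        p = net.config.tactile
        e = np.full((41, 41), p.theta)
        for _ in range(600):
            net.step(e, np.zeros((41, 41)), learn=False)
        assert np.allclose(net.z_tactile, (p.f_min + p.f_max) / 2, atol=1e-4)

    def test_multisensory_input_zero_at_rest(self, cfg):
        net = PPSNetwork(cfg)
        u_m = np.sum(net.w_tactile * net.z_tactile) + np.sum(net.w_visual * net.z_visual)
        assert u_m < 1e-6

    def test_activation_bounds_hold_throughout_a_trial(self, cfg):
        net = PPSNetwork(cfg)
        vis = StimulusSpec(**{**cfg.visual_stimulus.__dict__, "onset": 0.0,
                              "offset": 800.0})
        zeros = np.zeros((41, 41))
        tact = StimulusSpec(**{**cfg.tactile_stimulus.__dict__, "onset": 300.0,
                               "offset": 600.0})
        for t in range(800):
            net.step(external_input(tact, cfg.grid, t, cfg.sim.rf_sigma_tactile),
                     external_input(vis, cfg.grid, t, cfg.sim.rf_sigma_visual))
            for z, p in ((net.z_tactile, cfg.tactile), (net.z_visual, cfg.visual)):
                assert z.min() >= p.f_min and z.max() <= p.f_max
            assert 0.0 <= net.w_visual.min()
            assert net.w_visual.max() <= net.w_visual_max + 1e-12
            assert net.w_tactile.max() <= net.w_tactile_max + 1e-12


class TestHebbianRule:
    def test_no_change_at_basal_weights_below_gate(self, cfg):
        net = PPSNetwork(cfg)
        w_before = net.w_visual.copy()
        net.z_multi = 0.0  # below the gate; weights at basal
        net.hebbian_update()
        assert np.array_equal(net.w_visual, w_before)
        assert np.array_equal(net.w_tactile, net.w_tactile_basal)

    def test_saturated_weights_only_forget(self, cfg):
        net = PPSNetwork(cfg)
        net.w_visual[:] = net.w_visual_max
        net.z_visual[:] = 1.0
        net.z_multi = 1.0
        net.hebbian_update()
        k = cfg.hebbian.k_h
        expected = net.w_visual_max - k * (net.w_visual_max - net.w_visual_basal)
        assert np.allclose(net.w_visual, expected)

    def test_closed_form_decay_matches_simulation(self, cfg):
        net = PPSNetwork(cfg)
        rng = np.random.default_rng(0)
        net.w_visual = net.w_visual_basal + 0.5 * rng.random((41, 41)) * (
            net.w_visual_max - net.w_visual_basal)
        w_start = net.w_visual.copy()
        n = 500
        zeros = np.zeros((41, 41))
        for _ in range(n):
            net.step(zeros, zeros, learn=True)
        expected = net.w_visual_basal + (1 - cfg.hebbian.k_h) ** n * (
            w_start - net.w_visual_basal)
        rel = np.abs(net.w_visual - expected) / np.abs(w_start - net.w_visual_basal).max()
        assert rel.max() < 1e-10

    def test_idle_equals_stepped_forgetting(self, cfg):
        a, b = PPSNetwork(cfg), PPSNetwork(cfg)
        for net in (a, b):
            net.w_visual = net.w_visual_basal * 1.2
            np.clip(net.w_visual, None, net.w_visual_max, out=net.w_visual)
        a.idle(0.25)
        zeros = np.zeros((41, 41))
        for _ in range(250):
            b.step(zeros, zeros, learn=True)
        assert np.allclose(a.w_visual, b.w_visual, atol=1e-12)


class TestDecodeRT:
    def test_zero_trace_times_out(self):
        assert np.isnan(decode_rt(np.zeros(100), 4.0))

    def test_ramp_crossing(self):
        trace = np.linspace(0, 8, 241)  # crosses 4 exactly at step 120
        assert decode_rt(trace, 4.0) == 120.0

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            decode_rt([], 4.0)


class TestTrials:
    def test_unisensory_slower_than_near_multisensory(self, cfg):
        net = PPSNetwork(cfg)
        uni = net.run_trial(None, 800.0, learn=False)
        net.reset_weights()
        vis = StimulusSpec(**{**cfg.visual_stimulus.__dict__,
                              "start_distance": 200.0, "velocity": 75.0})
        near = net.run_trial(vis, (200 - 55.25) / 75 * 1000, learn=False)
        assert near["network_rt"] < uni["network_rt"]
        assert uni["network_rt"] > 0

    def test_far_stimulus_approximates_unisensory(self, cfg):
        cfg.visual_stimulus.start_distance = 400.0
        net = PPSNetwork(cfg)
        uni = net.run_trial(None, 400.0, learn=False)
        vis = StimulusSpec(**{**cfg.visual_stimulus.__dict__,
                              "start_distance": 400.0, "velocity": 75.0})
        far = net.run_trial(vis, 400.0, learn=False)  # still ~370 cm away
        assert abs(far["network_rt"] - uni["network_rt"]) <= 2.0

    def test_monotone_weights_speed_repeated_trials(self, cfg):
        cfg.hebbian.tau_h = 1e9  # forgetting effectively off
        net = PPSNetwork(cfg)
        vis = StimulusSpec(**{**cfg.visual_stimulus.__dict__,
                              "start_distance": 200.0, "velocity": 75.0})
        onset = (200 - 103.25) / 75 * 1000
        first = net.run_trial(vis, onset)
        second = net.run_trial(vis, onset)
        assert second["network_rt"] <= first["network_rt"]

    def test_frozen_rt_non_increasing_toward_body(self, cfg):
        net = PPSNetwork(cfg)
        rts = []
        for d in (175.25, 127.25, 79.25, 55.25):
            net.reset_weights()
            vis = StimulusSpec(**{**cfg.visual_stimulus.__dict__,
                                  "start_distance": 200.0, "velocity": 75.0})
            rts.append(net.run_trial(vis, (200 - d) / 75 * 1000,
                                     learn=False)["network_rt"])
        assert all(b <= a for a, b in zip(rts, rts[1:]))


class TestSessions:
    def _fast_kwargs(self):
        # short sessions: two interior distances, high velocity
        return dict(distances_cm=(103.25, 127.25), velocity=150.0, n_reps=2)

    def test_schedule_is_seeded_permutation(self):
        a = session_schedule((100.0, 150.0), 75.0, n_reps=3, seed=4)
        b = session_schedule((100.0, 150.0), 75.0, n_reps=3, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 9  # 2 conditions * 3 + unisensory * 3
        assert (a["condition"] == 0).sum() == 3

    def test_same_seed_bitwise_identical_rt_tables(self, cfg):
        t1 = run_session(PPSNetwork(cfg), seed=7, **self._fast_kwargs())
        t2 = run_session(PPSNetwork(cfg), seed=7, **self._fast_kwargs())
        pd.testing.assert_frame_equal(t1, t2)

    def test_unisensory_only_schedule_leaves_weights_basal(self, cfg):
        net = PPSNetwork(cfg)
        sched = session_schedule((103.25,), 150.0, n_reps=3, seed=0)
        sched = sched[sched["condition"] == 0].reset_index(drop=True)
        run_session(net, schedule=sched)
        # visual presynaptic activity is at rest, so no visual reinforcement
        assert np.allclose(net.w_visual, net.w_visual_basal, atol=1e-6)
        assert np.allclose(net.w_tactile, net.w_tactile_basal, atol=1e-9)
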