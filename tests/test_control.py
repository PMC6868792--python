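"""Velocity shaping, kinematics, target generation and the trial engine."""

import numpy as np
import pytest

import myoknn as mk
from myoknn.control import (
    ControllerConfig,
    OracleDecoder,
    SessionSpec,
    generate_postural_block,
    generate_session_targets,
    integrate_hand,
    run_session,
    run_trial,
    shape_velocity,
    validate_session_targets,
)
from myoknn.hand import ROM_MAX, ROM_MIN, ROM_SPAN, HandState, neutral_posture


class TestShapeVelocity:
    def test_subthreshold_commands_zeroed(self):
        cfg = ControllerConfig()
        np.testing.assert_allclose(
            shape_velocity([0.05, 0.0, 0.0], cfg), 0.0
        )

    def test_gain_applied_before_unit_scaling(self):
        cfg = ControllerConfig(gain=3.0)
        v = shape_velocity([0.2, 0.0, 0.0], cfg)
        assert v[0] == pytest.approx(0.6 * cfg.max_speed[0])

    def test_saturates_at_max_speed(self):
        cfg = ControllerConfig(gain=7.0)
        v = shape_velocity([1.0, 1.0, 1.0], cfg)
        np.testing.assert_allclose(v, cfg.max_speed)

    def test_negative_commands_symmetric(self):
        cfg = ControllerConfig()
        np.testing.assert_allclose(
            shape_velocity([-0.2, 0, 0], cfg), -shape_velocity([0.2, 0, 0], cfg)
        )


class TestIntegrateHand:
    def test_zero_velocity_identity(self):
        s = neutral_posture().as_array()
        np.testing.assert_array_equal(integrate_hand(s, np.zeros(3), 0.05), s)

    def test_clips_at_rom_boundary(self):
        s = np.array([179.0, 0.0, 50.0])
        out = integrate_hand(s, np.array([90.0, 0.0, 0.0]), 0.05)
        assert out[0] == 180.0

    def test_euler_step_arithmetic(self):
        s = np.array([90.0, -10.0, 50.0])
        out = integrate_hand(s, np.array([0.0, 40.0, 0.0]), 0.05)
        assert out[1] == pytest.approx(-8.0)


class TestTargets:
    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_session_targets_satisfy_protocol_constraints(self, seed):
        spec = SessionSpec(n_targets=80, block_size=16, seed=seed)
        targets = generate_session_targets(spec)
        assert len(targets) == 80
        validate_session_targets(targets)  # independent post-hoc validator

    def test_same_seed_same_targets(self):
        spec = SessionSpec(seed=5)
        a = generate_session_targets(spec)
        b = generate_session_targets(spec)
        assert all(
            np.array_equal(x.as_array(), y.as_array()) for x, y in zip(a, b)
        )

    def test_postural_block_alternates_neutral_and_extremes(self):
        block = generate_postural_block(seed=3)
        assert len(block) == 16
        for i, t in enumerate(block):
            if i % 2 == 0:
                np.testing.assert_allclose(t.as_array(), [90.0, 5.0, 50.0])
            else:
                frac = (t.as_array() - ROM_MIN) / ROM_SPAN
                assert set(np.round(frac, 10)) <= {0.10, 0.90}


class _ScriptedDecoder:
    """Replays a fixed sequence of raw commands, ignoring subject intent."""

    def __init__(self, commands):
        self.commands = list(commands)
        self.i = 0

    def decode(self, intent, rng):
        cmd = self.commands[self.i] if self.i < len(self.commands) else [0, 0, 0]
        self.i += 1
        return np.asarray(cmd, dtype=float)


class TestRunTrial:
    def _policy(self):
        return mk.SubjectPolicy(intent_noise_sd=0.0)

    def test_zero_command_fails_at_exactly_30s(self):
        dec = _ScriptedDecoder([])
        target = HandState(160.0, 60.0, 90.0)
        rec = run_trial(dec, self._policy(), target, seed=0)
        assert not rec.success
        assert rec.trial_time_s == 30.0
        assert rec.trajectory.shape[0] == 601

    def test_perfect_decoder_nearby_target_succeeds_fast(self):
        target = HandState.from_array(
            neutral_posture().as_array() + 0.31 * ROM_SPAN
        )
        rec = run_trial(OracleDecoder(), self._policy(), target, seed=0)
        assert rec.success
        assert rec.trial_time_s >= 1.05  # at least one movement frame + dwell

    def test_dwell_counter_resets_on_tolerance_exit(self):
        """Push out of tolerance mid-dwell; the 1 s hold must restart.

        Frames 1-13: stationary then drifting but inside +-27 deg pronation
        tolerance; frame 14 exits; the return path re-enters at frame 15 and
        the 20-frame dwell completes at frame 34 (1.7 s).
        """
        cmds = [[0, 0, 0]] * 10 + [[1, 0, 0]] * 4 + [[-1, 0, 0]] * 4
        dec = _ScriptedDecoder(cmds)
        rec = run_trial(dec, self._policy(), neutral_posture(), seed=0)
        assert rec.success
        assert rec.trial_time_s == pytest.approx(34 * 0.05)
        assert rec.dwell_start_index == 15

    def test_in_tolerance_start_completes_dwell_in_one_second(self):
        rec = run_trial(_ScriptedDecoder([]), self._policy(), neutral_posture())
        assert rec.success
        assert rec.trial_time_s == pytest.approx(1.0)

    def test_trajectory_never_leaves_rom(self):
        dec = _ScriptedDecoder([[1.0, 1.0, 1.0]] * 600)
        rec = run_trial(dec, self._policy(), HandState(160.0, 60.0, 90.0), seed=0)
        assert np.all(rec.trajectory >= ROM_MIN - 1e-9)
        assert np.all(rec.trajectory <= ROM_MAX + 1e-9)

    def test_bitwise_reproducible_given_seed(self):
        policy = mk.SubjectPolicy()
        target = HandState(150.0, 50.0, 80.0)
        a = run_trial(OracleDecoder(), policy, target, seed=42)
        b = run_trial(OracleDecoder(), policy, target, seed=42)
        assert np.array_equal(a.trajectory, b.trajectory)
        assert a.trial_time_s == b.trial_time_s


class TestRunSession:
    def test_oracle_decoder_session_ceiling(self):
        """A perfect decoder passes every trial: the engine's sanity ceiling."""
        spec = SessionSpec(n_targets=16, block_size=16, seed=2)
        res = run_session(spec, OracleDecoder())
        assert res.summary["success_rate"] == 100.0
        assert res.summary["path_efficiency_mean"] > 80.0

    def test_temporal_session_block_structure(self):
        spec = SessionSpec(n_targets=32, block_size=16, seed=0)
        res = run_session(spec, OracleDecoder())
        assert len(res.trials) == 32

    def test_postural_session_targets(self):
        spec = SessionSpec(n_targets=16, block_size=16, protocol="postural", seed=0)
        res = run_session(spec, OracleDecoder())
        np.testing.assert_allclose(
            res.trials[0].target.as_array(), [90.0, 5.0, 50.0]
        )

    def test_empty_session_flagged_undefined(self):
        spec = SessionSpec(n_targets=0, block_size=16, seed=0)
        res = run_session(spec, OracleDecoder())
        assert res.summary["undefined"]

    def test_success_implies_final_dwell_in_tolerance(self):
        spec = SessionSpec(n_targets=16, block_size=16, seed=7)
        res = run_session(spec, OracleDecoder())
        for t in res.trials:
            assert t.success
            tail = t.trajectory[-20:]
            tol = 0.15 * ROM_SPAN
            assert np.all(np.abs(tail - t.target.as_array()) <= tol + 1e-9)
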