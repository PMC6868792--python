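"""Virtual subject: synergies, EMG synthesis, conditions, cyclic bursts."""

import numpy as np
import pytest

import myoknn as mk
from myoknn.labeling import IntentSeries
from myoknn.synthetic import (
    ConfigurationError,
    ObservabilityError,
    apply_recording_condition,
    axis_pulse_intent,
    identity_crosstalk,
    make_synergy_matrix,
    realized_snr_db,
    simulate_cyclic_contraction,
    simulate_emg,
    surface_crosstalk,
    virtual_subject_intent,
)


def _held_intent(direction, duration=10.0, step=0.05, rest=5.0):
    """Intent held constant for `duration` s, then zero for `rest` s."""
    times = np.arange(step, duration + rest + 1e-9, step)
    values = np.zeros((len(times), 3))
    values[times <= duration] = direction
    return IntentSeries(times=times, values=values)


class TestSynergy:
    def test_rows_unit_norm_and_rank_three_by_svd_oracle(self):
        W = make_synergy_matrix(8, seed=1)
        np.testing.assert_allclose(np.linalg.norm(W, axis=1), 1.0, atol=1e-12)
        sv = np.linalg.svd(W, compute_uv=False)
        assert np.sum(sv > 1e-10) == 3

    def test_deterministic_given_seed(self):
        assert np.array_equal(make_synergy_matrix(8, 1), make_synergy_matrix(8, 1))

    def test_three_muscle_case_is_near_axis_aligned(self):
        W = make_synergy_matrix(3, seed=0)
        # first three rows are perturbed +x, +y, +z directions
        assert np.all(np.abs(np.diag(W)) > 0.8)

    def test_too_few_muscles_rejected(self):
        with pytest.raises(ObservabilityError):
            make_synergy_matrix(2, seed=0)


class TestSimulateEmg:
    def test_zero_intent_zero_baseline_is_pure_noise(self):
        cfg = mk.VirtualSubjectConfig(seed=3, baseline_activation=0.0)
        times = np.arange(0.05, 10.0, 0.05)
        intent = IntentSeries(times=times, values=np.zeros((len(times), 3)))
        rec = simulate_emg(intent, cfg)
        # channels uncorrelated with any muscle-envelope structure: the
        # signal is white noise of the calibration-fallback unit variance
        assert np.std(rec.samples) == pytest.approx(1.0, rel=0.05)

    def test_tuned_channel_has_largest_envelope_rms(self):
        """With identity crosstalk and only one muscle tuned to [1,0,0],
        holding intent [1,0,0] makes that channel's RMS dominate."""
        s2 = 1.0 / np.sqrt(2.0)
        W = np.array(
            [
                [1.0, 0.0, 0.0],   # the pronation agonist under test
                [0.0, 1.0, 0.0],
                [0.0, 0.0, 1.0],
                [-1.0, 0.0, 0.0],
                [0.0, -1.0, 0.0],
                [0.0, 0.0, -1.0],
                [0.0, s2, s2],     # mixed-action muscles without any +x pull
                [0.0, -s2, s2],
            ]
        )
        cfg = mk.VirtualSubjectConfig(
            synergy=W, crosstalk=np.eye(8), seed=0, target_snr_db=30.0
        )
        rec = simulate_emg(_held_intent([1.0, 0.0, 0.0]), cfg)
        active = rec.samples[:, : int(10.0 * cfg.sample_rate)]
        rms = np.sqrt(np.mean(active**2, axis=1))
        assert np.argmax(rms) == 0
        assert rms[0] > 1.5 * np.sort(rms)[-2]

    def test_bitwise_deterministic_given_seed(self):
        cfg = mk.VirtualSubjectConfig(seed=7)
        intent = _held_intent([0.5, -0.5, 0.0])
        a = simulate_emg(intent, cfg)
        b = simulate_emg(intent, cfg)
        assert np.array_equal(a.samples, b.samples)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_realized_snr_within_band(self, seed):
        """Active/quiet RMS ratio matches the target within +-1.5 dB."""
        cfg = mk.VirtualSubjectConfig(seed=seed, target_snr_db=34.0)
        intent = axis_pulse_intent()
        rec = simulate_emg(intent, cfg)
        snr = realized_snr_db(rec, intent)
        assert np.all(np.abs(snr - 34.0) < 1.5)

    def test_zero_intent_channels_uncorrelated_with_envelopes(self):
        cfg = mk.VirtualSubjectConfig(seed=11)
        times = np.arange(0.05, 5.0 + 1e-9, 0.05)
        intent = IntentSeries(times=times, values=np.zeros((len(times), 3)))
        rec = simulate_emg(intent, cfg)
        # any reference envelope is constant-zero activation; correlate
        # against an independent band-limited surrogate instead
        surrogate = np.random.default_rng(99).standard_normal(rec.n_samples)
        r = np.corrcoef(rec.samples[0], surrogate)[0, 1]
        assert abs(r) < 0.1

    def test_out_of_range_intent_rejected(self):
        cfg = mk.VirtualSubjectConfig(seed=0)
        times = np.arange(0.05, 1.0, 0.05)
        bad = IntentSeries(times=times, values=np.zeros((len(times), 3)))
        object.__setattr__(bad, "values", bad.values + 1.5)
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            simulate_emg(bad, cfg)

    def test_nonpositive_target_snr_rejected(self):
        with pytest.raises(ConfigurationError):
            mk.VirtualSubjectConfig(seed=0, target_snr_db=0.0)


class TestRecordingConditions:
    def test_intramuscular_offdiagonal_mass(self):
        cfg = apply_recording_condition(mk.VirtualSubjectConfig(seed=0), "intramuscular")
        C = cfg.crosstalk
        offdiag = C.sum(axis=1) - np.diag(C)
        assert np.all(offdiag <= 0.02 + 1e-12)
        assert cfg.target_snr_db == 34.0

    def test_surface_mixes_at_least_three_sources(self):
        cfg = apply_recording_condition(mk.VirtualSubjectConfig(seed=0), "surface")
        assert np.all((cfg.crosstalk > 0.05).sum(axis=1) >= 3)
        assert cfg.target_snr_db == 25.0

    def test_input_config_unchanged_and_unknown_condition_rejected(self):
        cfg = mk.VirtualSubjectConfig(seed=0)
        before = cfg.crosstalk.copy()
        apply_recording_condition(cfg, "surface")
        assert np.array_equal(cfg.crosstalk, before)
        with pytest.raises(ValueError):
            apply_recording_condition(cfg, "epidural")

    def test_rows_stochastic(self):
        for C in (identity_crosstalk(8), surface_crosstalk(8)):
            np.testing.assert_allclose(C.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(C >= 0)


class TestVirtualSubject:
    def test_zero_error_gives_zero_intent(self):
        policy = mk.SubjectPolicy(intent_noise_sd=0.0)
        hand = mk.neutral_posture().as_array()
        np.testing.assert_allclose(
            virtual_subject_intent(hand, hand, policy), 0.0
        )

    def test_saturates_at_full_scale(self):
        policy = mk.SubjectPolicy(gain=50.0, intent_noise_sd=0.0)
        out = virtual_subject_intent(
            mk.hand.ROM_MIN, mk.hand.ROM_MAX, policy
        )
        np.testing.assert_allclose(out, 1.0)

    def test_proportional_formula(self):
        """gain=2 at normalized error 0.25 -> intent component 0.5."""
        policy = mk.SubjectPolicy(gain=2.0, intent_noise_sd=0.0)
        hand = mk.hand.ROM_MIN.copy()
        target = hand + 0.25 * mk.hand.ROM_SPAN
        np.testing.assert_allclose(
            virtual_subject_intent(hand, target, policy), 0.5
        )


class TestCyclicContraction:
    def test_duty_cycle_and_duration_arithmetic(self):
        rec, truth = simulate_cyclic_contraction(10, 2.0, 1.0, 20.0, seed=0)
        assert truth["duty_cycle"] == pytest.approx(2.0 / 3.0)
        assert rec.duration == pytest.approx(30.0)

    def test_symmetric_on_off_duty_half(self):
        _, truth = simulate_cyclic_contraction(4, 1.5, 1.5, 25.0, seed=1)
        assert truth["duty_cycle"] == pytest.approx(0.5)

    def test_snr_definition_burst_over_noise(self):
        """20 dB ground truth means burst RMS / noise RMS = 10."""
        _, truth = simulate_cyclic_contraction(8, 2.0, 2.0, 20.0, seed=2)
        assert truth["burst_rms"] / truth["noise_rms"] == pytest.approx(10.0, rel=0.05)

    def test_requires_two_cycles(self):
        with pytest.raises(ValueError):
            simulate_cyclic_contraction(1, 1.0, 1.0, 20.0)
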