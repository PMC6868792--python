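"""Simulate one cued training session of synthetic intramuscular EMG.

Builds the 27-posture x 5-repetition cue schedule, derives the ground-truth
intent trajectory a compliant subject would produce, and synthesizes the
8-channel recording at the intramuscular SNR preset.
"""

import numpy as np

import myoknn as mk

schedule = mk.build_cue_schedule(repetitions=5, seed=0)
print(f"cue schedule: {len(schedule.trials)} trials, "
      f"{schedule.duration:.0f} s total (prepare/go/rest = 2/2/1 s)")

cfg = mk.apply_recording_condition(mk.VirtualSubjectConfig(seed=0), "intramuscular")
intent = mk.cue_intent_trajectory(schedule)
recording = mk.simulate_emg(intent, cfg)
print(f"recording: {recording.n_channels} channels x {recording.n_samples} "
      f"samples at {recording.sample_rate:.0f} Hz ({recording.duration:.0f} s)")

snr = mk.realized_snr_db(recording, intent)
print(f"realized per-channel SNR: {np.round(snr, 1)} dB (target "
      f"{cfg.target_snr_db} dB)")
print("-> active-segment RMS over quiet-segment RMS per channel; the "
      "calibrated sensor noise puts every channel within ~0.1 dB of the "
      "intramuscular preset")
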