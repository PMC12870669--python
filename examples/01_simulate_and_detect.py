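"""Synthesize a bursty EEG recording, clean it, and detect spectral events.

Builds one 8-channel frontal recording with beta bursts planted at 1.5 per
5 s epoch on every channel, runs the standard preprocessing (0.5-50 Hz
zero-phase FIR, bad-channel/segment rejection, common average reference,
5 s epochs) and the factor-of-median event scan, then compares detected
beta event statistics with the planted ground truth.
"""
import numpy as np

import sefpredict as sp

bursts = {ch: [sp.BurstSpec("beta", 20.0, 1.5, 10.0, 8.0)]
          for ch in sp.FRONTAL_CHANNELS}
spec = sp.RecordingSpec(duration_s=120.0, fs_hz=200.0, seed=7, bursts=bursts)
rec, planted = sp.generate_recording(spec)
print(f"recording: {rec.n_channels} channels x {rec.duration_s:.0f} s, "
      f"{len(planted)} bursts planted")

epochs, report = sp.preprocess(rec)
print(f"after cleaning: {epochs.n_epochs} five-second epochs, "
      f"{len(report.dropped_segments)} one-second windows dropped")

frame, sef = sp.detect_and_aggregate(epochs)
beta = sef[sef.band == "beta"]
print("\nper-channel beta events (rate = events per 5 s epoch):")
print(beta[["channel", "event_rate", "mean_duration_s",
            "mean_peak_power_fom"]].round(3).to_string(index=False))

planted_rate = len(planted) / (rec.duration_s / 5) / rec.n_channels
detected_rate = beta["event_rate"].mean()
print(f"\nplanted {planted_rate:.2f} vs detected {detected_rate:.2f} "
      "beta events/epoch/channel; durations are FWHM of the wavelet power "
      "blob, so a 10-cycle 20 Hz burst (0.5 s envelope) reads out near "
      f"{beta['mean_duration_s'].mean():.2f} s.")
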