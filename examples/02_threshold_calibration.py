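"""Reproduce the event-threshold calibration: how well does the power in
the suprathreshold time-frequency area track mean band power across epochs,
at cutoffs of 2, 4, and 6 x the per-frequency median?

The event threshold is chosen so that the area counted as "events" best
accounts for the epoch-to-epoch variation of mean band power.
"""
import sefpredict as sp

bursts = {ch: [
    sp.BurstSpec("delta_theta", 3.5, 1.0, 4.0, 14.5),
    sp.BurstSpec("alpha", 10.0, 1.2, 7.0, 9.0),
    sp.BurstSpec("beta", 20.0, 1.5, 10.0, 8.0),
] for ch in sp.FRONTAL_CHANNELS}
spec = sp.RecordingSpec(duration_s=150.0, fs_hz=200.0, seed=3, bursts=bursts)
rec, _ = sp.generate_recording(spec)
epochs, _ = sp.preprocess(rec)

print("Pearson r(suprathreshold power area, mean band power) across epochs")
print(f"{'band':<12} {'cutoff 2':>9} {'cutoff 4':>9} {'cutoff 6':>9}")
for band in ("delta_theta", "alpha", "beta"):
    tfr = sp.compute_tfr(epochs, channels=["Fp1"])
    r = sp.calibrate_threshold(tfr, band)
    print(f"{band:<12} {r[2.0]:>9.3f} {r[4.0]:>9.3f} {r[6.0]:>9.3f}")
print("\nHigher r at a cutoff means events defined at that threshold carry "
      "more of the mean-power signal; on bursty data the correlation stays "
      "high up to 6x median because the planted transients dominate power.")
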