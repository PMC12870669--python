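"""Event-detection contracts: FOM normalization, maxima/FWHM extraction
against a brute-force oracle, aggregation, and threshold calibration."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sefpredict as sp
from sefpredict.events import TimeFrequencyMap, _fwhm_1d, events_to_frame
from conftest import make_sine_recording


def tfr_from_fom(fom, freqs, fs=50.0, wavelet_cycles=0.01):
    """Hand-built map: fom taken as given (per-frequency median of the
    implied power is irrelevant for maxima/width logic); tiny wavelet_cycles
    keeps the edge mask at one sample."""
    fom = np.asarray(fom, dtype=float)
    if fom.ndim == 2:
        fom = fom[None, None]  # (E=1, C=1, F, T)
    med = np.ones(fom.shape[1:3])
    return TimeFrequencyMap(
        power=fom.copy(), fom_power=fom, freqs_hz=np.asarray(freqs, dtype=float),
        fs_hz=fs, channel_labels=["Fp1"], per_freq_median=med,
        wavelet_cycles=wavelet_cycles,
    )


def brute_force_events(fom, freqs, fs, threshold, band, wavelet_cycles=0.01):
    """Independent exhaustive scan: every grid point in the band (outside a
    one-point edge margin) that beats all 8 neighbors — strictly, or equal
    while earlier in (time, frequency) order — and reaches the threshold."""
    F, T = fom.shape
    found = []
    for fi in range(F):
        if not (band[0] <= freqs[fi] <= band[1]):
            continue
        edge = min(int(np.ceil(0.5 * wavelet_cycles / freqs[fi] * fs)), int(0.4 * T))
        for ti in range(T):
            if ti < edge or ti >= T - edge:
                continue
            v = fom[fi, ti]
            if v < threshold:
                continue
            is_max = True
            for df in (-1, 0, 1):
                for dt in (-1, 0, 1):
                    if df == 0 and dt == 0:
                        continue
                    fj, tj = fi + df, ti + dt
                    if not (0 <= fj < F and 0 <= tj < T):
                        continue
                    nb = fom[fj, tj]
                    earlier = dt > 0 or (dt == 0 and df > 0)
                    if (v < nb) or (v == nb and not earlier):
                        is_max = False
            if is_max:
                # FWHM by explicit walk with linear interpolation
                def width(profile, peak, step):
                    half = profile[peak] / 2
                    right = len(profile) - 1 - peak
                    for j in range(peak + 1, len(profile)):
                        if profile[j] < half:
                            right = j - 1 - peak + (profile[j - 1] - half) / (profile[j - 1] - profile[j])
                            break
                    left = peak
                    for j in range(peak - 1, -1, -1):
                        if profile[j] < half:
                            left = peak - j - 1 + (profile[j + 1] - half) / (profile[j + 1] - profile[j])
                            break
                    return (left + right) * step
                dur = width(fom[fi, :], ti, 1.0 / fs)
                span = width(fom[:, ti], fi, freqs[1] - freqs[0])
                found.append((freqs[fi], ti / fs, v, dur, span))
    return sorted(found)


class TestComputeTfr:
    def test_zero_signal_flagged_degenerate(self):
        epochs = sp.EpochedRecording(
            data=np.zeros((2, 1, 500)), fs_hz=100.0, channel_labels=["Fp1"])
        tfr = sp.compute_tfr(epochs)
        assert tfr.degenerate_channels == ["Fp1"]
        assert np.all(tfr.power == 0)
        assert np.all(tfr.fom_power == 0)

    def test_pure_sinusoid_peaks_at_its_frequency(self):
        rec = make_sine_recording(10.0, fs=250, duration=15, n_channels=1)
        epochs = sp.epoch_and_select(rec, channels=("Ch0",))
        tfr = sp.compute_tfr(epochs)
        interior = tfr.power[:, 0, :, 300:-300]
        peak_freqs = tfr.freqs_hz[np.argmax(interior, axis=1)]
        assert np.all(peak_freqs == 10.0)

    def test_shape_contract(self):
        rng = np.random.default_rng(0)
        epochs = sp.EpochedRecording(
            data=rng.standard_normal((3, 2, 1250)), fs_hz=250.0,
            channel_labels=["Fp1", "Fz"])
        tfr = sp.compute_tfr(epochs)
        assert tfr.power.shape == (3, 2, 30, 1250)
        assert tfr.per_freq_median.shape == (2, 30)

    def test_grid_above_nyquist_rejected(self):
        epochs = sp.EpochedRecording(
            data=np.zeros((1, 1, 500)), fs_hz=100.0, channel_labels=["Fp1"])
        with pytest.raises(ValueError, match="Nyquist"):
            sp.compute_tfr(epochs, freqs_hz=np.arange(1.0, 60.0))

    def test_fom_median_exactly_one(self, bursty_epochs):
        tfr = sp.compute_tfr(bursty_epochs, channels=["Fp1"])
        med = np.median(tfr.fom_power, axis=(0, 3))
        assert np.abs(med - 1.0).max() < 1e-9


class TestFindEvents:
    CFG = sp.EventDetectionConfig()

    def test_flat_fom_no_events(self):
        tfr = tfr_from_fom(np.ones((30, 50)), np.arange(1.0, 31.0))
        assert sp.find_events(tfr, self.CFG, "beta") == []

    def test_gaussian_blob_duration_matches_analytic_fwhm(self):
        freqs = np.arange(1.0, 31.0)
        fs, T = 50.0, 200
        t = np.arange(T) / fs
        sigma_t, sigma_f = 0.25, 2.0
        blob = 1.0 + 7.0 * np.exp(
            -((t[None, :] - 2.0) ** 2) / (2 * sigma_t**2)
            - ((freqs[:, None] - 20.0) ** 2) / (2 * sigma_f**2)
        )
        tfr = tfr_from_fom(blob, freqs, fs)
        evs = sp.find_events(tfr, self.CFG, "beta")
        assert len(evs) == 1
        ev = evs[0]
        assert ev.peak_power_fom == pytest.approx(8.0, rel=1e-6)
        assert ev.peak_freq_hz == 20.0
        # FWHM of 1 + 7*gauss at half-max 4: width where gauss = 3/7
        analytic = 2 * sigma_t * np.sqrt(2 * np.log(7 / 3))
        assert ev.duration_s == pytest.approx(analytic, rel=0.05)
        assert not ev.censored_time

    def test_two_maxima_one_region_two_events(self):
        # one connected suprathreshold region along a single row, strictly
        # unimodal between its two peaks (7 and 9)
        freqs = np.arange(15.0, 30.0)
        fom = np.full((15, 60), 0.5)
        row = np.concatenate([
            np.linspace(1.0, 6.1, 3, endpoint=False),
            np.linspace(6.1, 7.0, 18, endpoint=False),   # rise to peak 1 (t=20)
            [7.0],
            np.linspace(6.9, 6.3, 10, endpoint=False),   # dip (still above 6)
            np.linspace(6.35, 9.0, 8, endpoint=False),   # rise to peak 2 (t=40)
            [9.0],
            np.linspace(8.0, 1.0, 19),                   # fall below threshold
        ])
        fom[5, :] = row
        tfr = tfr_from_fom(fom, freqs)
        evs = sp.find_events(tfr, self.CFG, "beta")
        peaks = sorted((e.peak_time_s, e.peak_power_fom) for e in evs)
        assert [p[1] for p in peaks] == [7.0, 9.0]

    def test_censoring_flag_at_epoch_edge(self):
        freqs = np.arange(15.0, 30.0)
        fom = np.ones((15, 40))
        fom[7, :] = 8.0          # ridge never dropping below half along time
        fom[7, 20] = 8.5
        tfr = tfr_from_fom(fom, freqs)
        evs = sp.find_events(tfr, self.CFG, "beta")
        assert len(evs) == 1
        assert evs[0].censored_time

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        freqs = np.arange(14.0, 20.0)  # 6 rows
        fom = rng.uniform(0.5, 5.0, size=(6, 50))
        # sprinkle suprathreshold points, including exact-tie plateaus
        for _ in range(6):
            fi, ti = rng.integers(0, 6), rng.integers(2, 48)
            fom[fi, ti] = rng.uniform(6.0, 12.0)
        fom[3, 10] = fom[3, 11] = 9.0  # plateau tie
        cfg = sp.EventDetectionConfig(bands=sp.BandSet(alpha=(6.0, 13.0), beta=(14.0, 19.0)))
        tfr = tfr_from_fom(fom, freqs)
        evs = sp.find_events(tfr, cfg, "beta")
        got = sorted(
            (e.peak_freq_hz, e.peak_time_s, e.peak_power_fom, e.duration_s, e.freq_span_hz)
            for e in evs
        )
        expected = brute_force_events(fom, freqs, tfr.fs_hz, 6.0, (14.0, 19.0))
        assert len(got) == len(expected)
        for g, x in zip(got, expected):
            assert g == pytest.approx(x, rel=1e-12)

    def test_scale_invariance_of_events(self, bursty_epochs):
        tfr1 = sp.compute_tfr(bursty_epochs, channels=["Fp1"])
        scaled = sp.EpochedRecording(
            data=bursty_epochs.data * 37.0, fs_hz=bursty_epochs.fs_hz,
            channel_labels=list(bursty_epochs.channel_labels))
        tfr2 = sp.compute_tfr(scaled, channels=["Fp1"])
        np.testing.assert_allclose(tfr1.fom_power, tfr2.fom_power, rtol=1e-9)
        e1 = events_to_frame(sp.find_events(tfr1, self.CFG, "beta"))
        e2 = events_to_frame(sp.find_events(tfr2, self.CFG, "beta"))
        pd.testing.assert_frame_equal(e1, e2, rtol=1e-9)

    def test_all_events_reach_threshold_and_band(self, bursty_epochs):
        tfr = sp.compute_tfr(bursty_epochs, channels=["Fp1", "Fz"])
        for band in ("delta_theta", "alpha", "beta"):
            lo, hi = self.CFG.bands[band]
            for ev in sp.find_events(tfr, self.CFG, band):
                assert ev.peak_power_fom >= 6.0
                assert lo <= ev.peak_freq_hz <= hi
                assert ev.duration_s > 0


class TestFwhm:
    def test_interpolated_triangle_width(self):
        profile = np.array([0.0, 2.0, 8.0, 2.0, 0.0])
        width, censored = _fwhm_1d(profile, 2, 1.0)
        # crossings at 4.0: between idx 1-2 and 2-3, 2/3 of the step away
        assert width == pytest.approx(4 / 3)
        assert not censored


class TestAggregate:
    def test_rate_is_count_over_epochs(self):
        evs = [sp.SpectralEvent("Fp1", 0, 1.0, 20.0, 8.0, 0.2, 3.0, "beta")
               for _ in range(10)]
        sef = sp.aggregate_sef(evs, n_epochs=20, channels=["Fp1"])
        row = sef[(sef.channel == "Fp1") & (sef.band == "beta")].iloc[0]
        assert row.event_rate == 0.5
        assert row.n_events == 10

    def test_empty_cell_nan_aggregates_zero_rate(self):
        sef = sp.aggregate_sef([], n_epochs=5, channels=["Fp1"])
        assert (sef.event_rate == 0).all()
        assert sef.mean_duration_s.isna().all()

    def test_single_event_means_equal_event(self):
        ev = sp.SpectralEvent("Fz", 1, 2.0, 10.0, 7.5, 0.31, 2.5, "alpha")
        sef = sp.aggregate_sef([ev], n_epochs=4, channels=["Fz"])
        row = sef[(sef.channel == "Fz") & (sef.band == "alpha")].iloc[0]
        assert row.mean_duration_s == pytest.approx(0.31)
        assert row.mean_peak_power_fom == pytest.approx(7.5)
        assert row.mean_freq_span_hz == pytest.approx(2.5)


class TestCalibration:
    @pytest.fixture(scope="class")
    def tfr(self, bursty_epochs):
        return sp.compute_tfr(bursty_epochs, channels=["Fp1"])

    def test_cutoff_zero_perfect_correlation(self, tfr):
        r = sp.calibrate_threshold(tfr, "beta", cutoffs=(0.0,))
        assert r[0.0] == pytest.approx(1.0, abs=1e-12)

    def test_huge_cutoff_undefined(self, tfr):
        r = sp.calibrate_threshold(tfr, "beta", cutoffs=(1e9,))
        assert np.isnan(r[1e9])

    def test_standard_cutoffs_finite_in_all_bands(self, tfr):
        for band in ("delta_theta", "alpha", "beta"):
            r = sp.calibrate_threshold(tfr, band)
            assert set(r) == {2.0, 4.0, 6.0}
            for cut in (2.0, 4.0):
                assert np.isfinite(r[cut])

    def test_needs_ten_epochs(self):
        tfr = tfr_from_fom(np.ones((30, 50)), np.arange(1.0, 31.0))
        with pytest.raises(ValueError, match="10 epochs"):
            sp.calibrate_threshold(tfr, "beta")
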