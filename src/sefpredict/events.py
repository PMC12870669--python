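"""Transient spectral event detection and per-subject SEF aggregation.

The time-frequency representation (TFR) is Morlet wavelet power on a 1 Hz
grid from 1-30 Hz (7 cycles at every frequency by default).  Power at each
frequency is normalized by its median across all epochs and samples of the
subject/channel ("factor of median", FOM), so the event threshold is
expressed in units of typical power at that frequency.  Events are local
maxima of the FOM map in the 2-D (frequency, time) grid that reach the
threshold (default 6x median); multiple events may share one suprathreshold
region.  Each event carries its peak power, full-width-at-half-maximum
duration along time, and FWHM frequency span.

Spectral event features (SEF) per channel and band are the event rate per
5 s epoch and the unweighted means of duration, frequency span and peak
FOM power across that cell's events.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.stats import pearsonr

from .bands import BandSet, DEFAULT_BANDS
from .recording import EpochedRecording

logger = logging.getLogger(__name__)

EVENT_COLUMNS = (
    "channel", "epoch_index", "peak_time_s", "peak_freq_hz", "peak_power_fom",
    "duration_s", "freq_span_hz", "band_label", "censored_time", "censored_freq",
)


@dataclass
class EventDetectionConfig:
    """Detection parameters.

    find_method=1 means every suprathreshold local maximum is one event,
    allowing multiple events per connected suprathreshold region (the only
    supported method).
    """

    threshold_fom: float = 6.0
    find_method: int = 1
    bands: BandSet = field(default_factory=BandSet)
    wavelet_cycles: float = 7.0
    freq_lo_hz: float = 1.0
    freq_hi_hz: float = 30.0
    freq_step_hz: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold_fom <= 0:
            raise ValueError("threshold_fom must be positive")
        if self.find_method != 1:
            raise ValueError("only find_method=1 is supported")

    @property
    def freqs_hz(self) -> np.ndarray:
        return np.arange(self.freq_lo_hz, self.freq_hi_hz + 1e-9, self.freq_step_hz)


@dataclass
class TimeFrequencyMap:
    """Morlet power and its FOM normalization for one or more channels.

    power and fom_power have shape (n_epochs, n_channels, n_freqs,
    n_samples); per_freq_median has shape (n_channels, n_freqs).  At every
    (channel, frequency) the median of fom_power over all epochs and samples
    is exactly 1; channels whose median power is 0 at some frequency are
    recorded in degenerate_channels and their fom is set to 0 there.
    """

    power: np.ndarray
    fom_power: np.ndarray
    freqs_hz: np.ndarray
    fs_hz: float
    channel_labels: list[str]
    per_freq_median: np.ndarray
    wavelet_cycles: float
    degenerate_channels: list[str] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]

    @property
    def n_samples(self) -> int:
        return self.power.shape[3]

    def edge_mask_samples(self, freq_hz: float) -> int:
        """Samples at each epoch edge excluded from the maxima search at this
        frequency: half the wavelet support, capped at 40% of the epoch."""
        half = int(np.ceil(0.5 * (self.wavelet_cycles / freq_hz) * self.fs_hz))
        return min(half, int(0.4 * self.n_samples))


def _morlet(f0: float, fs: float, n_cycles: float, max_len: int) -> np.ndarray:
    """Complex Morlet, unit energy, support +-4 sigma capped at max_len."""
    sigma_t = n_cycles / (2 * np.pi * f0)
    half = min(int(np.ceil(4 * sigma_t * fs)), (max_len - 1) // 2)
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * f0 * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    w /= np.sqrt(np.sum(np.abs(w) ** 2))
    return w


def compute_tfr(
    epochs: EpochedRecording,
    freqs_hz: np.ndarray | None = None,
    cycles: float = 7.0,
    channels: list[str] | None = None,
) -> TimeFrequencyMap:
    """Morlet wavelet power per epoch/channel/frequency/sample, with
    per-frequency median (FOM) normalization.

    The per-frequency median is taken across ALL epochs and samples of the
    channel.  Wavelet support longer than the epoch is capped at the epoch
    length; the affected edge samples are excluded from the maxima search
    downstream via :meth:`TimeFrequencyMap.edge_mask_samples`.
    """
    if freqs_hz is None:
        freqs_hz = np.arange(1.0, 31.0)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if freqs_hz.max() >= epochs.fs_hz / 2:
        raise ValueError(
            f"frequency grid reaches {freqs_hz.max()} Hz, at or above Nyquist "
            f"({epochs.fs_hz / 2} Hz)"
        )
    if channels is None:
        channels = list(epochs.channel_labels)
    idx = [epochs.channel_labels.index(ch) for ch in channels]
    data = epochs.data[:, idx, :]  # (E, C, T)
    E, C, T = data.shape

    power = np.empty((E, C, len(freqs_hz), T))
    for i, f0 in enumerate(freqs_hz):
        w = _morlet(f0, epochs.fs_hz, cycles, max_len=T)
        conv = fftconvolve(data, w[None, None, :], mode="same", axes=-1)
        power[:, :, i, :] = np.abs(conv) ** 2

    med = np.median(power, axis=(0, 3))  # (C, F)
    degenerate = [channels[c] for c in range(C) if np.any(med[c] == 0)]
    if degenerate:
        logger.warning("zero median power (degenerate FOM) on channels %s", degenerate)
    safe_med = np.where(med == 0, np.inf, med)
    fom = power / safe_med[None, :, :, None]

    return TimeFrequencyMap(
        power=power, fom_power=fom, freqs_hz=freqs_hz, fs_hz=epochs.fs_hz,
        channel_labels=list(channels), per_freq_median=med,
        wavelet_cycles=cycles, degenerate_channels=degenerate,
    )


# ---------------------------------------------------------------------------
# event finding
# ---------------------------------------------------------------------------

@dataclass
class SpectralEvent:
    """One detected transient event."""

    channel: str
    epoch_index: int
    peak_time_s: float
    peak_freq_hz: float
    peak_power_fom: float
    duration_s: float
    freq_span_hz: float
    band_label: str
    censored_time: bool = False
    censored_freq: bool = False


def _local_maxima_mask(fom: np.ndarray) -> np.ndarray:
    """Local maxima of a (F, T) grid against all 8 neighbors.

    A point wins against a neighbor if it is strictly larger, or equal and
    earlier in (time, then frequency) order — so plateau ties resolve to the
    earliest-time, lowest-frequency member.  Missing neighbors (grid edges)
    always lose.
    """
    F, T = fom.shape
    pad = np.full((F + 2, T + 2), -np.inf)
    pad[1:-1, 1:-1] = fom
    ok = np.ones((F, T), dtype=bool)
    for df in (-1, 0, 1):
        for dt in (-1, 0, 1):
            if df == 0 and dt == 0:
                continue
            nb = pad[1 + df : F + 1 + df, 1 + dt : T + 1 + dt]
            later = dt > 0 or (dt == 0 and df > 0)  # neighbor follows in scan order
            if later:
                ok &= fom >= nb
            else:
                ok &= fom > nb
    return ok


def _fwhm_1d(profile: np.ndarray, peak_idx: int, step: float) -> tuple[float, bool]:
    """Full width at half the peak value along a 1-D profile, with linear
    interpolation at the crossings; censored (width to the edge) when the
    half level is not reached before the array ends."""
    half = profile[peak_idx] / 2.0
    censored = False

    right = profile.size - 1 - peak_idx
    for j in range(peak_idx + 1, profile.size):
        if profile[j] < half:
            frac = (profile[j - 1] - half) / (profile[j - 1] - profile[j])
            right = (j - 1 - peak_idx) + frac
            break
    else:
        censored = True

    left = peak_idx
    for j in range(peak_idx - 1, -1, -1):
        if profile[j] < half:
            frac = (profile[j + 1] - half) / (profile[j + 1] - profile[j])
            left = (peak_idx - j - 1) + frac
            break
    else:
        censored = True

    return (left + right) * step, censored


def find_events(
    tfr: TimeFrequencyMap, cfg: EventDetectionConfig, band_label: str,
    channel: str | None = None,
) -> list[SpectralEvent]:
    """Suprathreshold local maxima of the FOM map within a band.

    Maxima are evaluated against all 8 neighbors on the full grid (so a
    band-edge point adjacent to a larger out-of-band value is not an event);
    candidate peaks are restricted to the band rows and to samples outside
    the per-frequency edge mask.  FWHM duration is measured along time at
    the peak frequency, the frequency span along frequency at the peak time;
    widths cut off by the epoch or grid boundary are flagged censored.
    """
    lo, hi = cfg.bands[band_label]
    freqs = tfr.freqs_hz
    if lo < freqs.min() or hi > freqs.max():
        raise ValueError(f"band {band_label} {(lo, hi)} outside frequency grid")
    band_rows = np.where((freqs >= lo) & (freqs <= hi))[0]
    chans = tfr.channel_labels if channel is None else [channel]

    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    events: list[SpectralEvent] = []
    for ch in chans:
        c = tfr.channel_labels.index(ch)
        for e in range(tfr.n_epochs):
            fom = tfr.fom_power[e, c]  # (F, T)
            maxima = _local_maxima_mask(fom)
            cand = np.zeros_like(maxima)
            for fi in band_rows:
                m = tfr.edge_mask_samples(freqs[fi])
                if m < tfr.n_samples - m:
                    cand[fi, m : tfr.n_samples - m] = True
            sel = maxima & cand & (fom >= cfg.threshold_fom)
            for fi, ti in zip(*np.nonzero(sel)):
                dur, cens_t = _fwhm_1d(fom[fi, :], ti, 1.0 / tfr.fs_hz)
                span, cens_f = _fwhm_1d(fom[:, ti], fi, df)
                events.append(
                    SpectralEvent(
                        channel=ch, epoch_index=int(e),
                        peak_time_s=float(ti / tfr.fs_hz),
                        peak_freq_hz=float(freqs[fi]),
                        peak_power_fom=float(fom[fi, ti]),
                        duration_s=float(dur), freq_span_hz=float(span),
                        band_label=band_label,
                        censored_time=bool(cens_t), censored_freq=bool(cens_f),
                    )
                )
    return events


def events_to_frame(events: list[SpectralEvent]) -> pd.DataFrame:
    if not events:
        return pd.DataFrame(columns=list(EVENT_COLUMNS))
    return pd.DataFrame([vars(ev) for ev in events], columns=list(EVENT_COLUMNS))


def aggregate_sef(
    events: list[SpectralEvent] | pd.DataFrame,
    n_epochs: int,
    channels: list[str],
    bands: BandSet = DEFAULT_BANDS,
) -> pd.DataFrame:
    """SEF table: per (channel, band) event rate and mean event features.

    Rate is events per 5 s epoch (count / n_epochs); duration, span and
    peak power are unweighted means over the cell's events (censored widths
    included), NaN when the cell has no events.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    frame = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    rows = []
    for ch in channels:
        for band in bands.labels:
            cell = frame[(frame["channel"] == ch) & (frame["band_label"] == band)]
            n = len(cell)
            rows.append(
                {
                    "channel": ch, "band": band,
                    "event_rate": n / n_epochs,
                    "mean_duration_s": cell["duration_s"].mean() if n else np.nan,
                    "mean_freq_span_hz": cell["freq_span_hz"].mean() if n else np.nan,
                    "mean_peak_power_fom": cell["peak_power_fom"].mean() if n else np.nan,
                    "n_events": n,
                }
            )
    return pd.DataFrame(rows)


def detect_and_aggregate(
    epochs: EpochedRecording, cfg: EventDetectionConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: TFR + event detection on every channel and band.

    Channels are processed one at a time to bound memory.  Returns
    (event frame, SEF table).
    """
    cfg = cfg or EventDetectionConfig()
    all_events: list[SpectralEvent] = []
    for ch in epochs.channel_labels:
        tfr = compute_tfr(epochs, cfg.freqs_hz, cfg.wavelet_cycles, channels=[ch])
        for band in cfg.bands.labels:
            all_events.extend(find_events(tfr, cfg, band))
    frame = events_to_frame(all_events)
    sef = aggregate_sef(frame, epochs.n_epochs, list(epochs.channel_labels), cfg.bands)
    return frame, sef


def calibrate_threshold(
    tfr: TimeFrequencyMap, band_label: str,
    cutoffs: tuple[float, ...] = (2.0, 4.0, 6.0),
    cfg: EventDetectionConfig | None = None,
    channel: str | None = None,
) -> dict[float, float]:
    """Per cutoff: Pearson correlation, across epochs, between the raw power
    summed over the suprathreshold {FOM >= cutoff} area of the band and the
    epoch's mean band power.

    At cutoff 0 the suprathreshold area is the whole band, so the
    correlation is exactly 1; as the cutoff grows the area vanishes and the
    correlation degrades to NaN.  Aggregation across subjects is the
    caller's mean.
    """
    cfg = cfg or EventDetectionConfig()
    if tfr.n_epochs < 10:
        raise ValueError("need >= 10 epochs for a stable calibration correlation")
    lo, hi = cfg.bands[band_label]
    band_rows = (tfr.freqs_hz >= lo) & (tfr.freqs_hz <= hi)
    c = 0 if channel is None else tfr.channel_labels.index(channel)

    power = tfr.power[:, c, band_rows, :]   # (E, Fb, T)
    fom = tfr.fom_power[:, c, band_rows, :]
    mean_power = power.mean(axis=(1, 2))
    out: dict[float, float] = {}
    for cut in cutoffs:
        area_sum = np.where(fom >= cut, power, 0.0).sum(axis=(1, 2))
        if np.ptp(area_sum) == 0 or np.ptp(mean_power) == 0:
            logger.warning("zero variance across epochs at cutoff %s; r undefined", cut)
            out[float(cut)] = np.nan
        else:
            out[float(cut)] = float(pearsonr(area_sum, mean_power)[0])
    return out
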