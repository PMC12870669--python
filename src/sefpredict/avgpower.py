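"""Averaged power features (APF): absolute and relative band power,
cordance, and orthogonalized power-envelope connectivity (PEC).

Cordance here is the classic channel-space formulation: absolute and
relative band power are z-scored ACROSS channels within the subject and
band, and the channel's cordance is the mean of its two z-scores.  PEC is
the Hipp-style pointwise orthogonalization: for each ordered pair the
analytic signal of one channel is projected off the other's phase, the
amplitude envelopes are correlated, and the two directions are averaged
(symmetric by construction).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, periodogram, sosfiltfilt

from .bands import BandSet, DEFAULT_BANDS
from .recording import EpochedRecording

logger = logging.getLogger(__name__)


@dataclass
class PowerSpectrum:
    """Channels x frequencies PSD in µV²/Hz (epoch-averaged periodograms)."""

    psd: np.ndarray
    freqs_hz: np.ndarray
    channel_labels: list[str]
    method: str = "hann periodogram averaged over 5 s epochs"


def compute_psd(epochs: EpochedRecording) -> PowerSpectrum:
    """Welch-style estimate: Hann-windowed periodogram of each 5 s epoch,
    averaged across epochs."""
    f, p = periodogram(epochs.data, fs=epochs.fs_hz, window="hann", axis=-1,
                       detrend=False, scaling="density")
    return PowerSpectrum(
        psd=p.mean(axis=0), freqs_hz=f, channel_labels=list(epochs.channel_labels)
    )


def band_powers(
    ps: PowerSpectrum, bands: BandSet = DEFAULT_BANDS,
    total_range_hz: tuple[float, float] = (0.5, 50.0),
) -> pd.DataFrame:
    """Absolute power per band (trapezoid integral of the PSD over the band)
    and the total over the analyzed range, per channel (µV²)."""
    f = ps.freqs_hz
    rows = {}
    for label, (lo, hi) in list(bands.as_dict().items()) + [("total", total_range_hz)]:
        sel = (f >= lo) & (f <= hi)
        if not sel.any():
            raise ValueError(f"band {label} {(lo, hi)} outside the PSD grid")
        rows[label] = np.trapezoid(ps.psd[:, sel], f[sel], axis=1)
    out = pd.DataFrame(rows, index=ps.channel_labels)
    out.index.name = "channel"
    return out


def relative_power(abs_band: np.ndarray | float, abs_total: np.ndarray | float):
    """Band power divided by all-band absolute power, in [0, 1]; NaN where
    the total is zero."""
    abs_band = np.asarray(abs_band, dtype=float)
    abs_total = np.asarray(abs_total, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(abs_total > 0, abs_band / abs_total, np.nan)
    if np.isnan(out).any():
        logger.warning("zero total power; relative power NaN")
    return out if out.ndim else float(out)


def cordance(abs_power: np.ndarray, rel_power: np.ndarray) -> np.ndarray:
    """Per-channel average of across-channel z-scored absolute and relative
    band power; zeros (with a warning) when a quantity has no variance."""
    abs_power = np.asarray(abs_power, dtype=float)
    rel_power = np.asarray(rel_power, dtype=float)
    if abs_power.size < 3:
        raise ValueError("cordance needs >= 3 channels")

    def _z(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        if sd == 0:
            logger.warning("zero variance across channels; cordance z set to 0")
            return np.zeros_like(x)
        return (x - x.mean()) / sd

    return (_z(abs_power) + _z(rel_power)) / 2.0


def _band_analytic(epochs: EpochedRecording, band: tuple[float, float]) -> np.ndarray:
    """Band-passed analytic signal per epoch/channel (order-4 Butterworth,
    zero-phase), shape (E, C, T) complex."""
    lo, hi = band
    sos = butter(4, [lo, hi], btype="bandpass", fs=epochs.fs_hz, output="sos")
    filt = sosfiltfilt(sos, epochs.data, axis=-1)
    return hilbert(filt, axis=-1)


def _env_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Correlation of |x| with the envelope of y orthogonalized on x."""
    y_orth = np.imag(y * np.conj(x) / np.maximum(np.abs(x), 1e-30))
    env_x, env_y = np.abs(x), np.abs(y_orth)
    # orthogonalized component vanishing (identical/proportional channels)
    # leaves only rounding noise, which must not be correlated against
    if env_y.mean() < 1e-9 * max(env_x.mean(), 1e-30):
        return 0.0
    if env_x.std() == 0 or env_y.std() == 0:
        return 0.0
    return float(np.corrcoef(env_x, env_y)[0, 1])


def pec(
    epochs: EpochedRecording, band: tuple[float, float],
    channel_a: str, channel_b: str,
) -> float:
    """Two-way orthogonalized power-envelope correlation for one pair.

    Each channel is band-pass filtered per epoch; the analytic signal of one
    is projected off the other's instantaneous phase; the amplitude
    envelopes are Pearson-correlated across the concatenated epoch samples;
    the two orthogonalization directions are averaged.
    """
    for ch in (channel_a, channel_b):
        if ch not in epochs.channel_labels:
            raise ValueError(f"channel {ch!r} not present")
    ia = epochs.channel_labels.index(channel_a)
    ib = epochs.channel_labels.index(channel_b)
    analytic = _band_analytic(epochs, band)
    a = analytic[:, ia, :].ravel()
    b = analytic[:, ib, :].ravel()
    if np.abs(a).std() == 0 or np.abs(b).std() == 0:
        logger.warning("flat channel in PEC; returning NaN")
        return float("nan")
    return 0.5 * (_env_corr(a, b) + _env_corr(b, a))


def apf_table(
    epochs: EpochedRecording, bands: BandSet = DEFAULT_BANDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All averaged power features for one subject.

    Returns
    -------
    per_channel : DataFrame indexed by channel with columns
        ``abs_power_total``, ``abs_power_<band>``, ``rel_power_<band>``,
        ``cordance_<band>``.
    per_pair : DataFrame with columns channel_a, channel_b (alphabetical
        order within the pair), band, pec.
    """
    ps = compute_psd(epochs)
    bp = band_powers(ps, bands)
    per_channel = pd.DataFrame(index=bp.index)
    per_channel["abs_power_total"] = bp["total"]
    for band in bands.labels:
        per_channel[f"abs_power_{band}"] = bp[band]
        per_channel[f"rel_power_{band}"] = relative_power(
            bp[band].to_numpy(), bp["total"].to_numpy()
        )
    for band in bands.labels:
        per_channel[f"cordance_{band}"] = cordance(
            per_channel[f"abs_power_{band}"].to_numpy(),
            per_channel[f"rel_power_{band}"].to_numpy(),
        )

    analytic = {band: _band_analytic(epochs, bands[band]) for band in bands.labels}
    rows = []
    for ch_a, ch_b in combinations(sorted(epochs.channel_labels), 2):
        ia = epochs.channel_labels.index(ch_a)
        ib = epochs.channel_labels.index(ch_b)
        for band in bands.labels:
            sig = analytic[band]
            a = sig[:, ia, :].ravel()
            b = sig[:, ib, :].ravel()
            val = 0.5 * (_env_corr(a, b) + _env_corr(b, a))
            rows.append({"channel_a": ch_a, "channel_b": ch_b, "band": band, "pec": val})
    return per_channel, pd.DataFrame(rows)
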