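"""Ground-truthed synthetic resting-state EEG and cohort generation.

The generator emulates the statistical structure the downstream analysis
assumes: a 1/f-shaped background, transient band-limited bursts in the
delta/theta, alpha and beta bands, and a cohort whose depression-score
%change depends linearly on a planted burst feature (frontopolar beta event
duration, negative direction) in the treated arm and on nothing in the
placebo-like arm.

Background model
----------------
The background is a bank of log-spaced constant-amplitude oscillators
(about 2-3 per Morlet bandwidth at every analysis frequency) whose
instantaneous frequencies drift slowly (Ornstein-Uhlenbeck), with
amplitudes shaped so the power spectral density falls off as 1/f^chi.
Narrowband power of a sum of a few constant-modulus phasors has bounded
tails, so the background essentially never crosses the 6x factor-of-median
event threshold: planted bursts are, by construction, the only spectral
events.  A Gaussian background cannot serve this role: for any Gaussian
process the Morlet power envelope is exponentially distributed and exceeds
6x its median on a fixed ~1.6% of the time-frequency area, which at
ordinary analysis bandwidths produces several spurious event maxima per
epoch and makes planted-event recovery ill-posed.

All randomness flows from explicit integer seeds; identical seeds give
bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .bands import BandSet, DEFAULT_BANDS, FRONTAL_CHANNELS
from .recording import RawRecording

PLANTED_COLUMNS = ("channel", "onset_s", "center_freq_hz", "n_cycles",
                   "amplitude_uv", "band_label")

EPOCH_LEN_S = 5.0


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class BurstSpec:
    """One class of transient bursts to inject on a channel.

    rate_per_epoch is the Poisson mean per 5 s epoch; n_cycles sets the
    planted duration (n_cycles / center_freq_hz seconds under a Hann taper);
    amplitude_uv is the mean peak amplitude with lognormal variation of
    coefficient of variation amplitude_cv.
    """

    band_label: str
    center_freq_hz: float
    rate_per_epoch: float
    n_cycles: float
    amplitude_uv: float
    amplitude_cv: float = 0.15
    bands: BandSet = field(default_factory=BandSet, repr=False)

    def __post_init__(self) -> None:
        lo, hi = self.bands[self.band_label]
        if not lo <= self.center_freq_hz <= hi:
            raise ValueError(
                f"center_freq_hz={self.center_freq_hz} outside {self.band_label} band {(lo, hi)}"
            )
        if self.rate_per_epoch < 0:
            raise ValueError("rate_per_epoch must be >= 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def duration_s(self) -> float:
        return self.n_cycles / self.center_freq_hz


@dataclass
class RecordingSpec:
    """Specification of one synthetic continuous recording."""

    channels: tuple[str, ...] = FRONTAL_CHANNELS
    fs_hz: float = 250.0
    duration_s: float = 120.0
    background_exponent: float = 1.0
    background_scale_uv: float = 20.0
    #: variance fraction of the background common to all channels
    #: (volume-conduction-like; keeps inter-channel correlations realistic)
    shared_fraction: float = 0.90
    #: bursts per channel label; channels absent from the map get none
    bursts: dict[str, list[BurstSpec]] = field(default_factory=dict)
    seed: int = 0
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.fs_hz < 100:
            raise ValueError("fs_hz must be >= 100 (Nyquist above the 50 Hz lowpass)")
        if self.duration_s <= 5:
            raise ValueError("duration_s must exceed one 5 s epoch")
        if not 0.0 <= self.shared_fraction < 1.0:
            raise ValueError("shared_fraction must be in [0, 1)")
        for ch, specs in self.bursts.items():
            if ch not in self.channels:
                raise ValueError(f"burst channel {ch!r} not in channel list")
            for bs in specs:
                if bs.center_freq_hz >= self.fs_hz / 2:
                    raise ValueError(
                        f"burst center frequency {bs.center_freq_hz} Hz violates "
                        f"Nyquist at fs={self.fs_hz} Hz"
                    )


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def _oscillator_bank(
    rng: np.random.Generator,
    n_samples: int,
    fs_hz: float,
    chi: float,
    f_lo: float = 0.7,
    f_hi: float = 55.0,
    spacing_q: float = 4.5,
    drift_rel: float = 0.02,
    drift_tau_s: float = 0.5,
) -> np.ndarray:
    """One unit-RMS realization of the envelope-regularized 1/f background."""
    f_hi = min(f_hi, 0.45 * fs_hz)
    ratio = 1.0 + 1.0 / spacing_q
    n_osc = int(np.floor(np.log(f_hi / f_lo) / np.log(ratio))) + 1
    fk = f_lo * ratio ** np.arange(n_osc)
    # PSD ~ amp^2 / spacing with spacing ~ f/q  =>  amp ~ f^((1-chi)/2)
    amps = fk ** ((1.0 - chi) / 2.0)

    alpha = np.exp(-1.0 / (drift_tau_s * fs_hz))
    sd_eq = drift_rel * fk
    burn = int(5 * drift_tau_s * fs_hz)
    eps = rng.standard_normal((n_osc, n_samples + burn))
    eps *= (sd_eq * np.sqrt(1 - alpha**2))[:, None]
    drift = lfilter([1.0], [1.0, -alpha], eps, axis=1)[:, burn:]
    phase0 = rng.uniform(0, 2 * np.pi, size=n_osc)
    phase = 2 * np.pi * np.cumsum(fk[:, None] + drift, axis=1) / fs_hz + phase0[:, None]
    x = (amps[:, None] * np.cos(phase)).sum(axis=0)
    x /= x.std()
    return x


def _hann_burst(fs_hz: float, f0: float, n_cycles: float, amplitude: float,
                phase: float) -> np.ndarray:
    n = max(int(round(n_cycles / f0 * fs_hz)), 2)
    t = np.arange(n) / fs_hz
    taper = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / (n - 1))
    return amplitude * taper * np.cos(2 * np.pi * f0 * t + phase)


def generate_recording(spec: RecordingSpec) -> tuple[RawRecording, pd.DataFrame]:
    """Synthesize one recording; return it with its planted-event log.

    The planted-event log is a DataFrame with columns
    ``channel, onset_s, center_freq_hz, n_cycles, amplitude_uv, band_label``
    (one row per injected burst, ground truth for recovery tests).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs_hz))
    n_ch = len(spec.channels)

    shared = _oscillator_bank(rng, n, spec.fs_hz, spec.background_exponent)
    w_shared = np.sqrt(spec.shared_fraction)
    w_own = np.sqrt(1.0 - spec.shared_fraction)
    gains = 1.0 + 0.05 * rng.standard_normal(n_ch)  # mild per-channel coupling jitter
    data = np.empty((n_ch, n))
    for c in range(n_ch):
        own = _oscillator_bank(rng, n, spec.fs_hz, spec.background_exponent)
        data[c] = w_shared * gains[c] * shared + w_own * own
    data *= spec.background_scale_uv

    rows: list[tuple] = []
    n_epochs_equiv = spec.duration_s / EPOCH_LEN_S
    for c, ch in enumerate(spec.channels):
        for bs in spec.bursts.get(ch, []):
            count = rng.poisson(bs.rate_per_epoch * n_epochs_equiv)
            if count == 0:
                continue
            onsets = np.sort(rng.uniform(0, spec.duration_s - bs.duration_s, size=count))
            sigma = np.sqrt(np.log1p(bs.amplitude_cv**2))
            mu = np.log(bs.amplitude_uv) - sigma**2 / 2
            amplitudes = np.exp(rng.normal(mu, sigma, size=count))
            phases = rng.uniform(0, 2 * np.pi, size=count)
            for o, a, ph in zip(onsets, amplitudes, phases):
                burst = _hann_burst(spec.fs_hz, bs.center_freq_hz, bs.n_cycles, a, ph)
                i0 = int(round(o * spec.fs_hz))
                seg = data[c, i0 : i0 + burst.size]
                seg += burst[: seg.size]
                rows.append((ch, float(o), bs.center_freq_hz, bs.n_cycles,
                             float(a), bs.band_label))

    planted = pd.DataFrame(rows, columns=list(PLANTED_COLUMNS))
    rec = RawRecording(
        data=data,
        fs_hz=spec.fs_hz,
        channel_labels=list(spec.channels),
        subject_id=spec.subject_id,
    )
    return rec, planted


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: per-band, per-subject parameter distributions: (mean, sd, lo, hi) of a
#: truncated normal for each burst parameter. ``amp`` is the mean burst
#: amplitude in µV, chosen so planted beta events land near peak FOM ~10
#: after the standard preprocessing pipeline (common average reference
#: included).
DEFAULT_SUBJECT_VARIATION: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "delta_theta": {
        "center_freq_hz": (3.5, 0.4, 2.5, 4.5),
        "n_cycles": (4.0, 1.0, 2.0, 6.0),
        "rate_per_epoch": (1.0, 0.25, 0.3, 2.0),
        "amp": (14.5, 2.2, 7.0, 26.0),
    },
    "alpha": {
        "center_freq_hz": (10.0, 1.0, 7.0, 13.0),
        "n_cycles": (7.0, 1.5, 4.0, 10.0),
        "rate_per_epoch": (1.2, 0.25, 0.3, 2.5),
        "amp": (9.0, 1.4, 4.5, 17.0),
    },
    "beta": {
        "center_freq_hz": (20.0, 1.0, 16.0, 26.0),
        "n_cycles": (10.0, 2.0, 6.0, 14.0),
        "rate_per_epoch": (1.5, 0.3, 0.5, 3.0),
        "amp": (8.0, 1.2, 3.5, 15.0),
    },
}

#: sd of the per-channel jitter applied to the subject-level n_cycles draw
#: (spatial heterogeneity; makes single channels carry unique information)
CHANNEL_NCYCLES_JITTER = 1.0


@dataclass
class CohortSpec:
    """Specification of a synthetic treatment cohort.

    ``effect_weights`` maps feature names (e.g. ``Fp1_beta_duration``) to
    weights applied to the standardized *true planted* feature values.  The
    latent predictor is mapped affinely onto a %change scale with mean -40
    and total sd 25 (clipped to [-100, +50]); ``outcome_noise_sd`` is the
    residual sd on that scale, so the planted effect explains
    1 - (outcome_noise_sd/25)^2 of the outcome variance.
    """

    n_subjects: int = 82
    arm: str = "sertraline_like"
    effect_weights: dict[str, float] = field(default_factory=dict)
    outcome_noise_sd: float = 20.0
    baseline_hamd_mean: float = 18.5
    baseline_hamd_sd: float = 3.5
    per_subject_variation: dict = field(
        default_factory=lambda: {b: dict(v) for b, v in DEFAULT_SUBJECT_VARIATION.items()}
    )
    seed: int = 0
    channels: tuple[str, ...] = FRONTAL_CHANNELS
    fs_hz: float = 200.0
    duration_s: float = 150.0
    background_exponent: float = 1.0
    background_scale_uv: float = 20.0
    shared_fraction: float = 0.90

    OUTCOME_MEAN = -40.0
    OUTCOME_SD = 25.0

    def __post_init__(self) -> None:
        if self.n_subjects < 6:
            raise ValueError("n_subjects must be >= 6 (cannot stratify 3 folds)")
        if self.arm not in ("sertraline_like", "placebo_like"):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.arm == "placebo_like" and any(w != 0 for w in self.effect_weights.values()):
            raise ValueError("placebo_like cohorts must have all effect weights = 0")
        if self.outcome_noise_sd > self.OUTCOME_SD:
            raise ValueError("outcome_noise_sd cannot exceed the total outcome sd (25)")

    @classmethod
    def sertraline_like(cls, n_subjects: int = 82, seed: int = 0, **kw) -> "CohortSpec":
        kw.setdefault("effect_weights", {"Fp1_beta_duration": -1.0})
        kw.setdefault("outcome_noise_sd", 20.0)
        return cls(n_subjects=n_subjects, arm="sertraline_like", seed=seed, **kw)

    @classmethod
    def placebo_like(cls, n_subjects: int = 94, seed: int = 0, **kw) -> "CohortSpec":
        kw.setdefault("outcome_noise_sd", 25.0)
        return cls(n_subjects=n_subjects, arm="placebo_like",
                   effect_weights={}, seed=seed, **kw)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, size=None) -> np.ndarray:
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def _draw_subject_params(rng: np.random.Generator, cspec: CohortSpec,
                         bands: BandSet) -> dict:
    """Per-subject, per-band, per-channel burst parameters."""
    params: dict[str, dict] = {}
    for band in bands.labels:
        dist = cspec.per_subject_variation[band]
        cf = float(_trunc_normal(rng, *dist["center_freq_hz"]))
        ncyc_subj = float(_trunc_normal(rng, *dist["n_cycles"]))
        rate = float(_trunc_normal(rng, *dist["rate_per_epoch"]))
        amp = float(_trunc_normal(rng, *dist["amp"]))
        ncyc_lo = dist["n_cycles"][2]
        ncyc_ch = np.clip(
            ncyc_subj + CHANNEL_NCYCLES_JITTER * rng.standard_normal(len(cspec.channels)),
            max(2.0, ncyc_lo - 2.0), dist["n_cycles"][3] + 2.0,
        )
        params[band] = {
            "center_freq_hz": cf,
            "rate_per_epoch": rate,
            "amplitude_uv": amp,
            "n_cycles": {ch: float(v) for ch, v in zip(cspec.channels, ncyc_ch)},
        }
    return params


def _true_feature(params: dict, name: str) -> float:
    """True planted value of a named feature, e.g. 'Fp1_beta_duration'."""
    for band in ("delta_theta", "alpha", "beta"):
        suffix_map = {
            "duration": lambda p, ch: p[band]["n_cycles"][ch] / p[band]["center_freq_hz"],
            "rate": lambda p, ch: p[band]["rate_per_epoch"],
            "power": lambda p, ch: p[band]["amplitude_uv"] ** 2,
            "freq_span": lambda p, ch: p[band]["center_freq_hz"] / p[band]["n_cycles"][ch],
        }
        for feat, fn in suffix_map.items():
            tail = f"_{band}_{feat}"
            if name.endswith(tail):
                ch = name[: -len(tail)]
                return fn(params, ch)
    raise KeyError(f"cannot interpret feature name {name!r}")


def _outcomes_from_latent(rng: np.random.Generator, cspec: CohortSpec,
                          latent: np.ndarray) -> pd.DataFrame:
    n = cspec.n_subjects
    noise = rng.normal(0.0, cspec.outcome_noise_sd, size=n)
    if np.ptp(latent) > 0:
        z = (latent - latent.mean()) / latent.std()
        b = np.sqrt(max(cspec.OUTCOME_SD**2 - cspec.outcome_noise_sd**2, 0.0))
        pct = cspec.OUTCOME_MEAN + b * z + noise
    else:
        pct = cspec.OUTCOME_MEAN + noise
    pct = np.clip(pct, -100.0, 50.0)

    baseline = np.round(
        _trunc_normal(rng, cspec.baseline_hamd_mean, cspec.baseline_hamd_sd, 14, 30, size=n)
    ).astype(int)
    post = np.clip(np.round(baseline * (1 + pct / 100.0)), 0, 52).astype(int)
    pct_exact = 100.0 * (post - baseline) / baseline
    age = np.round(_trunc_normal(rng, 38.7, 12.0, 18, 65, size=n)).astype(int)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "age": age,
            "baseline_hamd": baseline,
            "post_hamd": post,
            "pct_change": pct_exact,
            "arm": cspec.arm,
            "responder": pct_exact <= -50.0,
            "remitter": post <= 7,
        }
    )


def generate_cohort(
    cspec: CohortSpec, bands: BandSet = DEFAULT_BANDS
) -> tuple[list[RawRecording], pd.DataFrame, dict]:
    """Generate per-subject recordings, the clinical table, and ground truth.

    Returns
    -------
    recordings : list of RawRecording
    clinical : DataFrame  (ClinicalTable: subject_id, age, baseline_hamd,
        post_hamd, pct_change, arm, responder, remitter)
    truth : dict with keys ``effect_weights``, ``true_features`` (DataFrame of
        the true values of every weighted feature per subject), ``latent``,
        ``planted_events`` (per-subject planted logs), ``subject_params``.
    """
    rng = np.random.default_rng(cspec.seed)
    all_params = [_draw_subject_params(rng, cspec, bands) for _ in range(cspec.n_subjects)]

    names = sorted(cspec.effect_weights)
    tf = pd.DataFrame(
        {nm: [_true_feature(p, nm) for p in all_params] for nm in names},
        index=[f"sub-{i:03d}" for i in range(cspec.n_subjects)],
    )
    if names:
        z = (tf - tf.mean()) / tf.std(ddof=0)
        latent = sum(cspec.effect_weights[nm] * z[nm].to_numpy() for nm in names)
    else:
        latent = np.zeros(cspec.n_subjects)
    clinical = _outcomes_from_latent(rng, cspec, np.asarray(latent, dtype=float))

    recordings: list[RawRecording] = []
    planted_logs: dict[str, pd.DataFrame] = {}
    child_seeds = rng.integers(0, 2**31 - 1, size=cspec.n_subjects)
    for i, params in enumerate(all_params):
        sid = f"sub-{i:03d}"
        bursts = {
            ch: [
                BurstSpec(
                    band_label=band,
                    center_freq_hz=params[band]["center_freq_hz"],
                    rate_per_epoch=params[band]["rate_per_epoch"],
                    n_cycles=params[band]["n_cycles"][ch],
                    amplitude_uv=params[band]["amplitude_uv"],
                )
                for band in bands.labels
            ]
            for ch in cspec.channels
        }
        rspec = RecordingSpec(
            channels=cspec.channels,
            fs_hz=cspec.fs_hz,
            duration_s=cspec.duration_s,
            background_exponent=cspec.background_exponent,
            background_scale_uv=cspec.background_scale_uv,
            shared_fraction=cspec.shared_fraction,
            bursts=bursts,
            seed=int(child_seeds[i]),
            subject_id=sid,
        )
        rec, planted = generate_recording(rspec)
        recordings.append(rec)
        planted_logs[sid] = planted

    truth = {
        "effect_weights": dict(cspec.effect_weights),
        "true_features": tf,
        "latent": np.asarray(latent, dtype=float),
        "planted_events": planted_logs,
        "subject_params": all_params,
    }
    return recordings, clinical, truth


def generate_feature_cohort(
    cspec: CohortSpec, bands: BandSet = DEFAULT_BANDS,
    measurement_noise: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Fast cohort: emit a synthetic SEF table directly, without rendering EEG.

    Used for modeling-level calibration studies (permutation-test type-I
    error, importance ranking) where the EEG rendering and detection stage
    is irrelevant.  The returned frame has the SefTable layout
    (subject_id, channel, band, event_rate, mean_duration_s,
    mean_freq_span_hz, mean_peak_power_fom, n_events) with values equal to
    the subject's true planted parameters plus relative measurement noise.
    """
    rng = np.random.default_rng(cspec.seed)
    all_params = [_draw_subject_params(rng, cspec, bands) for _ in range(cspec.n_subjects)]

    names = sorted(cspec.effect_weights)
    sids = [f"sub-{i:03d}" for i in range(cspec.n_subjects)]
    tf = pd.DataFrame(
        {nm: [_true_feature(p, nm) for p in all_params] for nm in names}, index=sids
    )
    if names:
        z = (tf - tf.mean()) / tf.std(ddof=0)
        latent = sum(cspec.effect_weights[nm] * z[nm].to_numpy() for nm in names)
    else:
        latent = np.zeros(cspec.n_subjects)
    clinical = _outcomes_from_latent(rng, cspec, np.asarray(latent, dtype=float))

    n_epochs = int(cspec.duration_s // EPOCH_LEN_S)
    rows = []
    for sid, params in zip(sids, all_params):
        for ch in cspec.channels:
            for band in bands.labels:
                p = params[band]
                n_events = rng.poisson(p["rate_per_epoch"] * n_epochs)
                rate = n_events / n_epochs
                dur = p["n_cycles"][ch] / p["center_freq_hz"]
                span = p["center_freq_hz"] / p["n_cycles"][ch]
                power = 10.0 * (p["amplitude_uv"] / cspec.per_subject_variation[band]["amp"][0]) ** 2
                noise = 1.0 + measurement_noise * rng.standard_normal(3)
                rows.append((sid, ch, band, rate,
                             dur * noise[0], span * noise[1], power * noise[2],
                             int(n_events)))
    sef = pd.DataFrame(
        rows,
        columns=["subject_id", "channel", "band", "event_rate", "mean_duration_s",
                 "mean_freq_span_hz", "mean_peak_power_fom", "n_events"],
    )
    truth = {"effect_weights": dict(cspec.effect_weights),
             "true_features": tf, "latent": np.asarray(latent, dtype=float)}
    return sef, clinical, truth


# ---------------------------------------------------------------------------
# artifact output
# ---------------------------------------------------------------------------

def write_cohort(
    recordings: list[RawRecording], clinical: pd.DataFrame, truth: dict,
    out_dir: str | Path,
) -> Path:
    """Write a cohort to disk: one EDF per subject, clinical CSV, truth JSON."""
    from .io import write_edf

    out = Path(out_dir)
    (out / "edf").mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_edf(rec, out / "edf" / f"{rec.subject_id}.edf")
    clinical.to_csv(out / "clinical.csv", index=False)

    planted = pd.concat(
        [df.assign(subject_id=sid) for sid, df in truth["planted_events"].items()],
        ignore_index=True,
    ) if truth.get("planted_events") else pd.DataFrame()
    planted.to_csv(out / "planted_events.csv", index=False)

    truth_json = {
        "effect_weights": truth["effect_weights"],
        "latent": [float(v) for v in truth["latent"]],
        "true_features": {
            c: [float(v) for v in truth["true_features"][c]]
            for c in truth["true_features"].columns
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(truth_json, indent=2))
    return out
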