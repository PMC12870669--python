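"""Canonical frequency bands and the frontal 10-20 montage.

Band edges follow the convention of defining a low-frequency "delta/theta"
band around the low tail of the resting power spectrum, an alpha band wide
enough to cover the closed-eyes alpha peak, and a beta band up to 29 Hz.
Bounds are inclusive on the 1 Hz analysis grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field

#: Frontal 10-20 electrodes, in canonical order.
FRONTAL_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "Fz", "F4", "F3", "F7", "F8",
)


@dataclass(frozen=True)
class BandSet:
    """Inclusive frequency bands (Hz) used throughout the pipeline.

    Invariant: bands are non-overlapping and ordered low to high.
    """

    delta_theta: tuple[float, float] = (2.0, 5.0)
    alpha: tuple[float, float] = (6.0, 14.0)
    beta: tuple[float, float] = (15.0, 29.0)

    def __post_init__(self) -> None:
        items = [self.delta_theta, self.alpha, self.beta]
        for lo, hi in items:
            if not lo < hi:
                raise ValueError(f"band bounds must be increasing, got {(lo, hi)}")
        for (lo_a, hi_a), (lo_b, hi_b) in zip(items, items[1:]):
            if hi_a >= lo_b:
                raise ValueError("bands must be non-overlapping and ordered")

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {
            "delta_theta": self.delta_theta,
            "alpha": self.alpha,
            "beta": self.beta,
        }

    @property
    def labels(self) -> tuple[str, ...]:
        return ("delta_theta", "alpha", "beta")

    def __getitem__(self, label: str) -> tuple[float, float]:
        return self.as_dict()[label]


DEFAULT_BANDS = BandSet()

#: Spectral event features aggregated per (channel, band), in report order.
SEF_FEATURES: tuple[str, ...] = ("power", "rate", "duration", "freq_span")
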