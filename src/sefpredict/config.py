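"""Pipeline configuration: a nested dataclass that round-trips through YAML."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class CohortConfig:
    arm: str = "sertraline_like"
    n_subjects: int = 82
    seed: int = 0
    fs_hz: float = 200.0
    duration_s: float = 150.0


@dataclass
class PreprocessConfig:
    hp_hz: float = 0.5
    lp_hz: float = 50.0
    corr_threshold: float = 0.8
    flat_seconds: float = 5.0
    z_amp_threshold: float = 5.0
    kurt_z_threshold: float = 5.0
    epoch_len_s: float = 5.0


@dataclass
class EventsConfig:
    threshold_fom: float = 6.0
    wavelet_cycles: float = 7.0
    freq_lo_hz: float = 1.0
    freq_hi_hz: float = 30.0


@dataclass
class ModelingConfig:
    feature_set: str = "sef"
    n_perm: int = 500
    seed: int = 0
    n_importance_repeats: int = 10
    alphas: list[float] = field(default_factory=lambda: [0.1, 0.3, 1.0, 3.0, 10.0])
    l1_ratios: list[float] = field(default_factory=lambda: [0.1, 0.5, 0.9])
    fit_intercept: list[bool] = field(default_factory=lambda: [True, False])


@dataclass
class PosthocConfig:
    top_k: int = 5
    correction: str = "bonferroni"


@dataclass
class PipelineConfig:
    out_dir: str = "sefpredict_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    events: EventsConfig = field(default_factory=EventsConfig)
    modeling: ModelingConfig = field(default_factory=ModelingConfig)
    posthoc: PosthocConfig = field(default_factory=PosthocConfig)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        raw = yaml.safe_load(p.read_text() if p.exists() else str(source)) or {}
        return cls(
            out_dir=raw.get("out_dir", cls.out_dir),
            cohort=CohortConfig(**raw.get("cohort", {})),
            preprocess=PreprocessConfig(**raw.get("preprocess", {})),
            events=EventsConfig(**raw.get("events", {})),
            modeling=ModelingConfig(**raw.get("modeling", {})),
            posthoc=PosthocConfig(**raw.get("posthoc", {})),
        )
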