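"""End-to-end orchestration: simulate -> preprocess -> features -> fit ->
posthoc, with file artifacts between stages so each can be rerun alone.

Artifacts (under the configured output directory):
  simulate    edf/sub-*.edf, clinical.csv, planted_events.csv, ground_truth.json
  preprocess  epochs/sub-*.npz, preprocess_report.json
  features    sef.csv, events.csv [, apf_channel.csv, apf_pairs.csv]
  fit         model_report.json
  posthoc     posthoc.json
Every run also writes resolved_config.yaml and run.log (stage timings).
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import avgpower, events as ev, modeling, posthoc as ph, synthgen
from .preprocess import preprocess as preprocess_recording
from .bands import DEFAULT_BANDS, FRONTAL_CHANNELS
from .config import PipelineConfig
from .io import read_edf
from .recording import EpochedRecording

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"{needed_by!r} needs {path} — run the {stage!r} stage first"
        )
    return path


def _setup_run(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "resolved_config.yaml")
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logging.getLogger("sefpredict").addHandler(handler)
    return out


def stage_simulate(cfg: PipelineConfig) -> Path:
    out = _setup_run(cfg)
    t0 = time.time()
    c = cfg.cohort
    maker = (synthgen.CohortSpec.sertraline_like if c.arm == "sertraline_like"
             else synthgen.CohortSpec.placebo_like)
    cspec = maker(n_subjects=c.n_subjects, seed=c.seed,
                  fs_hz=c.fs_hz, duration_s=c.duration_s)
    recordings, clinical, truth = synthgen.generate_cohort(cspec)
    synthgen.write_cohort(recordings, clinical, truth, out)
    logger.info("simulate: %d subjects in %.1f s", c.n_subjects, time.time() - t0)
    return out


def stage_preprocess(cfg: PipelineConfig) -> Path:
    out = _setup_run(cfg)
    t0 = time.time()
    edf_dir = _require(out / "edf", "simulate", "preprocess")
    ep_dir = out / "epochs"
    ep_dir.mkdir(exist_ok=True)
    p = cfg.preprocess
    reports = {}
    for f in sorted(edf_dir.glob("*.edf")):
        rec = read_edf(f)
        epochs, report = preprocess_recording(
            rec, hp_hz=p.hp_hz, lp_hz=p.lp_hz, corr_threshold=p.corr_threshold,
            flat_seconds=p.flat_seconds, z_amp_threshold=p.z_amp_threshold,
            kurt_z_threshold=p.kurt_z_threshold, epoch_len_s=p.epoch_len_s,
        )
        np.savez_compressed(
            ep_dir / f"{rec.subject_id}.npz",
            data=epochs.data, fs_hz=epochs.fs_hz,
            channel_labels=np.array(epochs.channel_labels),
            epoch_len_s=epochs.epoch_len_s,
        )
        reports[rec.subject_id] = {
            "dropped_channels": report.dropped_channels,
            "dropped_segments": {str(k): v for k, v in report.dropped_segments.items()},
            "missing_requested_channels": report.missing_requested_channels,
            "filter_settings": report.filter_settings,
        }
    (out / "preprocess_report.json").write_text(json.dumps(reports, indent=2, sort_keys=True))
    logger.info("preprocess: %d recordings in %.1f s", len(reports), time.time() - t0)
    return out


def _load_epochs(path: Path) -> EpochedRecording:
    z = np.load(path, allow_pickle=False)
    return EpochedRecording(
        data=z["data"], fs_hz=float(z["fs_hz"]),
        channel_labels=[str(s) for s in z["channel_labels"]],
        epoch_len_s=float(z["epoch_len_s"]), subject_id=path.stem,
    )


def stage_features(cfg: PipelineConfig) -> Path:
    out = _setup_run(cfg)
    t0 = time.time()
    ep_dir = _require(out / "epochs", "preprocess", "features")
    e = cfg.events
    det = ev.EventDetectionConfig(
        threshold_fom=e.threshold_fom, wavelet_cycles=e.wavelet_cycles,
        freq_lo_hz=e.freq_lo_hz, freq_hi_hz=e.freq_hi_hz,
    )
    need_apf = cfg.modeling.feature_set in ("apf", "both")

    sefs, frames, apf_ch, apf_pr = [], [], [], []
    for f in sorted(ep_dir.glob("*.npz")):
        epochs = _load_epochs(f)
        frame, sef = ev.detect_and_aggregate(epochs, det)
        sefs.append(sef.assign(subject_id=epochs.subject_id))
        frames.append(frame.assign(subject_id=epochs.subject_id))
        if need_apf:
            per_ch, per_pair = avgpower.apf_table(epochs)
            apf_ch.append(per_ch.reset_index().assign(subject_id=epochs.subject_id))
            apf_pr.append(per_pair.assign(subject_id=epochs.subject_id))
    pd.concat(sefs, ignore_index=True).to_csv(out / "sef.csv", index=False)
    pd.concat(frames, ignore_index=True).to_csv(out / "events.csv", index=False)
    if need_apf:
        pd.concat(apf_ch, ignore_index=True).to_csv(out / "apf_channel.csv", index=False)
        pd.concat(apf_pr, ignore_index=True).to_csv(out / "apf_pairs.csv", index=False)
    logger.info("features: %d subjects in %.1f s", len(sefs), time.time() - t0)
    return out


def stage_fit(cfg: PipelineConfig) -> modeling.ModelReport:
    out = _setup_run(cfg)
    t0 = time.time()
    clinical = pd.read_csv(_require(out / "clinical.csv", "simulate", "fit"))
    m = cfg.modeling
    sef = apf_channel = apf_pairs = None
    if m.feature_set in ("sef", "both"):
        sef = pd.read_csv(_require(out / "sef.csv", "features", "fit"))
    if m.feature_set in ("apf", "both"):
        apf_channel = pd.read_csv(_require(out / "apf_channel.csv", "features", "fit"))
        apf_pairs = pd.read_csv(_require(out / "apf_pairs.csv", "features", "fit"))

    fm = modeling.assemble_features(
        clinical, sef=sef, apf_channel=apf_channel, apf_pairs=apf_pairs,
        feature_set=m.feature_set,
    )
    grid = modeling.GridSpec(
        alphas=tuple(m.alphas), l1_ratios=tuple(m.l1_ratios),
        fit_intercept=tuple(m.fit_intercept),
    )
    report = modeling.run_model_protocol(
        fm, grid=grid, seed=m.seed, n_perm=m.n_perm,
        n_importance_repeats=m.n_importance_repeats,
    )
    (out / "model_report.json").write_text(report.to_json())
    logger.info("fit: %s features, %d perms in %.1f s",
                m.feature_set, m.n_perm, time.time() - t0)
    return report


def stage_posthoc(cfg: PipelineConfig) -> dict:
    out = _setup_run(cfg)
    t0 = time.time()
    report = json.loads(_require(out / "model_report.json", "fit", "posthoc").read_text())
    clinical = pd.read_csv(_require(out / "clinical.csv", "simulate", "posthoc"))
    sef = pd.read_csv(_require(out / "sef.csv", "features", "posthoc"))

    imp = pd.DataFrame(report["importances"])
    top = ph.top_k_features(imp, k=cfg.posthoc.top_k)

    fm = modeling.assemble_features(clinical, sef=sef, feature_set="sef")
    result = ph.posthoc_report(fm.X, clinical, top, method=cfg.posthoc.correction)
    result["top_features"] = top
    (out / "posthoc.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    logger.info("posthoc: %d features tested in %.1f s",
                result["m_tests"], time.time() - t0)
    return result


_STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "features": stage_features,
    "fit": stage_fit,
    "posthoc": stage_posthoc,
}


def run(cfg: PipelineConfig, stages: list[str] | None = None) -> Path:
    """Run the named stages (default: all) in order; abort naming the
    failing stage."""
    order = ["simulate", "preprocess", "features", "fit", "posthoc"]
    todo = order if stages is None else [s for s in order if s in set(stages)]
    for name in todo:
        try:
            _STAGES[name](cfg)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(name, exc) from exc
    return Path(cfg.out_dir)
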