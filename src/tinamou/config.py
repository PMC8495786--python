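"""Pipeline configuration and stage runner.

One YAML file with per-stage blocks mirrors the pipeline's table of
defaults field-for-field: spectrogram (STFT settings), architecture,
training and augmentation (hyperparameters), detection (threshold 0.85,
grouping gap 0.75 s, smoothing weights 1/0.5) and ecology (1-h lumping,
trap-day rate basis).  Overrides of any default are logged; every stage
artifact is stamped with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from tinamou.classifier import AugmentationConfig, ModelArchitectureSpec, TrainingConfig
from tinamou.spectrogram import SpectrogramConfig

log = logging.getLogger(__name__)

STAGES = ("synth", "train", "classify", "events", "ecology")


@dataclass(frozen=True)
class DetectionConfig:
    threshold: float = 0.85
    gap_s: float = 0.75
    smoothing_w_center: float = 1.0
    smoothing_w_neighbor: float = 0.5


@dataclass(frozen=True)
class EcologyConfig:
    lump_window_h: float = 1.0
    rate_per: float = 1000.0
    exclude_species: tuple[str, ...] = ()
    equipment_cost: float | None = None


@dataclass(frozen=True)
class SynthConfig:
    """Synthetic survey study design (the generator's defaults)."""

    n_sites: int = 10
    n_days: int = 1
    session_duration_s: float = 360.0
    n_species: int = 4
    rates_per_hour: tuple[float, ...] = (25.0, 50.0, 100.0, 200.0)
    snr_range_db: tuple[float, float] = (5.0, 15.0)
    noise_dbfs: float = -28.0
    clips_per_class: int = 96


@dataclass(frozen=True)
class IngestConfig:
    target_db: float = -2.0
    mute_s: float = 5.0
    window_s: float = 2.0
    hop_s: float = 0.25


@dataclass
class PipelineConfig:
    spectrogram: SpectrogramConfig = field(default_factory=SpectrogramConfig)
    architecture: ModelArchitectureSpec = field(default_factory=ModelArchitectureSpec)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    augmentation_noise: AugmentationConfig = field(
        default_factory=lambda: AugmentationConfig.for_submodel("noise"))
    augmentation_no_noise: AugmentationConfig = field(
        default_factory=lambda: AugmentationConfig.for_submodel("no_noise"))
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    ecology: EcologyConfig = field(default_factory=EcologyConfig)
    ingest: IngestConfig = field(default_factory=IngestConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0
    workdir: str = "pipeline_run"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(tp, block):
            if block is None:
                return tp()
            fields = {f.name for f in dataclasses.fields(tp)}
            unknown = set(block) - fields
            if unknown:
                raise ValueError(f"unknown keys in {tp.__name__}: {sorted(unknown)}")
            kwargs = {}
            for f in dataclasses.fields(tp):
                if f.name in block:
                    v = block[f.name]
                    kwargs[f.name] = tuple(tuple(x) if isinstance(x, list) else x for x in v) \
                        if isinstance(v, list) else v
            return tp(**kwargs)

        cfg = cls(
            spectrogram=build(SpectrogramConfig, d.get("spectrogram")),
            architecture=build(ModelArchitectureSpec, d.get("architecture")),
            training=build(TrainingConfig, d.get("training")),
            augmentation_noise=build(AugmentationConfig, d.get("augmentation_noise")),
            augmentation_no_noise=build(AugmentationConfig, d.get("augmentation_no_noise")),
            detection=build(DetectionConfig, d.get("detection")),
            ecology=build(EcologyConfig, d.get("ecology")),
            ingest=build(IngestConfig, d.get("ingest")),
            synth=build(SynthConfig, d.get("synth")),
            seed=int(d.get("seed", 0)),
            workdir=str(d.get("workdir", "pipeline_run")),
        )
        for name, default in (("spectrogram", SpectrogramConfig()),
                              ("architecture", ModelArchitectureSpec()),
                              ("training", TrainingConfig()),
                              ("detection", DetectionConfig())):
            if getattr(cfg, name) != default:
                log.info("config block %r overrides defaults", name)
        return cfg

    def dump(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    @classmethod
    def load(cls, path: Path | str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(_plain(self.to_dict()), sort_keys=True).encode()).hexdigest()[:12]


def _plain(obj: Any) -> Any:
    """Recursively convert to YAML/JSON-safe plain python types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _stamp(workdir: Path, stage: str, config: "PipelineConfig") -> None:
    manifest = {"stage": stage, "config_hash": config.config_hash, "seed": config.seed}
    (workdir / f"{stage}.manifest.json").write_text(json.dumps(manifest, indent=2))


def run_pipeline(config: PipelineConfig, stage_range: Sequence[str] = STAGES,
                 workdir: Path | str | None = None) -> dict:
    """Execute pipeline stages in order on the synthetic survey.

    Stages: ``synth`` (generate survey audio + clips) -> ``train`` (two
    submodels) -> ``classify`` (ensemble + smoothing + threshold) ->
    ``events`` (grouping) -> ``ecology`` (event rates per species).  Each
    stage reads its predecessors' artifacts from the working directory, so
    a later stage without its upstream artifact fails with the stage name
    to rerun.
    """
    from tinamou import synth
    from tinamou.classifier import AugmentationConfig, train_submodel
    from tinamou.detection import (classify_recording, detections_to_frame, events_to_frame,
                                   group_vocal_events, smooth_probabilities, threshold_detections)
    from tinamou.ingest import load_recording_metadata, preprocess, read_wav
    from tinamou.species import fixture_templates

    for s in stage_range:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; stages are {STAGES}")
    stage_range = [s for s in STAGES if s in stage_range]
    workdir = Path(workdir or config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    out: dict = {}
    sc = config.synth
    templates = fixture_templates(sc.n_species)
    species = sorted(templates)
    rates = dict(zip(species, sc.rates_per_hour))

    if "synth" in stage_range:
        sites = [(f"S{i:02d}", "terra_firme" if i % 2 == 0 else "floodplain")
                 for i in range(sc.n_sites)]
        synth.generate_survey(sites, rates, sc.n_days, config.seed, workdir / "audio",
                              templates, sc.session_duration_s,
                              snr_range_db=sc.snr_range_db, noise_dbfs=sc.noise_dbfs)
        clips = synth.generate_training_clips(templates, sc.clips_per_class, seed=config.seed + 1,
                                              snr_range_db=sc.snr_range_db, noise_dbfs=sc.noise_dbfs)
        clips.split_train_validation(seed=config.seed + 2)
        with open(workdir / "clips.pkl", "wb") as fh:
            pickle.dump(clips, fh)
        _stamp(workdir, "synth", config)

    if "train" in stage_range:
        clips_path = workdir / "clips.pkl"
        if not clips_path.exists():
            raise FileNotFoundError("missing training clips; rerun stage 'synth'")
        with open(clips_path, "rb") as fh:
            clips = pickle.load(fh)
        submodels = []
        for kind, aug in (("no_noise", config.augmentation_no_noise),
                          ("noise", config.augmentation_noise)):
            cfg = replace(config.training, seed=config.seed + (10 if kind == "noise" else 0))
            submodels.append(train_submodel(clips, config.architecture, cfg, aug, config.spectrogram))
        with open(workdir / "models.pkl", "wb") as fh:
            pickle.dump(submodels, fh)
        _stamp(workdir, "train", config)

    if "classify" in stage_range:
        for artifact, stage in ((workdir / "models.pkl", "train"),
                                (workdir / "audio" / "recordings.csv", "synth")):
            if not artifact.exists():
                raise FileNotFoundError(f"missing artifact {artifact.name}; rerun stage {stage!r}")
        with open(workdir / "models.pkl", "rb") as fh:
            submodels = pickle.load(fh)
        recordings = load_recording_metadata(workdir / "audio" / "recordings.csv")
        dets = []
        for rec in recordings:
            wave, _ = read_wav(rec.file_path, expect_rate=rec.sample_rate)
            wave = preprocess(wave, rec, config.ingest.target_db, config.ingest.mute_s)
            series = classify_recording(rec, wave, submodels, config.spectrogram,
                                        config.ingest.window_s, config.ingest.hop_s)
            smoothed = smooth_probabilities(series, config.detection.smoothing_w_center,
                                            config.detection.smoothing_w_neighbor)
            dets.extend(threshold_detections(smoothed, config.detection.threshold))
        detections_to_frame(dets).to_csv(workdir / "detections.csv", index=False)
        out["detections"] = dets
        _stamp(workdir, "classify", config)

    if "events" in stage_range:
        if "detections" in out:
            dets = out["detections"]
        elif (workdir / "detections.csv").exists():
            dets = _detections_from_csv(workdir / "detections.csv", workdir / "audio")
        else:
            raise FileNotFoundError("missing detections.csv; rerun stage 'classify'")
        events = group_vocal_events(dets, config.detection.gap_s)
        events_to_frame(events).to_csv(workdir / "events.csv", index=False)
        out["events"] = events
        _stamp(workdir, "events", config)

    if "ecology" in stage_range:
        ev_path = workdir / "events.csv"
        if not ev_path.exists():
            raise FileNotFoundError("missing events.csv; rerun stage 'events'")
        ev = pd.read_csv(ev_path)
        hours = sc.n_sites * sc.n_days * 2 * sc.session_duration_s / 3600.0
        rows = []
        for sp in species:
            n = int((ev["species"] == sp).sum()) if len(ev) else 0
            rows.append({"species": sp, "events": n, "events_per_hour": n / hours,
                         "programmed_rate": rates[sp]})
        effort = pd.DataFrame(rows)
        effort.to_csv(workdir / "effort.csv", index=False)
        out["effort"] = effort
        _stamp(workdir, "ecology", config)
    return out


def _detections_from_csv(path: Path, audio_dir: Path):
    from tinamou.detection import Detection
    from tinamou.ingest import load_recording_metadata

    recs = {r.file_path.name: r for r in load_recording_metadata(audio_dir / "recordings.csv")}
    df = pd.read_csv(path)
    dets = []
    for _, row in df.iterrows():
        dets.append(Detection(recs.get(str(row["file"])), float(row["start_s"]),
                              float(row["end_s"]) - float(row["start_s"]), str(row["label"]),
                              float(row["max_prob"]), str(row["review_status"])))
    return dets
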