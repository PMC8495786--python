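"""Second-pass dataset supplementation and retraining.

After the first classification pass is reviewed, every ground-truthed
positive window becomes a candidate training clip.  The pass-2 training
set per class is the larger of a cap (2,000 clips; 4,000 for junk) sampled
without replacement from the pooled base + verified clips, or the whole
pool when it is smaller.  The same architecture and hyperparameters are
reused; the sole training change is class-balanced batch generation, to
offset the much larger class imbalance of the supplemented dataset.
Validation sets are rebuilt preferring survey-origin clips.  Windows
confirmed in pass 1 are grandfathered — never re-queued for review.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np

from tinamou.classifier import (
    AugmentationConfig,
    ModelArchitectureSpec,
    TrainingConfig,
    TrainedSubmodel,
    train_submodel,
)
from tinamou.dataset import Clip, ClipDataset
from tinamou.detection import Detection, group_vocal_events
from tinamou.spectrogram import SpectrogramConfig

log = logging.getLogger(__name__)

CAP_SPECIES = 2000
CAP_JUNK = 4000


def detections_to_clips(detections: Sequence[Detection], waveforms: Mapping[str, np.ndarray],
                        sample_rate: int = 16_000) -> list[Clip]:
    """Cut confirmed/relabelled detections into survey-verified clips."""
    clips = []
    for d in detections:
        if d.review_status not in ("confirmed", "relabelled"):
            continue
        wave = waveforms[d.recording.file_path.name]
        i = int(round(d.start_s * sample_rate))
        n = int(round(d.window_s * sample_rate))
        seg = wave[i : i + n]
        if len(seg) < n or not np.any(seg):  # drop truncated or silent (muted) windows
            continue
        clips.append(Clip(np.asarray(seg, dtype=np.float32), d.effective_label, origin="survey_verified"))
    return clips


def supplement_training_set(
    base: ClipDataset,
    verified: Sequence[Clip],
    rng: np.random.Generator,
    cap_species: int = CAP_SPECIES,
    cap_junk: int = CAP_JUNK,
    junk_label: str = "junk",
    val_fraction: float = 0.2,
) -> ClipDataset:
    """Build the pass-2 dataset: pool base and verified clips, cap per class.

    Per class the pool is base ∪ verified; when the pool exceeds its cap
    (``cap_junk`` for the junk class, ``cap_species`` otherwise) the cap is
    sampled without replacement, else everything is kept.  Validation
    quotas are refilled preferring survey-origin clips.

    Raises
    ------
    ValueError
        If any base class ends up with zero clips.
    """
    pools: dict[str, list[Clip]] = {}
    for c in base.clips:
        pools.setdefault(c.label, []).append(replace_clip(c))
    for c in verified:
        pools.setdefault(c.label, []).append(replace_clip(c))
    out: list[Clip] = []
    for label in sorted(pools):
        pool = pools[label]
        if not pool:
            raise ValueError(f"class {label!r} has zero clips")
        cap = cap_junk if label == junk_label else cap_species
        if len(pool) > cap:
            idx = rng.choice(len(pool), size=cap, replace=False)
            pool = [pool[i] for i in sorted(idx)]
        # validation preference: survey-origin first, then external
        n_val = max(1, int(round(val_fraction * len(pool)))) if len(pool) > 1 else 0
        order = list(rng.permutation(len(pool)))
        order.sort(key=lambda i: pool[i].origin != "survey_verified")
        for rank, i in enumerate(order):
            pool[i].split = "validation" if rank < n_val else "train"
        out.extend(pool)
    return ClipDataset(out)


def replace_clip(c: Clip) -> Clip:
    return Clip(c.waveform, c.label, origin=c.origin, split=c.split)


def review_from_truth(detections: Sequence[Detection], truth: "pd.DataFrame",
                      min_overlap_s: float = 0.5, junk_label: str = "junk") -> list[Detection]:
    """Resolve review statuses against a ground-truth event table.

    Emulates the manual review step on synthetic surveys where truth is
    known: a window overlapping (by at least ``min_overlap_s``) a truth
    event of its predicted species is confirmed; one overlapping only a
    different species is relabelled to that species; one overlapping
    nothing is rejected (junk predictions are confirmed when they overlap
    nothing).  ``truth`` columns: file, species, onset_s, offset_s.
    """
    import pandas as pd  # noqa: F811 - local to keep module import light

    by_file: dict[str, pd.DataFrame] = {k: v for k, v in truth.groupby("file")}
    for d in detections:
        fname = d.recording.file_path.name if d.recording else ""
        tt = by_file.get(fname)
        overlaps: dict[str, float] = {}
        if tt is not None:
            ov = np.minimum(tt["offset_s"], d.end_s) - np.maximum(tt["onset_s"], d.start_s)
            for sp, o in zip(tt["species"], ov):
                if o >= min_overlap_s:
                    overlaps[sp] = max(overlaps.get(sp, 0.0), float(o))
        if d.label in overlaps:
            d.review_status = "confirmed"
        elif overlaps:
            best = max(overlaps, key=overlaps.get)
            d.review_status = "relabelled"
            d.review_label = best
        elif d.label == junk_label:
            d.review_status = "confirmed"
        else:
            d.review_status = "rejected"
    return list(detections)


def run_second_pass(
    recordings,
    waveforms: Mapping[str, np.ndarray],
    base_dataset: ClipDataset,
    pass1_detections: Sequence[Detection],
    arch: ModelArchitectureSpec,
    train_cfg: TrainingConfig,
    spec_config: SpectrogramConfig,
    gap_s: float = 0.75,
    threshold: float = 0.85,
    cap_species: int = CAP_SPECIES,
    cap_junk: int = CAP_JUNK,
    rng: np.random.Generator | None = None,
    reclassify: bool = True,
):
    """Retrain on the supplemented dataset and reclassify the survey.

    Returns ``(submodels, detections, events, dataset)``.  Pass-1
    confirmed windows are grandfathered into the pass-2 detections; only
    newly positive windows are left unreviewed.  Balanced batches are
    forced on (the sole training change between passes).
    """
    from tinamou.detection import classify_recording, smooth_probabilities, threshold_detections

    rng = rng or np.random.default_rng(train_cfg.seed)
    verified = detections_to_clips(pass1_detections, waveforms,
                                   sample_rate=spec_config.sample_rate)
    dataset = supplement_training_set(base_dataset, verified, rng,
                                      cap_species=cap_species, cap_junk=cap_junk)
    cfg = replace(train_cfg, balanced_batches=True)
    submodels = []
    for kind in ("no_noise", "noise"):
        aug = AugmentationConfig.for_submodel(kind)
        sub_cfg = replace(cfg, seed=cfg.seed + (0 if kind == "no_noise" else 1))
        submodels.append(train_submodel(dataset, arch, sub_cfg, aug, spec_config))
    grandfathered = {
        (d.recording.file_path.name, round(d.start_s, 6))
        for d in pass1_detections
        if d.review_status in ("confirmed", "relabelled")
    }
    detections: list[Detection] = []
    if not reclassify:
        return submodels, detections, [], dataset
    for rec in recordings:
        series = classify_recording(rec, waveforms[rec.file_path.name], submodels, spec_config)
        smoothed = smooth_probabilities(series)
        for d in threshold_detections(smoothed, threshold):
            key = (rec.file_path.name, round(d.start_s, 6))
            if key in grandfathered:
                d.review_status = "confirmed"
            detections.append(d)
    events = group_vocal_events(detections, gap_s)
    return submodels, detections, events, dataset
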