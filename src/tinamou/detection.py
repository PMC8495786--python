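"""Detection post-processing: smoothing, thresholding, eventization, review.

The ensemble yields one 12-class probability vector per overlapping 2-s
window.  Post-processing:

1. temporal smoothing — each vector is replaced by the weighted average of
   itself (weight 1) and its immediate neighbours (weight 0.5), with
   boundary weights renormalized;
2. thresholding — windows whose smoothed maximum class probability is
   below 0.85 are removed; the rest take the argmax label (junk-labelled
   windows are kept internally but never become species events);
3. eventization — per recording and species, retained windows whose
   intervals lie closer than 0.75 s merge into a single vocal event;
4. review bookkeeping — manual confirm/relabel/reject decisions are merged
   in, and windows confirmed in an earlier pass are grandfathered (never
   re-queued for review).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from tinamou.ingest import SurveyRecording
from tinamou.species import JUNK_LABEL

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.85
DEFAULT_GAP_S = 0.75
DEFAULT_W_CENTER = 1.0
DEFAULT_W_NEIGHBOR = 0.5


@dataclass
class ProbabilitySeries:
    """Per-window class probabilities along a recording's time axis."""

    recording: SurveyRecording | None
    starts_s: np.ndarray  # strictly increasing window starts
    probs: np.ndarray  # (n_windows, n_classes), rows sum to 1
    class_labels: tuple[str, ...]
    window_s: float = 2.0

    def __post_init__(self) -> None:
        self.starts_s = np.asarray(self.starts_s, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or len(self.starts_s) != len(self.probs):
            raise ValueError("starts/probs length mismatch")
        if len(self.starts_s) > 1 and np.any(np.diff(self.starts_s) <= 0):
            raise ValueError("window starts must be strictly increasing")


@dataclass
class Detection:
    """One retained window with its review state."""

    recording: SurveyRecording | None
    start_s: float
    window_s: float
    label: str
    max_prob: float
    review_status: str = "unreviewed"  # unreviewed|confirmed|relabelled|rejected
    review_label: str | None = None

    @property
    def effective_label(self) -> str:
        if self.review_status == "relabelled" and self.review_label:
            return self.review_label
        return self.label

    @property
    def end_s(self) -> float:
        return self.start_s + self.window_s


@dataclass
class VocalEvent:
    """A species-labelled time interval built from retained windows."""

    species: str
    recording: SurveyRecording | None
    start_s: float
    end_s: float
    n_windows: int

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("event end must be after start")

    @property
    def site_id(self):
        return self.recording.site_id if self.recording else None

    @property
    def habitat(self):
        return self.recording.habitat if self.recording else None

    @property
    def session(self):
        return self.recording.session if self.recording else None

    @property
    def timestamp(self) -> pd.Timestamp | None:
        """Absolute (naive local) event start from the session clock."""
        if self.recording is None:
            return None
        from tinamou.synth import SESSION_STARTS

        base = pd.Timestamp(f"{self.recording.date} {SESSION_STARTS[self.recording.session]}")
        return base + pd.Timedelta(seconds=self.start_s)


def smooth_probabilities(series: ProbabilitySeries,
                         w_center: float = DEFAULT_W_CENTER,
                         w_neighbor: float = DEFAULT_W_NEIGHBOR) -> ProbabilitySeries:
    """Weighted moving average over adjacent windows.

    Interior rows: ``(w_c * p_t + w_n * p_{t-1} + w_n * p_{t+1}) /
    (w_c + 2 w_n)``.  Boundary rows use only their existing neighbour with
    the weights renormalized, so row sums are preserved exactly.
    """
    p = series.probs
    if len(p) == 0:
        return series
    out = np.empty_like(p)
    for t in range(len(p)):
        acc = w_center * p[t]
        wsum = w_center
        if t > 0:
            acc = acc + w_neighbor * p[t - 1]
            wsum += w_neighbor
        if t < len(p) - 1:
            acc = acc + w_neighbor * p[t + 1]
            wsum += w_neighbor
        out[t] = acc / wsum
    return replace(series, probs=out)


def threshold_detections(series: ProbabilitySeries,
                         threshold: float = DEFAULT_THRESHOLD) -> list[Detection]:
    """Keep windows whose (smoothed) maximum class probability is >= threshold.

    The retained label is the argmax class; argmax ties break toward the
    lowest class index with a warning.  Junk-labelled windows are retained
    here (they matter for review bookkeeping) but are excluded from
    species events downstream.
    """
    dets: list[Detection] = []
    for t in range(len(series.probs)):
        row = series.probs[t]
        m = float(row.max())
        if m < threshold:
            continue
        winners = np.flatnonzero(row == m)
        if len(winners) > 1:
            log.warning("argmax tie at window %.2fs; taking lowest class index", series.starts_s[t])
        dets.append(
            Detection(
                recording=series.recording,
                start_s=float(series.starts_s[t]),
                window_s=series.window_s,
                label=series.class_labels[int(winners[0])],
                max_prob=m,
            )
        )
    return dets


def group_vocal_events(detections: Sequence[Detection],
                       gap_s: float = DEFAULT_GAP_S) -> list[VocalEvent]:
    """Merge retained windows into per-species vocal events.

    Per (recording, species), windows are treated as intervals
    ``[start, start + window]``; sweeping in start order, a window joins
    the current event when the gap to the event's end is < ``gap_s``
    (events >= ``gap_s`` apart stay separate).  Rejected windows are
    excluded; relabelled windows count under their review label; junk
    windows never form events.
    """
    groups: dict[tuple[int, str], list[Detection]] = {}
    for d in detections:
        if d.review_status == "rejected":
            continue
        label = d.effective_label
        if label == JUNK_LABEL:
            continue
        groups.setdefault((id(d.recording), label), []).append(d)
    events: list[VocalEvent] = []
    for (_, label), ds in groups.items():
        ds.sort(key=lambda d: d.start_s)
        cur_start, cur_end, n = ds[0].start_s, ds[0].end_s, 1
        for d in ds[1:]:
            if d.start_s - cur_end < gap_s:
                cur_end = max(cur_end, d.end_s)
                n += 1
            else:
                events.append(VocalEvent(label, ds[0].recording, cur_start, cur_end, n))
                cur_start, cur_end, n = d.start_s, d.end_s, 1
        events.append(VocalEvent(label, ds[0].recording, cur_start, cur_end, n))
    events.sort(key=lambda e: (str(e.recording.file_path) if e.recording else "", e.start_s, e.species))
    return events


def merge_review_labels(detections: Sequence[Detection],
                        review: pd.DataFrame,
                        grandfathered: set[tuple[str, float]] | None = None) -> list[Detection]:
    """Apply a manual-review table to the detection list.

    ``review`` columns: file, start_s, status (confirmed|relabelled|
    rejected) [, label].  Keys that match no detection are skipped with a
    warning.  Windows in ``grandfathered`` — (file, start_s) keys confirmed
    in a previous pass — are marked confirmed without re-review.
    """
    by_key = {
        (d.recording.file_path.name if d.recording else "", round(d.start_s, 6)): d
        for d in detections
    }
    if grandfathered:
        for key in grandfathered:
            d = by_key.get((key[0], round(key[1], 6)))
            if d is not None:
                d.review_status = "confirmed"
    for _, row in review.iterrows():
        key = (str(row["file"]), round(float(row["start_s"]), 6))
        d = by_key.get(key)
        if d is None:
            log.warning("review entry %s matches no detection; skipped", key)
            continue
        status = str(row["status"])
        if status not in ("confirmed", "relabelled", "rejected"):
            log.warning("unknown review status %r for %s; skipped", status, key)
            continue
        d.review_status = status
        if status == "relabelled":
            d.review_label = str(row.get("label", d.label))
    return list(detections)


def review_queue(detections: Sequence[Detection]) -> list[Detection]:
    """Detections still needing manual review (not yet reviewed)."""
    return [d for d in detections if d.review_status == "unreviewed"]


DETECTION_COLUMNS = ("file", "site", "habitat", "session", "start_s", "end_s",
                     "label", "max_prob", "review_status", "review_label")
EVENT_COLUMNS = ("file", "site", "habitat", "session", "species", "start_s",
                 "end_s", "n_windows", "timestamp")


def detections_to_frame(detections: Sequence[Detection]) -> pd.DataFrame:
    rows = []
    for d in detections:
        rec = d.recording
        rows.append(
            {
                "file": rec.file_path.name if rec else "",
                "site": rec.site_id if rec else "",
                "habitat": rec.habitat if rec else "",
                "session": rec.session if rec else "",
                "start_s": d.start_s,
                "end_s": d.end_s,
                "label": d.label,
                "max_prob": d.max_prob,
                "review_status": d.review_status,
                "review_label": d.review_label or "",
            }
        )
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def events_to_frame(events: Sequence[VocalEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rec = e.recording
        rows.append(
            {
                "file": rec.file_path.name if rec else "",
                "site": e.site_id or "",
                "habitat": e.habitat or "",
                "session": e.session or "",
                "species": e.species,
                "start_s": e.start_s,
                "end_s": e.end_s,
                "n_windows": e.n_windows,
                "timestamp": e.timestamp,
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def classify_recording(
    recording: SurveyRecording,
    waveform: np.ndarray,
    submodels,
    spec_config,
    window_s: float = 2.0,
    hop_s: float = 0.25,
    batch_size: int = 256,
) -> ProbabilitySeries:
    """Window a preprocessed recording and run the ensemble over it."""
    from tinamou.classifier import ensemble_predict
    from tinamou.ingest import window_stream
    from tinamou.spectrogram import window_to_image

    windows = window_stream(waveform, recording.sample_rate, window_s, hop_s, source=recording)
    if not windows:
        return ProbabilitySeries(recording, np.empty(0), np.empty((0, len(submodels[0].class_labels))),
                                 submodels[0].class_labels, window_s)
    images = np.stack([window_to_image(w, spec_config) for w in windows]).astype(np.float32)
    probs = ensemble_predict(submodels, images, batch_size)
    starts = np.array([w.start_s for w in windows])
    return ProbabilitySeries(recording, starts, probs, submodels[0].class_labels, window_s)
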