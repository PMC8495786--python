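"""Survey-audio ingest and preprocessing.

Reads ARU survey WAV files and applies the preprocessing the pipeline
mandates, in this order:

1. mute the recorder wake-up spike (first 5 s of the first file of each
   recording session) — before gain normalization, so the spike cannot
   dominate the peak estimate;
2. peak-normalize to -2 dBFS maximum gain;
3. split into overlapping 2-s analysis windows advanced by 0.25 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

log = logging.getLogger(__name__)

SURVEY_SAMPLE_RATE = 16_000
DEFAULT_TARGET_DB = -2.0
DEFAULT_MUTE_S = 5.0
DEFAULT_WINDOW_S = 2.0
DEFAULT_HOP_S = 0.25


@dataclass
class SurveyRecording:
    """One survey WAV file plus its site/session metadata."""

    file_path: Path
    site_id: str
    habitat: str
    deployment_id: str
    session: str  # "AM" | "PM"
    session_initial: bool
    date: str
    sample_rate: int = SURVEY_SAMPLE_RATE
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        self.file_path = Path(self.file_path)
        if self.duration_s < 0:
            raise ValueError("duration_s must be positive")

    def to_row(self) -> dict:
        return {
            "file": self.file_path.name,
            "site": self.site_id,
            "habitat": self.habitat,
            "deployment": self.deployment_id,
            "session": self.session,
            "session_initial": self.session_initial,
            "date": self.date,
            "sample_rate": self.sample_rate,
            "duration_s": self.duration_s,
        }


@dataclass
class AudioWindow:
    """Fixed-length analysis window cut from a recording."""

    source: SurveyRecording | None
    start_s: float
    duration_s: float
    samples: np.ndarray


def read_wav(path: Path | str, expect_rate: int | None = SURVEY_SAMPLE_RATE, resample: bool = False) -> tuple[np.ndarray, int]:
    """Read a PCM WAV as float in [-1, 1].

    Non-16-kHz survey audio is rejected unless ``resample=True``, in which
    case it is polyphase-resampled to ``expect_rate``.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    if expect_rate is not None and rate != expect_rate:
        if not resample:
            raise ValueError(
                f"{path}: sample rate {rate} Hz != expected {expect_rate} Hz "
                "(pass resample=True to convert)"
            )
        from scipy.signal import resample_poly
        from math import gcd

        g = gcd(rate, expect_rate)
        data = resample_poly(data, expect_rate // g, rate // g)
        rate = expect_rate
    return data, rate


def load_recording_metadata(csv_path: Path | str, audio_dir: Path | str | None = None) -> list[SurveyRecording]:
    """Load recording metadata CSV (columns: file, site, habitat,
    deployment, session, session_initial, date [, sample_rate, duration_s])."""
    df = pd.read_csv(csv_path)
    base = Path(audio_dir) if audio_dir is not None else Path(csv_path).parent
    recs = []
    for _, row in df.iterrows():
        recs.append(
            SurveyRecording(
                file_path=base / str(row["file"]),
                site_id=str(row["site"]),
                habitat=str(row["habitat"]),
                deployment_id=str(row["deployment"]),
                session=str(row["session"]),
                session_initial=bool(row["session_initial"]),
                date=str(row["date"]),
                sample_rate=int(row.get("sample_rate", SURVEY_SAMPLE_RATE)),
                duration_s=float(row.get("duration_s", 0.0)),
            )
        )
    return recs


def normalize_gain(waveform: np.ndarray, target_db: float = DEFAULT_TARGET_DB) -> np.ndarray:
    """Peak-normalize so the maximum absolute amplitude is ``target_db``
    dBFS (pure scaling; -2 dBFS → peak 0.7943).

    Raises
    ------
    ValueError
        On an all-zero waveform (no finite scale factor exists).
    """
    peak = float(np.max(np.abs(waveform)))
    if peak == 0.0:
        raise ValueError("cannot normalize an all-zero waveform")
    return waveform * (10.0 ** (target_db / 20.0) / peak)


def mute_wakeup_spike(
    waveform: np.ndarray,
    recording: SurveyRecording,
    mute_s: float = DEFAULT_MUTE_S,
    sample_rate: int | None = None,
) -> np.ndarray:
    """Zero the first ``mute_s`` seconds of a session-initial file.

    The recorder firmware writes a high-amplitude spike when waking from
    standby; muting must precede gain normalization.  Non-initial files
    pass through unchanged.  Files shorter than the mute length are fully
    zeroed with a warning rather than rejected.
    """
    if not recording.session_initial:
        return waveform
    rate = sample_rate or recording.sample_rate
    n_mute = int(round(mute_s * rate))
    out = waveform.copy()
    if n_mute >= len(out):
        log.warning(
            "%s: file (%.2f s) shorter than mute window (%.2f s); fully zeroed",
            recording.file_path.name, len(out) / rate, mute_s,
        )
        out[:] = 0.0
    else:
        out[:n_mute] = 0.0
    return out


def window_stream(
    waveform: np.ndarray,
    sample_rate: int = SURVEY_SAMPLE_RATE,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
    source: SurveyRecording | None = None,
) -> list[AudioWindow]:
    """Cut the waveform into full-length overlapping analysis windows.

    Yields ``floor((duration - window)/hop) + 1`` windows; trailing audio
    shorter than one window is dropped (the classifier needs fixed-length
    inputs).  A waveform shorter than one window yields an empty list with
    a warning.
    """
    n_win = int(round(window_s * sample_rate))
    n_hop = int(round(hop_s * sample_rate))
    if len(waveform) < n_win:
        log.warning("waveform (%d samples) shorter than one window (%d); no windows", len(waveform), n_win)
        return []
    count = (len(waveform) - n_win) // n_hop + 1
    return [
        AudioWindow(
            source=source,
            start_s=i * n_hop / sample_rate,
            duration_s=window_s,
            samples=waveform[i * n_hop : i * n_hop + n_win],
        )
        for i in range(count)
    ]


def expected_window_count(duration_s: float, window_s: float = DEFAULT_WINDOW_S, hop_s: float = DEFAULT_HOP_S) -> int:
    """Closed-form window count for a recording of ``duration_s`` seconds."""
    if duration_s < window_s:
        return 0
    return int(np.floor((duration_s - window_s) / hop_s + 1e-9)) + 1


def preprocess(
    waveform: np.ndarray,
    recording: SurveyRecording,
    target_db: float = DEFAULT_TARGET_DB,
    mute_s: float = DEFAULT_MUTE_S,
) -> np.ndarray:
    """Full preprocessing chain: mute wake spike, then normalize gain."""
    muted = mute_wakeup_spike(waveform, recording, mute_s)
    return normalize_gain(muted, target_db)
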