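"""Labelled clip datasets for classifier training.

A :class:`ClipDataset` holds fixed-length audio clips, each tagged with a
class label, a provenance flag (``external`` reference-library audio vs
``survey_verified`` windows confirmed during review), and a train/validation
split tag.  Train and validation never share a clip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class Clip:
    waveform: np.ndarray
    label: str
    origin: str = "external"  # "external" | "survey_verified"
    split: str = "train"  # "train" | "validation"

    def __post_init__(self) -> None:
        if self.origin not in ("external", "survey_verified"):
            raise ValueError(f"unknown origin {self.origin!r}")


class ClipDataset:
    """Container of labelled clips with per-class bookkeeping."""

    def __init__(self, clips: Iterable[Clip]):
        self.clips: list[Clip] = list(clips)

    def __len__(self) -> int:
        return len(self.clips)

    @property
    def labels(self) -> list[str]:
        """Class labels present, sorted."""
        return sorted({c.label for c in self.clips})

    def counts(self, split: str | None = None) -> dict[str, int]:
        """Per-class clip counts, optionally restricted to one split."""
        out: dict[str, int] = {}
        for c in self.clips:
            if split is None or c.split == split:
                out[c.label] = out.get(c.label, 0) + 1
        return out

    def subset(self, split: str) -> "ClipDataset":
        return ClipDataset([c for c in self.clips if c.split == split])

    def by_class(self, split: str | None = None) -> dict[str, list[Clip]]:
        out: dict[str, list[Clip]] = {}
        for c in self.clips:
            if split is None or c.split == split:
                out.setdefault(c.label, []).append(c)
        return out

    def split_train_validation(self, val_fraction: float = 0.2, seed: int = 0) -> None:
        """Assign split tags per class, stratified, without overlap."""
        rng = np.random.default_rng(seed)
        for label, clips in self.by_class().items():
            idx = rng.permutation(len(clips))
            n_val = max(1, int(round(val_fraction * len(clips)))) if len(clips) > 1 else 0
            for i, j in enumerate(idx):
                clips[j].split = "validation" if i < n_val else "train"

    def manifest(self) -> pd.DataFrame:
        """Per-class counts with origin breakdown (one row per class)."""
        rows = []
        for label in self.labels:
            cs = [c for c in self.clips if c.label == label]
            rows.append(
                {
                    "class": label,
                    "n_train": sum(c.split == "train" for c in cs),
                    "n_validation": sum(c.split == "validation" for c in cs),
                    "n_external": sum(c.origin == "external" for c in cs),
                    "n_survey_verified": sum(c.origin == "survey_verified" for c in cs),
                }
            )
        return pd.DataFrame(rows)
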