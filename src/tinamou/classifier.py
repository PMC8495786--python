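"""CNN classifier: architecture, augmentation, training, ensemble.

The detector is a pair of identically structured CNN submodels trained on
band-limited log-Mel spectrogram images — one with additive Gaussian-noise
augmentation ("noise"), one without ("no_noise") — whose class
probabilities are averaged into the prediction ensemble.

Architecture (input 256x256x1): five convolution blocks
(32x7x7 stride 2, 64x5x5, 128x3x3, 256x3x3, 512x3x3), each conv bias-free
with L2 kernel + activity regularization and batch normalization
(momentum 0.01) before ReLU, 2x2 max pooling after the first four blocks,
then flatten -> dense(256, ReLU) -> dropout(0.5) -> dense(n_classes,
softmax).  A ``width_scale`` divisor shrinks every conv filter count
(the deployed models used width_scale 2, i.e. half-width layers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from tinamou import nn
from tinamou.dataset import Clip, ClipDataset
from tinamou.spectrogram import SpectrogramConfig, window_to_image

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelArchitectureSpec:
    """Structural description of the CNN."""

    input_px: int = 256
    conv_blocks: tuple[tuple[int, int, int], ...] = (
        (32, 7, 2), (64, 5, 1), (128, 3, 1), (256, 3, 1), (512, 3, 1),
    )  # (filters, kernel, stride)
    pool_after_blocks: int = 4  # 2x2 max-pool after blocks 1..4
    dense_units: int = 256
    dropout: float = 0.5
    output_units: int = 12
    l2: float = 1e-6
    batchnorm_momentum: float = 0.01
    width_scale: int = 1  # divisor on conv filter counts

    def __post_init__(self) -> None:
        if self.width_scale < 1:
            raise ValueError("width_scale must be >= 1")
        if self.output_units < 2:
            raise ValueError("output_units must be >= 2")
        for filters, kernel, stride in self.conv_blocks:
            if min(filters, kernel, stride) < 1:
                raise ValueError(f"invalid conv block ({filters},{kernel},{stride})")
        if any(f // self.width_scale < 1 for f, _, _ in self.conv_blocks):
            raise ValueError("width_scale reduces a conv block below one filter")

    @property
    def scaled_filters(self) -> tuple[int, ...]:
        return tuple(f // self.width_scale for f, _, _ in self.conv_blocks)


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyperparameters (defaults are the deployed values)."""

    batch_size: int = 64
    epochs: int = 20
    learning_rate: float = 0.0075
    l2: float = 1e-6
    dropout: float = 0.5
    network_size_scale: int = 2
    balanced_batches: bool = False
    seed: int = 0


@dataclass(frozen=True)
class AugmentationConfig:
    """Per-spectrogram stochastic augmentation.

    Range-valued fields are drawn uniformly per image.  The dB offset is a
    pre-normalization intensity offset: on the [0,1]-normalized log image
    an offset of ``o`` dB subtracts ``|o|/dynamic_range_db`` with the
    result clipped at the floor, emulating a fainter call.  Gaussian noise
    intensity is likewise in dB — the standard deviation of per-pixel
    jitter on the log-spectrogram, i.e. ``intensity/dynamic_range_db`` in
    normalized-image units — keeping its units consistent with the other
    intensity-valued augmentation parameters.
    """

    gaussian_noise_intensity: float = 0.0  # 0.8 for the "noise" submodel
    gaussian_blur: float = 0.0
    horizontal_shift_px: tuple[int, int] = (0, 20)
    vertical_shift_px: tuple[int, int] = (0, 2)
    db_offset_range: tuple[float, float] = (0.0, -40.0)
    dynamic_range_db: float = 80.0

    @classmethod
    def for_submodel(cls, kind: str, input_px: int = 256) -> "AugmentationConfig":
        """Deployed augmentation settings: ``noise`` or ``no_noise``.

        The shift ranges are calibrated in pixels of the deployed 256-px
        image; for other image sizes they scale proportionally so the
        augmentation keeps the same meaning in seconds and Mel bins.
        """
        if kind not in ("noise", "no_noise"):
            raise ValueError(f"unknown submodel kind {kind!r}")
        scale = input_px / 256
        return cls(
            gaussian_noise_intensity=0.8 if kind == "noise" else 0.0,
            horizontal_shift_px=(0, round(20 * scale)),
            vertical_shift_px=(0, round(2 * scale)),
        )

    @classmethod
    def disabled(cls) -> "AugmentationConfig":
        return cls(horizontal_shift_px=(0, 0), vertical_shift_px=(0, 0), db_offset_range=(0.0, 0.0))


def trace_shapes(spec: ModelArchitectureSpec) -> list[tuple[str, tuple[int, ...]]]:
    """Spatial-shape trace through the conv stack ('same' padding)."""
    h = spec.input_px
    trace: list[tuple[str, tuple[int, ...]]] = [("input", (h, h, 1))]
    for i, ((filters, kernel, stride), f) in enumerate(zip(spec.conv_blocks, spec.scaled_filters)):
        h = -(-h // stride)  # ceil division: 'same' padding
        trace.append((f"conv{i + 1}", (h, h, f)))
        if i < spec.pool_after_blocks:
            h = h // 2
            trace.append((f"pool{i + 1}", (h, h, f)))
    trace.append(("flatten", (h * h * spec.scaled_filters[-1],)))
    trace.append(("dense", (spec.dense_units,)))
    trace.append(("output", (spec.output_units,)))
    return trace


def build_architecture(spec: ModelArchitectureSpec, seed: int = 0) -> nn.Network:
    """Instantiate the CNN as a :class:`tinamou.nn.Network`."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_ch = 1
    h = spec.input_px
    for i, ((_, kernel, stride), filters) in enumerate(zip(spec.conv_blocks, spec.scaled_filters)):
        layers.append(nn.Conv2D(in_ch, filters, kernel, stride, padding="same", l2=spec.l2, rng=rng))
        layers.append(nn.BatchNorm(filters, momentum=spec.batchnorm_momentum))
        layers.append(nn.ReLU())
        h = -(-h // stride)
        if i < spec.pool_after_blocks:
            layers.append(nn.MaxPool2())
            h = h // 2
        in_ch = filters
        if h < 1:
            raise ValueError(f"input_px {spec.input_px} too small for conv stack (collapses at block {i + 1})")
    layers.append(nn.Flatten())
    layers.append(nn.Dense(h * h * in_ch, spec.dense_units, rng=rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dropout(spec.dropout))
    layers.append(nn.Dense(spec.dense_units, spec.output_units, rng=rng))
    net = nn.Network(layers)
    log.info("built CNN width_scale=%d: %d parameters", spec.width_scale, net.n_params)
    return net


def augment_spectrogram(image: np.ndarray, config: AugmentationConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Apply the augmentation chain to one normalized [0,1] image.

    Order: dB offset, horizontal (time) shift with zero fill, vertical
    (frequency) shift, additive Gaussian noise; output clipped to [0,1].
    An all-zero configuration is the identity.
    """
    out = image
    lo, hi = sorted(config.db_offset_range)
    if hi != lo or lo != 0.0:
        offset_db = rng.uniform(lo, hi)
        out = np.clip(out + offset_db / config.dynamic_range_db, 0.0, None)
    hlo, hhi = config.horizontal_shift_px
    if hhi > 0:
        shift = int(rng.integers(hlo, hhi + 1)) * (1 if rng.random() < 0.5 else -1)
        out = _shift2d(out, cols=shift)
    vlo, vhi = config.vertical_shift_px
    if vhi > 0:
        shift = int(rng.integers(vlo, vhi + 1)) * (1 if rng.random() < 0.5 else -1)
        out = _shift2d(out, rows=shift)
    if config.gaussian_noise_intensity > 0:
        std = config.gaussian_noise_intensity / config.dynamic_range_db
        out = out + rng.normal(0.0, std, size=out.shape)
    if out is image:
        return image.copy()
    return np.clip(out, 0.0, 1.0)


def _shift2d(img: np.ndarray, rows: int = 0, cols: int = 0) -> np.ndarray:
    """Translate with zero fill (positive = toward higher index)."""
    out = np.zeros_like(img)
    h, w = img.shape
    rs, cs = rows, cols
    src_r = slice(max(0, -rs), min(h, h - rs))
    dst_r = slice(max(0, rs), min(h, h + rs))
    src_c = slice(max(0, -cs), min(w, w - cs))
    dst_c = slice(max(0, cs), min(w, w + cs))
    out[dst_r, dst_c] = img[src_r, src_c]
    return out


def make_balanced_batches(dataset: ClipDataset, batch_size: int,
                          rng: np.random.Generator, split: str = "train") -> Iterator[list[Clip]]:
    """One epoch of class-balanced batches.

    Classes are filled round-robin so per-batch class counts differ by at
    most one; each class cycles through a private shuffled order and
    reshuffles when exhausted (rare classes are effectively oversampled
    with replacement).  One epoch is ``ceil(largest class size * n_classes
    / batch_size)`` batches.
    """
    pools = dataset.by_class(split)
    for label in dataset.labels:
        if not pools.get(label):
            raise ValueError(f"class {label!r} has no clips in split {split!r}")
    labels = sorted(pools)
    if not labels:
        raise ValueError("empty dataset")
    cursors = {lb: [] for lb in labels}

    def draw(label: str) -> Clip:
        if not cursors[label]:
            cursors[label] = list(rng.permutation(len(pools[label])))
        return pools[label][cursors[label].pop()]

    largest = max(len(c) for c in pools.values())
    n_batches = -(-largest * len(labels) // batch_size)
    order = 0
    for _ in range(n_batches):
        batch = []
        for i in range(batch_size):
            batch.append(draw(labels[(order + i) % len(labels)]))
        order = (order + batch_size) % len(labels)
        yield batch


def _plain_batches(dataset: ClipDataset, batch_size: int,
                   rng: np.random.Generator, split: str = "train") -> Iterator[list[Clip]]:
    clips = [c for c in dataset.clips if c.split == split]
    idx = rng.permutation(len(clips))
    for i in range(0, len(clips), batch_size):
        yield [clips[j] for j in idx[i : i + batch_size]]


@dataclass
class TrainedSubmodel:
    """A trained CNN plus the class ordering it predicts over."""

    network: nn.Network
    class_labels: tuple[str, ...]
    arch: ModelArchitectureSpec
    history: dict = field(default_factory=dict)

    def predict_proba(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = images[:, None, :, :] if images.ndim == 3 else images
        return self.network.predict_proba(x, batch_size)


def clips_to_images(clips: Sequence[Clip], spec_config: SpectrogramConfig) -> np.ndarray:
    """Spectrogram-image pipeline over a clip list -> (n, px, px) array.

    Clips are peak-normalized to -2 dBFS first — the same gain convention
    applied to survey audio — so the absolute log floor means the same
    thing for training and survey spectrograms.
    """
    from tinamou.ingest import normalize_gain

    def prep(w: np.ndarray) -> np.ndarray:
        w = w.astype(np.float64)
        # silent clips (e.g. cut from a muted file head) have no gain to set
        return normalize_gain(w) if np.any(w) else w

    return np.stack([
        window_to_image(prep(c.waveform), spec_config) for c in clips
    ]).astype(np.float32)


def train_submodel(
    dataset: ClipDataset,
    arch: ModelArchitectureSpec,
    train_cfg: TrainingConfig,
    aug_cfg: AugmentationConfig,
    spec_config: SpectrogramConfig,
    images: Mapping[int, np.ndarray] | None = None,
) -> TrainedSubmodel:
    """Train one CNN submodel; deterministic given ``train_cfg.seed``.

    The dataset must carry train/validation split tags with no overlap.
    Per epoch the history records the mean training loss and validation
    macro-F1.  ``images`` may supply precomputed spectrogram images keyed
    by ``id(clip)`` to avoid recomputation across submodels.

    Raises
    ------
    RuntimeError
        If the loss becomes non-finite (divergence).
    """
    from tinamou.evaluation import confusion_matrix, macro_metrics

    labels = tuple(sorted(dataset.labels))
    label_idx = {lb: i for i, lb in enumerate(labels)}
    arch = replace(arch, output_units=len(labels), dropout=train_cfg.dropout,
                   l2=train_cfg.l2, width_scale=train_cfg.network_size_scale)
    rng = np.random.default_rng(train_cfg.seed)
    net = build_architecture(arch, seed=int(rng.integers(2**31 - 1)))
    opt = nn.Adam(net, lr=train_cfg.learning_rate)

    if images is None:
        cache = {id(c): img for c, img in
                 zip(dataset.clips, clips_to_images(dataset.clips, spec_config))}
    else:
        cache = images
    val_clips = [c for c in dataset.clips if c.split == "validation"]
    x_val = np.stack([cache[id(c)] for c in val_clips]) if val_clips else None
    y_val = np.array([label_idx[c.label] for c in val_clips]) if val_clips else None

    train_clips = [c for c in dataset.clips if c.split == "train"]
    history: dict = {"loss": [], "val_macro_f1": []}
    sub = TrainedSubmodel(net, labels, arch, history)
    for epoch in range(train_cfg.epochs):
        batches = (make_balanced_batches(dataset, train_cfg.batch_size, rng)
                   if train_cfg.balanced_batches
                   else _plain_batches(dataset, train_cfg.batch_size, rng))
        losses = []
        for batch in batches:
            x = np.stack([augment_spectrogram(cache[id(c)], aug_cfg, rng) for c in batch])
            y = np.zeros((len(batch), len(labels)))
            y[np.arange(len(batch)), [label_idx[c.label] for c in batch]] = 1.0
            loss = net.loss_and_grads(x[:, None, :, :], y, rng=rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss!r} "
                    f"(lr={train_cfg.learning_rate}, batch={train_cfg.batch_size})"
                )
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)) if losses else np.nan)
        if train_clips:
            # low batch-norm momentum leaves running stats tracking the last
            # (augmented) batch; recalibrate on clean training images so
            # validation and deployment inference are stable
            x_train = np.stack([cache[id(c)] for c in train_clips])
            nn.recalibrate_batchnorm(net, x_train[:, None, :, :])
        if x_val is not None:
            pred = np.argmax(sub.predict_proba(x_val), axis=1)
            cm = confusion_matrix(y_val, pred, classes=np.arange(len(labels)))
            history["val_macro_f1"].append(macro_metrics(cm)["macro_f1"])
    return sub


def ensemble_predict(submodels: Sequence[TrainedSubmodel], images: np.ndarray,
                     batch_size: int = 256) -> np.ndarray:
    """Element-wise arithmetic mean of the submodels' class probabilities."""
    if not submodels:
        raise ValueError("need at least one submodel")
    orders = {s.class_labels for s in submodels}
    if len(orders) > 1:
        raise ValueError(f"submodels disagree on class ordering: {orders}")
    probs = [s.predict_proba(images, batch_size) for s in submodels]
    return np.mean(probs, axis=0)
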