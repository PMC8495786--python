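"""Band-limited log-Mel spectrogram images.

Each 2-s analysis window becomes a square single-channel image: magnitude
STFT (Hann window, 1,024-sample frames, 64-sample stride at 16 kHz), a
triangular Mel filter bank of 64 filters built directly on the 900-2,900 Hz
band, log compression, then bilinear rescaling to the native 512x512 px
image (downsampled to 256x256 before the CNN).

Image orientation: rows are Mel frequency (low frequency at row 0),
columns are time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal
from skimage.transform import resize as _sk_resize

from tinamou.ingest import AudioWindow

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpectrogramConfig:
    """STFT / Mel settings (defaults match the survey pipeline)."""

    image_px: int = 512
    channels: int = 1
    fft_window: int = 1024
    stride: int = 64
    band_hz: tuple[float, float] = (900.0, 2900.0)
    sample_rate: int = 16_000
    mel_bins: int = 64
    downsample_px: int = 256
    log_floor: float = 1e-6  # epsilon added to power before log

    def __post_init__(self) -> None:
        for name in ("image_px", "fft_window", "stride", "sample_rate", "mel_bins", "downsample_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.band_hz
        if not (0 <= lo < hi <= self.sample_rate / 2):
            raise ValueError(f"band {self.band_hz} outside [0, Nyquist] or inverted")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")


@dataclass
class MelSpectrogram:
    """Square log-Mel image; rows = Mel frequency, cols = time."""

    pixels: np.ndarray
    native_px: int
    config: SpectrogramConfig | None = None
    source: AudioWindow | None = None


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    """HTK Mel scale: 2595 log10(1 + f/700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filter_bank(config: SpectrogramConfig) -> np.ndarray:
    """Triangular Mel filters spanning exactly ``band_hz``.

    Returns a (mel_bins, n_fft_bins) matrix.  Filter centres are equally
    spaced on the Mel scale between the band edges; adjacent filters meet
    at each other's centres, so the band is covered without gaps.
    """
    n_fft = config.fft_window
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / config.sample_rate)
    edges_mel = np.linspace(hz_to_mel(config.band_hz[0]), hz_to_mel(config.band_hz[1]), config.mel_bins + 2)
    edges_hz = np.asarray(mel_to_hz(edges_mel))
    bank = np.zeros((config.mel_bins, len(fft_freqs)))
    for i in range(config.mel_bins):
        lo, mid, hi = edges_hz[i : i + 3]
        up = (fft_freqs - lo) / (mid - lo)
        down = (hi - fft_freqs) / (hi - mid)
        bank[i] = np.clip(np.minimum(up, down), 0.0, None)
    return bank


def mel_bin_for_frequency(config: SpectrogramConfig, freq_hz: float) -> int:
    """Index of the Mel filter whose response peaks nearest ``freq_hz``."""
    edges_mel = np.linspace(hz_to_mel(config.band_hz[0]), hz_to_mel(config.band_hz[1]), config.mel_bins + 2)
    centres = np.asarray(mel_to_hz(edges_mel[1:-1]))
    return int(np.argmin(np.abs(centres - freq_hz)))


def stft_log_mel(window: AudioWindow | np.ndarray, config: SpectrogramConfig) -> MelSpectrogram:
    """Compute the band-limited log-Mel image of one analysis window.

    Magnitude-squared STFT -> Mel filter bank on ``band_hz`` ->
    ``log(power + log_floor)`` -> bilinear rescale to
    ``image_px x image_px``.
    """
    samples = window.samples if isinstance(window, AudioWindow) else np.asarray(window, dtype=float)
    if isinstance(window, AudioWindow) and window.source is not None:
        if window.source.sample_rate != config.sample_rate:
            raise ValueError(
                f"window sample rate {window.source.sample_rate} != config {config.sample_rate}"
            )
    _, _, spec = signal.spectrogram(
        samples,
        fs=config.sample_rate,
        window="hann",
        nperseg=config.fft_window,
        noverlap=config.fft_window - config.stride,
        detrend=False,
        mode="magnitude",
    )
    power = spec.astype(float) ** 2  # (n_fft_bins, n_frames)
    mel_power = mel_filter_bank(config) @ power  # (mel_bins, n_frames)
    logmel = np.log(mel_power + config.log_floor)
    pixels = _bilinear_to_square(logmel, config.image_px)
    return MelSpectrogram(pixels=pixels, native_px=config.image_px, config=config,
                          source=window if isinstance(window, AudioWindow) else None)


def _bilinear_to_square(grid: np.ndarray, out_px: int) -> np.ndarray:
    """Bilinear rescale of a (freq x time) grid to out_px x out_px."""
    return _sk_resize(grid, (out_px, out_px), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def resize_image(spec: MelSpectrogram, out_px: int = 256) -> MelSpectrogram:
    """Bilinear resize of a square spectrogram image (512 -> 256 for the CNN).

    Upsampling is allowed but warned about, since it adds no information.
    """
    h, w = spec.pixels.shape
    if h != w:
        raise ValueError(f"resize_image expects a square image, got {spec.pixels.shape}")
    if out_px > h:
        log.warning("upsampling spectrogram %d px -> %d px", h, out_px)
    pixels = _bilinear_to_square(spec.pixels, out_px)
    return MelSpectrogram(pixels=pixels, native_px=spec.native_px, config=spec.config, source=spec.source)


def normalize_image(pixels: np.ndarray) -> np.ndarray:
    """Per-image min-max normalization to [0, 1] (constant image -> zeros)."""
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi == lo:
        return np.zeros_like(pixels)
    return (pixels - lo) / (hi - lo)


def window_to_image(window: AudioWindow | np.ndarray, config: SpectrogramConfig) -> np.ndarray:
    """Full image pipeline for the classifier: STFT log-Mel at native
    resolution, downsample, min-max normalize."""
    spec = stft_log_mel(window, config)
    if config.downsample_px != config.image_px:
        spec = resize_image(spec, config.downsample_px)
    return normalize_image(spec.pixels)
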