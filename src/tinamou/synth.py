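"""Synthetic soundscape generation.

Produces labelled survey audio and training clips with the statistical
structure the detection pipeline assumes: tonal calls with fundamentals in
the 900-2,900 Hz band mixed over a pink (1/f) ambient-noise bed, organised
into the AM (5:00-7:30) / PM (16:00-18:30) session schedule of the field
survey, with per-site per-species event rates drawn as Poisson counts.

Everything is seeded: identical seeds yield byte-identical audio and truth
tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from tinamou.dataset import Clip, ClipDataset
from tinamou.ingest import SurveyRecording
from tinamou.species import JUNK_LABEL, SURVEY_BAND_HZ, SpeciesCallTemplate

log = logging.getLogger(__name__)

#: Session start clock times (local, naive) of the recorder schedule.
SESSION_STARTS = {"AM": "05:00", "PM": "16:00"}

#: Ambient pink-noise bed level, dBFS RMS.  Chosen as a realistic rainforest
#: ambient level leaving ~25 dB of headroom for calls.
DEFAULT_NOISE_DBFS = -28.0

#: Per-event in-band signal-to-noise range (dB) for scripted calls; spans
#: faint-but-audible to close-range vocalisations.
DEFAULT_SNR_RANGE_DB = (5.0, 15.0)


@dataclass
class SoundscapeScript:
    """Plan for one rendered session: events over a noise bed."""

    site_id: str
    habitat: str  # "terra_firme" | "floodplain"
    session: str  # "AM" | "PM"
    duration_s: float
    events: list[tuple[str, float, float]] = field(default_factory=list)  # (species, onset_s, snr_db)
    noise_dbfs: float = DEFAULT_NOISE_DBFS
    noise_slope: float = 1.0  # spectral power exponent: S(f) ~ 1/f**slope
    seed: int = 0
    session_initial: bool = True

    def __post_init__(self) -> None:
        if self.habitat not in ("terra_firme", "floodplain"):
            raise ValueError(f"unknown habitat {self.habitat!r}")
        if self.session not in SESSION_STARTS:
            raise ValueError(f"unknown session {self.session!r}")
        for sp, onset, _ in self.events:
            if not 0 <= onset < self.duration_s:
                raise ValueError(f"event onset {onset} outside [0, {self.duration_s})")
        self.events.sort(key=lambda e: (e[1], e[0]))


def make_call_waveform(template: SpeciesCallTemplate, sample_rate: int) -> np.ndarray:
    """Render one call phrase as a peak-normalised waveform.

    The fundamental follows the template's piecewise-linear contour; the
    harmonic stack is summed with the template's relative amplitudes under
    a raised-cosine attack/decay envelope.

    Raises
    ------
    ValueError
        If the harmonic stack reaches above the Nyquist frequency.
    """
    if template.max_frequency > sample_rate / 2:
        raise ValueError(
            f"template {template.species_id!r} reaches {template.max_frequency:.0f} Hz, "
            f"above Nyquist ({sample_rate / 2:.0f} Hz) at {sample_rate} Hz sampling"
        )
    n = int(round(template.phrase_duration * sample_rate))
    t_frac = np.arange(n) / max(n - 1, 1)
    f0 = template.f0_at(t_frac)
    phase = 2.0 * np.pi * np.cumsum(f0) / sample_rate
    env = _envelope(t_frac, *template.amplitude_envelope)
    wave = np.zeros(n)
    for k, amp in enumerate(template.harmonics, start=1):
        wave += amp * np.sin(k * phase)
    wave *= env
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave /= peak
    return wave


def _envelope(t_frac: np.ndarray, attack: float, decay: float) -> np.ndarray:
    """Raised-cosine attack/decay envelope on fractional phrase time."""
    env = np.ones_like(t_frac)
    if attack > 0:
        m = t_frac < attack
        env[m] = 0.5 - 0.5 * np.cos(np.pi * t_frac[m] / attack)
    if decay > 0:
        m = t_frac > 1.0 - decay
        env[m] = np.minimum(env[m], 0.5 - 0.5 * np.cos(np.pi * (1.0 - t_frac[m]) / decay))
    return env


def pink_noise(n: int, rng: np.random.Generator, slope: float = 1.0) -> np.ndarray:
    """Broadband noise with power spectral density ~ 1/f**slope, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-slope / 2.0)
    noise = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(noise**2))
    return noise / rms if rms > 0 else noise


def band_rms(waveform: np.ndarray, sample_rate: int, band: tuple[float, float] = SURVEY_BAND_HZ) -> float:
    """RMS of the waveform's spectral content inside ``band`` (Hz)."""
    spec = np.fft.rfft(waveform)
    f = np.fft.rfftfreq(len(waveform), d=1.0 / sample_rate)
    mask = (f >= band[0]) & (f <= band[1])
    # Parseval: band energy / N gives mean-square of the band-limited part
    return float(np.sqrt(np.sum(np.abs(spec[mask]) ** 2) / (len(waveform) * max(len(waveform), 1)) * 2))


def render_session(
    script: SoundscapeScript,
    templates: Mapping[str, SpeciesCallTemplate],
    sample_rate: int = 16_000,
    wake_spike: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a scripted session to audio plus its ground-truth table.

    Calls are mixed at their scripted in-band (900-2,900 Hz) SNR over the
    pink-noise bed.  Calls running past the file end are truncated in the
    audio, but the truth table stores the untruncated offset, mirroring how
    a recorder clips an ongoing call at file rollover.  When the script is
    flagged ``session_initial`` a recorder wake-up spike is written at t=0
    (the downstream ingest step is expected to mute it).

    Returns
    -------
    (waveform, truth)
        ``waveform`` in [-1, 1]; ``truth`` columns: species, onset_s,
        offset_s, snr_db.
    """
    for sp, _, _ in script.events:
        if sp not in templates:
            raise KeyError(f"no template for scripted species {sp!r}")
    rng = np.random.default_rng(script.seed)
    n = int(round(script.duration_s * sample_rate))
    noise = pink_noise(n, rng, script.noise_slope) * 10 ** (script.noise_dbfs / 20.0)
    noise_band = band_rms(noise, sample_rate)
    wave = noise.copy()
    rows = []
    for sp, onset, snr_db in script.events:
        call = make_call_waveform(templates[sp], sample_rate)
        call_band = band_rms(call, sample_rate)
        gain = noise_band * 10 ** (snr_db / 20.0) / call_band
        start = int(round(onset * sample_rate))
        seg = call[: max(0, n - start)] * gain
        wave[start : start + len(seg)] += seg
        rows.append(
            {
                "species": sp,
                "onset_s": onset,
                "offset_s": onset + templates[sp].phrase_duration,
                "snr_db": snr_db,
            }
        )
    if wake_spike and script.session_initial:
        # high-amplitude transient in the first 100 ms, as the recorder
        # firmware writes when waking from standby
        k = int(0.1 * sample_rate)
        spike_rng = np.random.default_rng(script.seed + 1)
        wave[:k] += 0.95 * spike_rng.choice([-1.0, 1.0], size=k) * np.linspace(1, 0, k)
    np.clip(wave, -1.0, 1.0, out=wave)
    truth = pd.DataFrame(rows, columns=["species", "onset_s", "offset_s", "snr_db"])
    return wave, truth


def write_wav(path: Path | str, waveform: np.ndarray, sample_rate: int = 16_000) -> None:
    """Write PCM 16-bit mono WAV."""
    pcm = np.clip(waveform, -1.0, 1.0)
    wavfile.write(str(path), sample_rate, (pcm * 32767.0).astype(np.int16))


def generate_survey(
    sites: Sequence[tuple[str, str]],
    per_species_rates: Mapping[str, float],
    n_days: int,
    seed: int,
    out_dir: Path | str,
    templates: Mapping[str, SpeciesCallTemplate],
    session_duration_s: float = 150.0,
    sample_rate: int = 16_000,
    snr_range_db: tuple[float, float] = DEFAULT_SNR_RANGE_DB,
    noise_dbfs: float = DEFAULT_NOISE_DBFS,
) -> tuple[list[SurveyRecording], pd.DataFrame]:
    """Generate a multi-site survey: WAV files plus a truth event database.

    Per recording, each species' event count is a Poisson draw at its
    programmed rate (events/hour) times the session duration; onsets are
    uniform and SNRs uniform in ``snr_range_db``.  File names encode
    site, date and session (``<site>_<date>_<session>.wav``).

    Returns the recording metadata list and the concatenated truth table
    (columns: file, site_id, habitat, session, date, species, onset_s,
    offset_s, snr_db).  Also writes ``recordings.csv`` and ``truth.csv``
    alongside the audio.
    """
    for sp, rate in per_species_rates.items():
        if rate < 0:
            raise ValueError(f"negative rate for {sp}")
        if sp not in templates:
            raise KeyError(f"no template for {sp!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    hours = session_duration_s / 3600.0
    recordings: list[SurveyRecording] = []
    truth_frames = []
    base = pd.Timestamp("2019-07-15")
    for day in range(n_days):
        date = (base + pd.Timedelta(days=day)).date().isoformat()
        for site_id, habitat in sites:
            for session in ("AM", "PM"):
                events = []
                for sp, rate in per_species_rates.items():
                    count = rng.poisson(rate * hours)
                    onsets = rng.uniform(0.0, session_duration_s, size=count)
                    snrs = rng.uniform(*snr_range_db, size=count)
                    events += [(sp, float(o), float(s)) for o, s in zip(onsets, snrs)]
                script = SoundscapeScript(
                    site_id=site_id,
                    habitat=habitat,
                    session=session,
                    duration_s=session_duration_s,
                    events=events,
                    noise_dbfs=noise_dbfs,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    session_initial=True,
                )
                wave, truth = render_session(script, templates, sample_rate)
                fname = f"{site_id}_{date}_{session}.wav"
                write_wav(out_dir / fname, wave, sample_rate)
                rec = SurveyRecording(
                    file_path=out_dir / fname,
                    site_id=site_id,
                    habitat=habitat,
                    deployment_id="synthetic",
                    session=session,
                    session_initial=True,
                    date=date,
                    sample_rate=sample_rate,
                    duration_s=session_duration_s,
                )
                recordings.append(rec)
                truth.insert(0, "file", fname)
                truth.insert(1, "site_id", site_id)
                truth.insert(2, "habitat", habitat)
                truth.insert(3, "session", session)
                truth.insert(4, "date", date)
                truth_frames.append(truth)
    truth_db = pd.concat(truth_frames, ignore_index=True)
    truth_db.to_csv(out_dir / "truth.csv", index=False)
    pd.DataFrame([r.to_row() for r in recordings]).to_csv(out_dir / "recordings.csv", index=False)
    return recordings, truth_db


def generate_training_clips(
    templates: Mapping[str, SpeciesCallTemplate],
    n_per_class: int,
    seed: int,
    noise_variants: int = 3,
    sample_rate: int = 16_000,
    clip_duration_s: float = 2.0,
    snr_range_db: tuple[float, float] = DEFAULT_SNR_RANGE_DB,
    noise_dbfs: float = DEFAULT_NOISE_DBFS,
    distractor_margin_hz: float = 150.0,
) -> ClipDataset:
    """Generate a labelled 2-s clip dataset (species classes + junk).

    Species clips are single calls over a pink-noise bed at a random SNR,
    with a small random onset jitter.  Junk clips cycle through
    ``noise_variants`` flavours: pure pink noise at varied levels, and
    tonal distractors drawn from the parts of the survey band at least
    ``distractor_margin_hz`` from every template fundamental (several
    Mel bins at analysis resolution), so the junk class is acoustically
    distinct from the species classes without being trivially silent.
    If no such frequency exists the margin is halved, with a warning,
    until the allowed set is nonempty.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    n = int(round(clip_duration_s * sample_rate))
    template_f0s = np.array(
        [hz for t in templates.values() for _, hz in t.f0_contour], dtype=float
    )
    allowed = _allowed_distractor_bands(template_f0s, distractor_margin_hz)
    clips: list[Clip] = []
    for sp, template in templates.items():
        call = make_call_waveform(template, sample_rate)
        for _ in range(n_per_class):
            noise = pink_noise(n, rng) * 10 ** (noise_dbfs / 20.0)
            snr = rng.uniform(*snr_range_db)
            gain = band_rms(noise, sample_rate) * 10 ** (snr / 20.0) / band_rms(call, sample_rate)
            jitter = int(rng.integers(0, max(1, n // 16)))
            wave = noise.copy()
            seg = (call * gain)[: n - jitter]
            wave[jitter : jitter + len(seg)] += seg
            clips.append(Clip(np.clip(wave, -1, 1).astype(np.float32), sp, origin="external"))
    # junk class
    for i in range(n_per_class):
        noise = pink_noise(n, rng) * 10 ** ((noise_dbfs + rng.uniform(-6, 6)) / 20.0)
        wave = noise
        if noise_variants > 1 and i % noise_variants != 0:
            f = _sample_from_bands(allowed, rng)
            tone = SpeciesCallTemplate(
                JUNK_LABEL, ((0.0, f), (1.0, f * rng.uniform(0.99, 1.01))),
                phrase_duration=clip_duration_s,
                harmonics=(1.0,),
            )
            snr = rng.uniform(*snr_range_db)
            distractor = make_call_waveform(tone, sample_rate)
            gain = band_rms(noise, sample_rate) * 10 ** (snr / 20.0) / band_rms(distractor, sample_rate)
            wave = noise + distractor * gain
        clips.append(Clip(np.clip(wave, -1, 1).astype(np.float32), JUNK_LABEL, origin="external"))
    return ClipDataset(clips)


def _allowed_distractor_bands(template_f0s: np.ndarray, margin_hz: float) -> list[tuple[float, float]]:
    """Sub-bands of the survey band at least ``margin_hz`` from every
    template fundamental; the margin halves (with a warning) until the
    allowed set is nonempty."""
    lo, hi = SURVEY_BAND_HZ
    while margin_hz >= 1.0:
        edges = sorted([lo] + [f for f in template_f0s for f in (f - margin_hz, f + margin_hz)] + [hi])
        bands = []
        for a, b in zip(edges, edges[1:]):
            mid = (a + b) / 2
            if a < b and lo <= a and b <= hi and np.min(np.abs(template_f0s - mid)) >= margin_hz:
                bands.append((a, b))
        if bands:
            return bands
        log.warning("no distractor band at margin %.0f Hz; halving", margin_hz)
        margin_hz /= 2
    return [(lo, hi)]


def _sample_from_bands(bands: list[tuple[float, float]], rng: np.random.Generator) -> float:
    widths = np.array([b - a for a, b in bands])
    i = rng.choice(len(bands), p=widths / widths.sum())
    return float(rng.uniform(*bands[i]))
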