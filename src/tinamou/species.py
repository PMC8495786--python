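"""Class labels and species call templates.

The survey distinguishes 12 classes: the 11 tinamou species recorded at
Los Amigos (genera *Tinamus* and *Crypturellus*) plus a ``junk`` class for
all other audio.  Tinamou vocalizations at this site are stereotyped tonal
whistles with fundamental frequencies in the 900-2,900 Hz band; the
:class:`SpeciesCallTemplate` captures the minimal structure the synthetic
soundscapes need — a piecewise-linear fundamental contour, a harmonic
stack, and an attack/decay amplitude envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

JUNK_LABEL = "junk"

#: The 11 tinamou species at the study site, in alphabetical order by
#: scientific name, followed by the junk class.
CLASS_LABELS: tuple[str, ...] = (
    "Crypturellus_atrocapillus",
    "Crypturellus_bartletti",
    "Crypturellus_cinereus",
    "Crypturellus_obsoletus",
    "Crypturellus_soui",
    "Crypturellus_strigulosus",
    "Crypturellus_undulatus",
    "Crypturellus_variegatus",
    JUNK_LABEL,
    "Tinamus_guttatus",
    "Tinamus_major",
    "Tinamus_tao",
)

#: Frequency band (Hz) containing tinamou fundamentals at this site.
SURVEY_BAND_HZ: tuple[float, float] = (900.0, 2900.0)


@dataclass(frozen=True)
class SpeciesCallTemplate:
    """Parametric description of one species' typical 2-s call phrase.

    Parameters
    ----------
    species_id
        Class label the template belongs to.
    f0_contour
        Piecewise-linear fundamental-frequency contour as ``(t_frac, hz)``
        breakpoints, with ``t_frac`` in [0, 1] spanning the phrase.  For
        species classes every frequency must lie in the 900-2,900 Hz
        survey band.
    phrase_duration
        Phrase length in seconds (the windowing unit of the pipeline).
    harmonics
        Relative linear amplitudes of the harmonic stack; element ``k``
        scales the (k+1)-th multiple of the fundamental.
    amplitude_envelope
        ``(attack_frac, decay_frac)`` — fractions of the phrase spent
        ramping up from and back down to silence (raised-cosine ramps).
    """

    species_id: str
    f0_contour: tuple[tuple[float, float], ...]
    phrase_duration: float = 2.0
    harmonics: tuple[float, ...] = (1.0, 0.35, 0.12)
    amplitude_envelope: tuple[float, float] = (0.15, 0.25)

    def __post_init__(self) -> None:
        if self.phrase_duration <= 0:
            raise ValueError("phrase_duration must be positive")
        if not self.f0_contour:
            raise ValueError("f0_contour needs at least one breakpoint")
        fr = [hz for _, hz in self.f0_contour]
        if self.species_id != JUNK_LABEL:
            lo, hi = SURVEY_BAND_HZ
            if min(fr) < lo or max(fr) > hi:
                raise ValueError(
                    f"{self.species_id}: f0 contour {min(fr):.0f}-{max(fr):.0f} Hz "
                    f"outside the {lo:.0f}-{hi:.0f} Hz survey band"
                )

    @property
    def max_frequency(self) -> float:
        """Highest frequency the harmonic stack reaches."""
        return max(hz for _, hz in self.f0_contour) * len(self.harmonics)

    def f0_at(self, t_frac: np.ndarray) -> np.ndarray:
        """Fundamental frequency (Hz) at fractional phrase times."""
        ts = np.array([t for t, _ in self.f0_contour])
        fs = np.array([hz for _, hz in self.f0_contour])
        return np.interp(t_frac, ts, fs)


def default_templates() -> dict[str, SpeciesCallTemplate]:
    """Illustrative call templates for all 11 species.

    No field measurements of per-species call structure are bundled; these
    contours are plausible whistled phrases spread across the survey band
    so that classes are acoustically distinct.
    """
    specs = {
        "Crypturellus_atrocapillus": ((0.0, 1050.0), (1.0, 1150.0)),
        "Crypturellus_bartletti": ((0.0, 1500.0), (0.5, 1620.0), (1.0, 1500.0)),
        "Crypturellus_cinereus": ((0.0, 2000.0), (1.0, 2000.0)),
        "Crypturellus_obsoletus": ((0.0, 1300.0), (1.0, 1800.0)),
        "Crypturellus_soui": ((0.0, 2200.0), (0.6, 2500.0), (1.0, 2350.0)),
        "Crypturellus_strigulosus": ((0.0, 1750.0), (1.0, 1700.0)),
        "Crypturellus_undulatus": ((0.0, 1200.0), (0.4, 1350.0), (1.0, 1250.0)),
        "Crypturellus_variegatus": ((0.0, 2600.0), (1.0, 2750.0)),
        "Tinamus_guttatus": ((0.0, 950.0), (1.0, 1000.0)),
        "Tinamus_major": ((0.0, 1400.0), (0.3, 1450.0), (0.7, 1380.0), (1.0, 1420.0)),
        "Tinamus_tao": ((0.0, 2850.0), (1.0, 2800.0)),
    }
    out = {}
    for sp, contour in specs.items():
        # trim the harmonic stack where it would cross the 8 kHz Nyquist
        # of the 16-kHz survey recordings
        fmax = max(hz for _, hz in contour)
        harmonics = (1.0, 0.35, 0.12) if fmax * 3 <= 7900 else (1.0, 0.35)
        out[sp] = SpeciesCallTemplate(sp, contour, harmonics=harmonics)
    return out


def fixture_templates(n_species: int = 4) -> dict[str, SpeciesCallTemplate]:
    """Small well-separated template set for pipeline-scale experiments.

    Fundamentals at roughly 1150/1600/2100/2600 Hz keep the classes far
    apart on the band-limited Mel axis, which is what the end-to-end
    recovery experiments assume.
    """
    f0s = np.linspace(1150.0, 2600.0, n_species)
    names = [CLASS_LABELS[i] for i in range(n_species)]
    out = {}
    for name, f0 in zip(names, f0s):
        out[name] = SpeciesCallTemplate(
            name,
            ((0.0, float(f0)), (0.5, float(f0) * 1.04), (1.0, float(f0))),
            harmonics=(1.0, 0.3),
        )
    return out
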