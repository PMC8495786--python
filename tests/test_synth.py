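"""Synthetic soundscape generator: waveforms, sessions, surveys, clips."""

import numpy as np
import pandas as pd
import pytest

from tinamou.species import JUNK_LABEL, SpeciesCallTemplate, fixture_templates
from tinamou.synth import (
    SoundscapeScript,
    band_rms,
    generate_survey,
    generate_training_clips,
    make_call_waveform,
    pink_noise,
    render_session,
)


class TestMakeCallWaveform:
    def test_flat_tone_has_fft_peak_at_f0(self):
        tpl = SpeciesCallTemplate("Tinamus_major", ((0.0, 1900.0), (1.0, 1900.0)),
                                  harmonics=(1.0,), amplitude_envelope=(0.0, 0.0))
        wave = make_call_waveform(tpl, 16_000)
        assert len(wave) == 32_000
        freqs = np.fft.rfftfreq(len(wave), 1 / 16_000)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(wave)))]
        assert peak == pytest.approx(1900.0, abs=2.0)

    def test_zero_envelope_gives_silence(self):
        tpl = SpeciesCallTemplate("Tinamus_major", ((0.0, 1500.0), (1.0, 1500.0)),
                                  amplitude_envelope=(0.5, 0.5))
        # full attack+decay covering the phrase leaves only interior energy;
        # a literal zero envelope comes from zero harmonics
        tpl0 = SpeciesCallTemplate("Tinamus_major", ((0.0, 1500.0), (1.0, 1500.0)),
                                   harmonics=(0.0,))
        assert np.all(make_call_waveform(tpl0, 16_000) == 0.0)

    def test_above_nyquist_rejected(self):
        tpl = SpeciesCallTemplate(JUNK_LABEL, ((0.0, 9000.0), (1.0, 9000.0)), harmonics=(1.0,))
        with pytest.raises(ValueError, match="Nyquist"):
            make_call_waveform(tpl, 16_000)

    def test_dominant_energy_in_f0_band(self, templates4):
        for tpl in templates4.values():
            wave = make_call_waveform(tpl, 16_000)
            total = np.sqrt(np.mean(wave**2))
            inband = band_rms(wave, 16_000, (900.0, 2900.0))
            assert inband > 0.7 * total


class TestRenderSession:
    def _script(self, events, seed=5, **kw):
        return SoundscapeScript("S00", "terra_firme", "AM", 30.0, events=list(events),
                                seed=seed, session_initial=False, **kw)

    def test_empty_event_list_noise_only(self, templates4):
        wave, truth = render_session(self._script([]), templates4)
        assert truth.empty and len(wave) == 30 * 16_000

    def test_truth_matches_script(self, templates4):
        sp = sorted(templates4)[0]
        events = [(sp, 1.0, 10.0), (sp, 12.5, 8.0), (sp, 25.0, 12.0)]
        _, truth = render_session(self._script(events), templates4)
        assert list(truth["onset_s"]) == [1.0, 12.5, 25.0]
        assert list(truth["offset_s"]) == [3.0, 14.5, 27.0]
        assert len(truth) == 3

    def test_seed_reproducibility_byte_identical(self, templates4):
        sp = sorted(templates4)[0]
        s1 = self._script([(sp, 2.0, 10.0)], seed=9)
        s2 = self._script([(sp, 2.0, 10.0)], seed=9)
        w1, _ = render_session(s1, templates4)
        w2, _ = render_session(s2, templates4)
        assert w1.tobytes() == w2.tobytes()

    def test_truncated_call_keeps_untruncated_offset(self, templates4):
        sp = sorted(templates4)[0]
        wave, truth = render_session(self._script([(sp, 29.0, 10.0)]), templates4)
        assert truth.loc[0, "offset_s"] == pytest.approx(31.0)
        assert len(wave) == 30 * 16_000

    def test_unknown_species_rejected(self, templates4):
        with pytest.raises(KeyError):
            render_session(self._script([("Nothocercus_bonapartei", 1.0, 10.0)]), templates4)

    def test_scripted_snr_is_delivered_in_band(self, templates4):
        sp = sorted(templates4)[0]
        script = self._script([(sp, 5.0, 12.0)], seed=3)
        wave, _ = render_session(script, templates4)
        noise, _ = render_session(self._script([], seed=3), templates4)
        call_part = wave - noise
        snr = 20 * np.log10(band_rms(call_part, 16_000) / band_rms(noise, 16_000))
        # call occupies ~2 s of 30 s: segment-level SNR recovered on the call span
        seg = slice(5 * 16_000, 7 * 16_000)
        snr_seg = 20 * np.log10(band_rms(call_part[seg], 16_000) / band_rms(noise[seg], 16_000))
        assert snr_seg == pytest.approx(12.0, abs=1.5)


class TestGenerateSurvey:
    def test_zero_rate_species_has_no_events(self, tmp_path, templates4):
        species = sorted(templates4)
        rates = {sp: 0.0 for sp in species}
        rates[species[0]] = 120.0
        _, truth = generate_survey([("S00", "terra_firme")], rates, 1, 11, tmp_path,
                                   templates4, session_duration_s=60.0)
        assert set(truth["species"]) <= {species[0]}

    def test_poisson_counts_within_3_sigma(self, tmp_path, templates4):
        sp = sorted(templates4)[0]
        rate = 120.0
        # 6 sites x 2 sessions x 300 s = 1 recorded hour -> lambda = 120
        _, truth = generate_survey([(f"S{i}", "terra_firme") for i in range(6)],
                                   {sp: rate}, 1, 13, tmp_path, templates4,
                                   session_duration_s=300.0)
        lam = 120.0
        assert abs(len(truth) - lam) < 3 * np.sqrt(lam)

    def test_negative_rate_rejected(self, tmp_path, templates4):
        with pytest.raises(ValueError):
            generate_survey([("S0", "terra_firme")], {sorted(templates4)[0]: -1.0},
                            1, 0, tmp_path, templates4)

    def test_file_naming_encodes_site_session_date(self, tmp_path, templates4):
        recs, _ = generate_survey([("S07", "floodplain")], {sorted(templates4)[0]: 10.0},
                                  1, 5, tmp_path, templates4, session_duration_s=30.0)
        names = sorted(r.file_path.name for r in recs)
        assert names == ["S07_2019-07-15_AM.wav", "S07_2019-07-15_PM.wav"]

    def test_different_seeds_differ(self, tmp_path, templates4):
        sp = sorted(templates4)[0]
        _, t1 = generate_survey([("S0", "terra_firme")], {sp: 120.0}, 1, 1,
                                tmp_path / "a", templates4, session_duration_s=120.0)
        _, t2 = generate_survey([("S0", "terra_firme")], {sp: 120.0}, 1, 2,
                                tmp_path / "b", templates4, session_duration_s=120.0)
        assert not t1["onset_s"].equals(t2["onset_s"])


class TestGenerateTrainingClips:
    def test_counts_and_durations(self, templates4):
        ds = generate_training_clips(templates4, 10, seed=21)
        counts = ds.counts()
        assert counts == {lbl: 10 for lbl in list(sorted(templates4)) + [JUNK_LABEL]}
        assert all(len(c.waveform) == 32_000 for c in ds.clips)

    def test_matched_filter_identifies_species(self, templates4):
        """Majority of one species' clips correlate best with its own template."""
        from tinamou.synth import make_call_waveform

        refs = {sp: make_call_waveform(t, 16_000) for sp, t in templates4.items()}
        ds = generate_training_clips(templates4, 12, seed=31)
        correct = total = 0
        for clip in ds.clips:
            if clip.label == JUNK_LABEL:
                continue
            scores = {sp: np.max(np.abs(np.correlate(clip.waveform, ref[:4000], mode="valid")))
                      for sp, ref in refs.items()}
            correct += max(scores, key=scores.get) == clip.label
            total += 1
        assert correct / total > 0.5

    def test_junk_distractors_avoid_template_fundamentals(self, templates4):
        ds = generate_training_clips(templates4, 9, seed=41)
        f0s = [hz for t in templates4.values() for _, hz in t.f0_contour]
        for clip in ds.clips:
            if clip.label != JUNK_LABEL:
                continue
            spec = np.abs(np.fft.rfft(clip.waveform.astype(float)))
            freqs = np.fft.rfftfreq(len(clip.waveform), 1 / 16_000)
            band = (freqs > 900) & (freqs < 2900)
            peak_f = freqs[band][np.argmax(spec[band])]
            peak_mag = spec[band].max()
            if peak_mag > 20 * np.median(spec[band]):  # tonal distractor present
                assert min(abs(peak_f - f) for f in f0s) > 100.0


def test_pink_noise_spectrum_slope(rng):
    """Average periodogram of 1/f noise falls with frequency."""
    n = 2**14
    psd = np.zeros(n // 2 + 1)
    for _ in range(20):
        psd += np.abs(np.fft.rfft(pink_noise(n, rng))) ** 2
    f = np.fft.rfftfreq(n)[1:]
    slope = np.polyfit(np.log(f[10:]), np.log(psd[1:][10:]), 1)[0]
    assert -1.4 < slope < -0.6
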