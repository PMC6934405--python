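"""Filterbank design, band filtering, envelope extraction and vocoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

from tevoc import (
    BandSpec,
    ToneSpec,
    VocoderConfig,
    Waveform,
    bandpass,
    design_filterbank,
    erb_number,
    extract_envelope,
    inverse_erb_number,
    make_tone,
    read_wav,
    vocode,
    write_wav,
)
from tevoc.vocoder import band_sos, vocoder_band_table


class TestErbNumber:
    def test_zero_maps_to_zero(self):
        assert erb_number(0.0) == 0.0

    @pytest.mark.parametrize("f, expected", [(100.0, 3.3696), (7800.0, 33.0659)])
    def test_known_values(self, f, expected):
        # direct evaluation of 21.4*log10(0.00437*f + 1)
        assert erb_number(f) == pytest.approx(expected, abs=1e-3)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            erb_number(-1.0)
        with pytest.raises(ValueError):
            inverse_erb_number(-0.5)

    def test_inverse_known_value(self):
        assert inverse_erb_number(8.319) == pytest.approx(331.0, abs=1.0)

    @given(st.floats(min_value=0.0, max_value=20000.0))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip_and_monotonicity(self, f):
        assert inverse_erb_number(erb_number(f)) == pytest.approx(f, rel=1e-6, abs=1e-6)
        assert erb_number(f + 1.0) > erb_number(f)


class TestFilterbank:
    def test_printed_interior_corners(self):
        bands = design_filterbank()
        interior = [round(b.hi) for b in bands[:-1]]
        assert interior[:3] == [331, 725, 1396]
        # equal ERB_N division puts the remaining corners within 1 Hz of
        # the reported 2538 and 4485
        assert abs(interior[3] - 2538) <= 1
        assert abs(interior[4] - 4485) <= 1

    def test_single_band_spans_full_range(self):
        bands = design_filterbank(VocoderConfig(n_channels=1))
        assert bands[0].lo == 100.0 and bands[0].hi == 7800.0

    def test_contiguity_exact(self):
        bands = design_filterbank()
        for a, b in zip(bands, bands[1:]):
            assert a.hi == b.lo

    def test_equal_erb_widths(self):
        widths = [erb_number(b.hi) - erb_number(b.lo) for b in design_filterbank()]
        assert np.ptp(widths) < 1e-9 * widths[0]

    def test_centers_are_geometric_means(self):
        for b in design_filterbank():
            assert b.center == pytest.approx(np.sqrt(b.lo * b.hi), rel=1e-12)
        assert round(design_filterbank()[2].center) == 1006

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            VocoderConfig(f_min=7800.0, f_max=100.0)

    def test_band_table_tsv(self):
        table = vocoder_band_table()
        lines = table.strip().split("\n")
        assert lines[0] == "channel\tlo_hz\tcenter_hz\thi_hz"
        assert len(lines) == 7
        assert lines[1].split("\t")[1] == "100"


class TestBandpass:
    def test_tone_at_center_passes(self):
        band = design_filterbank()[2]
        x = make_tone(ToneSpec(freq=band.center, duration=500, ramp=10, level=-20))
        loss_db = 20 * np.log10(bandpass(x, band).rms() / x.rms())
        assert loss_db > -1.0

    def test_tone_two_octaves_below_attenuated(self):
        band = design_filterbank()[3]  # 1396-2539 Hz
        x = make_tone(ToneSpec(freq=band.lo / 4, duration=500, ramp=10, level=-20))
        atten_db = -20 * np.log10(bandpass(x, band).rms() / x.rms())
        assert atten_db >= 40.0

    def test_one_pass_response_at_corners_and_slope(self):
        band = design_filterbank()[2]
        sos = band_sos(band, 22050.0)
        w, h = signal.sosfreqz(sos, worN=[band.lo, band.hi, band.lo / 2], fs=22050.0)
        mag_db = 20 * np.log10(np.abs(h))
        assert mag_db[0] == pytest.approx(-3.0, abs=0.3)
        assert mag_db[1] == pytest.approx(-3.0, abs=0.3)
        # one octave below the corner the one-pass skirt is near -24 dB/oct
        assert mag_db[2] < -18.0

    def test_zero_in_zero_out(self):
        band = design_filterbank()[0]
        x = Waveform(np.zeros(2048))
        assert np.allclose(bandpass(x, band).samples, 0.0)

    def test_band_above_nyquist_rejected(self):
        band = BandSpec(lo=4000.0, hi=12000.0, center=7000.0)
        with pytest.raises(ValueError):
            bandpass(Waveform(np.zeros(1024), 22050.0), band)

    def test_invalid_band_spec(self):
        with pytest.raises(ValueError):
            BandSpec(lo=500.0, hi=400.0, center=450.0)


class TestEnvelope:
    def test_am_tone_depth_recovered(self):
        rate = 22050.0
        t = np.arange(int(rate)) / rate
        m = 1.0
        x = Waveform((1 + m * np.sin(2 * np.pi * 8 * t)) * np.sin(2 * np.pi * 1000 * t), rate)
        env = extract_envelope(x, cutoff=45.0).samples
        mid = env[int(0.2 * rate):int(0.8 * rate)]  # trim filter edges
        depth = (mid.max() - mid.min()) / (mid.max() + mid.min())
        assert depth == pytest.approx(m, rel=0.05)

    def test_unmodulated_tone_constant_envelope(self):
        x = make_tone(ToneSpec(freq=1000, duration=1000, ramp=0, level=-20))
        env = extract_envelope(x, cutoff=45.0).samples
        mid = env[4000:-4000]
        assert np.std(mid) / np.mean(mid) < 0.02

    def test_fast_modulation_attenuated_per_response(self):
        rate = 22050.0
        t = np.arange(int(rate)) / rate
        x = Waveform((1 + np.sin(2 * np.pi * 60 * t)) * np.sin(2 * np.pi * 1000 * t), rate)
        env = extract_envelope(x, cutoff=45.0).samples
        mid = env[int(0.2 * rate):int(0.8 * rate)]
        depth = (mid.max() - mid.min()) / (mid.max() + mid.min())
        # zero-phase 4th-order Butterworth at 60/45 Hz: |H|^2 where
        # |H| = 1/sqrt(1 + (60/45)^8), applied twice
        expected = 1.0 / (1.0 + (60.0 / 45.0) ** 8)
        assert depth == pytest.approx(expected, abs=0.05)

    def test_envelope_nonnegative(self, rng):
        x = Waveform(rng.standard_normal(8192))
        assert np.all(extract_envelope(x, 45.0).samples >= 0)


class TestVocode:
    def test_silence_in_silence_out(self):
        x = Waveform(np.zeros(4096))
        assert np.allclose(vocode(x).samples, 0.0)

    def test_tone_at_center_dominates_own_carrier(self):
        bands = design_filterbank()
        x = make_tone(ToneSpec(freq=bands[2].center, duration=500, ramp=10, level=-20))
        y = vocode(x)
        spec = np.abs(np.fft.rfft(y.samples))
        freqs = np.fft.rfftfreq(len(y), 1 / y.rate)

        def power_near(f, width=50.0):
            sel = (freqs > f - width) & (freqs < f + width)
            return np.sum(spec[sel] ** 2)

        own = power_near(bands[2].center)
        for k, band in enumerate(bands):
            if k != 2:
                assert 10 * np.log10(own / power_near(band.center)) >= 20.0

    def test_two_tone_input_excites_both_carriers(self):
        bands = design_filterbank()
        rate = 22050.0
        t = np.arange(int(0.5 * rate)) / rate
        x = Waveform(0.1 * np.sin(2 * np.pi * bands[1].center * t)
                     + 0.1 * np.sin(2 * np.pi * bands[4].center * t), rate)
        y = vocode(x)
        spec = np.abs(np.fft.rfft(y.samples))
        freqs = np.fft.rfftfreq(len(y), 1 / y.rate)

        def peak_near(f):
            sel = (freqs > f - 50) & (freqs < f + 50)
            return spec[sel].max()

        background = np.median(spec)
        assert peak_near(bands[1].center) > 50 * background
        assert peak_near(bands[4].center) > 50 * background

    def test_output_rms_matches_input(self, rng):
        x = Waveform(rng.standard_normal(22050) * 0.1)
        y = vocode(x)
        assert len(y) == len(x)
        assert y.rms() / x.rms() == pytest.approx(1.0, abs=0.05)

    def test_envelope_domain_idempotence(self):
        # envelopes of a vocoded signal are already below the cutoff, so
        # re-vocoding should barely change them
        rng = np.random.default_rng(7)
        x = Waveform(rng.standard_normal(22050) * 0.1)
        cfg = VocoderConfig()
        y1 = vocode(x, cfg)
        y2 = vocode(y1, cfg)
        for band in design_filterbank(cfg):
            e1 = extract_envelope(bandpass(y1, band), cfg.env_cutoff).samples[2000:-2000]
            e2 = extract_envelope(bandpass(y2, band), cfg.env_cutoff).samples[2000:-2000]
            denom = np.sqrt(np.mean(e1**2))
            if denom > 1e-9:
                assert np.sqrt(np.mean((e1 - e2) ** 2)) / denom < 0.10


class TestWavIO:
    def test_16bit_round_trip(self, tmp_path):
        x = make_tone(ToneSpec(freq=1000, duration=100, ramp=5, level=-6))
        path = tmp_path / "tone.wav"
        write_wav(path, x, bit_depth=16)
        y = read_wav(path)
        assert y.rate == 22050.0
        assert np.max(np.abs(y.samples - x.samples)) <= 2**-15

    def test_float_round_trip_and_rate_preserved(self, tmp_path):
        x = make_tone(ToneSpec(freq=500, duration=50, ramp=5, level=-12), rate=44100.0)
        path = tmp_path / "tone44.wav"
        write_wav(path, x, bit_depth=32)
        y = read_wav(path)
        assert y.rate == 44100.0
        assert np.max(np.abs(y.samples - x.samples)) < 1e-6

    def test_stereo_requires_downmix_flag(self, tmp_path):
        from scipy.io import wavfile

        path = tmp_path / "stereo.wav"
        data = (np.ones((100, 2)) * 1000).astype(np.int16)
        wavfile.write(path, 22050, data)
        with pytest.raises(ValueError):
            read_wav(path)
        assert len(read_wav(path, downmix=True)) == 100

    def test_waveform_invariants(self):
        with pytest.raises(ValueError):
            Waveform(np.array([np.nan, 0.0]))
        with pytest.raises(ValueError):
            Waveform(np.array([]), 22050.0)
        with pytest.raises(ValueError):
            Waveform(np.zeros(10), rate=0.0)
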