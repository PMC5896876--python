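import numpy as np
import pytest

from nck.core import BETA, GAMMA, THETA, BandDefinition, PulseProtocol
from nck.detect import SPWEvent, detect_oscillations
from nck.spectral import (
    PowerSpectrum,
    RelativePowerSpectrum,
    band_power,
    event_relative_power,
    morlet_spectrogram,
    relative_power,
    spw_triggered_power,
    stim_power_modulation,
    welch_psd,
)
from nck.synth import GeneratorConfig, generate_session

from conftest import make_recording

FS = 1000.0


def sine(freq, duration, fs=FS, amplitude=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


class TestWelchPsd:
    def test_sine_peak_and_parseval(self):
        spec = welch_psd(sine(8.0, 60.0), FS, segment_length=1.0)
        assert spec.freqs[np.argmax(spec.power)] == 8.0
        assert abs(spec.integrated() - 0.5) < 0.025  # sine power A^2/2

    def test_zero_signal(self):
        spec = welch_psd(np.zeros(10_000), FS, 1.0)
        assert np.allclose(spec.power, 0.0)

    def test_white_noise_parseval(self, rng):
        x = rng.normal(0.0, 3.0, 120_000)
        spec = welch_psd(x, FS, 1.0)
        assert abs(spec.integrated() - 9.0) / 9.0 < 0.1

    def test_glued_pieces_and_skip_count(self, rng):
        pieces = [rng.standard_normal(3500), rng.standard_normal(500)]
        with pytest.warns(UserWarning, match="skipped"):
            spec = welch_psd(pieces, FS, 1.0)
        assert spec.n_segments == 3
        assert spec.n_skipped == 1

    def test_frequency_resolution(self):
        spec = welch_psd(sine(8.0, 10.0), FS, segment_length=0.5)
        assert spec.df == pytest.approx(2.0)


class TestRelativePower:
    def test_identity_ratio_one(self, rng):
        p = welch_psd(rng.standard_normal(20_000), FS, 1.0)
        rel = relative_power(p, p)
        assert np.allclose(rel.ratio[np.isfinite(rel.ratio)], 1.0)

    def test_double_ratio_two(self, rng):
        p = welch_psd(rng.standard_normal(20_000), FS, 1.0)
        p2 = PowerSpectrum(p.freqs, 2 * p.power, p.segment_length, p.n_segments)
        rel = relative_power(p2, p)
        finite = rel.ratio[np.isfinite(rel.ratio)]
        assert np.allclose(finite, 2.0)

    def test_zero_reference_marked_nan(self):
        freqs = np.arange(10.0)[1:]
        p = PowerSpectrum(freqs, np.ones(9), 1.0, 1)
        p0 = PowerSpectrum(freqs, np.r_[np.zeros(2), np.ones(7)], 1.0, 1)
        rel = relative_power(p, p0)
        assert np.isnan(rel.ratio[:2]).all() and np.isfinite(rel.ratio[2:]).all()

    def test_grid_mismatch_rejected(self):
        p = PowerSpectrum(np.arange(1.0, 10.0), np.ones(9), 1.0, 1)
        q = PowerSpectrum(np.arange(2.0, 11.0), np.ones(9), 1.0, 1)
        with pytest.raises(ValueError, match="grid"):
            relative_power(p, q)

    def test_burst_session_theta_elevated(self, quiet_config):
        session = generate_session(quiet_config)
        rec = session.recordings["HP"]
        events = detect_oscillations(rec)
        rel = event_relative_power(rec, events)
        assert band_power(rel, THETA) > 1.5
        high = BandDefinition("high", 150.0, 400.0)
        assert abs(band_power(rel, high) - 1.0) < 0.5


class TestMorletSpectrogram:
    def test_sine_ridge(self):
        freqs = np.arange(2.0, 40.0, 1.0)
        sg = morlet_spectrogram(sine(8.0, 10.0), FS, freqs)
        profile = sg.power[:, 2000:-2000].mean(axis=1)
        assert freqs[np.argmax(profile)] == 8.0
        octave = (freqs >= 5.7) & (freqs <= 11.3)
        assert profile[octave].sum() / profile.sum() >= 0.8

    def test_chirp_rising_ridge(self):
        from scipy.signal import chirp
        t = np.arange(int(20 * FS)) / FS
        x = chirp(t, f0=4.0, f1=40.0, t1=20.0)
        freqs = np.arange(2.0, 50.0, 1.0)
        sg = morlet_spectrogram(x, FS, freqs)
        cols = np.linspace(2000, x.size - 2000, 12).astype(int)
        ridge = [freqs[np.argmax(sg.power[:, c])] for c in cols]
        assert all(b >= a for a, b in zip(ridge, ridge[1:]))

    def test_zero_signal(self):
        sg = morlet_spectrogram(np.zeros(5000), FS, np.array([8.0, 20.0]))
        assert np.allclose(sg.power, 0.0)

    def test_invalid_freqs_rejected(self):
        with pytest.raises(ValueError):
            morlet_spectrogram(np.zeros(1000), FS, np.array([600.0]))


class TestBandPower:
    def test_flat_ratio(self):
        freqs = np.arange(1.0, 101.0)
        rel = RelativePowerSpectrum(freqs, np.ones(100))
        for band in (THETA, BETA, GAMMA):
            assert band_power(rel, band) == 1.0

    def test_band_selective_ratio(self):
        freqs = np.arange(1.0, 101.0)
        ratio = np.ones(100)
        ratio[(freqs >= 4) & (freqs < 12)] = 2.0
        rel = RelativePowerSpectrum(freqs, ratio)
        assert band_power(rel, THETA) == 2.0
        assert band_power(rel, GAMMA) == 1.0

    def test_empty_band_rejected(self):
        rel = RelativePowerSpectrum(np.arange(1.0, 10.0), np.ones(9))
        with pytest.raises(ValueError):
            band_power(rel, BandDefinition("ripple", 110.0, 250.0))

    def test_linearity(self, rng):
        freqs = np.arange(1.0, 101.0)
        vals = rng.random(100)
        a = band_power(RelativePowerSpectrum(freqs, vals), THETA)
        b = band_power(RelativePowerSpectrum(freqs, 3.0 * vals), THETA)
        assert b == pytest.approx(3.0 * a)


def fake_spws(times):
    return [SPWEvent(peak_time=t, amplitude=100.0) for t in times]


class TestSpwTriggeredPower:
    def test_stationary_noise_pre_equals_post(self, rng):
        x = rng.standard_normal(int(600 * FS))
        rec = make_recording(x, FS)
        times = np.arange(10.0, 590.0, 8.0)
        pre, post, _, dropped = spw_triggered_power(rec, fake_spws(times))
        theta_pre = band_power(pre, THETA)
        theta_post = band_power(post, THETA)
        assert abs(theta_post - theta_pre) / theta_pre < 0.1

    def test_post_burst_elevation(self, rng):
        # theta bursts starting ~100 ms after each trigger
        x = rng.normal(0.0, 5.0, int(600 * FS))
        times = np.arange(10.0, 590.0, 8.0)
        for t in times:
            i0 = int((t + 0.1) * FS)
            burst = sine(8.0, 1.2, amplitude=15.0)
            x[i0: i0 + burst.size] += burst * np.hanning(burst.size)
        rec = make_recording(x, FS)
        pre, post, _, _ = spw_triggered_power(rec, fake_spws(times))
        assert band_power(post, THETA) / band_power(pre, THETA) > 1.5

    def test_overlapping_epochs_dropped(self, rng):
        x = rng.standard_normal(int(120 * FS))
        rec = make_recording(x, FS)
        times = np.r_[np.arange(10.0, 60.0, 5.0), [61.0, 61.5]]
        *_, dropped = spw_triggered_power(rec, fake_spws(times))
        assert dropped >= 2

    def test_too_few_spws_rejected(self, rng):
        rec = make_recording(rng.standard_normal(int(60 * FS)), FS)
        with pytest.raises(ValueError, match="10"):
            spw_triggered_power(rec, fake_spws([10.0, 20.0]))

    def test_shuffled_triggers_null(self, rng):
        # circularly shifted triggers on burst-free noise: ratio ~ 1
        x = rng.standard_normal(int(600 * FS))
        rec = make_recording(x, FS)
        ratios = []
        for shift in np.linspace(0.0, 4.0, 8):
            times = np.arange(10.0, 590.0, 8.0) + shift
            pre, post, _, _ = spw_triggered_power(rec, fake_spws(times))
            ratios.append(band_power(post, THETA) / band_power(pre, THETA))
        lo, hi = np.percentile(ratios, [2.5, 97.5])
        assert lo <= 1.0 <= hi or abs(np.mean(ratios) - 1.0) < 0.05


class TestStimPowerModulation:
    @staticmethod
    def protocol(freq=8.0, n=12):
        return PulseProtocol.regular(10.0, train_frequency=freq, n_repeats=n)

    def test_null_ratios_near_one(self, rng):
        proto = self.protocol()
        dur = 10.0 + 12 * 9.0 + 10.0
        rec = make_recording(rng.standard_normal(int(dur * FS)), FS)
        out = stim_power_modulation(rec, proto, (THETA, BETA, GAMMA))
        for band in (THETA, BETA, GAMMA):
            assert abs(out[band.name] - 1.0) < 0.25

    def test_entrained_theta_elevated(self, rng):
        proto = self.protocol()
        dur = 10.0 + 12 * 9.0 + 10.0
        x = rng.normal(0.0, 5.0, int(dur * FS))
        for t in proto.train_onsets:
            burst = sine(8.0, 3.0, amplitude=15.0)
            i0 = int(t * FS)
            x[i0: i0 + burst.size] += burst
        out = stim_power_modulation(make_recording(x, FS), proto,
                                    (THETA, BETA, GAMMA))
        assert out[THETA.name] > 1.5
        assert out[THETA.name] > out[GAMMA.name]

    def test_table_grid_structure(self, rng):
        # ratio grid: three bands x three stimulation frequencies
        table = {}
        for f in (4.0, 8.0, 16.0):
            proto = self.protocol(freq=f)
            dur = 10.0 + 12 * 9.0 + 10.0
            rec = make_recording(rng.standard_normal(int(dur * FS)), FS)
            out = stim_power_modulation(rec, proto, (THETA, BETA, GAMMA))
            table[f] = {b.name: out[b.name] for b in (THETA, BETA, GAMMA)}
        assert set(table) == {4.0, 8.0, 16.0}
        for row in table.values():
            assert set(row) == {"theta", "beta", "gamma"}

    def test_too_few_trains_rejected(self, rng):
        proto = PulseProtocol.regular(10.0, n_repeats=3)
        rec = make_recording(rng.standard_normal(int(60 * FS)), FS)
        with pytest.raises(ValueError, match="5"):
            stim_power_modulation(rec, proto, (THETA,))
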