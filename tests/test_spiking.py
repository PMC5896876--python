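import numpy as np
import pytest

from nck.core import THETA, PulseProtocol, SpikeTrainSet
from nck.spiking import (
    circular_mean,
    efficacy_by_frequency,
    firing_rate,
    locked_fraction,
    phase_locking,
    rayleigh_test,
    spike_phases,
    spw_triggered_psth,
    stimulation_efficacy,
    PhaseLockingResult,
)

FS = 1000.0


def poisson_train(rng, rate, duration):
    n = rng.poisson(rate * duration)
    return np.unique(rng.uniform(0.0, duration, n))


def trainset(trains, duration, region="HP"):
    return SpikeTrainSet(list(range(len(trains))), trains, region, duration)


class TestFiringRate:
    def test_arithmetic(self):
        assert firing_rate(np.linspace(0.1, 59.9, 27), 60.0) == pytest.approx(0.45)

    def test_empty_train(self):
        assert firing_rate(np.array([]), 60.0) == 0.0

    def test_pooled_poisson(self, rng):
        rates = [firing_rate(poisson_train(rng, 0.45, 900.0), 900.0)
                 for _ in range(50)]
        assert abs(np.mean(rates) - 0.45) < 0.02

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            firing_rate(np.array([1.0]), 0.0)


class TestSpwTriggeredPsth:
    def test_poisson_flat(self, rng):
        duration = 1200.0
        trains = [poisson_train(rng, 2.0, duration) for _ in range(10)]
        triggers = np.arange(10.0, duration - 10.0, 10.0)
        psth = spw_triggered_psth(trainset(trains, duration), triggers)
        # every bin within the 99% Poisson band around the true rate
        n = triggers.size * 10 * 0.1 * 2.0
        from scipy import stats
        lo, hi = stats.poisson.interval(0.999, n)
        counts = psth.rate * triggers.size * 10 * 0.1
        assert np.all((counts >= lo) & (counts <= hi))

    def test_central_modulation(self, rng):
        duration = 1200.0
        triggers = np.arange(10.0, duration - 10.0, 10.0)
        trains = []
        for _ in range(10):
            base = poisson_train(rng, 1.0, duration)
            extra = np.concatenate([
                rng.uniform(t - 0.05, t + 0.05, rng.poisson(2.0 * 0.1))
                for t in triggers])
            trains.append(np.unique(np.concatenate([base, extra])))
        psth = spw_triggered_psth(trainset(trains, duration), triggers,
                                  window=1.0, binsize=0.1)
        center = psth.rate[np.abs(psth.bin_centers) < 0.05].mean()
        flank = psth.rate[np.abs(psth.bin_centers) > 0.5].mean()
        assert center / flank > 2.0

    def test_lagged_modulation_peak(self, rng):
        duration = 1200.0
        triggers = np.arange(10.0, duration - 10.0, 10.0)
        trains = []
        for _ in range(10):
            base = poisson_train(rng, 0.5, duration)
            extra = np.concatenate([
                rng.uniform(t + 0.04, t + 0.14, rng.poisson(0.3))
                for t in triggers])
            trains.append(np.unique(np.concatenate([base, extra])))
        psth = spw_triggered_psth(trainset(trains, duration), triggers,
                                  window=1.0, binsize=0.02)
        peak_time = psth.bin_centers[np.argmax(psth.rate)]
        assert 0.03 <= peak_time <= 0.15

    def test_too_few_triggers_rejected(self, rng):
        trains = trainset([poisson_train(rng, 1.0, 100.0)], 100.0)
        with pytest.raises(ValueError):
            spw_triggered_psth(trains, np.array([10.0, 20.0]))


class TestSpikePhases:
    def test_peak_spikes_zero_phase(self):
        t = np.arange(int(60 * FS)) / FS
        lfp = 50.0 * np.sin(2 * np.pi * 8 * t)
        peaks = (np.arange(100) + 0.25) / 8.0  # sine maxima
        phases = spike_phases(peaks, lfp, FS, THETA)
        assert np.abs(circular_mean(phases)) < 0.1

    def test_trough_spikes_pi_phase(self):
        t = np.arange(int(60 * FS)) / FS
        lfp = 50.0 * np.sin(2 * np.pi * 8 * t)
        troughs = (np.arange(100) + 0.75) / 8.0
        phases = spike_phases(troughs, lfp, FS, THETA)
        assert abs(abs(circular_mean(phases)) - np.pi) < 0.1

    def test_von_mises_mean_recovered(self, rng):
        t = np.arange(int(120 * FS)) / FS
        lfp = 50.0 * np.sin(2 * np.pi * 8 * t)
        # place spikes at times whose phase is drawn von Mises around pi/4
        draws = rng.vonmises(np.pi / 4, 2.0, 200)
        cycle = rng.integers(10, 900, 200)
        times = (cycle + 0.25) / 8.0 + draws / (2 * np.pi * 8.0)
        phases = spike_phases(np.sort(times), lfp, FS, THETA)
        err = np.angle(np.exp(1j * (circular_mean(phases) - np.pi / 4)))
        assert abs(err) < np.deg2rad(10)

    def test_out_of_range_spikes_dropped(self):
        lfp = np.sin(2 * np.pi * 8 * np.arange(int(60 * FS)) / FS)
        with pytest.warns(UserWarning, match="dropped"):
            phases = spike_phases(np.array([1.0, 100.0]), lfp, FS, THETA)
        assert phases.size == 1

    def test_interval_restriction(self):
        lfp = np.sin(2 * np.pi * 8 * np.arange(int(60 * FS)) / FS)
        spikes = np.array([1.0, 5.0, 20.0, 40.0])
        phases = spike_phases(spikes, lfp, FS, THETA, intervals=[(4.0, 25.0)])
        assert phases.size == 2


class TestRayleighTest:
    def test_identical_phases_maximal(self):
        r, z, p = rayleigh_test(np.full(50, 1.3))
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_small_sample_untested(self):
        r, z, p = rayleigh_test(np.zeros(5))
        assert np.isnan(p)

    def test_uniform_calibration(self, rng):
        # ~5% rejections at alpha 0.05 under the uniform null
        rejections = 0
        for _ in range(500):
            phases = rng.uniform(-np.pi, np.pi, 60)
            _, _, p = rayleigh_test(phases)
            rejections += p < 0.05
        assert 0.02 <= rejections / 500 <= 0.08

    def test_matches_monte_carlo_null(self, rng):
        # analytic p close to the simulated null distribution of R
        n = 40
        null_r = np.array([np.abs(np.exp(1j * rng.uniform(-np.pi, np.pi, n)).mean())
                           for _ in range(10_000)])
        for kappa in (0.35, 0.5, 0.7):
            phases = rng.vonmises(0.0, kappa, n)
            r, _, p = rayleigh_test(phases)
            p_mc = (np.sum(null_r >= r) + 1) / (null_r.size + 1)
            if 0.001 <= p_mc <= 0.2:
                assert abs(p - p_mc) / p_mc < 0.35


class TestLockedFraction:
    @staticmethod
    def result(uid, p):
        return PhaseLockingResult(uid, 50, 0.0, 0.5, p, p < 0.05)

    def test_reported_counts(self):
        results = [self.result(i, 0.01) for i in range(52)]
        results += [self.result(52 + i, 0.5) for i in range(258)]
        frac, n_locked, n_tested = locked_fraction(results)
        assert (n_locked, n_tested) == (52, 310)
        assert frac == pytest.approx(52 / 310, abs=1e-9)
        assert frac == pytest.approx(0.168, abs=0.001)

    def test_none_locked(self):
        results = [self.result(i, 0.9) for i in range(10)]
        assert locked_fraction(results)[0] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            locked_fraction([])

    def test_generated_locked_units_recovered(self, rng):
        # 20% of units strongly locked (kappa=2): recovered fraction ~0.2
        t = np.arange(int(300 * FS)) / FS
        lfp = 50.0 * np.sin(2 * np.pi * 8 * t)
        trains = []
        for u in range(60):
            if u < 12:
                draws = rng.vonmises(0.0, 2.0, 150)
                cycles = rng.choice(np.arange(10, 2300), 150, replace=False)
                st = np.sort((cycles + 0.25) / 8.0 + draws / (2 * np.pi * 8.0))
            else:
                st = poisson_train(rng, 0.5, 300.0)
            trains.append(st)
        results = phase_locking(trainset(trains, 300.0), lfp, FS, THETA)
        frac, n_locked, n_tested = locked_fraction(results)
        assert abs(frac - 0.2) < 0.08


class TestStimulationEfficacy:
    def test_deterministic_response(self):
        proto = PulseProtocol.regular(1.0, train_frequency=8.0, n_repeats=5)
        spikes = np.sort(proto.pulse_onsets + 0.005)
        eff = stimulation_efficacy(spikes, proto)
        assert eff.probability == 1.0
        assert eff.median_latency == pytest.approx(0.005)

    def test_no_spikes_zero(self):
        proto = PulseProtocol.regular(1.0, n_repeats=5)
        eff = stimulation_efficacy(np.array([]), proto)
        assert eff.probability == 0.0
        assert np.isnan(eff.median_latency)

    @pytest.mark.parametrize("rate", [0.5, 5.0, 50.0])
    def test_poisson_closed_form(self, rng, rate):
        proto = PulseProtocol(pulse_onsets=np.arange(1.0, 4001.0, 0.5),
                              train_frequency=2.0)
        duration = 4002.0
        st = poisson_train(rng, rate, duration)
        eff = stimulation_efficacy(st, proto)
        expected = 1.0 - np.exp(-0.015 * rate)
        assert abs(eff.probability - expected) < 0.02

    def test_too_few_pulses_rejected(self):
        proto = PulseProtocol(pulse_onsets=np.arange(5), train_frequency=1.0)
        with pytest.raises(ValueError):
            stimulation_efficacy(np.array([1.0]), proto)


class TestEfficacyByFrequency:
    @staticmethod
    def make_protocols():
        # disjoint in time so evoked spikes from one protocol cannot land
        # in another protocol's 15-ms windows
        starts = {4.0: 5.0, 8.0: 600.0, 16.0: 1200.0}
        return {f: PulseProtocol.regular(starts[f], train_frequency=f,
                                         n_repeats=20)
                for f in (4.0, 8.0, 16.0)}

    def test_falling_profile_recovered(self, rng):
        protocols = self.make_protocols()
        probs = {4.0: 0.9, 8.0: 0.6, 16.0: 0.3}
        # a single spike train responding to all three protocols
        spikes = []
        for f, proto in protocols.items():
            hit = rng.random(proto.pulse_onsets.size) < probs[f]
            spikes.append(proto.pulse_onsets[hit] + 0.005)
        st = np.unique(np.concatenate(spikes))
        trains = trainset([st], 2000.0)
        out = efficacy_by_frequency(trains, protocols)
        for f in (4.0, 8.0, 16.0):
            assert abs(out["per_frequency"][f] - probs[f]) < 0.05
        assert out["decreasing_with_frequency"]

    def test_flat_profile(self, rng):
        protocols = self.make_protocols()
        spikes = np.unique(np.concatenate(
            [p.pulse_onsets + 0.004 for p in protocols.values()]))
        out = efficacy_by_frequency(trainset([spikes], 2000.0), protocols)
        vals = list(out["per_frequency"].values())
        assert max(vals) - min(vals) < 1e-9

    def test_threshold_flagging(self, rng):
        protocols = self.make_protocols()
        proto16 = protocols[16.0]
        hit = rng.random(proto16.pulse_onsets.size) < 0.1
        st = np.unique(proto16.pulse_onsets[hit] + 0.005)
        out = efficacy_by_frequency(trainset([st], 2000.0), protocols)
        assert out["units_below_threshold_at_max"] == [0]

    def test_single_frequency_rejected(self):
        proto = PulseProtocol.regular(5.0, train_frequency=8.0, n_repeats=20)
        with pytest.raises(ValueError):
            efficacy_by_frequency(trainset([np.array([1.0])], 100.0),
                                  {8.0: proto})
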