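"""Single-unit analyses: firing rates, sharp-wave-triggered histograms,
Hilbert-phase locking with the Rayleigh test, and light-evoked spiking.

Phase convention: 0 rad at the peak of the band-filtered LFP, phases in
(-pi, pi]. Units with fewer than a configurable minimum of spikes are
marked untested rather than given an unreliable p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import BandDefinition, PulseProtocol, SpikeTrainSet, bandpass_array


@dataclass
class PSTH:
    bin_centers: np.ndarray   # s relative to trigger
    rate: np.ndarray          # Hz, mean over triggers and units
    n_triggers: int
    n_units: int

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_centers)
        if widths.size and not np.allclose(widths, widths[0]):
            raise ValueError("PSTH bins must be uniform")
        if np.any(self.rate < 0):
            raise ValueError("rates must be non-negative")


@dataclass
class PhaseLockingResult:
    unit_id: object
    n_spikes: int
    mean_phase: float         # rad in (-pi, pi]
    resultant_length: float   # R in [0, 1]
    rayleigh_p: float
    locked: bool
    tested: bool = True


@dataclass
class StimEfficacy:
    unit_id: object
    stim_frequency: float
    probability: float        # P(>=1 spike in the evoked window)
    median_latency: float     # s, NaN if no evoked spikes
    n_pulses: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")


def firing_rate(spike_times: np.ndarray, duration: float) -> float:
    """Spike count divided by recording duration."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return float(np.asarray(spike_times).size / duration)


def spw_triggered_psth(trains: SpikeTrainSet, trigger_times: np.ndarray,
                       window: float = 3.0, binsize: float = 0.1) -> PSTH:
    """Firing rate around each trigger, averaged over triggers and units.

    Overlapping trigger windows are counted independently.
    """
    trigger_times = np.asarray(trigger_times, dtype=float)
    if trigger_times.size < 10:
        raise ValueError("need >= 10 triggers")
    edges = np.arange(-window, window + binsize / 2, binsize)
    counts = np.zeros(edges.size - 1)
    for _, st in trains:
        for t in trigger_times:
            rel = st[(st >= t - window) & (st < t + window)] - t
            counts += np.histogram(rel, bins=edges)[0]
    rate = counts / (trigger_times.size * trains.n_units * binsize)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PSTH(bin_centers=centers, rate=rate,
                n_triggers=trigger_times.size, n_units=trains.n_units)


def spike_phases(spike_times: np.ndarray, lfp: np.ndarray, fs: float,
                 band: BandDefinition, intervals=None) -> np.ndarray:
    """Instantaneous band-filtered LFP phase at each spike (nearest sample).

    ``intervals`` optionally restricts spikes to a list of (start, stop)
    windows, e.g. detected oscillatory events. Spikes outside the LFP time
    range are dropped with a warning.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if intervals is not None:
        keep = np.zeros(spike_times.size, dtype=bool)
        for s0, s1 in intervals:
            keep |= (spike_times >= s0) & (spike_times < s1)
        spike_times = spike_times[keep]
    filt = bandpass_array(lfp, fs, band.f_low, band.f_high)
    phase = np.angle(signal.hilbert(filt))
    idx = np.round(spike_times * fs).astype(int)
    inside = (idx >= 0) & (idx < phase.size)
    if np.any(~inside):
        warnings.warn(f"{int((~inside).sum())} spikes outside LFP range dropped")
    return phase[idx[inside]]


def rayleigh_test(phases: np.ndarray, min_spikes: int = 10):
    """Rayleigh test of circular non-uniformity.

    Returns ``(R, Z, p)`` with R the mean resultant length, Z = n R^2, and
    p from the small-sample-corrected approximation
    ``p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n))`` (Zar 1999).
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < min_spikes:
        return np.nan, np.nan, np.nan
    c = np.exp(1j * phases).mean()
    r = np.abs(c)
    z = n * r ** 2
    rn = n * r
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n ** 2 - rn ** 2)) - (1 + 2 * n))
    return float(r), float(z), float(min(p, 1.0))


def circular_mean(phases: np.ndarray) -> float:
    return float(np.angle(np.exp(1j * np.asarray(phases)).mean()))


def phase_locking(trains: SpikeTrainSet, lfp: np.ndarray, fs: float,
                  band: BandDefinition, intervals=None, alpha: float = 0.05,
                  min_spikes: int = 10) -> list[PhaseLockingResult]:
    """Per-unit phase-locking statistics against one LFP channel."""
    results = []
    for uid, st in trains:
        ph = spike_phases(st, lfp, fs, band, intervals)
        r, z, p = rayleigh_test(ph, min_spikes)
        tested = np.isfinite(p)
        results.append(PhaseLockingResult(
            unit_id=uid, n_spikes=ph.size,
            mean_phase=circular_mean(ph) if ph.size else np.nan,
            resultant_length=r if tested else np.nan,
            rayleigh_p=p,
            locked=bool(tested and p < alpha),
            tested=bool(tested)))
    return results


def locked_fraction(results: list[PhaseLockingResult], alpha: float = 0.05):
    """(proportion locked, n locked, n tested) over tested units."""
    if not results:
        raise ValueError("no phase-locking results")
    tested = [r for r in results if r.tested]
    n_locked = sum(r.rayleigh_p < alpha for r in tested)
    n_tested = len(tested)
    frac = n_locked / n_tested if n_tested else 0.0
    return frac, n_locked, n_tested


def stimulation_efficacy(spike_times: np.ndarray, protocol: PulseProtocol,
                         unit_id=0, evoked_window: float = 0.015) -> StimEfficacy:
    """Probability of >= 1 spike within the evoked window after each pulse.

    The window is [onset, onset + 15 ms) by default; the median first-spike
    latency over responsive pulses is also reported.
    """
    onsets = protocol.pulse_onsets
    if onsets.size < 10:
        raise ValueError("need >= 10 pulses")
    st = np.asarray(spike_times, dtype=float)
    latencies = []
    hits = 0
    for t in onsets:
        sel = st[(st >= t) & (st < t + evoked_window)]
        if sel.size:
            hits += 1
            latencies.append(sel[0] - t)
    return StimEfficacy(unit_id=unit_id,
                        stim_frequency=protocol.train_frequency,
                        probability=hits / onsets.size,
                        median_latency=float(np.median(latencies)) if latencies else np.nan,
                        n_pulses=int(onsets.size))


def efficacy_by_frequency(trains: SpikeTrainSet, protocols: dict,
                          evoked_window: float = 0.015,
                          threshold: float = 0.25) -> dict:
    """Per-frequency mean efficacy across units plus threshold diagnostics.

    ``protocols`` maps stimulation frequency (Hz) to a PulseProtocol.
    Returns per-frequency means, a monotonicity flag (efficacy decreasing
    with frequency), and units below ``threshold`` at the highest frequency.
    """
    if len(protocols) < 2:
        raise ValueError("need protocols for >= 2 frequencies")
    freqs = sorted(protocols)
    table = {}
    per_unit_at_max = {}
    for f in freqs:
        effs = [stimulation_efficacy(st, protocols[f], uid, evoked_window)
                for uid, st in trains]
        table[f] = float(np.mean([e.probability for e in effs]))
        if f == freqs[-1]:
            per_unit_at_max = {e.unit_id: e.probability for e in effs}
    means = [table[f] for f in freqs]
    return {
        "per_frequency": table,
        "decreasing_with_frequency": all(a >= b for a, b in zip(means, means[1:])),
        "units_below_threshold_at_max": sorted(
            uid for uid, p in per_unit_at_max.items() if p < threshold),
    }
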