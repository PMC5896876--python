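"""Synthetic two-region session generator with full ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a 1/f colored-noise floor, discontinuous tapered theta bursts,
sharp-wave transients that reverse polarity across a designated pyramidal
channel with a superimposed ripple, delayed directional coupling between
regions, and spike trains with configurable rate, von Mises phase locking,
sharp-wave modulation, and light-evoked responses.

Every injected structure is returned as ground truth so each detector and
estimator downstream can be validated against known parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .core import PulseProtocol, Recording, SpikeTrainSet, bandpass_array
from .detect import OscillatoryEvent, SPWEvent


@dataclass
class GeneratorConfig:
    """Parameters of a synthetic session.

    Defaults follow the in-vivo values the pipeline is calibrated against
    (theta-burst occurrence ~8/min lasting ~3.5 s at ~110 uV over a 1/f
    background; sharp waves ~8.6/min; unit rates ~0.45 Hz).
    """

    duration: float = 300.0          # s
    fs: float = 1000.0               # Hz
    n_channels: int = 5              # per region
    channel_spacing_um: float = 50.0
    two_region: bool = True

    # background noise
    background_1overf_exponent: float = 1.0
    background_rms: float = 20.0     # uV per channel
    background_knee_hz: float = 0.1  # spectrum flattens below this frequency
    background_shared_fraction: float = 0.0

    # discontinuous theta bursts
    burst_rate: float = 8.1                # events/min
    burst_duration_mean: float = 3.5       # s
    burst_duration_sd: float = 0.1         # s
    burst_peak_amplitude: float = 110.6    # uV, envelope peak
    burst_center_freq: float = 8.0         # Hz
    burst_envelope: str = "tukey"          # "tukey" or "hann"
    burst_taper: float = 0.4               # tukey taper fraction
    burst_beta_amplitude: float = 0.0      # optional faster component, uV
    burst_beta_freq: float = 20.0
    # refractory between bursts: long enough that the sub-threshold dip
    # between consecutive events survives the detector's 200-ms merge rule
    burst_min_gap: float = 0.8             # s

    # sharp waves / ripples
    spw_rate: float = 8.6                  # events/min
    spw_amplitude: float = 223.8           # uV on the subtracted trace
    spw_sigma: float = 0.015               # s, Ricker width parameter
    spw_min_gap: float = 0.5               # s
    ripple_freq: float = 150.0             # Hz
    ripple_amplitude: float = 40.0         # uV on the pyramidal channel
    pyr_channel: int = 2                   # index within the HP region

    # cross-region coupling (HP -> PL)
    coupling_gain: float = 0.0
    coupling_lag: float = 0.015            # s
    coupling_band: tuple = (4.0, 12.0)
    # PL carries its own (independent) discontinuous bursts so that the
    # two regions are exchangeable under the uncoupled null
    pl_bursts: bool = True

    # spike trains
    n_units: int = 10
    unit_rate: float = 0.45                # Hz, homogeneous baseline
    locking_kappa: float = 0.0             # von Mises concentration
    locking_phase: float = 0.0             # preferred phase, rad (0 = peak)
    locked_fraction: float = 1.0           # fraction of units that lock
    spw_mod_factor: float = 1.0            # rate multiplier around SPWs
    spw_mod_window: float = 0.05           # s, half-window of modulation
    light_response_prob: float = 0.0       # per-pulse response probability
    light_latency: float = 0.005           # s, evoked-spike latency

    stim: PulseProtocol | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration", "fs", "burst_rate", "burst_duration_mean",
                     "burst_peak_amplitude", "background_rms", "spw_rate",
                     "spw_amplitude", "unit_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.background_1overf_exponent <= 2.0:
            raise ValueError("background_1overf_exponent must be in [0, 2]")
        if self.fs <= 2 * max(self.burst_center_freq, self.ripple_freq):
            raise ValueError("fs must exceed twice the highest generated frequency")


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------


def colored_noise(n: int, fs: float, exponent: float, rms: float,
                  knee_hz: float, rng: np.random.Generator) -> np.ndarray:
    """One channel of 1/f^exponent noise with target RMS via FFT shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaped = np.maximum(freqs, knee_hz) ** (-exponent / 2.0)
    shaped[0] = 0.0  # no DC
    spec *= shaped
    out = np.fft.irfft(spec, n=n)
    sd = out.std()
    if sd > 0:
        out *= rms / sd
    return out


def generate_background(cfg: GeneratorConfig, rng: np.random.Generator,
                        region: str = "HP") -> Recording:
    """Colored-noise floor, one independent process per channel.

    ``background_shared_fraction`` mixes in a common process so channels can
    share volume-conducted variance.
    """
    n = int(round(cfg.duration * cfg.fs))
    chans = np.empty((cfg.n_channels, n))
    shared = None
    a = cfg.background_shared_fraction
    if a > 0:
        shared = colored_noise(n, cfg.fs, cfg.background_1overf_exponent,
                               cfg.background_rms, cfg.background_knee_hz, rng)
    for c in range(cfg.n_channels):
        own = colored_noise(n, cfg.fs, cfg.background_1overf_exponent,
                            cfg.background_rms, cfg.background_knee_hz, rng)
        if shared is None:
            chans[c] = own
        else:
            chans[c] = np.sqrt(1 - a) * own + np.sqrt(a) * shared
    depths = np.arange(cfg.n_channels) * cfg.channel_spacing_um
    return Recording(chans, cfg.fs, depths, region=region)


# ---------------------------------------------------------------------------
# event placement
# ---------------------------------------------------------------------------


def _renewal_event_times(rate_per_min: float, mean_dur: float, sd_dur: float,
                         total: float, min_gap: float,
                         rng: np.random.Generator) -> list[tuple[float, float]]:
    """Place non-overlapping events whose long-run rate equals the target.

    Events are a renewal process: each cycle is (gap, event), with the gap a
    refractory minimum plus an exponential chosen so the expected cycle
    length is 1/rate. This achieves the configured occurrence exactly in
    expectation, unlike naive Poisson placement with overlap rejection,
    which thins the realized rate.
    """
    if rate_per_min <= 0:
        return []
    rate_s = rate_per_min / 60.0
    mean_cycle = 1.0 / rate_s
    mean_gap = mean_cycle - mean_dur
    if mean_gap <= min_gap:
        warnings.warn(
            f"requested rate {rate_per_min}/min unachievable without overlap; "
            f"using minimum gap {min_gap}s (achieved rate "
            f"{60.0 / (min_gap + mean_dur):.2f}/min)"
        )
        mean_exp = 0.0
    else:
        mean_exp = mean_gap - min_gap
    events = []
    # random phase start so the process is stationary over [0, total]
    t = rng.uniform(0, min_gap + (mean_exp if mean_exp > 0 else mean_dur))
    while True:
        dur = max(0.2, rng.normal(mean_dur, sd_dur))
        if t + dur > total:
            break
        events.append((t, t + dur))
        gap = min_gap + (rng.exponential(mean_exp) if mean_exp > 0 else 0.0)
        t += dur + gap
    return events


# ---------------------------------------------------------------------------
# theta bursts
# ---------------------------------------------------------------------------


def _burst_waveform(dur: float, fs: float, cfg: GeneratorConfig,
                    rng: np.random.Generator) -> np.ndarray:
    n = max(int(round(dur * fs)), 8)
    t = np.arange(n) / fs
    if cfg.burst_envelope == "hann":
        env = signal.windows.hann(n)
    else:
        env = signal.windows.tukey(n, alpha=cfg.burst_taper)
    phase0 = rng.uniform(0, 2 * np.pi)
    w = cfg.burst_peak_amplitude * env * np.sin(
        2 * np.pi * cfg.burst_center_freq * t + phase0)
    if cfg.burst_beta_amplitude > 0:
        w += cfg.burst_beta_amplitude * env * np.sin(
            2 * np.pi * cfg.burst_beta_freq * t + rng.uniform(0, 2 * np.pi))
    return w


def inject_theta_bursts(rec: Recording, cfg: GeneratorConfig,
                        rng: np.random.Generator) -> tuple[Recording, list[OscillatoryEvent]]:
    """Add discontinuous narrow-band bursts; return modified copy + truth.

    Bursts are coherent across channels (added identically to every
    channel), so they cancel on cross-channel difference traces used for
    sharp-wave detection.
    """
    out = rec.samples.copy()
    truth: list[OscillatoryEvent] = []
    if cfg.burst_peak_amplitude == 0 or cfg.burst_rate == 0:
        return rec.copy_with(out), truth
    spans = _renewal_event_times(cfg.burst_rate, cfg.burst_duration_mean,
                                 cfg.burst_duration_sd, rec.duration,
                                 cfg.burst_min_gap, rng)
    for start, stop in spans:
        w = _burst_waveform(stop - start, rec.fs, cfg, rng)
        i0 = int(round(start * rec.fs))
        i1 = min(i0 + w.size, rec.n_samples)
        out[:, i0:i1] += w[: i1 - i0]
        truth.append(OscillatoryEvent(
            start=start, stop=start + (i1 - i0) / rec.fs,
            peak_amplitude=cfg.burst_peak_amplitude,
            channel=0, region=rec.region))
    return rec.copy_with(out), truth


# ---------------------------------------------------------------------------
# sharp waves + ripples
# ---------------------------------------------------------------------------


def _ricker(sigma: float, fs: float) -> np.ndarray:
    """Zero-mean biphasic transient (Mexican hat), unit peak at center."""
    half = int(round(4 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    return (1.0 - (t / sigma) ** 2) * np.exp(-(t ** 2) / (2 * sigma ** 2))


def inject_spw_ripples(rec: Recording, cfg: GeneratorConfig,
                       rng: np.random.Generator) -> tuple[Recording, list[SPWEvent]]:
    """Add polarity-reversing sharp waves with a ripple on the pyr channel.

    Channels shallower than the pyramidal channel receive +A/2 * w(t),
    deeper channels -A/2 * w(t), so the (above - below) subtraction trace
    carries the full configured amplitude. The ripple rides only on the
    pyramidal channel and therefore cancels in the subtraction.
    """
    if rec.n_channels < 3:
        raise ValueError("need >= 3 channels to inject reversing sharp waves")
    out = rec.samples.copy()
    truth: list[SPWEvent] = []
    if cfg.spw_rate == 0 or cfg.spw_amplitude == 0:
        return rec.copy_with(out), truth
    pyr = cfg.pyr_channel
    wave = _ricker(cfg.spw_sigma, rec.fs)
    half = wave.size // 2
    # ripple burst with gaussian envelope
    tr = np.arange(-3 * 0.01, 3 * 0.01, 1 / rec.fs)
    ripple = (cfg.ripple_amplitude * np.exp(-tr ** 2 / (2 * 0.01 ** 2))
              * np.sin(2 * np.pi * cfg.ripple_freq * tr))
    rhalf = ripple.size // 2
    spans = _renewal_event_times(cfg.spw_rate, 2 * half / rec.fs, 0.0,
                                 rec.duration, cfg.spw_min_gap, rng)
    for start, _stop in spans:
        center = int(round(start * rec.fs)) + half
        i0, i1 = center - half, center + half + 1
        if i0 < 0 or i1 > rec.n_samples:
            continue
        for c in range(rec.n_channels):
            if c < pyr:
                out[c, i0:i1] += 0.5 * cfg.spw_amplitude * wave
            elif c > pyr:
                out[c, i0:i1] -= 0.5 * cfg.spw_amplitude * wave
        j0, j1 = center - rhalf, center - rhalf + ripple.size
        if 0 <= j0 and j1 <= rec.n_samples:
            out[pyr, j0:j1] += ripple
        truth.append(SPWEvent(peak_time=center / rec.fs,
                              amplitude=cfg.spw_amplitude, pyr_channel=pyr))
    return rec.copy_with(out), truth


# ---------------------------------------------------------------------------
# coupling
# ---------------------------------------------------------------------------


def couple_regions(src: Recording, dst: Recording, cfg: GeneratorConfig) -> Recording:
    """Add a delayed, band-limited copy of ``src`` into every ``dst`` channel.

    Ground-truth direction is src -> dst only.
    """
    if cfg.coupling_lag < 0:
        raise ValueError("coupling_lag must be >= 0")
    if src.fs != dst.fs or src.n_samples != dst.n_samples:
        raise ValueError("recordings must share fs and duration")
    if cfg.coupling_lag >= dst.duration:
        raise ValueError("coupling_lag must be shorter than the recording")
    if cfg.coupling_gain == 0:
        return dst.copy_with(dst.samples.copy())
    lo, hi = cfg.coupling_band
    drive = bandpass_array(src.samples[min(cfg.pyr_channel, src.n_channels - 1)],
                           src.fs, lo, hi)
    shift = int(round(cfg.coupling_lag * src.fs))
    delayed = np.zeros_like(drive)
    if shift < drive.size:
        delayed[shift:] = drive[: drive.size - shift]
    out = dst.samples + cfg.coupling_gain * delayed[None, :]
    return dst.copy_with(out)


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------


def _locked_spikes_for_burst(start: float, stop: float, rate: float,
                             cfg: GeneratorConfig,
                             rng: np.random.Generator) -> np.ndarray:
    """Spikes during a burst, one Bernoulli draw per oscillation cycle with
    von Mises phase; keeps the expected rate equal to the baseline rate."""
    f = cfg.burst_center_freq
    cycle_starts = np.arange(start, stop - 1.0 / f, 1.0 / f)
    if cycle_starts.size == 0:
        return np.array([])
    p = min(1.0, rate / f)
    fire = rng.random(cycle_starts.size) < p
    if not np.any(fire):
        return np.array([])
    if cfg.locking_kappa > 0:
        phases = rng.vonmises(cfg.locking_phase, cfg.locking_kappa, int(fire.sum()))
    else:
        phases = rng.uniform(-np.pi, np.pi, int(fire.sum()))
    return cycle_starts[fire] + (phases % (2 * np.pi)) / (2 * np.pi * f)


def generate_spike_trains(rec: Recording, cfg: GeneratorConfig,
                          rng: np.random.Generator,
                          bursts: list[OscillatoryEvent] | None = None,
                          spws: list[SPWEvent] | None = None,
                          stim: PulseProtocol | None = None,
                          locked_units: np.ndarray | None = None) -> SpikeTrainSet:
    """Inhomogeneous Poisson trains with optional locking and modulation.

    - baseline: homogeneous Poisson at ``unit_rate``
    - during bursts (if ``locking_kappa`` > 0 and the unit is flagged as
      locked): spikes are drawn per theta cycle with von Mises phase
    - around SPW peaks: rate multiplied by ``spw_mod_factor``
    - after light pulses: one evoked spike with ``light_response_prob`` at
      ``light_latency``
    """
    T = rec.duration
    burst_spans = [(ev.start, ev.stop) for ev in (bursts or [])]
    if locked_units is None:
        n_locked = int(round(cfg.locked_fraction * cfg.n_units))
        locked_units = np.zeros(cfg.n_units, dtype=bool)
        locked_units[:n_locked] = True
    trains = []
    for u in range(cfg.n_units):
        n_base = rng.poisson(cfg.unit_rate * T)
        spikes = rng.uniform(0, T, n_base)
        if burst_spans and cfg.locking_kappa >= 0 and locked_units[u] and cfg.locking_kappa > 0:
            # replace in-burst baseline spikes with phase-locked spikes
            in_burst = np.zeros(spikes.size, dtype=bool)
            for s0, s1 in burst_spans:
                in_burst |= (spikes >= s0) & (spikes < s1)
            spikes = spikes[~in_burst]
            for s0, s1 in burst_spans:
                spikes = np.concatenate(
                    [spikes, _locked_spikes_for_burst(s0, s1, cfg.unit_rate, cfg, rng)])
        if spws and cfg.spw_mod_factor > 1.0:
            extra_rate = cfg.unit_rate * (cfg.spw_mod_factor - 1.0)
            for ev in spws:
                w0 = max(0.0, ev.peak_time - cfg.spw_mod_window)
                w1 = min(T, ev.peak_time + cfg.spw_mod_window)
                n_extra = rng.poisson(extra_rate * (w1 - w0))
                spikes = np.concatenate([spikes, rng.uniform(w0, w1, n_extra)])
        if stim is not None and cfg.light_response_prob > 0:
            hit = rng.random(stim.pulse_onsets.size) < cfg.light_response_prob
            evoked = stim.pulse_onsets[hit] + cfg.light_latency
            spikes = np.concatenate([spikes, evoked[evoked < T]])
        spikes = np.unique(spikes)
        spikes = spikes[(spikes >= 0) & (spikes <= T)]
        trains.append(spikes)
    return SpikeTrainSet(unit_ids=list(range(cfg.n_units)), spike_times=trains,
                         region=rec.region, recording_duration=T)


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Registry of everything injected into a synthetic session."""

    bursts: dict = field(default_factory=dict)    # region -> [OscillatoryEvent]
    spws: list = field(default_factory=list)      # [SPWEvent]
    pyr_channel: int = 0
    coupling: dict = field(default_factory=dict)  # {"src","dst","gain","lag"}
    locked_units: dict = field(default_factory=dict)


@dataclass
class Session:
    """A complete synthetic or loaded session."""

    recordings: dict        # region -> Recording
    spikes: dict            # region -> SpikeTrainSet
    stim: PulseProtocol | None = None
    truth: GroundTruth | None = None
    config: GeneratorConfig | None = None


def generate_session(cfg: GeneratorConfig) -> Session:
    """Deterministic full session from one seed: HP (bursts + SPWs + units),
    optionally PL driven by HP through a delayed band-limited projection."""
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth(pyr_channel=cfg.pyr_channel)

    hp = generate_background(cfg, rng, region="HP")
    hp, hp_bursts = inject_theta_bursts(hp, cfg, rng)
    if cfg.n_channels >= 3:
        hp, spws = inject_spw_ripples(hp, cfg, rng)
    else:
        spws = []
    truth.bursts["HP"] = hp_bursts
    truth.spws = spws

    recordings = {"HP": hp}
    spikes = {}
    n_locked = int(round(cfg.locked_fraction * cfg.n_units))
    locked = np.zeros(cfg.n_units, dtype=bool)
    locked[:n_locked] = True
    spikes["HP"] = generate_spike_trains(hp, cfg, rng, bursts=hp_bursts,
                                         spws=spws, stim=cfg.stim,
                                         locked_units=locked)
    truth.locked_units["HP"] = locked

    if cfg.two_region:
        pl = generate_background(cfg, rng, region="PL")
        if cfg.pl_bursts:
            pl, pl_bursts = inject_theta_bursts(pl, cfg, rng)
            truth.bursts["PL"] = pl_bursts
        pl = couple_regions(hp, pl, cfg)
        recordings["PL"] = pl
        truth.coupling = {"src": "HP", "dst": "PL",
                          "gain": cfg.coupling_gain, "lag": cfg.coupling_lag}
        locked_pl = np.zeros(cfg.n_units, dtype=bool)
        locked_pl[:n_locked] = True
        spikes["PL"] = generate_spike_trains(pl, cfg, rng, bursts=hp_bursts,
                                             spws=spws, stim=cfg.stim,
                                             locked_units=locked_pl)
        truth.locked_units["PL"] = locked_pl

    return Session(recordings=recordings, spikes=spikes, stim=cfg.stim,
                   truth=truth, config=cfg)
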