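"""Domain types and signal conditioning shared by every analysis stage.

All voltages are in microvolts, all timestamps in seconds from recording
start, and channel depths in micrometers with positive = deeper (ventral).
Filtering is zero-phase (forward-backward Butterworth) so that phase-based
analyses downstream (Hilbert phase, imaginary coherence) stay valid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal


class InvalidBandError(ValueError):
    """A frequency band is incompatible with the sampling rate."""


class InsufficientDataError(ValueError):
    """The signal is too short for the requested operation."""


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[f_low, f_high)`` in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise InvalidBandError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got ({self.f_low}, {self.f_high})"
            )


# Canonical bands used throughout the analyses.
THETA = BandDefinition("theta", 4.0, 12.0)
BETA = BandDefinition("beta", 12.0, 30.0)
GAMMA = BandDefinition("gamma", 30.0, 100.0)
RIPPLE = BandDefinition("ripple", 110.0, 250.0)
DEFAULT_BANDS = (THETA, BETA, GAMMA)


@dataclass
class Recording:
    """Multi-channel continuous voltage recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltage traces in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_depths : ndarray, shape (n_channels,)
        Depth offset of each channel in micrometers, strictly monotonic
        (increasing = deeper).
    region : str
        Region label, e.g. ``"PL"``, ``"dHP"``, ``"ivHP"``.
    t0 : float
        Recording start time in seconds.
    """

    samples: np.ndarray
    fs: float
    channel_depths: np.ndarray
    region: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channel_depths = np.asarray(self.channel_depths, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (n_channels, n_samples) matrix")
        if self.channel_depths.shape != (self.samples.shape[0],):
            raise ValueError(
                f"channel_depths has {self.channel_depths.size} entries for "
                f"{self.samples.shape[0]} channels"
            )
        diffs = np.diff(self.channel_depths)
        if self.n_channels > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("channel_depths must be strictly monotonic")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("voltage samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel_at_depth(self, depth_um: float) -> int:
        """Index of the channel closest to ``depth_um``."""
        return int(np.argmin(np.abs(self.channel_depths - depth_um)))

    def copy_with(self, samples: np.ndarray, fs: float | None = None) -> "Recording":
        return replace(self, samples=samples, fs=self.fs if fs is None else fs)


@dataclass
class SpikeTrainSet:
    """Sorted single-unit spike times for one region."""

    unit_ids: list
    spike_times: list  # list of float64 arrays, seconds
    region: str = ""
    recording_duration: float = 0.0

    def __post_init__(self) -> None:
        if len(self.unit_ids) != len(self.spike_times):
            raise ValueError("unit_ids and spike_times must have equal length")
        clean = []
        for uid, st in zip(self.unit_ids, self.spike_times):
            st = np.asarray(st, dtype=float)
            if st.size and np.any(np.diff(st) <= 0):
                raise ValueError(f"unit {uid}: spike times must be strictly increasing")
            if st.size and (st[0] < 0 or st[-1] > self.recording_duration):
                raise ValueError(
                    f"unit {uid}: spikes outside [0, {self.recording_duration}]"
                )
            clean.append(st)
        self.spike_times = clean

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def __iter__(self):
        return iter(zip(self.unit_ids, self.spike_times))


@dataclass
class PulseProtocol:
    """Light pulse-train stimulation protocol.

    A protocol consists of ``n_repeats`` trains of pulses delivered at
    ``train_frequency`` for ``train_duration`` seconds, separated by
    ``inter_train_interval`` seconds of silence.
    """

    pulse_onsets: np.ndarray  # seconds
    pulse_width: float = 0.003
    train_frequency: float = 8.0
    train_duration: float = 3.0
    inter_train_interval: float = 6.0
    n_repeats: int = 30

    def __post_init__(self) -> None:
        self.pulse_onsets = np.asarray(self.pulse_onsets, dtype=float)
        if self.pulse_onsets.size and np.any(np.diff(self.pulse_onsets) <= 0):
            raise ValueError("pulse onsets must be strictly increasing")
        # within-train spacing must equal 1/train_frequency
        gaps = np.diff(self.pulse_onsets)
        within = gaps[gaps < 1.5 / self.train_frequency]
        if within.size and not np.allclose(within, 1.0 / self.train_frequency, atol=1e-6):
            raise ValueError("within-train pulse spacing must be 1/train_frequency")

    @property
    def train_onsets(self) -> np.ndarray:
        """Onset time of the first pulse of each train."""
        if self.pulse_onsets.size == 0:
            return np.array([])
        gaps = np.diff(self.pulse_onsets)
        starts = np.concatenate(([0], np.nonzero(gaps > 1.5 / self.train_frequency)[0] + 1))
        return self.pulse_onsets[starts]

    @classmethod
    def regular(
        cls,
        start: float,
        train_frequency: float = 8.0,
        pulse_width: float = 0.003,
        train_duration: float = 3.0,
        inter_train_interval: float = 6.0,
        n_repeats: int = 30,
    ) -> "PulseProtocol":
        """Build the canonical repeated pulse-train protocol."""
        pulses = []
        n_per_train = int(round(train_duration * train_frequency))
        for rep in range(n_repeats):
            t_train = start + rep * (train_duration + inter_train_interval)
            pulses.extend(t_train + np.arange(n_per_train) / train_frequency)
        return cls(
            pulse_onsets=np.array(pulses),
            pulse_width=pulse_width,
            train_frequency=train_frequency,
            train_duration=train_duration,
            inter_train_interval=inter_train_interval,
            n_repeats=n_repeats,
        )


# ---------------------------------------------------------------------------
# Signal conditioning
# ---------------------------------------------------------------------------


def _sos_bandpass(f_low: float, f_high: float, fs: float, order: int):
    nyq = fs / 2.0
    if f_high >= nyq:
        raise InvalidBandError(
            f"band edge {f_high} Hz >= Nyquist frequency {nyq} Hz"
        )
    return signal.butter(order, [f_low, f_high], btype="bandpass", fs=fs, output="sos")


def _filtfilt_checked(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    n_sections = sos.shape[0]
    padlen = 3 * (2 * n_sections + 1)
    if x.shape[-1] <= 3 * padlen:
        raise InsufficientDataError(
            f"signal length {x.shape[-1]} too short for zero-phase filtering "
            f"(need > {3 * padlen} samples)"
        )
    return signal.sosfiltfilt(sos, x, axis=-1)


def bandpass_filter(rec: Recording, band: BandDefinition, order: int = 3) -> Recording:
    """Zero-phase Butterworth band-pass of every channel.

    The filter is applied forward and backward (``sosfiltfilt``), which
    doubles the effective order and cancels phase distortion.
    """
    sos = _sos_bandpass(band.f_low, band.f_high, rec.fs, order)
    return rec.copy_with(_filtfilt_checked(sos, rec.samples))


def bandpass_array(
    x: np.ndarray, fs: float, f_low: float, f_high: float, order: int = 3
) -> np.ndarray:
    """Zero-phase Butterworth band-pass on a bare array (last axis = time)."""
    sos = _sos_bandpass(f_low, f_high, fs, order)
    return _filtfilt_checked(sos, np.asarray(x, dtype=float))


def lowpass_array(x: np.ndarray, fs: float, f_high: float, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth low-pass on a bare array."""
    nyq = fs / 2.0
    if f_high >= nyq:
        raise InvalidBandError(f"cutoff {f_high} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, f_high, btype="lowpass", fs=fs, output="sos")
    return _filtfilt_checked(sos, np.asarray(x, dtype=float))


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased resampling to ``target_fs``.

    Uses polyphase resampling, which low-pass filters before decimating so
    spectral content below ``target_fs / 2`` is preserved.
    """
    if target_fs <= 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if target_fs >= rec.fs:
        warnings.warn(
            f"target_fs {target_fs} >= fs {rec.fs}; returning recording unchanged"
        )
        return rec.copy_with(rec.samples.copy())
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    out = signal.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=-1)
    return rec.copy_with(out, fs=rec.fs * frac.numerator / frac.denominator)


def mua_filter(rec: Recording, f_low: float = 500.0, f_high: float = 5000.0,
               order: int = 3) -> Recording:
    """Spike-band (default 500-5000 Hz) band-pass for multi-unit activity.

    If the sampling rate cannot support the upper edge, it is clipped to
    ``0.45 * fs`` with a warning.
    """
    if f_high >= 0.5 * rec.fs:
        clipped = 0.45 * rec.fs
        warnings.warn(
            f"upper edge {f_high} Hz unsupported at fs {rec.fs} Hz; "
            f"clipping to {clipped} Hz"
        )
        f_high = clipped
    if f_low >= f_high:
        raise InvalidBandError(
            f"sampling rate {rec.fs} Hz too low for spike-band filtering"
        )
    sos = _sos_bandpass(f_low, f_high, rec.fs, order)
    return rec.copy_with(_filtfilt_checked(sos, rec.samples))
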