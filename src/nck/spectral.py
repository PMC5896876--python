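"""Spectral analysis: Welch PSD on glued segments, relative power, Morlet
spectrograms, band summaries, and event-/stimulation-locked power.

Welch estimates use non-overlapping Hann-tapered windows. "Glued" means a
set of signal pieces (e.g. all detected oscillatory events) is chopped into
windows of one segment length each and the periodograms averaged across all
windows of all pieces; pieces shorter than one segment are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import BandDefinition, PulseProtocol, Recording


@dataclass
class PowerSpectrum:
    freqs: np.ndarray          # Hz
    power: np.ndarray          # uV^2/Hz
    segment_length: float      # s
    n_segments: int
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def integrated(self) -> float:
        """Total power (trapezoidal integral of the density)."""
        return float(np.trapezoid(self.power, self.freqs))


@dataclass
class RelativePowerSpectrum:
    freqs: np.ndarray
    ratio: np.ndarray          # unitless; NaN where reference power is 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)


@dataclass
class Spectrogram:
    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray          # (n_freqs, n_times)

    def __post_init__(self) -> None:
        if self.power.shape != (self.freqs.size, self.times.size):
            raise ValueError("power matrix dimensions inconsistent")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


def _windows_from_pieces(pieces, nperseg: int):
    """Chop each piece into non-overlapping windows of nperseg samples."""
    wins, skipped = [], 0
    for piece in pieces:
        piece = np.asarray(piece, dtype=float)
        n = piece.size // nperseg
        if n == 0:
            skipped += 1
            continue
        wins.append(piece[: n * nperseg].reshape(n, nperseg))
    if not wins:
        return None, skipped
    return np.vstack(wins), skipped


def _tapered_ffts(windows: np.ndarray, fs: float):
    """Hann-tapered one-sided FFTs with Welch density scaling."""
    nperseg = windows.shape[1]
    taper = signal.windows.hann(nperseg, sym=False)
    scale = 1.0 / (fs * (taper ** 2).sum())
    spec = np.fft.rfft(windows * taper, axis=1)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return freqs, spec, scale


def welch_psd(pieces, fs: float, segment_length: float = 1.0) -> PowerSpectrum:
    """Welch PSD over glued pieces with non-overlapping Hann windows.

    ``pieces`` is either one 1-D array or a sequence of 1-D arrays (e.g.
    per-event signal excerpts). Frequency resolution is 1/segment_length.
    """
    if isinstance(pieces, np.ndarray) and pieces.ndim == 1:
        pieces = [pieces]
    nperseg = int(round(segment_length * fs))
    windows, skipped = _windows_from_pieces(pieces, nperseg)
    if windows is None:
        raise ValueError("no piece is at least one segment long")
    if skipped:
        warnings.warn(f"{skipped} pieces shorter than one segment skipped")
    freqs, spec, scale = _tapered_ffts(windows, fs)
    psd = scale * np.mean(np.abs(spec) ** 2, axis=0)
    if nperseg % 2 == 0:
        psd[1:-1] *= 2.0
    else:
        psd[1:] *= 2.0
    return PowerSpectrum(freqs=freqs, power=psd, segment_length=segment_length,
                         n_segments=windows.shape[0], n_skipped=skipped)


def relative_power(p: PowerSpectrum, p0: PowerSpectrum) -> RelativePowerSpectrum:
    """Pointwise ratio P(f)/P0(f); zero-reference bins are marked NaN."""
    if p.freqs.shape != p0.freqs.shape or not np.allclose(p.freqs, p0.freqs):
        raise ValueError("frequency grids differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p0.power > 0, p.power / p0.power, np.nan)
    return RelativePowerSpectrum(freqs=p.freqs.copy(), ratio=ratio)


def morlet_spectrogram(x: np.ndarray, fs: float, freqs: np.ndarray,
                       omega0: float = 6.0) -> Spectrogram:
    """|CWT|^2 with a complex Morlet mother wavelet (default 6 cycles).

    Wavelets are L2-normalized, so a unit sine yields a stable ridge at its
    frequency regardless of scale.
    """
    x = np.asarray(x, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError("frequencies must lie in (0, fs/2)")
    power = np.empty((freqs.size, x.size))
    for i, f in enumerate(freqs):
        s = omega0 / (2 * np.pi * f)                 # scale in seconds
        half = int(np.ceil(4 * s * fs))
        t = np.arange(-half, half + 1) / fs
        psi = (np.pi ** -0.25 / np.sqrt(s * fs)
               * np.exp(1j * omega0 * t / s) * np.exp(-(t ** 2) / (2 * s ** 2)))
        w = signal.fftconvolve(x, psi, mode="same")
        power[i] = np.abs(w) ** 2
    return Spectrogram(times=np.arange(x.size) / fs, freqs=freqs, power=power)


def band_power(spectrum, band: BandDefinition) -> float:
    """Mean over bins with f_low <= f < f_high (NaN bins excluded)."""
    if isinstance(spectrum, PowerSpectrum):
        freqs, values = spectrum.freqs, spectrum.power
    else:
        freqs, values = spectrum.freqs, spectrum.ratio
    sel = (freqs >= band.f_low) & (freqs < band.f_high)
    if not np.any(sel):
        raise ValueError(f"band {band.name} contains no frequency bins")
    vals = values[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"band {band.name} has no defined bins")
    return float(vals.mean())


def event_relative_power(rec: Recording, events, channel: int = 0,
                         segment_length: float = 1.0) -> RelativePowerSpectrum:
    """P(f) from within-event segments over P0(f) from inter-event segments."""
    x = rec.samples[channel]
    fs = rec.fs
    in_pieces, out_pieces = [], []
    prev = 0.0
    for ev in sorted(events, key=lambda e: e.start):
        i0, i1 = int((ev.start - rec.t0) * fs), int((ev.stop - rec.t0) * fs)
        in_pieces.append(x[i0:i1])
        j0, j1 = int(prev * fs), i0
        if j1 > j0:
            out_pieces.append(x[j0:j1])
        prev = ev.stop - rec.t0
    tail = x[int(prev * fs):]
    if tail.size:
        out_pieces.append(tail)
    p = welch_psd(in_pieces, fs, segment_length)
    p0 = welch_psd(out_pieces, fs, segment_length)
    return relative_power(p, p0)


def spw_triggered_power(rec: Recording, spws, channel: int = 0, *,
                        pre_window: float = 1.5, post_window: float = 1.5,
                        segment_length: float = 0.3,
                        spectrogram_freqs: np.ndarray | None = None):
    """Pre- vs post-sharp-wave PSDs plus the SPW-aligned mean spectrogram.

    Epochs whose windows overlap a neighbouring sharp wave are dropped.
    Returns ``(pre, post, aligned_map, n_dropped)``.
    """
    if len(spws) < 10:
        raise ValueError("need >= 10 sharp waves")
    x = rec.samples[channel]
    fs = rec.fs
    peaks = np.sort([ev.peak_time - rec.t0 for ev in spws])
    pre_pieces, post_pieces, epochs = [], [], []
    dropped = 0
    for i, t in enumerate(peaks):
        lo, hi = t - pre_window, t + post_window
        if lo < 0 or hi * fs > x.size:
            dropped += 1
            continue
        if (i > 0 and peaks[i - 1] > lo) or (i + 1 < peaks.size and peaks[i + 1] < hi):
            dropped += 1
            continue
        c = int(t * fs)
        pre_pieces.append(x[c - int(pre_window * fs): c])
        post_pieces.append(x[c: c + int(post_window * fs)])
        epochs.append((c - int(pre_window * fs), c + int(post_window * fs)))
    if not pre_pieces:
        raise ValueError("all sharp-wave epochs were dropped")
    pre = welch_psd(pre_pieces, fs, segment_length)
    post = welch_psd(post_pieces, fs, segment_length)
    if spectrogram_freqs is None:
        spectrogram_freqs = np.arange(4.0, 101.0, 4.0)
    n_ep = int((pre_window + post_window) * fs)
    acc = np.zeros((len(spectrogram_freqs), n_ep))
    for i0, i1 in epochs:
        sg = morlet_spectrogram(x[i0:i1], fs, spectrogram_freqs)
        acc += sg.power[:, :n_ep]
    aligned = Spectrogram(
        times=np.arange(n_ep) / fs - pre_window,
        freqs=np.asarray(spectrogram_freqs, dtype=float),
        power=acc / len(epochs))
    return pre, post, aligned, dropped


def stim_power_modulation(rec: Recording, protocol: PulseProtocol,
                          bands, channel: int = 0,
                          segment_length: float = 3.0) -> dict:
    """Per-band P_stim/P_pre ratios averaged across pulse trains.

    For each train the PSD of the stimulation window and of the equally
    long preceding window are computed with ``segment_length`` segments.
    The per-band ratio is taken per train on band-averaged power (a
    pointwise per-train ratio of single-segment periodograms is a ratio of
    exponential variates with unusable tails) and then averaged across
    trains; the returned ``_spectrum`` is the ratio of train-averaged PSDs.
    """
    onsets = protocol.train_onsets - rec.t0
    if onsets.size < 5:
        raise ValueError("need >= 5 pulse trains")
    x = rec.samples[channel]
    fs = rec.fs
    w = protocol.train_duration
    n_w = int(round(w * fs))
    stim_psds, pre_psds = [], []
    dropped = 0
    for t in onsets:
        c = int(round(t * fs))
        if c - n_w < 0 or c + n_w > x.size:
            dropped += 1
            continue
        stim_psds.append(welch_psd(x[c: c + n_w], fs, min(segment_length, w)))
        pre_psds.append(welch_psd(x[c - n_w: c], fs, min(segment_length, w)))
    if dropped:
        warnings.warn(f"{dropped} truncated trains dropped")
    if not stim_psds:
        raise ValueError("no usable trains")
    out = {}
    for band in bands:
        per_train = []
        for ps, pp in zip(stim_psds, pre_psds):
            denom = band_power(pp, band)
            if denom > 0:
                per_train.append(band_power(ps, band) / denom)
        out[band.name] = float(np.mean(per_train))
    freqs = stim_psds[0].freqs
    mean_stim = np.mean([p.power for p in stim_psds], axis=0)
    mean_pre = np.mean([p.power for p in pre_psds], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_pre > 0, mean_stim / mean_pre, np.nan)
    out["_spectrum"] = RelativePowerSpectrum(freqs=freqs, ratio=ratio)
    out["_n_trains"] = len(stim_psds)
    return out
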