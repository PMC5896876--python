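"""Detection of discontinuous oscillatory events and sharp waves.

Oscillations: deflections of the sliding RMS of the 1-100 Hz filtered
signal above a variance-dependent threshold. The threshold comes from a
Gaussian fit to the RMS histogram restricted to [0, histogram mode]: the
left flank of the background mode is noise-only even in busy recordings,
so the fit recovers the noise mean/SD and the threshold is mean + k*SD.
Events closer than 200 ms are merged (merge precedes the duration rule),
and only events lasting more than 1 s are kept.

Sharp waves: the 1-300 Hz filtered signals from the channels 100 um above
and 100 um below the pyramidal-layer channel are subtracted; peaks of the
difference exceeding 5 standard deviations are sharp waves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, signal

from .core import InsufficientDataError, Recording, bandpass_array


@dataclass
class OscillatoryEvent:
    """One detected (or injected) discontinuous oscillatory event."""

    start: float
    stop: float
    peak_amplitude: float
    channel: int = 0
    region: str = ""

    @property
    def duration(self) -> float:
        return self.stop - self.start

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("event stop must exceed start")
        if self.peak_amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass
class SPWEvent:
    """One sharp wave on the cross-channel subtraction trace."""

    peak_time: float
    amplitude: float
    pyr_channel: int = 0


class DegenerateHistogramError(ValueError):
    """RMS histogram has no usable structure for threshold fitting."""


class NoReversalError(ValueError):
    """No polarity reversal found; pyramidal channel must be set manually."""


def compute_rms(x: np.ndarray, fs: float, window: float = 0.2) -> np.ndarray:
    """Centered sliding-window RMS, same length as input.

    Edges are padded by reflection (``uniform_filter1d`` reflect mode).
    """
    n_win = int(round(window * fs))
    if n_win < 10:
        raise ValueError(f"window of {n_win} samples too short (need >= 10)")
    x = np.asarray(x, dtype=float)
    if n_win > x.size:
        raise InsufficientDataError("RMS window longer than signal")
    mean_sq = ndimage.uniform_filter1d(x ** 2, size=n_win, mode="reflect")
    return np.sqrt(np.maximum(mean_sq, 0.0))


def _freedman_diaconis_bins(values: np.ndarray) -> int:
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return 1
    width = 2 * iqr / values.size ** (1 / 3)
    return max(int(np.ceil((values.max() - values.min()) / width)), 1)


def fit_threshold(rms: np.ndarray, k: float = 3.0) -> float:
    """Variance-dependent threshold from a Gaussian fit to the RMS histogram.

    The histogram is built on the value range [0, mode], i.e. up to the
    location of the global maximum of the RMS histogram; a Gaussian is
    fitted to that restricted range and the threshold is
    ``fitted mean + k * fitted SD``.
    """
    rms = np.asarray(rms, dtype=float)
    if rms.size < 1000:
        raise InsufficientDataError("need >= 1000 RMS samples for threshold fit")
    if np.ptp(rms) == 0:
        raise DegenerateHistogramError("all RMS values identical")
    # locate the histogram mode on a fixed fine grid with light smoothing --
    # the mode position must be stable or the restricted fit below collapses
    hi = np.percentile(rms, 99.5)
    counts, edges = np.histogram(rms, bins=200, range=(rms.min(), hi))
    counts = np.convolve(counts, np.ones(5) / 5.0, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode_value = centers[np.argmax(counts)]
    sel = rms[rms <= mode_value]
    if sel.size < 100:
        # mode at the extreme left; take the lower half instead
        sel = rms[rms <= np.median(rms)]
    nb = min(max(_freedman_diaconis_bins(sel), 4), 400)
    c2, e2 = np.histogram(sel, bins=nb)
    x2 = 0.5 * (e2[:-1] + e2[1:])
    if np.count_nonzero(c2) < 3:
        raise DegenerateHistogramError("restricted RMS histogram is degenerate")

    def gauss(x, a, mu, sd):
        return a * np.exp(-((x - mu) ** 2) / (2 * sd ** 2))

    p0 = (c2.max(), mode_value, max(sel.std(), 1e-12))
    try:
        popt, _ = optimize.curve_fit(gauss, x2, c2, p0=p0, maxfev=5000)
        mu, sd = popt[1], abs(popt[2])
        if not (np.isfinite(mu) and np.isfinite(sd)) or sd == 0:
            raise RuntimeError("non-finite fit")
    except RuntimeError:
        warnings.warn("Gaussian fit failed; falling back to empirical mean + k*SD")
        mu, sd = sel.mean(), sel.std()
    return float(mu + k * sd)


def _intervals_from_mask(mask: np.ndarray, fs: float) -> list[tuple[float, float]]:
    diff = np.diff(mask.astype(np.int8))
    starts = np.nonzero(diff == 1)[0] + 1
    stops = np.nonzero(diff == -1)[0] + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        stops = np.concatenate((stops, [mask.size]))
    return [(s / fs, e / fs) for s, e in zip(starts, stops)]


def merge_close_intervals(spans: list[tuple[float, float]],
                          max_gap: float = 0.2) -> list[tuple[float, float]]:
    """Fuse intervals whose separation is below ``max_gap`` seconds."""
    if not spans:
        return []
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s - merged[-1][1] < max_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def detect_oscillations(rec: Recording, channel: int = 0, *,
                        detection_band: tuple = (1.0, 100.0),
                        amplitude_band: tuple = (4.0, 100.0),
                        rms_window: float = 0.2,
                        threshold_k: float = 3.0,
                        merge_gap: float = 0.2,
                        min_duration: float = 1.0) -> list[OscillatoryEvent]:
    """Detect discontinuous oscillatory events on one channel.

    Returns disjoint, time-sorted events. Amplitude is the maximum absolute
    deflection of the ``amplitude_band``-filtered trace within the event.
    """
    if rec.duration < 60.0:
        raise InsufficientDataError(
            "need >= 60 s of signal for threshold estimation")
    x = rec.samples[channel]
    det = bandpass_array(x, rec.fs, *detection_band)
    rms = compute_rms(det, rec.fs, rms_window)
    thr = fit_threshold(rms, k=threshold_k)
    spans = _intervals_from_mask(rms > thr, rec.fs)
    spans = merge_close_intervals(spans, merge_gap)
    spans = [(s, e) for s, e in spans if e - s > min_duration]
    amp_trace = np.abs(bandpass_array(x, rec.fs, *amplitude_band))
    events = []
    for s, e in spans:
        i0, i1 = int(s * rec.fs), int(e * rec.fs)
        amp = float(amp_trace[i0:i1].max()) if i1 > i0 else 0.0
        events.append(OscillatoryEvent(start=s + rec.t0, stop=e + rec.t0,
                                       peak_amplitude=amp, channel=channel,
                                       region=rec.region))
    _assert_event_rules(events, merge_gap, min_duration)
    return events


def _assert_event_rules(events, merge_gap, min_duration) -> None:
    for prev, nxt in zip(events, events[1:]):
        assert nxt.start - prev.stop >= merge_gap - 1e-9, "events not merged"
    for ev in events:
        assert ev.duration > min_duration - 1e-9, "short event survived filter"


def subtraction_trace(rec: Recording, pyr_channel: int,
                      offset_um: float = 100.0,
                      band: tuple = (1.0, 300.0)) -> np.ndarray:
    """Filtered(above) - filtered(below) trace around the pyramidal channel."""
    if rec.n_channels < 3:
        raise ValueError("need >= 3 channels for the subtraction trace")
    depth = rec.channel_depths[pyr_channel]
    above = rec.channel_at_depth(depth - offset_um)
    below = rec.channel_at_depth(depth + offset_um)
    if above == pyr_channel or below == pyr_channel or above == below:
        warnings.warn("no channels at +/-100 um; using nearest neighbours")
        above = max(pyr_channel - 1, 0)
        below = min(pyr_channel + 1, rec.n_channels - 1)
    hi = min(band[1], 0.45 * rec.fs)
    filt = bandpass_array(rec.samples[[above, below]], rec.fs, band[0], hi)
    return filt[0] - filt[1]


def detect_spws(rec: Recording, pyr_channel: int, *,
                threshold_sd: float = 5.0,
                refractory: float = 0.1,
                offset_um: float = 100.0,
                band: tuple = (1.0, 300.0)) -> list[SPWEvent]:
    """Detect sharp waves as peaks of |subtraction trace| above k*SD.

    Peaks closer than ``refractory`` seconds keep only the larger one.
    """
    d = subtraction_trace(rec, pyr_channel, offset_um, band)
    sd = d.std()
    if sd == 0:
        return []
    thr = threshold_sd * sd
    distance = max(int(refractory * rec.fs), 1)
    peaks, props = signal.find_peaks(np.abs(d), height=thr, distance=distance)
    return [SPWEvent(peak_time=p / rec.fs + rec.t0,
                     amplitude=float(abs(d[p])), pyr_channel=pyr_channel)
            for p in peaks]


def select_pyr_channel(rec: Recording, *, threshold_sd: float = 5.0,
                       band: tuple = (1.0, 300.0)) -> int:
    """Channel maximizing the sharp-wave polarity-reversal score.

    For each candidate channel the SPW-triggered average of its neighbours
    is computed; the score is positive when the average flips sign from the
    channel above to the channel below.
    """
    if rec.n_channels < 3:
        raise ValueError("need >= 3 channels to locate the reversal")
    hi = min(band[1], 0.45 * rec.fs)
    filt = bandpass_array(rec.samples, rec.fs, band[0], hi)
    best_score, best_c = 0.0, None
    half = int(0.05 * rec.fs)
    for c in range(1, rec.n_channels - 1):
        d = filt[c - 1] - filt[c + 1]
        sd = d.std()
        if sd == 0:
            continue
        peaks, _ = signal.find_peaks(np.abs(d), height=threshold_sd * sd,
                                     distance=int(0.1 * rec.fs))
        if peaks.size == 0:
            continue
        peaks = peaks[(peaks > half) & (peaks < rec.n_samples - half)]
        if peaks.size == 0:
            continue
        up = np.mean([filt[c - 1][p] for p in peaks])
        dn = np.mean([filt[c + 1][p] for p in peaks])
        if np.sign(up) != np.sign(dn) and up != 0 and dn != 0:
            score = abs(up - dn) * peaks.size
            if score > best_score:
                best_score, best_c = score, c
    if best_c is None:
        raise NoReversalError(
            "no polarity reversal detected; choose the pyramidal channel manually")
    return best_c
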