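"""Cross-region coupling: imaginary coherence, wavelet denoising, VAR
fitting, generalized partial directed coherence, and cross-correlograms.

Imaginary coherence is computed as the squared imaginary part of the
segment-averaged cross-spectrum normalized by the auto-spectra,
    C_xy(f) = Im(P_xy(f))^2 / (P_xx(f) P_yy(f)),
which discards zero-lag (volume-conducted) synchrony. An unsquared
variant |Im P_xy| / sqrt(P_xx P_yy) is available via ``squared=False``.

gPDC comes from a least-squares vector autoregression: with
Abar(f) = I - sum_r A_r exp(-i 2 pi f r / fs) and noise SDs sigma_k,
    pi_ij(f) = (|Abar_ij(f)| / sigma_i) / sqrt(sum_k |Abar_kj(f)|^2 / sigma_k^2)
so each source column satisfies sum_i pi_ij(f)^2 = 1 identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from statsmodels.tsa.api import VAR

from .core import BandDefinition, bandpass_array
from .spectral import _tapered_ffts, _windows_from_pieces


@dataclass
class CoherenceSpectrum:
    freqs: np.ndarray
    values: np.ndarray  # unitless, NaN where auto-power vanishes

    def __post_init__(self) -> None:
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() >= 1 + 1e-9):
            raise ValueError("coherence values must lie in [0, 1)")


@dataclass
class VarFit:
    coefs: np.ndarray        # (p, k, k), coefs[r][i, j]: j -> i at lag r+1
    sigma: np.ndarray        # (k, k) residual covariance
    order: int
    fs: float

    @property
    def noise_variances(self) -> np.ndarray:
        return np.diag(self.sigma)


@dataclass
class GPDCResult:
    freqs: np.ndarray
    pi: np.ndarray           # (n_freqs, k, k); pi[:, i, j] = strength j -> i
    var_order: int

    def band_mean(self, band: BandDefinition, i: int, j: int) -> float:
        sel = (self.freqs >= band.f_low) & (self.freqs < band.f_high)
        if not np.any(sel):
            raise ValueError(f"band {band.name} outside frequency grid")
        return float(self.pi[sel, i, j].mean())


@dataclass
class CrossCorrelogram:
    lags: np.ndarray         # s, symmetric grid
    values: np.ndarray       # normalized correlation in [-1, 1]

    @property
    def peak_lag(self) -> float:
        return float(self.lags[np.argmax(np.abs(self.values))])

    @property
    def peak_value(self) -> float:
        return float(self.values[np.argmax(np.abs(self.values))])


class UnstableVarError(ValueError):
    """Fitted VAR is not stable (companion spectral radius >= 1)."""


def imaginary_coherence(x: np.ndarray, y: np.ndarray, fs: float,
                        segment_length: float = 1.0,
                        squared: bool = True) -> CoherenceSpectrum:
    """Imaginary coherence from Welch-style segment-averaged spectra."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must be simultaneous and equal-length")
    nperseg = int(round(segment_length * fs))
    if x.size // nperseg < 8:
        raise ValueError("need >= 8 segments")
    wx, _ = _windows_from_pieces([x], nperseg)
    wy, _ = _windows_from_pieces([y], nperseg)
    freqs, sx, _ = _tapered_ffts(wx, fs)
    _, sy, _ = _tapered_ffts(wy, fs)
    pxy = np.mean(sx * np.conj(sy), axis=0)
    pxx = np.mean(np.abs(sx) ** 2, axis=0)
    pyy = np.mean(np.abs(sy) ** 2, axis=0)
    denom = pxx * pyy
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, np.imag(pxy) ** 2 / denom, np.nan)
        if not squared:
            c = np.sqrt(c)
    return CoherenceSpectrum(freqs=freqs, values=c)


# ---------------------------------------------------------------------------
# wavelet denoising (Daubechies-4, periodized pyramid)
# ---------------------------------------------------------------------------

# Daubechies wavelet with 4 vanishing moments (8-tap orthonormal filter)
_D4_LO = np.array([
    0.23037781330885523, 0.7148465705525415, 0.6308807679295904,
    -0.02798376941698385, -0.18703481171888114, 0.030841381835986965,
    0.032883011666982945, -0.010597401784997278,
])
_D4_HI = ((-1.0) ** np.arange(8)) * _D4_LO[::-1]
_NTAP = _D4_LO.size


def _dwt_step(x: np.ndarray):
    n = x.size
    idx = (np.arange(0, n, 2)[:, None] + np.arange(_NTAP)[None, :]) % n
    windows = x[idx]
    return windows @ _D4_LO, windows @ _D4_HI


def _idwt_step(a: np.ndarray, d: np.ndarray) -> np.ndarray:
    n = 2 * a.size
    x = np.zeros(n)
    idx = (np.arange(0, n, 2)[:, None] + np.arange(_NTAP)[None, :]) % n
    for k in range(_NTAP):
        np.add.at(x, idx[:, k], a * _D4_LO[k] + d * _D4_HI[k])
    return x


def wavelet_denoise(x: np.ndarray, levels: int = 5) -> np.ndarray:
    """Soft-threshold wavelet shrinkage (db4, universal threshold).

    The noise SD is the median absolute deviation of the finest detail
    coefficients divided by 0.6745; noise-dominated detail levels are
    soft-thresholded at sigma * sqrt(2 ln n). Levels whose own MAD exceeds
    3x the noise scale are signal-dominated (they carry the band-limited
    oscillation) and are left untouched -- blanket universal thresholding
    would shrink oscillatory coefficients by a large fraction. Input is
    padded (edge-replicated) to the next multiple of 2^levels and trimmed
    after reconstruction.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError("need at least 64 samples for denoising")
    levels = min(levels, int(np.log2(x.size)) - 2)
    n0 = x.size
    block = 2 ** levels
    pad = (-n0) % block
    xp = np.concatenate([x, np.full(pad, x[-1])]) if pad else x.copy()
    approx = xp
    details = []
    for _ in range(levels):
        approx, d = _dwt_step(approx)
        details.append(d)
    noise_mad = np.median(np.abs(details[0]))
    sigma = noise_mad / 0.6745
    thr = sigma * np.sqrt(2 * np.log(xp.size))
    details = [
        d if np.median(np.abs(d)) > 3 * noise_mad
        else np.sign(d) * np.maximum(np.abs(d) - thr, 0.0)
        for d in details
    ]
    for d in reversed(details):
        approx = _idwt_step(approx, d)
    return approx[:n0]


# ---------------------------------------------------------------------------
# VAR + gPDC
# ---------------------------------------------------------------------------


def fit_var(data: np.ndarray, fs: float, max_order: int = 20,
            ic: str = "bic") -> VarFit:
    """Least-squares VAR fit with information-criterion order selection.

    ``data`` is (n_obs, n_channels). The fit must be stable (companion
    matrix spectral radius < 1) and the noise covariance non-singular.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("data must be (n_obs, k>=2)")
    if np.any(data.std(axis=0) == 0):
        raise ValueError("degenerate (constant) channel in VAR input")
    model = VAR(data)
    res = model.fit(maxlags=max_order, ic=ic, trend="c")
    order = res.k_ar
    if order == 0:
        res = model.fit(1, trend="c")
        order = 1
    coefs = res.coefs
    sigma = np.asarray(res.sigma_u)
    if np.linalg.matrix_rank(sigma) < sigma.shape[0]:
        raise ValueError("singular residual covariance")
    k = data.shape[1]
    companion = np.zeros((k * order, k * order))
    companion[:k, :] = np.hstack([coefs[r] for r in range(order)])
    if order > 1:
        companion[k:, :-k] = np.eye(k * (order - 1))
    radius = np.max(np.abs(np.linalg.eigvals(companion)))
    if radius >= 1.0:
        raise UnstableVarError(f"unstable VAR fit (spectral radius {radius:.4f})")
    return VarFit(coefs=coefs, sigma=sigma, order=order, fs=fs)


def gpdc(fit: VarFit, freqs: np.ndarray) -> GPDCResult:
    """Generalized partial directed coherence of a fitted VAR."""
    freqs = np.asarray(freqs, dtype=float)
    p, k, _ = fit.coefs.shape
    sigma2 = fit.noise_variances
    if np.any(sigma2 <= 0):
        raise ValueError("non-positive noise variance")
    inv_sd = 1.0 / np.sqrt(sigma2)
    lags = np.arange(1, p + 1)
    # Abar(f) = I - sum_r A_r e^{-i 2 pi f r / fs}
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags) / fit.fs)  # (nf, p)
    abar = np.eye(k)[None, :, :] - np.einsum("fr,rij->fij", phase, fit.coefs)
    weighted = np.abs(abar) * inv_sd[None, :, None]          # |Abar_ij|/sigma_i
    denom = np.sqrt(np.sum(weighted ** 2, axis=1, keepdims=True))
    pi = weighted / denom
    return GPDCResult(freqs=freqs, pi=pi, var_order=p)


def directed_coupling_report(x: np.ndarray, y: np.ndarray, fs: float,
                             events, bands=None, *,
                             analysis_fs: float = 200.0,
                             max_order: int = 20,
                             denoise: bool = True,
                             min_event_duration: float = 1.0) -> dict:
    """Per-band mean gPDC in both directions over oscillatory segments.

    Each detected oscillatory event is excerpted from both signals,
    decimated to ``analysis_fs``, wavelet-denoised, fitted with a VAR, and
    its gPDC band means averaged across events. Direction keys are
    ``"x->y"`` and ``"y->x"``.
    """
    if bands is None:
        from .core import BETA, THETA
        bands = (THETA, BETA)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    q = int(round(fs / analysis_fs))
    freqs = np.linspace(1.0, analysis_fs / 2 - 5.0, 120)
    per_event = {(band.name, direction): [] for band in bands
                 for direction in ("x->y", "y->x")}
    n_used = 0
    for ev in events:
        if ev.duration < min_event_duration:
            continue
        i0, i1 = int(ev.start * fs), int(ev.stop * fs)
        seg = np.vstack([x[i0:i1], y[i0:i1]])
        if q > 1:
            seg = signal.decimate(seg, q, axis=1, zero_phase=True)
        if denoise and seg.shape[1] >= 64:
            seg = np.vstack([wavelet_denoise(ch) for ch in seg])
        seg = seg - seg.mean(axis=1, keepdims=True)
        if seg.shape[1] < 10 * max_order:
            continue
        try:
            fit = fit_var(seg.T, analysis_fs, max_order=max_order)
            res = gpdc(fit, freqs)
        except (ValueError, np.linalg.LinAlgError):
            continue
        for band in bands:
            per_event[(band.name, "x->y")].append(res.band_mean(band, 1, 0))
            per_event[(band.name, "y->x")].append(res.band_mean(band, 0, 1))
        n_used += 1
    if n_used < 3:
        raise ValueError(f"only {n_used} usable oscillatory segments (need >= 3)")
    out = {"n_segments": n_used}
    for (name, direction), vals in per_event.items():
        out[f"{name}:{direction}"] = float(np.mean(vals))
    return out


def band_crosscorrelation(x: np.ndarray, y: np.ndarray, fs: float,
                          band: BandDefinition,
                          max_lag: float = 0.2) -> CrossCorrelogram:
    """Normalized cross-correlation of band-filtered signals over +/-max_lag.

    Positive peak lag means y lags x (x leads).
    """
    xf = bandpass_array(x, fs, band.f_low, band.f_high)
    yf = bandpass_array(y, fs, band.f_low, band.f_high)
    xf = (xf - xf.mean()) / (xf.std() or 1.0)
    yf = (yf - yf.mean()) / (yf.std() or 1.0)
    n = xf.size
    full = signal.correlate(yf, xf, mode="full") / n
    lags = signal.correlation_lags(n, n, mode="full") / fs
    sel = np.abs(lags) <= max_lag
    return CrossCorrelogram(lags=lags[sel], values=np.clip(full[sel], -1, 1))
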