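"""Resting-state power spectra, power-law fitting and vasomotion peaks.

The resting ΔHbT spectrum follows an approximate power law P = a·f^−β;
after an OLS fit on the log-resampled spectrum the 1/f-like trend is
removed by pre-whitening (dividing by the fitted model) so that narrowband
vasomotion peaks become detectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import windows

__all__ = [
    "PowerLawFit",
    "SpectrumFit",
    "rest_segments",
    "multitaper_psd",
    "log_resample",
    "fit_power_law",
    "prewhiten_and_peak",
    "fit_resting_spectrum",
]


def rest_segments(
    velocity: np.ndarray,
    fs: float,
    trial_bounds: Sequence[tuple[float, float]],
    move_threshold: float = 0.5,
    max_move_fraction: float = 0.10,
) -> list[tuple[float, float]]:
    """Trials qualifying as resting state.

    A trial is kept when the fraction of samples with |velocity| above
    ``move_threshold`` is strictly below ``max_move_fraction``.
    """
    v = np.abs(np.asarray(velocity, float))
    kept = []
    for t0, t1 in trial_bounds:
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        seg = v[i0:i1]
        if len(seg) == 0:
            continue
        if np.mean(seg > move_threshold) < max_move_fraction:
            kept.append((t0, t1))
    return kept


def multitaper_psd(
    trace: np.ndarray,
    fs: float,
    time_bandwidth: float = 2.0,
    n_tapers: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided multitaper PSD using DPSS tapers.

    Eigenvalue-weighted average of tapered periodograms; the trace is
    demeaned first.  ``n_tapers`` above the usable 2·TW−1 limit is clamped
    with a warning.  Normalized as a density: the integral over frequency
    recovers the variance.
    """
    x = np.asarray(trace, float)
    n = len(x)
    if n < 8:
        raise ValueError("trace too short for a multitaper estimate")
    k_max = int(2 * time_bandwidth - 1)
    if n_tapers > k_max:
        warnings.warn(
            f"n_tapers={n_tapers} exceeds 2*TW-1={k_max}; clamping", stacklevel=2
        )
        n_tapers = k_max
    tapers, eig = windows.dpss(n, time_bandwidth, Kmax=n_tapers, return_ratios=True)
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2
    power = (eig[:, None] * spec).sum(axis=0) / eig.sum() / fs
    power *= 2.0  # one-sided
    power[0] /= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return freqs, power


def log_resample(
    freqs: np.ndarray, power: np.ndarray, n_bins: int = 24
) -> tuple[np.ndarray, np.ndarray]:
    """Rebin a spectrum onto logarithmically spaced frequency bins.

    Geometric-mean frequency and arithmetic-mean power per bin; empty bins
    are dropped.  DC must be excluded beforehand (it is dropped here).
    """
    if n_bins < 3:
        raise ValueError("need at least 3 logarithmic bins")
    f = np.asarray(freqs, float)
    p = np.asarray(power, float)
    keep = f > 0
    f, p = f[keep], p[keep]
    if len(f) < n_bins:
        raise ValueError("fewer spectral samples than requested bins")
    edges = np.geomspace(f[0], f[-1], n_bins + 1)
    idx = np.clip(np.searchsorted(edges, f, side="right") - 1, 0, n_bins - 1)
    fo, po = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            fo.append(np.exp(np.log(f[sel]).mean()))
            po.append(p[sel].mean())
    return np.array(fo), np.array(po)


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10 power on log10 frequency: P = a·f^−β."""

    a: float
    beta: float

    def model(self, freqs: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(freqs, float) ** (-self.beta)


def fit_power_law(
    freqs: np.ndarray,
    power: np.ndarray,
    fit_band: tuple[float, float] = (0.005, 1.0),
) -> PowerLawFit:
    """Fit P = a·f^−β by ordinary least squares in log-log space.

    Operates on an (already log-resampled) spectrum; requires at least five
    bins inside ``fit_band``.
    """
    f = np.asarray(freqs, float)
    p = np.asarray(power, float)
    m = (f >= fit_band[0]) & (f <= fit_band[1]) & (p > 0)
    if np.unique(f[m]).size < 2:
        raise ValueError("degenerate spectrum: need at least two distinct frequencies")
    if m.sum() < 5:
        raise ValueError("need at least 5 bins inside the fit band")
    slope, intercept = np.polyfit(np.log10(f[m]), np.log10(p[m]), 1)
    return PowerLawFit(a=10.0**intercept, beta=-slope)


def prewhiten_and_peak(
    freqs: np.ndarray,
    power: np.ndarray,
    fit: PowerLawFit,
    search_band: tuple[float, float] = (0.01, 0.5),
    min_peak_ratio: float = 1.05,
) -> tuple[np.ndarray, float, float, float, bool]:
    """Divide the spectrum by the fitted power-law trend and locate the peak.

    Returns ``(whitened, peak_freq, peak_power, peak_fraction, has_peak)``;
    ``peak_fraction`` is the whitened peak power over the summed whitened
    power across the full range.  ``has_peak`` is False when the whitened
    maximum does not exceed ``min_peak_ratio`` (a pure power law whitens to
    ≈1 everywhere).
    """
    f = np.asarray(freqs, float)
    p = np.asarray(power, float)
    whitened = p / fit.model(f)
    m = (f >= search_band[0]) & (f <= search_band[1])
    if not m.any():
        raise ValueError("empty search band")
    i = np.flatnonzero(m)[np.argmax(whitened[m])]
    peak_freq = float(f[i])
    peak_power = float(whitened[i])
    peak_fraction = peak_power / whitened.sum()
    return whitened, peak_freq, peak_power, peak_fraction, peak_power > min_peak_ratio


@dataclass
class SpectrumFit:
    """Resting-state spectrum with its power-law fit and whitened peak."""

    freqs: np.ndarray
    power: np.ndarray
    a: float
    beta: float
    whitened: np.ndarray
    peak_freq: float
    peak_power: float
    peak_fraction: float
    has_peak: bool
    n_segments: int


def fit_resting_spectrum(
    traces: Sequence[np.ndarray] | np.ndarray,
    fs: float,
    time_bandwidth: float = 2.0,
    n_tapers: int = 3,
    n_bins: int = 24,
    drop_lowest: int = 2,
    fit_band: tuple[float, float] = (0.005, 1.0),
    search_band: tuple[float, float] = (0.01, 0.5),
) -> SpectrumFit:
    """Full resting-state chain: multitaper PSD averaged over equal-length
    rest segments → log resampling → power-law fit → pre-whitened peak.

    The lowest ``drop_lowest`` log bins are excluded from the fit band: the
    spectral estimate is biased where the taper bandwidth is comparable to
    the frequency, and resting spectra roll off below ~0.02 Hz.
    """
    if isinstance(traces, np.ndarray) and traces.ndim == 1:
        traces = [traces]
    psds = []
    freqs = None
    for tr in traces:
        f, p = multitaper_psd(tr, fs, time_bandwidth, n_tapers)
        if freqs is None:
            freqs = f
        elif len(f) != len(freqs):
            raise ValueError("rest segments must have equal length")
        psds.append(p)
    power = np.mean(psds, axis=0)
    fb, pb = log_resample(freqs, power, n_bins)
    fit = fit_power_law(fb[drop_lowest:], pb[drop_lowest:], fit_band)
    whitened, pk_f, pk_p, pk_frac, has_peak = prewhiten_and_peak(
        fb, pb, fit, search_band
    )
    return SpectrumFit(
        freqs=fb, power=pb, a=fit.a, beta=fit.beta, whitened=whitened,
        peak_freq=pk_f, peak_power=pk_p, peak_fraction=pk_frac,
        has_peak=has_peak, n_segments=len(psds),
    )
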