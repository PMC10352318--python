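"""Electrophysiology: filtering, spike detection, rates, spectrograms,
EMG power and current source density."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import butter, oaconvolve, sosfiltfilt
from scipy.signal.windows import gaussian

from .spectral import multitaper_psd

__all__ = [
    "SpikeTrain",
    "bandpass",
    "detect_spikes",
    "spike_rate",
    "mt_spectrogram",
    "normalize_spectrogram",
    "emg_power",
    "band_power_trace",
    "csd_profile",
    "find_layer4",
    "evoked_rates",
]

MUA_BAND = (300.0, 5000.0)
LFP_BAND = (1.0, 100.0)


def bandpass(trace: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, no group delay)."""
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"invalid band ({lo}, {hi}) at fs={fs}")
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(trace, float))


@dataclass
class SpikeTrain:
    spike_times: np.ndarray  # s, sorted
    channel: int = 0
    detection_sd: float = 4.0

    def __len__(self) -> int:
        return len(self.spike_times)


def detect_spikes(
    mua: np.ndarray,
    fs: float,
    threshold_sd: float = 4.0,
    refractory_s: float = 1e-3,
    channel: int = 0,
    robust_sd: bool = False,
) -> SpikeTrain:
    """Threshold crossings of |v − mean| > threshold_sd·SD with a refractory
    period; the first crossing of a violating pair is kept.

    ``robust_sd`` estimates the SD from the median absolute deviation,
    which is insensitive to the spikes themselves.
    """
    v = np.asarray(mua, float)
    mu = v.mean()
    if robust_sd:
        sd = np.median(np.abs(v - np.median(v))) / 0.6744897501960817
    else:
        sd = v.std()
    if sd == 0:
        raise ValueError("zero-variance trace: cannot set a spike threshold")
    above = np.abs(v - mu) > threshold_sd * sd
    # onsets of excursions
    onsets = np.flatnonzero(above & ~np.roll(above, 1))
    if above[0]:
        onsets = np.union1d(onsets, [0])
    times = onsets / fs
    kept = []
    last = -np.inf
    for t in times:
        if t - last >= refractory_s:
            kept.append(t)
            last = t
    return SpikeTrain(np.asarray(kept), channel=channel, detection_sd=threshold_sd)


def spike_rate(
    train: SpikeTrain | np.ndarray,
    duration: float,
    sigma: float = 0.1,
    fs_out: float = 100.0,
) -> np.ndarray:
    """Firing-rate trace (Hz): binarized train convolved with a unit-area
    Gaussian kernel (the trace integrates to the spike count)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    times = train.spike_times if isinstance(train, SpikeTrain) else np.asarray(train)
    n = int(round(duration * fs_out))
    counts = np.zeros(n)
    if len(times):
        idx = np.clip((np.asarray(times) * fs_out).astype(int), 0, n - 1)
        np.add.at(counts, idx, 1.0)
    m = int(np.ceil(4 * sigma * fs_out))
    kern = gaussian(2 * m + 1, sigma * fs_out)
    kern /= kern.sum() / fs_out  # unit area in time
    return np.convolve(counts, kern, mode="same")


def mt_spectrogram(
    lfp: np.ndarray,
    fs: float,
    window_s: float = 5.0,
    step_s: float = 0.5,
    time_bandwidth: float = 2.0,
    n_tapers: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window multitaper spectrogram.

    Returns (times, freqs, power) with times at window centers and power of
    shape (n_freqs, n_windows).
    """
    x = np.asarray(lfp, float)
    w = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if len(x) < w:
        raise ValueError("trace shorter than one window")
    starts = np.arange(0, len(x) - w + 1, step)
    cols = []
    freqs = None
    for s in starts:
        f, p = multitaper_psd(x[s : s + w], fs, time_bandwidth, n_tapers)
        freqs = f
        cols.append(p)
    times = (starts + w / 2) / fs
    return times, freqs, np.column_stack(cols)


def normalize_spectrogram(
    spec: np.ndarray,
    times: np.ndarray,
    baseline_interval: tuple[float, float],
) -> np.ndarray:
    """Per-frequency percent change from the mean power over a baseline
    interval of at least 2 minutes of rest."""
    t0, t1 = baseline_interval
    if t1 - t0 < 120.0:
        raise ValueError("baseline interval must span at least 120 s")
    m = (times >= t0) & (times < t1)
    if not m.any():
        raise ValueError("baseline interval outside the spectrogram")
    base = spec[:, m].mean(axis=1, keepdims=True)
    return 100.0 * (spec - base) / base


def emg_power(
    emg: np.ndarray,
    fs: float,
    band: tuple[float, float] = MUA_BAND,
    sigma_s: float = 0.05,
) -> np.ndarray:
    """EMG power trace: band-pass → rectify → square → Gaussian smooth.

    When the sampling rate cannot carry the nominal 300 Hz–5 kHz band the
    upper edge is clamped just below Nyquist, with a warning.
    """
    lo, hi = band
    nyq = fs / 2
    if hi >= nyq:
        hi = 0.998 * nyq
        warnings.warn(
            f"EMG band clamped to ({lo:g}, {hi:g}) Hz at fs={fs:g}", stacklevel=2
        )
        if lo >= hi:
            lo = hi / 2
    x = bandpass(emg, fs, lo, hi)
    x = np.abs(x) ** 2
    m = int(np.ceil(4 * sigma_s * fs))
    kern = gaussian(2 * m + 1, sigma_s * fs)
    kern /= kern.sum()
    return oaconvolve(x, kern, mode="same")


def band_power_trace(
    lfp: np.ndarray,
    fs: float,
    lo: float,
    hi: float,
    sigma_s: float = 0.5,
) -> np.ndarray:
    """Instantaneous band power: band-pass, square, Gaussian smooth."""
    x = bandpass(lfp, fs, lo, hi) ** 2
    m = int(np.ceil(4 * sigma_s * fs))
    kern = gaussian(2 * m + 1, sigma_s * fs)
    kern /= kern.sum()
    return oaconvolve(x, kern, mode="same")


def csd_profile(laminar_lfp: np.ndarray, channel_spacing: float) -> np.ndarray:
    """Current source density along a laminar probe, sink-positive.

    CSD[i] = (V[i−1] − 2·V[i] + V[i+1]) / Δz² for interior channels, so a
    localized negative-potential trough (an extracellular sink) yields a
    positive value at its channel.  Any depth-affine potential maps to zero.
    """
    v = np.asarray(laminar_lfp, float)
    if v.ndim != 2 or v.shape[0] < 3:
        raise ValueError("need a (channels, time) array with >= 3 channels")
    return (v[:-2] - 2 * v[1:-1] + v[2:]) / channel_spacing**2


def find_layer4(
    csd: np.ndarray,
    fs: float,
    stim_onsets: Sequence[float],
    response_window: tuple[float, float] = (0.0, 0.1),
    sink_fraction: float = 0.5,
) -> int:
    """Layer-4 channel: earliest large stimulus-evoked sink.

    Averages the CSD across stimuli, finds each interior channel's peak
    sink in the response window, and among channels whose peak reaches
    ``sink_fraction`` of the global maximum returns the one with the
    earliest peak (as an index into the original channel array).
    """
    w0 = int(round(response_window[0] * fs))
    w1 = int(round(response_window[1] * fs))
    snips = []
    for t in stim_onsets:
        i = int(round(t * fs))
        if i + w1 <= csd.shape[1] and i + w0 >= 0:
            snips.append(csd[:, i + w0 : i + w1])
    if not snips:
        raise ValueError("no stimulus with full response-window coverage")
    avg = np.mean(snips, axis=0)
    peaks = avg.max(axis=1)
    lat = avg.argmax(axis=1)
    big = np.flatnonzero(peaks >= sink_fraction * peaks.max())
    ch = big[np.argmin(lat[big])]
    return int(ch) + 1  # interior-channel offset


def evoked_rates(
    rate: np.ndarray,
    fs: float,
    stim_onsets: Sequence[float],
    early_window: tuple[float, float] = (0.0, 0.1),
    steady_window: tuple[float, float] = (0.2, 0.5),
    baseline_window: tuple[float, float] = (-1.0, 0.0),
) -> dict[str, float]:
    """Mean firing rate in the early (0–100 ms) and steady-state
    (200–500 ms) post-stimulus windows plus the pre-stimulus baseline,
    averaged over stimuli with full coverage."""
    rate = np.asarray(rate, float)
    out = {"early": [], "steady": [], "baseline": [], "n": 0}
    for t in stim_onsets:
        i = int(round(t * fs))
        wins = {}
        ok = True
        for name, (a, b) in (
            ("early", early_window), ("steady", steady_window),
            ("baseline", baseline_window),
        ):
            j0, j1 = i + int(round(a * fs)), i + int(round(b * fs))
            if j0 < 0 or j1 > len(rate) or j1 <= j0:
                ok = False
                break
            wins[name] = rate[j0:j1].mean()
        if ok:
            for k, v in wins.items():
                out[k].append(v)
            out["n"] += 1
    if out["n"] == 0:
        raise ValueError("no stimulus with full window coverage")
    return {
        "early_hz": float(np.mean(out["early"])),
        "steady_hz": float(np.mean(out["steady"])),
        "baseline_hz": float(np.mean(out["baseline"])),
        "n": out["n"],
    }
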