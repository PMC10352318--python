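"""Seeded generator of synthetic multi-channel recording sessions.

Emulates the statistical structure of head-fixed neonatal mouse
recordings: a semi-Markov arousal-state sequence with age-dependent
architecture, a ΔHbT trace built from state-dependent offsets (smoothed by
an exponential transition kernel), a 1/f^β background, a narrowband
vasomotion component and gamma-variate stimulus-evoked responses, plus raw
nuchal EMG (state-dependent tone, myoclonic twitches), hippocampal LFP
(state-dependent delta/theta/gamma content), treadmill velocity and an air
puff stimulus schedule.  A stimulus delivered during sleep can trigger an
awakening, which inserts a sleep→wake transition into the ground truth
instead of an evoked response.

Every draw goes through an explicit :class:`numpy.random.Generator`; fixing
``GeneratorConfig.seed`` reproduces every channel bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.signal.windows import hann

from . import defaults
from .defaults import AWAKE_STATES
from .session import RecordingSession

__all__ = [
    "StateParams",
    "GeneratorConfig",
    "StimOutcome",
    "GroundTruth",
    "sample_state_sequence",
    "schedule_stimuli",
    "synth_hbt",
    "synth_resting_trace",
    "synth_emg",
    "synth_lfp",
    "synth_velocity",
    "synth_spikes",
    "embed_spike_waveforms",
    "gamma_variate",
    "solve_gamma_shape",
    "power_law_noise",
    "implied_state_fractions",
    "generate_session",
]


@dataclass
class StateParams:
    """Per-state phenomenology of one arousal state.

    Parameters
    ----------
    hbt_offset:
        ΔHbT level (µM) relative to the quiescent-awake reference.
    emg_sigma:
        SD (arbitrary units) of the nuchal EMG noise in this state.
    twitch_rate:
        Poisson rate (events/s) of brief myoclonic EMG transients.
    delta_gain, theta_gain, gamma_gain:
        Unitless multipliers of the LFP band components.
    dwell_median:
        Median (s) of the log-normal bout-duration distribution.
    locomotion_prob:
        Probability per second of nonzero treadmill velocity.
    """

    state_label: str
    hbt_offset: float
    emg_sigma: float
    twitch_rate: float
    delta_gain: float
    theta_gain: float
    gamma_gain: float
    dwell_median: float
    locomotion_prob: float

    def __post_init__(self) -> None:
        if min(self.emg_sigma, self.twitch_rate, self.delta_gain,
               self.theta_gain, self.gamma_gain, self.locomotion_prob) < 0:
            raise ValueError("gains, sigmas and rates must be >= 0")
        if not self.dwell_median > 0:
            raise ValueError("dwell_median must be > 0")
        if not np.isfinite(self.hbt_offset):
            raise ValueError("hbt_offset must be finite")


@dataclass
class GeneratorConfig:
    """Full parameterization of one synthetic session."""

    age_group: str
    duration: float = 3600.0
    fs_hbt: float = 30.0
    fs_raw: float = 1000.0
    state_params: dict[str, StateParams] = field(default_factory=dict)
    transition_matrix: np.ndarray | None = None
    dwell_sigma: float = defaults.DWELL_SIGMA
    beta: float = 1.5
    noise_sigma: float = 4.0
    vasomotion_freq: float = 0.1
    vasomotion_amp: float = 1.0
    vasomotion_drift: float = 0.05
    evoked_template: tuple[float, float, float] = (16.8, 1.23, 1.72)
    p_awaken_given_sleep_stim: float = 0.5
    awaken_latency: float = 1.0
    transition_tau: float = 3.0
    isi_min: float = 60.0
    isi_jitter: float = 10.0
    stim_duration: float = 0.5
    stim_enabled: bool = True
    baseline_rate: float = 50.0
    evoked_rate_early: float = 100.0
    evoked_rate_steady: float = 120.0
    twitch_amp: float = 4.0
    twitch_duration: float = 0.1
    seed: int = 0

    @classmethod
    def for_age(cls, age_group: str, **overrides) -> "GeneratorConfig":
        """Build the default configuration for an age group.

        The defaults encode the published study conditions for that age
        (state offsets, architecture, evoked template, β, vasomotion,
        firing rates); any field can be overridden by keyword.
        """
        if age_group not in defaults.AGE_GROUPS:
            raise ValueError(f"unknown age group {age_group!r}")
        params = {}
        for label, row in defaults._STATE_TABLES[age_group].items():
            params[label] = StateParams(label, *row)
        rates = defaults.FIRING_RATES[age_group]
        vfreq, vamp = defaults.VASOMOTION[age_group]
        cfg = cls(
            age_group=age_group,
            state_params=params,
            transition_matrix=defaults.TRANSITION_MATRICES[age_group].copy(),
            beta=defaults.BETA[age_group],
            noise_sigma=defaults.NOISE_SIGMA[age_group],
            vasomotion_freq=vfreq,
            vasomotion_amp=vamp,
            evoked_template=defaults.EVOKED_TEMPLATES[age_group],
            p_awaken_given_sleep_stim=defaults.P_AWAKEN[age_group],
            baseline_rate=rates[0],
            evoked_rate_early=rates[1],
            evoked_rate_steady=rates[2],
        )
        for key, val in overrides.items():
            if not hasattr(cfg, key):
                raise TypeError(f"unknown config field {key!r}")
            setattr(cfg, key, val)
        cfg.validate()
        return cfg

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(self.state_params)

    def validate(self) -> None:
        if not 0.0 <= self.p_awaken_given_sleep_stim <= 1.0:
            raise ValueError("p_awaken_given_sleep_stim must be in [0, 1]")
        if self.fs_raw < 2 * 100.0:
            raise ValueError("fs_raw must be at least twice the highest LFP band edge")
        if self.noise_sigma < 0 or self.vasomotion_amp < 0:
            raise ValueError("variance parameters must be >= 0")
        P = np.asarray(self.transition_matrix, float)
        k = len(self.states)
        if P.shape != (k, k):
            raise ValueError("transition matrix shape must match state set")
        if (P < 0).any():
            raise ValueError("transition matrix must be nonnegative")
        # a state with neither inflow nor outflow can never occur
        for i in range(k):
            if P[i].sum() == 0 and P[:, i].sum() == 0:
                raise ValueError(f"state {self.states[i]!r} is unreachable")
        if not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must be stochastic")


@dataclass
class StimOutcome:
    """Ground-truth record of one stimulus: its pre-stimulus state, whether
    it triggered an awakening, and whether an evoked template was added."""

    t: float
    pre_state: str
    awakened: bool
    evoked: bool


@dataclass
class GroundTruth:
    """True state sequence and stimulus outcomes of a synthetic session."""

    state_sequence: list[tuple[str, float, float]]
    hbt_offsets: dict[str, float]
    stim_outcomes: list[StimOutcome]
    duration: float

    def label_at(self, t: float) -> str:
        for label, start, end in self.state_sequence:
            if start <= t < end:
                return label
        return self.state_sequence[-1][0]

    def to_hypnogram_labels(self, bin_s: float = 5.0) -> np.ndarray:
        """Majority ground-truth label per bin (oracle for scoring)."""
        n_bins = int(self.duration // bin_s)
        labels = np.empty(n_bins, dtype=object)
        overlap: list[dict[str, float]] = [dict() for _ in range(n_bins)]
        for label, start, end in self.state_sequence:
            b0 = max(int(start // bin_s), 0)
            b1 = min(int(np.ceil(end / bin_s)), n_bins)
            for b in range(b0, b1):
                lo, hi = b * bin_s, (b + 1) * bin_s
                ov = min(end, hi) - max(start, lo)
                if ov > 0:
                    overlap[b][label] = overlap[b].get(label, 0.0) + ov
        for b in range(n_bins):
            labels[b] = max(overlap[b], key=overlap[b].get)
        return labels

    def to_json(self) -> str:
        return json.dumps(
            {
                "state_sequence": self.state_sequence,
                "hbt_offsets": self.hbt_offsets,
                "stim_outcomes": [asdict(s) for s in self.stim_outcomes],
                "duration": self.duration,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            state_sequence=[tuple(iv) for iv in d["state_sequence"]],
            hbt_offsets=d["hbt_offsets"],
            stim_outcomes=[StimOutcome(**s) for s in d["stim_outcomes"]],
            duration=d["duration"],
        )


def implied_state_fractions(config: GeneratorConfig) -> dict[str, float]:
    """Long-run time-in-state fractions implied by the configuration.

    For a semi-Markov process the fraction of time in state *i* is
    π_i·E[dwell_i] normalized, with π the stationary distribution of the
    embedded chain and E[dwell] = median·exp(σ²/2) for the log-normal law.
    """
    P = np.asarray(config.transition_matrix, float)
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    pi = np.abs(pi) / np.abs(pi).sum()
    means = np.array(
        [config.state_params[s].dwell_median for s in config.states]
    ) * np.exp(config.dwell_sigma**2 / 2)
    f = pi * means
    f /= f.sum()
    return dict(zip(config.states, f))


def schedule_stimuli(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Air-puff onset times: inter-onset gaps of isi_min plus uniform jitter.

    The schedule leaves a 20-s tail margin so every stimulus has full
    peri-stimulus coverage.
    """
    rng = np.random.default_rng() if rng is None else rng
    onsets = []
    t = 20.0 + rng.uniform(0.0, config.isi_jitter)
    while t < config.duration - 20.0:
        onsets.append(t)
        t += config.isi_min + rng.uniform(0.0, config.isi_jitter)
    return np.asarray(onsets)


_SLEEP_LABELS = frozenset({"NREM", "REM", "active_asleep", "quiescent_asleep"})


def sample_state_sequence(
    config: GeneratorConfig,
    stim_onsets: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Draw the semi-Markov arousal-state sequence, with stimulus-triggered
    awakenings folded in.

    The chain is simulated forward in a single pass.  When a stimulus falls
    inside a sleep bout, an awakening is drawn with probability
    ``p_awaken_given_sleep_stim``; on success the bout is truncated at
    onset + ``awaken_latency`` and the chain resumes in ``active_awake``.
    Stimuli delivered in an awake state are marked for an evoked response.
    """
    config.validate()
    rng = np.random.default_rng() if rng is None else rng
    states = config.states
    P = np.asarray(config.transition_matrix, float)
    k = len(states)

    w, v = np.linalg.eig(P.T)
    pi = np.abs(np.real(v[:, np.argmin(np.abs(w - 1.0))]))
    pi /= pi.sum()
    current = int(rng.choice(k, p=pi))

    def draw_dwell(i: int) -> float:
        if np.isclose(P[i, i], 1.0):  # absorbing
            return config.duration
        med = config.state_params[states[i]].dwell_median
        return float(rng.lognormal(np.log(med), config.dwell_sigma))

    def draw_next(i: int) -> int:
        return int(rng.choice(k, p=P[i]))

    stims = sorted(float(t) for t in (stim_onsets if stim_onsets is not None else []))
    intervals: list[tuple[str, float, float]] = []
    outcomes: list[StimOutcome] = []
    t0, j = 0.0, 0
    while t0 < config.duration:
        end = t0 + draw_dwell(current)
        interrupted = False
        while j < len(stims) and stims[j] < min(end, config.duration):
            t_s = stims[j]
            pre = states[current]
            if pre in _SLEEP_LABELS and rng.random() < config.p_awaken_given_sleep_stim:
                t_cut = t_s + config.awaken_latency
                if t_cut < end:
                    outcomes.append(StimOutcome(t_s, pre, True, False))
                    j += 1
                    intervals.append((pre, t0, min(t_cut, config.duration)))
                    t0 = t_cut
                    current = states.index("active_awake")
                    interrupted = True
                    break
                outcomes.append(StimOutcome(t_s, pre, False, False))
            else:
                outcomes.append(StimOutcome(t_s, pre, False, pre in AWAKE_STATES))
            j += 1
        if interrupted:
            continue
        intervals.append((states[current], t0, min(end, config.duration)))
        t0 = end
        if t0 < config.duration:
            current = draw_next(current)

    offsets = {s: config.state_params[s].hbt_offset for s in states}
    return GroundTruth(intervals, offsets, outcomes, config.duration)


# ---------------------------------------------------------------------------
# channel synthesis

def power_law_noise(
    n: int, fs: float, beta: float, rng: np.random.Generator, sigma: float = 1.0
) -> np.ndarray:
    """1/f^β noise synthesized in the frequency domain.

    Fourier amplitudes follow f^(−β/2) with independent Gaussian phases,
    floored below 1/duration so the variance stays finite; the realization
    is rescaled to RMS ``sigma``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0 or n == 0:
        return np.zeros(n)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    floor = fs / n
    amp = np.where(f > 0, np.maximum(f, floor) ** (-beta / 2.0), 0.0)
    z = rng.standard_normal(len(f)) + 1j * rng.standard_normal(len(f))
    x = np.fft.irfft(amp * z, n)
    sd = x.std()
    return x * (sigma / sd) if sd > 0 else x


def _vasomotion(
    n: int, fs: float, f0: float, amp: float, drift: float, rng: np.random.Generator
) -> np.ndarray:
    # fixed-amplitude sinusoid whose phase diffuses slowly: concentrates
    # power in a narrow band around f0 while staying "sinusoid-like"
    if amp == 0 or n == 0:
        return np.zeros(n)
    dphi = 2 * np.pi * f0 / fs + (
        2 * np.pi * drift * f0 / np.sqrt(fs)
    ) * rng.standard_normal(n)
    return amp * np.sin(np.cumsum(dphi) + rng.uniform(0, 2 * np.pi))


def _gamma_fwhm(alpha: float, tp: float) -> float:
    # FWHM of h(t) = (t/tp)^a exp(a(1-t/tp)), peak 1 at tp; log-space for
    # numerical range
    def logh(t):
        x = t / tp
        return alpha * (np.log(x) + 1.0 - x)

    target = np.log(0.5)
    lo = brentq(lambda t: logh(t) - target, 1e-12 * tp, tp)
    upper = 2.0 * tp
    while logh(upper) > target:
        upper *= 2.0
    hi = brentq(lambda t: logh(t) - target, tp, upper)
    return hi - lo


def solve_gamma_shape(time_to_peak: float, fwhm: float) -> float:
    """Shape parameter of the gamma-variate with the requested peak time
    and width (FWHM/tp fixes the shape uniquely; solved by bisection)."""
    return brentq(lambda a: _gamma_fwhm(a, time_to_peak) - fwhm, 0.05, 500.0)


def gamma_variate(
    peak_amp: float, time_to_peak: float, fwhm: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Evoked-response template h(t), zero for t <= 0, peaking at
    ``time_to_peak`` with amplitude ``peak_amp`` and the given FWHM."""
    alpha = solve_gamma_shape(time_to_peak, fwhm)

    def h(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        out = np.zeros_like(t)
        pos = t > 0
        x = t[pos] / time_to_peak
        out[pos] = peak_amp * x**alpha * np.exp(alpha * (1 - x))
        return out

    return h


def _state_index_series(
    truth: GroundTruth, config: GeneratorConfig, fs: float
) -> np.ndarray:
    n = int(round(truth.duration * fs))
    idx = np.zeros(n, dtype=np.intp)
    order = {s: i for i, s in enumerate(config.states)}
    for label, start, end in truth.state_sequence:
        # sample i belongs to the interval containing time i/fs
        i0 = int(np.ceil(start * fs - 1e-9))
        i1 = min(int(np.ceil(end * fs - 1e-9)), n)
        idx[i0:i1] = order[label]
    return idx


def synth_hbt(
    truth: GroundTruth,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    add_noise: bool = True,
    add_vasomotion: bool = True,
) -> np.ndarray:
    """ΔHbT trace (µM, at fs_hbt): smoothed state offsets + 1/f^β background
    + vasomotion + evoked templates for stimuli delivered while awake."""
    config.validate()
    rng = np.random.default_rng() if rng is None else rng
    fs = config.fs_hbt
    n = int(round(truth.duration * fs))
    offsets = np.array(
        [truth.hbt_offsets[config.states[i]] for i in _state_index_series(truth, config, fs)]
    )
    # exponential relaxation toward the current state offset
    a = 1.0 - np.exp(-1.0 / (config.transition_tau * fs))
    trace, _ = lfilter([a], [1.0, a - 1.0], offsets, zi=[(1 - a) * offsets[0]])

    if truth.stim_outcomes and any(o.evoked for o in truth.stim_outcomes):
        h = gamma_variate(*config.evoked_template)
        t = np.arange(n) / fs
        span = int(round(30.0 * fs))
        for o in truth.stim_outcomes:
            if not o.evoked:
                continue
            i0 = int(np.floor(o.t * fs))
            i1 = min(i0 + span, n)
            trace[i0:i1] += h(t[i0:i1] - o.t)

    if add_noise and config.noise_sigma > 0:
        trace = trace + power_law_noise(n, fs, config.beta, rng, config.noise_sigma)
    if add_vasomotion and config.vasomotion_amp > 0:
        trace = trace + _vasomotion(
            n, fs, config.vasomotion_freq, config.vasomotion_amp,
            config.vasomotion_drift, rng,
        )
    return trace


def synth_resting_trace(
    config: GeneratorConfig,
    duration: float,
    rng: np.random.Generator | None = None,
    add_vasomotion: bool = True,
) -> np.ndarray:
    """Resting-state ΔHbT: 1/f^β background plus vasomotion, no state
    dynamics or stimuli (what a still, quietly awake animal would show)."""
    rng = np.random.default_rng() if rng is None else rng
    n = int(round(duration * config.fs_hbt))
    x = power_law_noise(n, config.fs_hbt, config.beta, rng, config.noise_sigma)
    if add_vasomotion:
        x = x + _vasomotion(
            n, config.fs_hbt, config.vasomotion_freq, config.vasomotion_amp,
            config.vasomotion_drift, rng,
        )
    return x


def synth_emg(
    truth: GroundTruth,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Raw nuchal EMG at fs_raw: state-dependent Gaussian tone plus Poisson
    myoclonic twitches (brief Hann-windowed high-amplitude bursts)."""
    rng = np.random.default_rng() if rng is None else rng
    fs = config.fs_raw
    idx = _state_index_series(truth, config, fs)
    sigmas = np.array([config.state_params[s].emg_sigma for s in config.states])
    emg = sigmas[idx] * rng.standard_normal(len(idx))
    burst_len = max(int(round(config.twitch_duration * fs)), 2)
    env = hann(burst_len)
    for label, start, end in truth.state_sequence:
        rate = config.state_params[label].twitch_rate
        if rate <= 0:
            continue
        count = rng.poisson(rate * (end - start))
        for t_tw in rng.uniform(start, end, size=count):
            i0 = int(t_tw * fs)
            i1 = min(i0 + burst_len, len(emg))
            emg[i0:i1] += (
                env[: i1 - i0] * config.twitch_amp * rng.standard_normal(i1 - i0)
            )
    return emg


_LFP_BANDS = {"delta": (1.0, 4.0, 1.0), "theta": (4.0, 10.0, 0.8), "gamma": (40.0, 100.0, 0.5)}


def _band_noise(n, fs, lo, hi, rng):
    f = np.fft.rfftfreq(n, 1.0 / fs)
    z = rng.standard_normal(len(f)) + 1j * rng.standard_normal(len(f))
    z[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(z, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def synth_lfp(
    truth: GroundTruth,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Raw hippocampal LFP at fs_raw: sum of band-limited noise components
    (delta 1–4, theta 4–10, gamma 40–100 Hz) scaled by per-state gains."""
    rng = np.random.default_rng() if rng is None else rng
    fs = config.fs_raw
    for name, (lo, hi, _) in _LFP_BANDS.items():
        if hi >= fs / 2:
            raise ValueError(f"{name} band edge {hi} Hz >= Nyquist ({fs / 2} Hz)")
    idx = _state_index_series(truth, config, fs)
    n = len(idx)
    lfp = np.zeros(n)
    gain_attr = {"delta": "delta_gain", "theta": "theta_gain", "gamma": "gamma_gain"}
    for name, (lo, hi, base) in _LFP_BANDS.items():
        gains = np.array(
            [getattr(config.state_params[s], gain_attr[name]) for s in config.states]
        )
        lfp += base * gains[idx] * _band_noise(n, fs, lo, hi, rng)
    return lfp


def synth_velocity(
    truth: GroundTruth,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Treadmill velocity (cm/s at fs_hbt): per-second Bernoulli locomotion
    blocks with rate locomotion_prob in each state, zero otherwise."""
    rng = np.random.default_rng() if rng is None else rng
    fs = config.fs_hbt
    n = int(round(truth.duration * fs))
    n_sec = int(np.ceil(truth.duration))
    sec_state = _state_index_series(truth, config, 1.0)
    if len(sec_state) < n_sec:
        sec_state = np.pad(sec_state, (0, n_sec - len(sec_state)), mode="edge")
    probs = np.array([config.state_params[s].locomotion_prob for s in config.states])
    moving = rng.random(n_sec) < probs[sec_state]
    speeds = np.abs(rng.normal(10.0, 3.0, size=n_sec)) * moving
    sec_of_sample = np.minimum((np.arange(n) / fs).astype(int), n_sec - 1)
    v = speeds[sec_of_sample]
    # movement stops the moment a non-locomotor state begins: gate each
    # sample by its own state so bouts do not leak across boundaries
    sample_state = _state_index_series(truth, config, fs)
    v[probs[sample_state] <= 0] = 0.0
    return v


def synth_spikes(
    config: GeneratorConfig,
    duration: float,
    stim_onsets: Sequence[float] = (),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Multiunit spike times from an inhomogeneous Poisson process.

    Rate is ``baseline_rate`` except during stimuli: ``evoked_rate_early``
    over the first 100 ms and ``evoked_rate_steady`` for the remainder of
    the 0.5-s puff.  No dead time is imposed: multiunit activity pools many
    neurons, so near-coincident events are genuine; the refractory rule
    belongs to threshold detection.
    """
    rng = np.random.default_rng() if rng is None else rng
    edges = [0.0]
    rates = []
    t_prev = 0.0
    for on in sorted(stim_onsets):
        if on >= duration:
            continue
        e0, e1 = on, min(on + 0.1, duration)
        s1 = min(on + config.stim_duration, duration)
        if e0 > t_prev:
            rates.append(config.baseline_rate)
            edges.append(e0)
        rates.append(config.evoked_rate_early)
        edges.append(e1)
        if s1 > e1:
            rates.append(config.evoked_rate_steady)
            edges.append(s1)
        t_prev = edges[-1]
    if t_prev < duration:
        rates.append(config.baseline_rate)
        edges.append(duration)
    times = []
    for (t0, t1), r in zip(zip(edges[:-1], edges[1:]), rates):
        if r <= 0:
            continue
        count = rng.poisson(r * (t1 - t0))
        times.append(rng.uniform(t0, t1, size=count))
    if not times:
        return np.array([])
    return np.sort(np.concatenate(times))


def embed_spike_waveforms(
    spike_times: np.ndarray,
    duration: float,
    fs: float,
    noise_sd: float = 1.0,
    spike_amp: float = 10.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Voltage trace with biphasic ~1-ms spike waveforms in Gaussian noise
    (to exercise threshold-based spike detection)."""
    rng = np.random.default_rng() if rng is None else rng
    n = int(round(duration * fs))
    v = noise_sd * rng.standard_normal(n)
    w_len = max(int(round(1e-3 * fs)), 3)
    tw = np.arange(w_len) / fs
    wave = -np.sin(2 * np.pi * tw / 1e-3) * hann(w_len)
    wave *= spike_amp * noise_sd / np.abs(wave).max()
    for ts in spike_times:
        i0 = int(ts * fs)
        i1 = min(i0 + w_len, n)
        v[i0:i1] += wave[: i1 - i0]
    return v


def generate_session(
    config: GeneratorConfig,
) -> tuple[RecordingSession, GroundTruth]:
    """Generate a full synthetic recording session and its ground truth.

    Independent random streams (spawned from ``config.seed``) drive the
    stimulus schedule, state sequence and each channel, so the session is
    bit-reproducible under a fixed seed.
    """
    config.validate()
    r_stim, r_state, r_hbt, r_emg, r_lfp, r_vel = np.random.default_rng(
        config.seed
    ).spawn(6)
    stims = schedule_stimuli(config, r_stim) if config.stim_enabled else np.array([])
    truth = sample_state_sequence(config, stim_onsets=stims, rng=r_state)
    session = RecordingSession(
        hbt=synth_hbt(truth, config, r_hbt),
        fs_hbt=config.fs_hbt,
        emg=synth_emg(truth, config, r_emg),
        lfp=synth_lfp(truth, config, r_lfp),
        fs_raw=config.fs_raw,
        velocity=synth_velocity(truth, config, r_vel),
        stim_onsets=stims,
        age_group=config.age_group,
        duration=config.duration,
    )
    session.validate()
    return session, truth
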