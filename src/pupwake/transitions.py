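"""Transition-triggered and stimulus-triggered ΔHbT analyses.

Arousal-state transitions qualify when flanked by at least 15 s in both
the preceding and following state.  Each event carries the mean ΔHbT over
the baseline window [t−15, t−5) and the response window [t+5, t+15)
around the boundary time t, and their difference (the transition delta):
sleep→wake transitions drive large negative deltas (vasoconstriction on
awakening), wake→sleep transitions large positive ones.

Stimulus-triggered analyses split evoked responses by the arousal state of
the bin immediately preceding each onset, and track the peri-stimulus
probability of being awake.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .defaults import AWAKE_STATES
from .hemo import PeriStimulusAverage, evoked_average
from .scoring import Hypnogram, extract_bouts

__all__ = [
    "TransitionEvent",
    "StateSplitEvoked",
    "find_transitions",
    "group_transitions",
    "peri_transition_average",
    "transition_stats",
    "split_stimuli_by_state",
    "evoked_by_state",
    "peristim_awake_probability",
]


@dataclass
class TransitionEvent:
    """A qualified arousal-state change with its window means (µM)."""

    from_state: str
    to_state: str
    t: float
    baseline_mean: float
    response_mean: float

    @property
    def delta(self) -> float:
        return self.response_mean - self.baseline_mean


def _window_mean(trace: np.ndarray, fs: float, t: float, lo: float, hi: float) -> float:
    i0 = int(round((t + lo) * fs))
    i1 = int(round((t + hi) * fs))
    return float(trace[i0:i1].mean())


def find_transitions(
    hypnogram: Hypnogram,
    hbt: np.ndarray,
    fs_hbt: float,
    min_pre: float = 15.0,
    min_post: float = 15.0,
    baseline_window: tuple[float, float] = (-15.0, -5.0),
    response_window: tuple[float, float] = (5.0, 15.0),
) -> list[TransitionEvent]:
    """Qualified transitions: one event per bout boundary with ≥ ``min_pre``
    s in the preceding state, ≥ ``min_post`` s in the following state, and
    both windows fully inside the recording."""
    hbt = np.asarray(hbt, float)
    events = []
    bouts = extract_bouts(hypnogram)
    dur = len(hbt) / fs_hbt
    for prev, nxt in zip(bouts[:-1], bouts[1:]):
        if prev.duration < min_pre or nxt.duration < min_post:
            continue
        t = prev.end
        if t + baseline_window[0] < 0 or t + response_window[1] > dur:
            continue
        events.append(
            TransitionEvent(
                prev.state,
                nxt.state,
                t,
                _window_mean(hbt, fs_hbt, t, *baseline_window),
                _window_mean(hbt, fs_hbt, t, *response_window),
            )
        )
    return events


def group_transitions(
    events: Sequence[TransitionEvent],
) -> dict[tuple[str, str], list[TransitionEvent]]:
    groups: dict[tuple[str, str], list[TransitionEvent]] = defaultdict(list)
    for ev in events:
        groups[(ev.from_state, ev.to_state)].append(ev)
    return dict(groups)


def peri_transition_average(
    hbt: np.ndarray,
    fs_hbt: float,
    events: Sequence[TransitionEvent],
    window_s: float = 30.0,
) -> PeriStimulusAverage:
    """Mean ± SD ΔHbT aligned at the transition time, in raw µM relative to
    the session reference (no per-event baseline correction)."""
    hbt = np.asarray(hbt, float)
    w = int(round(window_s * fs_hbt))
    snips = []
    for ev in events:
        i = int(round(ev.t * fs_hbt))
        if i - w >= 0 and i + w <= len(hbt):
            snips.append(hbt[i - w : i + w])
    if not snips:
        raise ValueError("no transition events with full window coverage")
    arr = np.vstack(snips)
    time = np.arange(-w, w) / fs_hbt
    return PeriStimulusAverage(time, arr.mean(0), arr.std(0), len(snips), fs_hbt)


def transition_stats(events: Sequence[TransitionEvent]) -> pd.DataFrame:
    """Per transition-type mean ± SD delta and count.

    Types with a single event report SD as NaN (flagged by ``n``); rare
    transitions are reported with their n rather than suppressed.
    """
    groups = group_transitions(events)
    if not groups:
        raise ValueError("no transition events to summarize")
    rows = []
    for (a, b), evs in sorted(groups.items()):
        deltas = np.array([e.delta for e in evs])
        rows.append(
            {
                "from_state": a,
                "to_state": b,
                "mean_delta_uM": deltas.mean(),
                "sd_delta_uM": deltas.std(ddof=1) if len(deltas) > 1 else float("nan"),
                "n": len(deltas),
            }
        )
    return pd.DataFrame(rows)


def split_stimuli_by_state(
    stim_onsets: Sequence[float], hypnogram: Hypnogram
) -> list[tuple[float, str]]:
    """Label each stimulus with the state of the bin immediately preceding
    its onset (the onset bin itself may already contain the
    stimulus-triggered awakening).  Onsets in the first bin or outside the
    scored span are excluded."""
    labeled = []
    for t in stim_onsets:
        b = int(t // hypnogram.bin_s) - 1
        if 0 <= b < hypnogram.n_bins:
            labeled.append((float(t), hypnogram.labels[b]))
    return labeled


@dataclass
class StateSplitEvoked:
    """Per-state stimulus-triggered average."""

    state: str
    peri: PeriStimulusAverage
    n_stimuli: int
    reported: bool = True


def evoked_by_state(
    hbt: np.ndarray,
    fs_hbt: float,
    labeled_onsets: Sequence[tuple[float, str]],
    pre_s: float = 5.0,
    post_s: float = 20.0,
    baseline_window: tuple[float, float] = (-3.0, 0.0),
    min_n: int = 3,
) -> dict[str, StateSplitEvoked]:
    """Evoked averages split by pre-stimulus state plus the pooled average.

    States with fewer than ``min_n`` stimuli are returned with
    ``reported=False`` and excluded from the pooled average, which is the
    count-weighted mean of the reported per-state averages (key ``"all"``).
    """
    by_state: dict[str, list[float]] = defaultdict(list)
    for t, s in labeled_onsets:
        by_state[s].append(t)
    out: dict[str, StateSplitEvoked] = {}
    pooled_onsets: list[float] = []
    for s, onsets in sorted(by_state.items()):
        peri = evoked_average(hbt, fs_hbt, onsets, pre_s, post_s, baseline_window)
        reported = peri.n >= min_n
        out[s] = StateSplitEvoked(s, peri, peri.n, reported)
        if reported:
            pooled_onsets.extend(onsets)
    if pooled_onsets:
        peri_all = evoked_average(
            hbt, fs_hbt, pooled_onsets, pre_s, post_s, baseline_window
        )
        out["all"] = StateSplitEvoked("all", peri_all, peri_all.n)
    return out


def peristim_awake_probability(
    hypnogram: Hypnogram,
    stim_onsets: Sequence[float],
    window_s: float = 30.0,
) -> pd.DataFrame:
    """Probability of being awake/asleep vs peri-stimulus time.

    For each stimulus with full window coverage, the hypnogram label is
    sampled at bin resolution over ±``window_s``; P(awake) is the fraction
    of stimuli whose label at that lag is an awake state, and
    P(awake) + P(asleep) = 1 at every lag.
    """
    bs = hypnogram.bin_s
    lags = np.arange(-window_s, window_s, bs) + bs / 2
    rows = []
    used = 0
    counts = np.zeros(len(lags))
    for t in stim_onsets:
        if t - window_s < 0 or t + window_s > hypnogram.duration:
            continue
        used += 1
        for k, lag in enumerate(lags):
            if hypnogram.label_at(t + lag) in AWAKE_STATES:
                counts[k] += 1
    if used == 0:
        raise ValueError("no stimulus with full peri-stimulus coverage")
    p_awake = counts / used
    return pd.DataFrame(
        {"lag_s": lags, "p_awake": p_awake, "p_asleep": 1.0 - p_awake,
         "n": used}
    )
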