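"""Rule-based arousal-state scoring in 5-s bins.

Automates manual sleep scoring from nuchal EMG power, hippocampal LFP band
powers and locomotion.  The decision tree mirrors the manual criteria:
locomotion ⇒ active awake; muscle tone without locomotion ⇒ quiescent
awake; atonia with elevated delta and without theta/gamma ⇒ NREM (P15,
adult); atonia with elevated theta×gamma (and myoclonic twitching) ⇒ REM
at P15/adult or active sleep at P10; remaining atonic bins ⇒ quiescent
sleep at P10.

Thresholds default to per-session estimates: the atonia and theta×gamma
cutoffs are placed by exact Otsu thresholding of the (bimodal) log-feature
distributions, which makes no assumption about how much of the session was
spent asleep.  Fixed-percentile cutoffs are available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .defaults import STATE_SETS

__all__ = [
    "Hypnogram",
    "Bout",
    "ScoringThresholds",
    "bimodal_threshold",
    "bin_features",
    "classify_bins",
    "extract_bouts",
    "state_fractions",
    "bout_survival",
    "hypnogram_accuracy",
]


@dataclass
class Hypnogram:
    """Per-bin arousal-state labels with an age-specific label set."""

    labels: np.ndarray  # dtype=object, one label per bin
    bin_s: float
    age_group: str

    def __post_init__(self) -> None:
        allowed = set(STATE_SETS[self.age_group])
        bad = set(np.unique(self.labels)) - allowed
        if bad:
            raise ValueError(f"labels {bad} not in the {self.age_group} label set")

    @property
    def n_bins(self) -> int:
        return len(self.labels)

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_s

    def label_at(self, t: float) -> str:
        i = int(t // self.bin_s)
        if not 0 <= i < self.n_bins:
            raise IndexError(f"time {t} outside the scored span")
        return self.labels[i]

    def to_frame(self) -> pd.DataFrame:
        starts = np.arange(self.n_bins) * self.bin_s
        return pd.DataFrame(
            {"bin_start_s": starts, "bin_end_s": starts + self.bin_s,
             "label": self.labels}
        )


@dataclass
class Bout:
    """Maximal run of one state; adjacent bouts have different states."""

    state: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def bimodal_threshold(x: np.ndarray) -> float:
    """Exact Otsu threshold of a 1-D sample: the split minimizing the
    total within-class variance, returned as the midpoint between the two
    classes' nearest members."""
    x = np.sort(np.asarray(x, float))
    n = len(x)
    if n < 2 or x[0] == x[-1]:
        return float(x[0]) if n else float("nan")
    csum = np.cumsum(x)
    csq = np.cumsum(x**2)
    ks = np.arange(1, n)
    var_lo = csq[ks - 1] - csum[ks - 1] ** 2 / ks
    sum_hi = csum[-1] - csum[ks - 1]
    var_hi = (csq[-1] - csq[ks - 1]) - sum_hi**2 / (n - ks)
    k = int(ks[np.argmin(var_lo + var_hi)])
    return float((x[k - 1] + x[k]) / 2)


def bin_features(
    emg_power: np.ndarray,
    delta: np.ndarray,
    theta: np.ndarray,
    gamma: np.ndarray,
    velocity: np.ndarray,
    fs_power: float,
    fs_velocity: float,
    bin_s: float = 5.0,
    move_threshold: float = 0.5,
    twitch_percentile: float = 95.0,
) -> pd.DataFrame:
    """Per-bin median features for scoring.

    All power traces must share ``fs_power`` and the same duration as the
    velocity trace (within one bin).  Columns: median EMG power and band
    powers, fraction of moving samples, and the count of brief (<1 s)
    EMG-power excursions above the session's ``twitch_percentile``.
    A final bin truncated by the session end is dropped.
    """
    traces = {"emg": emg_power, "delta": delta, "theta": theta, "gamma": gamma}
    durs = {k: len(v) / fs_power for k, v in traces.items()}
    durs["velocity"] = len(velocity) / fs_velocity
    if max(durs.values()) - min(durs.values()) > bin_s:
        raise ValueError(f"misaligned inputs: channel durations {durs}")
    n_bins = int(min(durs.values()) // bin_s)
    npb = int(round(bin_s * fs_power))
    npv = int(round(bin_s * fs_velocity))

    def per_bin_median(x, npts):
        return np.median(x[: n_bins * npts].reshape(n_bins, npts), axis=1)

    feats = {k: per_bin_median(np.asarray(v, float), npb) for k, v in traces.items()}
    v = np.abs(np.asarray(velocity, float))[: n_bins * npv].reshape(n_bins, npv)
    feats["moving_frac"] = np.mean(v > move_threshold, axis=1)

    # twitches: short (<1 s) excursions of EMG power above the session tail
    ep = np.asarray(emg_power, float)
    thr = np.percentile(ep, twitch_percentile)
    above = np.concatenate(([False], ep > thr, [False]))
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    run_starts, run_ends = edges[::2], edges[1::2]
    short = (run_ends - run_starts) / fs_power < 1.0
    twitch_counts = np.zeros(n_bins)
    bins_of = (run_starts[short] / fs_power // bin_s).astype(int)
    for b in bins_of[bins_of < n_bins]:
        twitch_counts[b] += 1
    feats["twitches"] = twitch_counts
    df = pd.DataFrame(feats)
    df.index = pd.Index(np.arange(n_bins) * bin_s, name="bin_start_s")
    df.attrs["bin_s"] = bin_s
    return df


@dataclass
class ScoringThresholds:
    """Resolved decision-tree cutoffs.

    When fields are left None they are estimated from the session:
    ``log_emg_atonia`` by Otsu on log EMG power (method="otsu") or at the
    30th percentile (method="percentile"); ``log_rem_score`` likewise on
    log(theta·gamma) over the atonic bins.
    """

    method: str = "otsu"
    log_emg_atonia: float | None = None
    log_rem_score: float | None = None
    # a bin counts as locomoting when the majority of its samples move,
    # consistent with majority-state labelling at 5-s resolution
    moving_frac: float = 0.5
    emg_percentile: float = 30.0
    band_percentile: float = 60.0


def _resolve_thresholds(
    features: pd.DataFrame, thresholds: ScoringThresholds
) -> ScoringThresholds:
    th = ScoringThresholds(**vars(thresholds))
    log_emg = np.log(features["emg"] + 1e-12)
    if th.log_emg_atonia is None:
        if th.method == "otsu":
            th.log_emg_atonia = bimodal_threshold(log_emg.to_numpy())
        elif th.method == "percentile":
            th.log_emg_atonia = float(np.percentile(log_emg, th.emg_percentile))
        else:
            raise ValueError(f"unknown threshold method {thresholds.method!r}")
    if th.log_rem_score is None:
        atonic = log_emg < th.log_emg_atonia
        score = np.log(features["theta"] * features["gamma"] + 1e-24)
        pool = score[atonic] if atonic.sum() >= 10 else score
        if th.method == "otsu":
            th.log_rem_score = bimodal_threshold(pool.to_numpy())
        else:
            th.log_rem_score = float(np.percentile(pool, th.band_percentile))
    return th


def classify_bins(
    features: pd.DataFrame,
    age_group: str,
    thresholds: ScoringThresholds | None = None,
    smooth: bool = True,
) -> Hypnogram:
    """Classify each 5-s bin into the age-specific arousal-state set.

    Decision tree (applied per bin):

    1. moving fraction above threshold → ``active_awake``;
    2. else EMG tone above the atonia cutoff → ``quiescent_awake``;
    3. else (atonia) theta×gamma score above cutoff — or, at P10, a
       twitch in the bin — → ``REM`` (P15/adult) / ``active_asleep`` (P10);
    4. remaining atonic bins → ``NREM`` (P15/adult) /
       ``quiescent_asleep`` (P10).

    ``smooth`` merges isolated single-bin labels into agreeing flanks.
    """
    if age_group not in STATE_SETS:
        raise ValueError(f"unknown age group {age_group!r}")
    th = _resolve_thresholds(features, thresholds or ScoringThresholds())
    log_emg = np.log(features["emg"].to_numpy() + 1e-12)
    score = np.log(features["theta"].to_numpy() * features["gamma"].to_numpy() + 1e-24)
    moving = features["moving_frac"].to_numpy() > th.moving_frac
    twitches = features["twitches"].to_numpy() if "twitches" in features else None

    p10 = age_group == "P10"
    rem_label = "active_asleep" if p10 else "REM"
    nrem_label = "quiescent_asleep" if p10 else "NREM"
    labels = np.empty(len(features), dtype=object)
    for i in range(len(features)):
        if moving[i]:
            labels[i] = "active_awake"
        elif log_emg[i] >= th.log_emg_atonia:
            labels[i] = "quiescent_awake"
        elif score[i] >= th.log_rem_score or (
            p10 and twitches is not None and twitches[i] > 0
        ):
            labels[i] = rem_label
        else:
            labels[i] = nrem_label
    if smooth:
        labels = _smooth_labels(labels)
    return Hypnogram(labels, features.attrs.get("bin_s", 5.0), age_group)


def _smooth_labels(labels: np.ndarray) -> np.ndarray:
    out = labels.copy()
    for i in range(1, len(out) - 1):
        if out[i - 1] == out[i + 1] != out[i]:
            out[i] = out[i - 1]
    return out


def extract_bouts(hypnogram: Hypnogram, merge_flickers: bool = False) -> list[Bout]:
    """Run-length encode the hypnogram into maximal single-state bouts."""
    labels = hypnogram.labels
    if len(labels) == 0:
        raise ValueError("empty hypnogram")
    if merge_flickers:
        labels = _smooth_labels(labels)
    bouts = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            bouts.append(
                Bout(labels[start], start * hypnogram.bin_s, i * hypnogram.bin_s)
            )
            start = i
    return bouts


def state_fractions(hypnogram: Hypnogram) -> dict[str, float]:
    """Fraction of session time per state (over the full age label set;
    fractions sum to one)."""
    if hypnogram.n_bins == 0:
        raise ValueError("empty hypnogram")
    out = {s: 0.0 for s in STATE_SETS[hypnogram.age_group]}
    vals, counts = np.unique(hypnogram.labels, return_counts=True)
    for v, c in zip(vals, counts):
        out[v] = c / hypnogram.n_bins
    return out


@dataclass
class SurvivalCurve:
    """Empirical bout-duration survival: S(t) = fraction of bouts > t."""

    durations: np.ndarray  # sorted
    survival: np.ndarray
    median: float
    n: int
    empty: bool = False


def bout_survival(bouts: Sequence[Bout], state: str) -> SurvivalCurve:
    """Survival curve and median duration of one state's bouts.

    The median is the smallest observed duration t with S(t) ≤ 0.5.
    """
    durs = np.sort([b.duration for b in bouts if b.state == state])
    n = len(durs)
    if n == 0:
        return SurvivalCurve(np.array([]), np.array([]), float("nan"), 0, empty=True)
    surv = 1.0 - np.arange(1, n + 1) / n  # S at each observed duration
    median = float(durs[np.argmax(surv <= 0.5)])
    return SurvivalCurve(durs, surv, median, n)


def hypnogram_accuracy(hypnogram: Hypnogram, true_labels: np.ndarray) -> float:
    """Fraction of bins whose scored label matches the ground truth."""
    n = min(hypnogram.n_bins, len(true_labels))
    if n == 0:
        raise ValueError("nothing to compare")
    return float(np.mean(hypnogram.labels[:n] == np.asarray(true_labels)[:n]))
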