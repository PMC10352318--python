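"""Default generator parameter tables per age group.

These tables are the ground truth that the analysis stages are validated
against: per-state ΔHbT offsets equal to the printed peri-transition
magnitudes, sleep architecture (state fractions and bout-duration medians)
matching published neonatal/adult head-fixed values, stimulus-evoked
response templates, 1/f spectral exponents, and vasomotion peak
frequencies.  Transition matrices of the embedded Markov chain are solved
so that the implied long-run state fractions (stationary visit rate x mean
dwell) reproduce the target time-in-state percentages.
"""

from __future__ import annotations

import numpy as np

AGE_GROUPS = ("P10", "P15", "adult")

#: age-specific arousal-state label sets, in transition-matrix row order
STATE_SETS: dict[str, tuple[str, ...]] = {
    "P10": ("active_awake", "quiescent_awake", "active_asleep", "quiescent_asleep"),
    "P15": ("active_awake", "quiescent_awake", "NREM", "REM"),
    "adult": ("active_awake", "quiescent_awake", "NREM", "REM"),
}

AWAKE_STATES = frozenset({"active_awake", "quiescent_awake"})

#: shape parameter (log-space SD) of the log-normal dwell-time law
DWELL_SIGMA = 0.6

# Embedded-chain transition matrices (rows follow STATE_SETS order).
# Solved from the balance equations so the semi-Markov stationary
# time-in-state fractions hit the targets below; REM exits only to the
# awake states (awakening from REM goes to active behaviour).
TRANSITION_MATRICES: dict[str, np.ndarray] = {
    "P15": np.array(
        [
            [0.0, 0.626, 0.374, 0.0],
            [0.17713, 0.0, 0.82287, 0.0],
            [0.5, 0.35546, 0.0, 0.14454],
            [1.0, 0.0, 0.0, 0.0],
        ]
    ),
    "P10": np.array(
        [
            [0.0, 0.6, 0.25, 0.15],
            [0.3, 0.0, 0.4, 0.3],
            [0.4, 0.12436, 0.0, 0.47564],
            [0.08525, 0.17229, 0.74246, 0.0],
        ]
    ),
    "adult": np.array(
        [
            [0.0, 0.8536, 0.1464, 0.0],
            [0.4554, 0.0, 0.5446, 0.0],
            [0.4, 0.4333, 0.0, 0.1667],
            [1.0, 0.0, 0.0, 0.0],
        ]
    ),
}

# Per-state parameters: (hbt_offset uM, emg_sigma au, twitch_rate /s,
# delta_gain, theta_gain, gamma_gain, dwell_median s, locomotion_prob /s)
_STATE_TABLES: dict[str, dict[str, tuple]] = {
    "P15": {
        # least-squares offsets over the four printed P15 transition deltas
        # (awake->NREM +12.35, NREM->REM +12.18, NREM->active_awake -13.43,
        # REM->active_awake -26.26); the system is overdetermined by one,
        # leaving balanced ~0.2 uM residuals on each pair
        "active_awake": (-1.30, 3.0, 0.0, 1.0, 1.8, 1.5, 21.0, 0.8),
        "quiescent_awake": (0.0, 1.5, 0.0, 1.0, 1.0, 1.0, 17.0, 0.0),
        "NREM": (12.35, 0.3, 0.0, 3.0, 1.0, 1.0, 24.0, 0.0),
        "REM": (24.75, 0.25, 0.2, 1.0, 3.0, 2.5, 34.0, 0.0),
    },
    "P10": {
        # least-squares offsets over the (mutually inconsistent) printed
        # P10 deltas; delta rhythm barely developed at this age
        "active_awake": (-0.86, 3.0, 0.0, 1.0, 1.5, 1.3, 21.0, 0.8),
        "quiescent_awake": (0.0, 1.5, 0.0, 1.0, 1.0, 1.0, 17.0, 0.0),
        "active_asleep": (14.87, 0.3, 0.3, 1.0, 2.5, 2.0, 53.0, 0.0),
        "quiescent_asleep": (11.20, 0.35, 0.0, 1.3, 1.0, 1.0, 19.0, 0.0),
    },
    "adult": {
        "active_awake": (3.0, 3.0, 0.0, 1.0, 1.8, 1.5, 40.0, 0.8),
        "quiescent_awake": (0.0, 1.5, 0.0, 1.0, 1.0, 1.0, 60.0, 0.0),
        "NREM": (15.0, 0.3, 0.0, 3.0, 1.0, 1.0, 50.0, 0.0),
        "REM": (30.0, 0.25, 0.2, 1.0, 3.0, 2.5, 60.0, 0.0),
    },
}

#: stimulus-evoked ΔHbT template (peak_amp uM, time_to_peak s, fwhm s)
EVOKED_TEMPLATES: dict[str, tuple[float, float, float]] = {
    "P10": (1.70, 2.69, 3.98),
    "P15": (2.16, 1.14, 1.83),
    "adult": (16.8, 1.23, 1.72),
}

#: 1/f^beta exponent of the resting ΔHbT background
BETA: dict[str, float] = {"P10": 1.846, "P15": 1.780, "adult": 1.235}

#: RMS amplitude (uM) of the 1/f background
NOISE_SIGMA: dict[str, float] = {"P10": 5.0, "P15": 4.0, "adult": 3.0}

#: narrowband vasomotion component: centre frequency (Hz), amplitude (uM)
VASOMOTION: dict[str, tuple[float, float]] = {
    "P10": (0.018, 2.5),
    "P15": (0.067, 1.5),
    "adult": (0.176, 2.0),
}

#: probability that a stimulus delivered in sleep triggers awakening
P_AWAKEN: dict[str, float] = {"P10": 0.5, "P15": 0.85, "adult": 0.2}

#: multiunit firing rates (Hz): baseline, evoked 0-100 ms, steady 200-500 ms
#: (adult entries adopt the oldest measured group, P28)
FIRING_RATES: dict[str, tuple[float, float, float]] = {
    "P10": (41.3, 81.2, 87.0),
    "P15": (58.6, 117.3, 138.4),
    "adult": (75.2, 140.6, 172.7),
}
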