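# pupwake

Arousal-state transitions dominate the hemodynamic signals of developing
mice.  In neonates (around postnatal day 10–15), sensory stimulation often
appears to drive a paradoxical *decrease* in cortical blood volume.  The
resolution of the paradox is behavioral: neonatal mice sleep most of the
time, cortical blood volume is tens of µM of total hemoglobin (ΔHbT)
higher during NREM and REM sleep than in quiet wakefulness, and a whisker
stimulus delivered during sleep wakes the animal up — the vasoconstriction
of awakening swamps the genuine, canonical neurovascular response that the
same stimulus evokes in the awake state.

`pupwake` is a Python library (plus a thin `pupwake` CLI) for analysing
this kind of multi-channel recording — widefield intrinsic-signal ΔHbT,
nuchal EMG, hippocampal LFP, treadmill velocity and stimulus times — and a
seeded synthetic-session generator that emulates the recordings' full
statistical structure with known ground truth, so that every analysis
stage is verifiable without any data download.

## What's in the box

| module | what it does |
|---|---|
| `pupwake.synthgen` | semi-Markov arousal sequences with age-specific architecture; ΔHbT = smoothed state offsets + 1/f^β background + narrowband vasomotion + gamma-variate evoked responses; state-dependent EMG (atonia, myoclonic twitches), LFP band content, locomotion; stimulus-triggered awakening; Poisson multiunit trains |
| `pupwake.hemo` | modified Beer–Lambert conversion Δ[HbT] = −ln(I/I₀)/(X·ξ); ROI averaging; stimulus-triggered averages and evoked metrics (peak, time-to-peak, FWHM, 0.5–3 s mean, 5–15 s undershoot) |
| `pupwake.spectral` | multitaper (DPSS) resting-state spectra, logarithmic resampling, OLS power-law fit P = a·f^−β, pre-whitening and vasomotion-peak metrics |
| `pupwake.ephys` | zero-phase band-pass, 4-SD spike detection with 1-ms refractory, Gaussian-kernel firing rates, sliding multitaper spectrograms, EMG power chain, current source density and layer-4 identification |
| `pupwake.scoring` | rule-based 5-s-bin sleep scoring (locomotion → EMG tone → theta×gamma / twitches), bout extraction, state fractions, bout-duration survival curves |
| `pupwake.transitions` | qualified state transitions (≥15 s flanks), baseline/response window deltas, peri-transition averages, evoked responses split by pre-stimulus state, peri-stimulus awake probability |
| `pupwake.pipeline` / `pupwake.cli` | `simulate → score → spectra → transitions → evoked` orchestration with YAML configs and a versioned results JSON |

## Worked example

Score sleep on a synthetic P15 session and recover the transition
hemodynamics (`examples/transition_deltas.py`, trimmed):

```text
     from_state        to_state  mean_delta_uM  sd_delta_uM   n
           NREM             REM          12.23         1.76  35
           NREM    active_awake         -12.03         2.03  91
            REM    active_awake         -23.89         1.91  28
   active_awake            NREM          12.51         1.66  55
quiescent_awake            NREM          11.28         2.00 166
```

Each row is one transition type; the delta is the mean ΔHbT over
[t+5, t+15) s minus [t−15, t−5) s around the scored boundary.  Falling
asleep raises blood volume by ~12 µM; awakening from REM drops it by
~24 µM — several times the adult sensory-evoked peak.  Splitting evoked
responses by pre-stimulus state (`examples/evoked_response.py`):

```text
    active_awake ( awake): n= 17  peak  17.17 µM  time-to-peak 1.10 s  FWHM 1.70 s
 quiescent_awake ( awake): n= 31  peak  16.36 µM  time-to-peak 1.20 s  FWHM 1.74 s
            NREM (  NREM): n= 11  peak   2.29 µM  ...  5–15 s mean  -1.68 µM
```

Awake stimulation recovers the generator's adult template (16.8 µM,
1.23 s, 1.72 s); stimulation in NREM shows the occluded, undershooting
response.  The other examples cover session simulation
(`simulate_session.py`), scoring accuracy (`score_sleep.py`, 96.9%
bin-level agreement with ground truth) and resting-state spectra
(`resting_spectrum.py`: β and the vasomotion peak per age).

Command-line equivalent:

```bash
pupwake simulate --age P15 --duration 1800 --seed 42 --out session/
pupwake score --in session/
pupwake transitions --in session/
pupwake report --age P15 --duration 3600 --seed 1 --out run/
```

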