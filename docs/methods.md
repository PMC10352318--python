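# Methods

This note documents the models, numerical choices and limitations behind
`pupwake`: what the synthetic-data generator assumes, how each analysis
stage is defined, and what passing the test suite does and does not show
about real recordings.

## The scientific setting

Widefield intrinsic-signal imaging at 530 nm (a hemoglobin isosbestic
point) reports total hemoglobin: vessel dilation increases absorbance and
decreases reflectance.  In head-fixed developing mice, the dominant source
of ΔHbT variance is not sensory input but arousal state — cortical blood
volume is substantially higher in NREM and REM sleep than in quiet
wakefulness, and neonates cycle between states on a time scale of tens of
seconds.  A sensory stimulus delivered during sleep tends to wake the
animal; the resulting vasoconstriction can exceed and invert the genuine
evoked response.  The package's analysis chain (scoring → transitions →
state-split evoked averages) makes that confound measurable; the generator
reproduces the statistical structure that makes it visible.

## Synthetic sessions

**Arousal-state sequence.**  A semi-Markov process: an embedded Markov
chain over the age-specific label set (P10: active/quiescent awake,
active/quiescent asleep; P15 and adult: active/quiescent awake, NREM,
REM), with log-normal dwell times parameterized by per-state medians
(shape σ = 0.6, giving the heavy right tail that empirical bout-survival
curves show).  REM exits only to awake states.  The long-run time-in-state
fraction of a semi-Markov chain is π·E[dwell] (normalized), with π the
embedded chain's stationary distribution; the default transition matrices
were solved from the balance equations so these implied fractions
reproduce the published architecture — P15: 27.8 / 24.1 / 39.9 / 8.17 %
(active awake / quiescent awake / NREM / REM) with bout-duration medians
21 / 17 / 24 / 34 s; P10: 57.19 % active sleep (median 53 s).  The P10
fractions other than the published active-sleep figure, and the whole
adult table (25 / 45 / 25 / 5 %, medians 40 / 60 / 50 / 60 s), are this
package's choices of a plausible architecture.  `implied_state_fractions`
computes the exact configured targets for any matrix.

**ΔHbT.**  Four additive parts, all in µM at 30 Hz:

1. *State offsets*, relative to quiescent awake = 0, relaxed toward the
   current state's level by a single-exponential kernel (τ = 3 s; the
   multi-second transition kinetics have no published functional form, so
   the simplest plausible kernel is used).  The P15 offsets are the
   least-squares encoding of the four published transition magnitudes
   (awake→NREM +12.35, NREM→REM +12.18, NREM→active awake −13.43,
   REM→active awake −26.26 µM): active awake −1.30, NREM +12.35,
   REM +24.75, with ~0.2 µM residual per pair because four pairwise
   differences overdetermine three free offsets.  The P10 published
   magnitudes are mutually inconsistent at the several-µM level under any
   scalar-offset model; the least-squares solution (−0.86 / +11.20 /
   +14.87 µM) is used.
2. *1/f^β background*, synthesized in the frequency domain (amplitude
   ∝ f^(−β/2), independent Gaussian phases, floored below 1/duration),
   rescaled to an RMS of 5 / 4 / 3 µM for P10 / P15 / adult.  β defaults:
   1.846 / 1.780 / 1.235.
3. *Vasomotion*: a fixed-amplitude sinusoid whose phase diffuses slowly
   (instantaneous-frequency jitter 5 % of the centre frequency), centred
   at 0.018 / 0.067 / 0.176 Hz with amplitude 2.5 / 1.5 / 2.0 µM.  A
   phase-diffusing sinusoid rather than band-passed noise keeps the band
   power stable realization-to-realization, which matters at 0.018 Hz
   where a 300-s trace holds barely five cycles.
4. *Evoked responses*: a gamma-variate h(t) = A·(t/tp)^α·exp(α(1−t/tp)),
   with α solved numerically so the FWHM matches the configured template
   (adult: 16.8 µM, 1.23 s, 1.72 s; P15: 2.16 µM, 1.14 s, 1.83 s; P10:
   1.70 µM, 2.69 s, 3.98 s), added for every stimulus delivered in an
   awake state.

**Stimulation and awakening.**  Air-puff onsets are scheduled with a
minimum inter-stimulus interval of 60 s plus uniform jitter (≤10 s), each
0.5 s long.  A stimulus falling in a sleep bout triggers an awakening with
probability `p_awaken_given_sleep_stim` (P15 default 0.85, back-computed
from the published peri-stimulus awake probabilities ~65 %→~95 %; P10 0.5
and adult 0.2 are package choices).  An awakening truncates the sleep bout
at onset + 1 s and resumes the chain in active awake; the whole insertion
happens while the state sequence is sampled, so `synth_hbt` remains a pure
renderer of ground truth.  Ground truth records each stimulus's
pre-stimulus state, whether it awakened the animal, and whether a template
was added.

**Other channels.**  EMG: per-state Gaussian tone (σ 3.0 / 1.5 / ~0.3 au
for active / quiescent / atonic states) plus Poisson myoclonic twitches
(0.1-s Hann-windowed bursts) in REM and P10 active sleep.  LFP: sum of
band-limited noise (delta 1–4, theta 4–10, gamma 40–100 Hz) scaled by
per-state gains; NREM is delta-dominant, REM (and P10 active sleep, its
developmental precursor) theta/gamma-dominant.  Velocity: 1-s Bernoulli
locomotion blocks (rate 0.8/s in active awake), gated per-sample by the
state so movement stops exactly at bout boundaries.  Spikes: inhomogeneous
Poisson at the published multiunit rates (baseline / 0–100 ms evoked /
200–500 ms steady; adult values adopt the oldest measured group).  No dead
time is imposed on generated trains — multiunit activity pools many units —
so configured rates are recovered exactly; the 1-ms refractory rule
belongs to spike *detection*.

Raw channels default to 1 kHz sampling, sufficient for the 40–100 Hz gamma
band at desk scale (acquisition hardware typically digitizes at 20 kHz;
tests that need the literal 300 Hz–5 kHz EMG/MUA band use short 20-kHz
fixtures, and at 1 kHz the band is clamped to 300–499 Hz with a warning).
All randomness flows through independent child generators spawned from a
single seed; a fixed seed reproduces every channel bit-identically.

## Analysis stages

**Beer–Lambert.**  Δ[HbT](t) = −ln(I(t)/I(t₀)) / (X(λ)·ξ(λ)), with I(t₀)
the mean intensity over a baseline window.  I₀ is read as the *temporal*
baseline — the only self-consistent interpretation for a Δ quantity.  The
defaults X = 0.57, ξ = 0.0054 µM⁻¹ are literature-derived working values
for 530 nm; every downstream result depends only on the product X·ξ, which
simply sets the µM scale.  An absorption-coefficient term sometimes listed
alongside this formula does not appear in it and is ignored.

**Evoked metrics.**  Snippets are baseline-corrected by their own
[−3, 0) s pre-onset mean (short enough to sit inside one arousal state).
Peak = maximum in a 0–5 s search window (the slowest neonatal
time-to-peaks, ~2.7 ± 1.3 s, must fit); FWHM by linear interpolation of
the half-maximum crossings flanking the peak; early mean over [0.5, 3) s;
undershoot mean over [5, 15) s.  A response that never rises above zero is
flagged `no_clear_peak` (matching the practice of excluding such animals
from peak/FWHM summaries) rather than producing numbers.

**Resting spectra.**  Rest = trials with strictly less than 10 % of
samples above the movement threshold.  PSDs are multitaper (DPSS)
estimates averaged across equal-length rest trials, then rebinned onto
logarithmically spaced frequencies (geometric-mean frequency,
arithmetic-mean power; 24 bins) to undo the linear grid's oversampling of
high frequencies; P = a·f^−β is fit by OLS in log₁₀–log₁₀ over
0.005–1 Hz, excluding the two lowest log bins where the taper bandwidth
biases the estimate and where real resting spectra roll off.  Pre-whitening
divides by the fitted model; the peak is the whitened maximum in
0.01–0.5 Hz (covering both the neonatal ~0.02 Hz and adult vasomotion
~0.1–0.3 Hz), flagged absent if it does not exceed 1.05.  `peak_fraction`
is the whitened peak over the summed whitened power — the stated
normalization of the published peak-fraction metric is ambiguous, and this
is one defensible reading, flagged as such.  Multitaper defaults are
TW = 2 with 3 tapers: on 300-s traces a larger bandwidth product smears
the very steep neonatal trend around 0.01–0.02 Hz and can displace the
P10 whitened peak a full log-bin low, which TW = 2 avoids at a modest
variance cost (the power-law fit then averages over bins and seeds).

**Electrophysiology.**  Band-pass filters are 4th-order Butterworth run
forward–backward (zero phase).  Spikes are crossings of |v − mean| >
4·SD with a 1-ms refractory period keeping the first crossing of a
violating pair; an MAD-based SD is available for spike-dense traces.
Rates convolve the binarized train with a unit-area 100-ms-SD Gaussian, so
the rate integral equals the spike count to machine precision.
Spectrograms use 5-s windows stepping by 0.5 s and are normalized as
percent change against ≥2 min of rest.  CSD is the second spatial
difference of the laminar LFP divided by Δz², reported *sink-positive*
(a localized negative-potential trough gives a positive value at its
channel); layer 4 is the interior channel with the earliest
stimulus-evoked sink among those reaching half the maximal sink amplitude.
Whether the spectrogram baseline should be velocity-rest or scored
quiescence is left configurable; velocity-rest is the default.

**Scoring.**  Features per 5-s bin: medians of EMG power and of
delta/theta/gamma LFP power, fraction of moving samples, and the count of
short (<1 s) EMG-power excursions above the session's 95th percentile
(twitches).  Decision tree: locomotion in the majority of the bin →
active awake; else EMG tone above the atonia cutoff → quiescent awake;
else theta×gamma above its cutoff (or, at P10, a twitch) → REM / active
asleep; else NREM / quiescent asleep.  The majority-vote locomotion rule
matches the majority-state convention of 5-s manual scoring.  Cutoffs are
estimated per session by exact Otsu thresholding (minimum within-class
variance) of the bimodal log-feature distributions — unlike fixed
percentiles, this makes no assumption about how much of the session was
spent asleep, which varies from ~50 % (P15) to ~75 % (P10).  Percentile
thresholds remain available as a config option, and all cutoffs can be set
explicitly.  P10 active sleep is detected primarily by its REM-like
theta×gamma signature with twitches as corroboration: a purely
twitch-per-bin rule misses the e^(−rate·5 s) of active-sleep bins that
happen to contain no twitch.  P10 uses a four-label taxonomy
(quiescent/active × awake/asleep), the variant its transition analyses
require.  Isolated single-bin labels are merged into agreeing flanks by
default.

**Transitions.**  A bout boundary qualifies when both flanking bouts last
≥15 s and the windows fit in the recording; the windows are [t−15, −5) and
[t+5, +15) s (all windows in the package are half-open).  The baseline
window therefore always lies inside the preceding bout.  The delta is the
response-window mean minus the baseline-window mean, in raw µM (no
per-event baseline correction, matching the absolute-ΔHbT convention of
peri-transition figures).  Rare transition types are reported with their n
rather than suppressed; single-event types have undefined SD.  Stimuli are
labeled by the state of the bin *before* the onset bin, since the onset
bin may already contain the stimulus-triggered awakening; per-state evoked
averages need ≥3 stimuli to be reported, and the pooled average is exactly
the count-weighted mean of the reported per-state averages.

**Known attenuation.**  The recovered transition deltas sit ~8–10 % below
the asymptotic offset differences: the exponential transition kernel has
not fully settled over the [t+5, t+15) window (a τ = 3 s kernel leaves
~5 % of the step), and the scored boundary is quantized to 5-s bins.
REM→active-awake recovers ≈ −24 µM against an encoded −26 µM; this is a
property of the window-based estimator itself, not of the scoring, since
ground-truth boundaries show nearly the same attenuation.

## What the synthetic tests do and do not show

The generator emulates the *statistical* structure the analyses assume:
state-conditional signal levels, 1/f background, narrowband vasomotion,
additive evoked templates, state-conditional EMG/LFP content.  It does not
model vascular biophysics (no compliance, delay or nonlinearity between
neural activity and ΔHbT), imaging artifacts (no motion, photobleaching or
vessel-pattern structure), volume conduction or realistic LFP waveforms,
or the non-stationarity of real sessions (the chain is time-homogeneous,
whereas real animals drift in arousal over hours).  Passing parameter
recovery therefore shows that the pipeline is a correct and calibrated
estimator under these assumptions — not that the assumptions capture every
feature of real recordings.  The degenerate-generator test (identical
parameters across states drive scoring to chance) guards against any
hidden use of ground truth.

## Problem sizes

Default verification scales were chosen to keep everything at desk scale:
architecture and transition recovery use three 10,000-s sessions per age;
evoked recovery three 3,000-s adult sessions (~100 awake stimuli);
spectral recovery 300-s resting traces (six per estimate for peak
detection, ten seeds for the exponent).  At these sizes every recovered
quantity sits several Monte-Carlo standard errors inside its tolerance,
except the P10 active-sleep fraction, whose long bouts (median 53 s) leave
only ~150 bouts per 10⁴-s session and a between-session spread of several
percentage points — the quoted value should be read with that sampling
error in mind.
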