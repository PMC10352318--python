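"""Score arousal state from EMG, hippocampal LFP and locomotion.

Runs the rule-based 5-s-bin classifier on a synthetic P15 session and
compares the scored hypnogram with the generator's ground truth: the state
fractions, the NREM/REM bout-duration medians, and the bin-level accuracy.
"""

from pupwake.pipeline import score_session
from pupwake.scoring import bout_survival, extract_bouts, hypnogram_accuracy, state_fractions
from pupwake.synthgen import GeneratorConfig, generate_session

cfg = GeneratorConfig.for_age("P15", duration=6000.0, seed=7, stim_enabled=False)
session, truth = generate_session(cfg)
hyp, _ = score_session(session)

print("scored state fractions (% of session):")
for state, frac in state_fractions(hyp).items():
    print(f"  {state:>16s}  {100 * frac:5.1f}%")

bouts = extract_bouts(hyp)
for state in ("NREM", "REM"):
    s = bout_survival(bouts, state)
    print(f"{state}: {s.n} bouts, median duration {s.median:.0f} s "
          f"(generator median {cfg.state_params[state].dwell_median:.0f} s)")

acc = hypnogram_accuracy(hyp, truth.to_hypnogram_labels())
print(f"bin-level agreement with ground truth: {100 * acc:.1f}%")
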