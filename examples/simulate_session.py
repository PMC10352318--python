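"""Generate a synthetic P15 recording session and look at its ground truth.

Builds a 30-minute session with the default P15 study conditions (sleep
architecture, state-dependent ΔHbT offsets, whisker-stimulation protocol)
and prints what the generator actually produced.
"""

import numpy as np

from pupwake.synthgen import GeneratorConfig, generate_session, implied_state_fractions

cfg = GeneratorConfig.for_age("P15", duration=1800.0, seed=42)
session, truth = generate_session(cfg)

print(f"session: {session.duration:.0f} s, {len(session.stim_onsets)} air puffs, "
      f"{len(truth.state_sequence)} arousal-state bouts")
print("\nconfigured long-run state fractions vs this session:")
emp = {}
for label, a, b in truth.state_sequence:
    emp[label] = emp.get(label, 0.0) + (b - a) / truth.duration
for state, target in implied_state_fractions(cfg).items():
    print(f"  {state:>16s}  target {100 * target:5.1f}%   realized {100 * emp.get(state, 0):5.1f}%")

sleep_stims = [o for o in truth.stim_outcomes if o.pre_state in ("NREM", "REM")]
awakened = sum(o.awakened for o in sleep_stims)
print(f"\nstimuli in sleep: {len(sleep_stims)}, of which {awakened} triggered awakening "
      f"(configured probability {cfg.p_awaken_given_sleep_stim})")
print(f"ΔHbT range: {session.hbt.min():.1f} to {session.hbt.max():.1f} µM "
      "(sleep states sit tens of µM above quiet wakefulness)")
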