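"""Pipeline orchestration: simulate → score → spectra → transitions → evoked.

`run_pipeline` executes the requested stages in dependency order on a
synthetic (or loaded) session, writes per-stage artifacts (hypnogram TSV,
spectrum CSV, transition CSV, metrics JSON) and a single versioned
results JSON with units embedded in every numeric field name.  The whole
run is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ephys, scoring, spectral, synthgen, transitions
from .hemo import evoked_metrics
from .session import RecordingSession, load_session, save_session

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "score_session"]

RESULTS_SCHEMA_VERSION = 1

ALL_STAGES = ("simulate", "score", "spectra", "transitions", "evoked")

_STAGE_DEPS = {
    "score": (),
    "spectra": (),
    "transitions": ("score",),
    "evoked": ("score",),
}


class PipelineError(RuntimeError):
    """Stage failure or unsatisfied stage dependency."""


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    age_group: str = "P15"
    duration: float = 3600.0
    seed: int = 0
    out_dir: str = "pupwake_run"
    stages: tuple[str, ...] = ALL_STAGES
    in_dir: str | None = None  # load instead of simulate
    save_session_files: bool = False
    session_format: str = "hdf5"
    generator_overrides: dict = field(default_factory=dict)
    bin_s: float = 5.0
    threshold_method: str = "otsu"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["stages"] = tuple(d.get("stages", ALL_STAGES))
        return cls(**d)


def score_session(
    session: RecordingSession,
    bin_s: float = 5.0,
    threshold_method: str = "otsu",
) -> tuple[scoring.Hypnogram, pd.DataFrame]:
    """Feature extraction + rule-based classification for one session."""
    emg_pow = ephys.emg_power(session.emg, session.fs_raw)
    delta = ephys.band_power_trace(session.lfp, session.fs_raw, 1.0, 4.0)
    theta = ephys.band_power_trace(session.lfp, session.fs_raw, 4.0, 10.0)
    gamma = ephys.band_power_trace(session.lfp, session.fs_raw, 40.0, 100.0)
    feats = scoring.bin_features(
        emg_pow, delta, theta, gamma, session.velocity,
        fs_power=session.fs_raw, fs_velocity=session.fs_hbt, bin_s=bin_s,
    )
    hyp = scoring.classify_bins(
        feats, session.age_group,
        scoring.ScoringThresholds(method=threshold_method),
    )
    return hyp, feats


def _stage_spectra(session: RecordingSession) -> dict:
    rest = spectral.rest_segments(
        session.velocity, session.fs_hbt, session.trial_bounds
    )
    # equal-length full trials only (PSDs are averaged bin-wise)
    full = [b for b in rest if np.isclose(b[1] - b[0], session.trial_s)]
    strict_rest = bool(full)
    if not full:
        # no trial meets the <10%-movement rule: fall back to the stillest
        # full-length trial so the stage still reports, flagged as non-rest
        v = np.abs(session.velocity)
        candidates = [
            b for b in session.trial_bounds if np.isclose(b[1] - b[0], session.trial_s)
        ]
        if not candidates:
            raise PipelineError("spectra: session shorter than one full trial")
        moving = [
            np.mean(v[int(t0 * session.fs_hbt) : int(t1 * session.fs_hbt)] > 0.5)
            for t0, t1 in candidates
        ]
        full = [candidates[int(np.argmin(moving))]]
    segs = [
        session.hbt[int(t0 * session.fs_hbt) : int(t1 * session.fs_hbt)]
        for t0, t1 in full
    ]
    fit = spectral.fit_resting_spectrum(segs, session.fs_hbt)
    return {"fit": fit, "rest_trials": full, "strict_rest": strict_rest}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the results dictionary (also written as ``results.json``).
    Raises :class:`PipelineError` when a requested stage's dependency is
    not part of the run.
    """
    stages = tuple(config.stages)
    for st in stages:
        for dep in _STAGE_DEPS.get(st, ()):
            if dep not in stages:
                raise PipelineError(f"stage {st!r} requires stage {dep!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")

    results: dict = {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "seed": config.seed,
        "age_group": config.age_group,
    }

    if config.in_dir is not None:
        session = load_session(config.in_dir)
        truth = None
    else:
        gen_cfg = synthgen.GeneratorConfig.for_age(
            config.age_group,
            duration=config.duration,
            seed=config.seed,
            **config.generator_overrides,
        )
        session, truth = synthgen.generate_session(gen_cfg)
        (out / "ground_truth.json").write_text(truth.to_json())
        if config.save_session_files:
            save_session(session, out / "session", config.session_format)
    results["n_stimuli"] = int(len(session.stim_onsets))
    results["duration_s"] = float(session.duration)

    hyp = None
    if "score" in stages:
        hyp, _ = score_session(session, config.bin_s, config.threshold_method)
        hyp.to_frame().to_csv(out / "hypnogram.tsv", sep="\t", index=False)
        fracs = scoring.state_fractions(hyp)
        results["state_fraction_pct"] = {
            k: round(100.0 * v, 4) for k, v in sorted(fracs.items())
        }
        bouts = scoring.extract_bouts(hyp)
        results["bout_median_s"] = {
            s: scoring.bout_survival(bouts, s).median
            for s in sorted(fracs)
            if scoring.bout_survival(bouts, s).n > 0
        }

    if "spectra" in stages:
        sp = _stage_spectra(session)
        fit = sp["fit"]
        pd.DataFrame(
            {"freq_hz": fit.freqs, "power": fit.power, "whitened": fit.whitened}
        ).to_csv(out / "spectrum.csv", index=False)
        results["spectral"] = {
            "beta": round(float(fit.beta), 4),
            "power_law_a": float(fit.a),
            "peak_freq_hz": round(float(fit.peak_freq), 4),
            "peak_power": round(float(fit.peak_power), 4),
            "peak_fraction": round(float(fit.peak_fraction), 6),
            "has_peak": bool(fit.has_peak),
            "n_rest_trials": fit.n_segments,
            "strict_rest": sp["strict_rest"],
        }

    if "transitions" in stages:
        events = transitions.find_transitions(hyp, session.hbt, session.fs_hbt)
        stats = transitions.transition_stats(events) if events else pd.DataFrame()
        stats.to_csv(out / "transitions.csv", index=False)
        results["transitions"] = {
            f"{r.from_state}->{r.to_state}": {
                "mean_delta_uM": round(float(r.mean_delta_uM), 4),
                "n": int(r.n),
            }
            for r in stats.itertuples()
        }

    if "evoked" in stages:
        labeled = transitions.split_stimuli_by_state(session.stim_onsets, hyp)
        results["evoked"] = {}
        if labeled:
            split = transitions.evoked_by_state(session.hbt, session.fs_hbt, labeled)
            for state, se in sorted(split.items()):
                m = evoked_metrics(se.peri)
                results["evoked"][state] = {
                    "peak_amp_uM": round(m.peak_amp, 4),
                    "time_to_peak_s": round(m.time_to_peak, 4)
                    if np.isfinite(m.time_to_peak) else None,
                    "fwhm_s": round(m.fwhm, 4) if np.isfinite(m.fwhm) else None,
                    "early_mean_uM": round(m.early_mean, 4),
                    "undershoot_mean_uM": round(m.undershoot_mean, 4),
                    "n_stimuli": se.n_stimuli,
                    "reported": se.reported,
                    "flags": list(m.flags),
                }
            prob = transitions.peristim_awake_probability(hyp, session.stim_onsets)
            prob.to_csv(out / "awake_probability.csv", index=False)
            pre = prob[prob.lag_s < -5]["p_awake"].mean()
            post = prob[(prob.lag_s > 5) & (prob.lag_s < 20)]["p_awake"].mean()
            results["awake_probability"] = {
                "pre_stim_pct": round(100 * float(pre), 2),
                "post_stim_pct": round(100 * float(post), 2),
            }

    (out / "results.json").write_text(json.dumps(results, indent=1, sort_keys=True))
    return results
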