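"""Generator contracts: state-sequence statistics, channel construction,
stimulus scheduling and bit-level reproducibility."""

import numpy as np
import pytest

from pupwake import spectral

from pupwake.ephys import band_power_trace
from pupwake.synthgen import (
    GeneratorConfig,
    StateParams,
    generate_session,
    gamma_variate,
    implied_state_fractions,
    power_law_noise,
    sample_state_sequence,
    schedule_stimuli,
    synth_emg,
    synth_hbt,
    synth_lfp,
    synth_spikes,
)


def _absorbing_config(**kw):
    cfg = GeneratorConfig.for_age("P15", duration=200.0, stim_enabled=False, **kw)
    P = np.zeros((4, 4))
    P[:, 2] = 1.0  # every state falls into NREM and stays
    cfg.transition_matrix = P
    return cfg


def empirical_fractions(truth):
    out = {}
    for label, a, b in truth.state_sequence:
        out[label] = out.get(label, 0.0) + (b - a)
    return {k: v / truth.duration for k, v in out.items()}


class TestStateSequence:
    def test_absorbing_state_fills_the_session(self):
        truth = sample_state_sequence(_absorbing_config(), rng=np.random.default_rng(0))
        assert len(truth.state_sequence) == 1
        assert truth.state_sequence[0] == ("NREM", 0.0, 200.0)

    def test_intervals_tile_session_exactly(self, p15_scored):
        _, _, truth, _ = p15_scored
        seq = truth.state_sequence
        assert seq[0][1] == 0.0
        assert seq[-1][2] == truth.duration
        for (_, _, e1), (_, s2, _) in zip(seq[:-1], seq[1:]):
            assert e1 == s2
        for lab1, lab2 in zip([s[0] for s in seq[:-1]], [s[0] for s in seq[1:]]):
            assert lab1 != lab2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_state_fractions_converge_to_targets(self, seed):
        cfg = GeneratorConfig.for_age("P15", duration=1e5, stim_enabled=False)
        truth = sample_state_sequence(cfg, rng=np.random.default_rng(seed))
        emp = empirical_fractions(truth)
        target = implied_state_fractions(cfg)
        for state in cfg.states:
            assert emp[state] == pytest.approx(target[state], abs=0.015)

    def test_dwell_median_matches_configuration(self):
        cfg = GeneratorConfig.for_age("P15", duration=1e5, stim_enabled=False)
        truth = sample_state_sequence(cfg, rng=np.random.default_rng(7))
        durs = [b - a for lab, a, b in truth.state_sequence[:-1] if lab == "NREM"]
        med = np.median(durs)
        assert med == pytest.approx(24.0, rel=0.20)

    def test_unreachable_state_rejected(self):
        cfg = GeneratorConfig.for_age("P15", duration=100.0)
        P = cfg.transition_matrix.copy()
        # isolate REM entirely: no inflow, no outflow
        P[:, 3] = 0.0
        P[3] = [0.0, 0.0, 0.0, 0.0]
        P[2] = [0.55, 0.45, 0.0, 0.0]
        cfg.transition_matrix = P
        with pytest.raises(ValueError, match="unreachable"):
            sample_state_sequence(cfg, rng=np.random.default_rng(0))


class TestStimuli:
    def test_short_session_yields_at_most_one_onset(self):
        cfg = GeneratorConfig.for_age("P15", duration=30.0)
        onsets = schedule_stimuli(cfg, np.random.default_rng(0))
        assert len(onsets) <= 1

    def test_gaps_respect_minimum_isi(self):
        cfg = GeneratorConfig.for_age("P15", duration=3600.0)
        onsets = schedule_stimuli(cfg, np.random.default_rng(1))
        assert len(onsets) > 30
        assert np.all(np.diff(onsets) >= cfg.isi_min)

    def test_jitter_makes_gaps_non_degenerate(self):
        cfg = GeneratorConfig.for_age("P15", duration=3600.0)
        gaps = np.concatenate(
            [
                np.diff(schedule_stimuli(cfg, np.random.default_rng(s)))
                for s in range(10)
            ]
        )
        assert gaps.var() > 0


class TestHbT:
    def test_constant_state_no_noise_gives_constant_offset(self):
        cfg = _absorbing_config(noise_sigma=0.0, vasomotion_amp=0.0)
        truth = sample_state_sequence(cfg, rng=np.random.default_rng(0))
        hbt = synth_hbt(truth, cfg)
        assert np.allclose(hbt, cfg.state_params["NREM"].hbt_offset)

    def test_smoothed_offsets_match_direct_recursion_oracle(self):
        cfg = GeneratorConfig.for_age(
            "P15", duration=300.0, noise_sigma=0.0, vasomotion_amp=0.0,
            stim_enabled=False,
        )
        truth = sample_state_sequence(cfg, rng=np.random.default_rng(5))
        hbt = synth_hbt(truth, cfg)
        # brute-force exponential relaxation
        fs = cfg.fs_hbt
        n = int(truth.duration * fs)
        x = np.array([truth.hbt_offsets[truth.label_at(i / fs)] for i in range(n)])
        a = 1.0 - np.exp(-1.0 / (cfg.transition_tau * fs))
        y = np.empty(n)
        y[0] = x[0]
        for i in range(1, n):
            y[i] = y[i - 1] + a * (x[i] - y[i - 1])
        assert np.allclose(hbt, y, atol=1e-10)

    def test_noise_spectral_exponent_recovered(self):
        betas = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            x = power_law_noise(9000, 30.0, beta=2.0, rng=rng, sigma=4.0)
            f, p = spectral.multitaper_psd(x, 30.0)
            fb, pb = spectral.log_resample(f, p)
            betas.append(spectral.fit_power_law(fb[2:], pb[2:]).beta)
        assert np.mean(betas) == pytest.approx(2.0, abs=0.15)

    def test_awake_stimuli_carry_the_evoked_template(self):
        # constant-awake session, many stimuli, noise on: the averaged
        # peri-stimulus peak matches the template peak within noise
        cfg = GeneratorConfig.for_age("adult", duration=4000.0, seed=21)
        P = np.zeros((4, 4))
        P[:, 0] = 1.0  # absorbing active_awake
        cfg.transition_matrix = P
        from pupwake.hemo import evoked_average

        from pupwake.synthgen import generate_session

        session, truth = generate_session(cfg)
        assert all(o.evoked for o in truth.stim_outcomes)
        peri = evoked_average(session.hbt, session.fs_hbt, session.stim_onsets)
        assert peri.n >= 20
        peak = peri.mean[peri.time >= 0].max()
        assert peak == pytest.approx(16.8, rel=0.12)


class TestEmgLfp:
    def _single_state_truth(self, cfg, label, duration=100.0):
        from pupwake.synthgen import GroundTruth

        return GroundTruth(
            [(label, 0.0, duration)],
            {s: cfg.state_params[s].hbt_offset for s in cfg.states},
            [],
            duration,
        )

    def test_nrem_emg_power_below_awake(self, rng):
        cfg = GeneratorConfig.for_age("P15", duration=100.0)
        nrem = synth_emg(self._single_state_truth(cfg, "NREM"), cfg, rng)
        awake = synth_emg(self._single_state_truth(cfg, "active_awake"), cfg, rng)
        assert (nrem**2).mean() < (awake**2).mean()

    def test_silent_config_gives_zero_trace(self, rng):
        cfg = GeneratorConfig.for_age("P15", duration=50.0)
        for p in cfg.state_params.values():
            p.emg_sigma = 0.0
            p.twitch_rate = 0.0
        truth = self._single_state_truth(cfg, "REM", 50.0)
        assert np.all(synth_emg(truth, cfg, rng) == 0.0)

    def test_rem_twitch_count_is_poisson(self):
        cfg = GeneratorConfig.for_age("P15", duration=100.0)
        cfg.state_params["REM"].twitch_rate = 0.1
        cfg.state_params["REM"].emg_sigma = 0.0  # isolate the twitches
        counts = []
        for seed in range(20):
            emg = synth_emg(
                self._single_state_truth(cfg, "REM"), cfg, np.random.default_rng(seed)
            )
            above = np.concatenate(([False], np.abs(emg) > 1.0, [False]))
            starts = np.flatnonzero(np.diff(above.astype(np.int8)))[::2]
            # one twitch burst crosses the threshold repeatedly; merge
            # crossings closer than the burst duration
            merged = 1 + int(np.sum(np.diff(starts) > 0.15 * cfg.fs_raw)) if len(starts) else 0
            counts.append(merged)
        # 0.1 events/s * 100 s = 10 expected; SEM over 20 seeds ~ 0.7
        assert np.mean(counts) == pytest.approx(10.0, abs=2.5)

    def test_state_band_content(self, rng):
        cfg = GeneratorConfig.for_age("P15", duration=100.0)
        fs = cfg.fs_raw
        nrem = synth_lfp(self._single_state_truth(cfg, "NREM"), cfg, rng)
        delta = band_power_trace(nrem, fs, 1, 4).mean()
        theta = band_power_trace(nrem, fs, 4, 10).mean()
        assert delta > theta
        rem = synth_lfp(self._single_state_truth(cfg, "REM"), cfg, rng)
        assert (
            band_power_trace(rem, fs, 4, 10).mean()
            / band_power_trace(rem, fs, 1, 4).mean()
            > 1.0
        )

    def test_lfp_band_above_nyquist_rejected(self, rng):
        cfg = GeneratorConfig.for_age("P15", duration=10.0)
        cfg.fs_raw = 150.0
        with pytest.raises(ValueError, match="Nyquist"):
            synth_lfp(self._single_state_truth(cfg, "NREM", 10.0), cfg, rng)


class TestSpikes:
    def test_zero_rate_gives_empty_train(self, rng):
        cfg = GeneratorConfig.for_age("P10", baseline_rate=0.0,
                                      evoked_rate_early=0.0, evoked_rate_steady=0.0)
        assert len(synth_spikes(cfg, 100.0, [], rng)) == 0

    def test_baseline_count_matches_configured_rate(self, rng):
        cfg = GeneratorConfig.for_age("P10")  # 41.3 Hz baseline
        t = synth_spikes(cfg, 100.0, [], rng)
        # Poisson(4130): 5 sigma ~ 320
        assert abs(len(t) - 4130) < 320

    def test_evoked_rate_doubles_during_stimulus(self):
        from pupwake.ephys import evoked_rates, spike_rate

        cfg = GeneratorConfig.for_age("P15")  # 58.6 baseline, 117.3 early
        onsets = np.arange(10.0, 600.0, 10.0)
        train = synth_spikes(cfg, 600.0, onsets, np.random.default_rng(2))
        # narrow kernel so smoothing does not smear the 100-ms window edges
        rate = spike_rate(train, 600.0, sigma=0.005, fs_out=1000.0)
        r = evoked_rates(rate, 1000.0, onsets)
        assert r["early_hz"] / r["baseline_hz"] == pytest.approx(2.0, rel=0.1)

    def test_train_is_sorted(self, rng):
        cfg = GeneratorConfig.for_age("adult")
        t = synth_spikes(cfg, 200.0, [], rng)
        assert np.all(np.diff(t) >= 0)


class TestDeterminism:
    def test_fixed_seed_reproduces_every_channel(self):
        a, ta = generate_session(GeneratorConfig.for_age("P15", duration=300.0, seed=9))
        b, tb = generate_session(GeneratorConfig.for_age("P15", duration=300.0, seed=9))
        for ch in ("hbt", "emg", "lfp", "velocity"):
            assert np.array_equal(getattr(a, ch), getattr(b, ch))
        assert ta.state_sequence == tb.state_sequence
        c, _ = generate_session(GeneratorConfig.for_age("P15", duration=300.0, seed=10))
        assert not np.array_equal(a.hbt, c.hbt)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            StateParams("x", 0.0, -1.0, 0.0, 1, 1, 1, 10.0, 0.0)
        with pytest.raises(ValueError):
            GeneratorConfig.for_age("P15", p_awaken_given_sleep_stim=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig.for_age("P42")


def test_gamma_variate_hits_requested_metrics():
    h = gamma_variate(10.0, 2.0, 3.0)
    t = np.linspace(0, 30, 300001)
    y = h(t)
    assert y.max() == pytest.approx(10.0, abs=1e-6)
    assert t[y.argmax()] == pytest.approx(2.0, abs=1e-3)
    above = t[y >= 5.0]
    assert above[-1] - above[0] == pytest.approx(3.0, abs=1e-2)
    assert np.all(h(np.array([-1.0, 0.0])) == 0.0)
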