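"""Transition qualification, window deltas, state-split evoked analyses."""

import numpy as np
import pytest

from pupwake.defaults import AWAKE_STATES
from pupwake.scoring import Hypnogram
from pupwake.transitions import (
    TransitionEvent,
    evoked_by_state,
    find_transitions,
    group_transitions,
    peri_transition_average,
    peristim_awake_probability,
    split_stimuli_by_state,
    transition_stats,
)


def _hyp(labels, bin_s=5.0, age="P15"):
    return Hypnogram(np.array(labels, dtype=object), bin_s, age)


class TestFindTransitions:
    fs = 10.0

    def test_single_qualified_boundary(self):
        hyp = _hyp(["NREM"] * 4 + ["active_awake"] * 4)  # 20 s / 20 s
        hbt = np.zeros(400)
        events = find_transitions(hyp, hbt, self.fs)
        assert len(events) == 1
        ev = events[0]
        assert (ev.from_state, ev.to_state, ev.t) == ("NREM", "active_awake", 20.0)

    def test_short_preceding_bout_excluded(self):
        # 10-s NREM bout precedes the boundary: below the 15-s rule
        hyp = _hyp(["quiescent_awake"] * 4 + ["NREM"] * 2 + ["active_awake"] * 6)
        hbt = np.zeros(600)
        events = find_transitions(hyp, hbt, self.fs)
        assert ("NREM", "active_awake") not in {
            (e.from_state, e.to_state) for e in events
        }

    def test_ideal_step_delta_is_exact(self):
        hyp = _hyp(["quiescent_awake"] * 4 + ["NREM"] * 4)
        hbt = np.where(np.arange(400) / self.fs < 20.0, 0.0, 12.0)
        (ev,) = find_transitions(hyp, hbt, self.fs)
        assert ev.delta == 12.0
        assert ev.baseline_mean == 0.0 and ev.response_mean == 12.0

    def test_windows_never_cross_session_edges(self, p15_scored):
        _, session, _, hyp = p15_scored
        for ev in find_transitions(hyp, session.hbt, session.fs_hbt):
            assert ev.t - 15.0 >= 0.0
            assert ev.t + 15.0 <= session.duration

    def test_delta_matches_bruteforce_two_window_oracle(self, p15_scored):
        _, session, _, hyp = p15_scored
        fs = session.fs_hbt
        for ev in find_transitions(hyp, session.hbt, fs)[:20]:
            i = int(round(ev.t * fs))
            base = session.hbt[i - int(15 * fs) : i - int(5 * fs)].mean()
            resp = session.hbt[i + int(5 * fs) : i + int(15 * fs)].mean()
            assert ev.delta == pytest.approx(resp - base, abs=1e-12)


class TestTransitionStats:
    def _ev(self, a, b, delta):
        return TransitionEvent(a, b, 100.0, 0.0, delta)

    def test_mean_by_hand_enumeration(self):
        deltas = [-10.0, -14.0, -16.29]
        evs = [self._ev("REM", "active_awake", d) for d in deltas]
        st = transition_stats(evs)
        assert st.mean_delta_uM.iloc[0] == pytest.approx(np.mean(deltas))
        assert st.n.iloc[0] == 3

    def test_single_event_group_has_undefined_sd(self):
        st = transition_stats([self._ev("NREM", "REM", 12.0)])
        assert st.n.iloc[0] == 1
        assert np.isnan(st.sd_delta_uM.iloc[0])

    def test_sleep_to_wake_deltas_negative_on_defaults(self, p15_scored):
        _, session, _, hyp = p15_scored
        events = find_transitions(hyp, session.hbt, session.fs_hbt)
        groups = group_transitions(events)
        for (a, b), evs in groups.items():
            if a in ("NREM", "REM") and b in AWAKE_STATES and len(evs) >= 5:
                assert np.mean([e.delta for e in evs]) < 0
            if a in AWAKE_STATES and b == "NREM" and len(evs) >= 5:
                assert np.mean([e.delta for e in evs]) > 0


class TestPeriTransitionAverage:
    def test_identical_events_have_zero_sd(self):
        fs = 10.0
        hbt = np.tile(np.concatenate([np.zeros(400), np.ones(400)]), 4)
        events = [
            TransitionEvent("quiescent_awake", "NREM", 40.0 + 80.0 * k, 0, 1)
            for k in range(4)
        ]
        peri = peri_transition_average(hbt, fs, events)
        assert peri.n == 4
        assert np.allclose(peri.sd, 0.0)
        assert np.allclose(peri.mean[peri.time >= 0], 1.0)

    def test_recovers_generator_offset_difference(self, p15_scored):
        cfg, session, _, hyp = p15_scored
        events = [
            e
            for e in find_transitions(hyp, session.hbt, session.fs_hbt)
            if (e.from_state, e.to_state) == ("quiescent_awake", "NREM")
        ]
        assert len(events) >= 10
        truth_delta = (
            cfg.state_params["NREM"].hbt_offset
            - cfg.state_params["quiescent_awake"].hbt_offset
        )
        assert np.mean([e.delta for e in events]) == pytest.approx(
            truth_delta, abs=3.0
        )


class TestStimulusSplit:
    def test_label_is_bin_before_onset(self):
        hyp = _hyp(["NREM", "NREM", "active_awake", "active_awake"])
        labeled = split_stimuli_by_state([12.0], hyp)  # onset in bin 2
        assert labeled == [(12.0, "NREM")]

    def test_all_awake_hypnogram(self):
        hyp = _hyp(["quiescent_awake"] * 10)
        labeled = split_stimuli_by_state([10.0, 20.0, 45.0], hyp)
        assert all(lab == "quiescent_awake" for _, lab in labeled)

    def test_onset_in_first_bin_excluded(self):
        hyp = _hyp(["NREM"] * 4)
        assert split_stimuli_by_state([2.0], hyp) == []

    def test_labels_match_ground_truth_pre_states(self, p15_stim_scored):
        # against the truth-binned hypnogram, the pre-onset-bin label agrees
        # with the generator's recorded pre-stimulus state except where the
        # state changed inside that very bin
        _, session, truth, _ = p15_stim_scored
        hyp_t = Hypnogram(truth.to_hypnogram_labels(), 5.0, "P15")
        labeled = dict(split_stimuli_by_state(session.stim_onsets, hyp_t))
        agree = total = 0
        for o in truth.stim_outcomes:
            if o.t not in labeled:
                continue
            total += 1
            bin_start = (int(o.t // 5.0) - 1) * 5.0
            changed = any(
                bin_start < s < o.t for _, s, _ in truth.state_sequence
            )
            if labeled[o.t] == o.pre_state or changed:
                agree += 1
        assert total >= 50
        assert agree == total


class TestEvokedByState:
    def test_single_state_pooled_equals_that_state(self, rng):
        fs = 10.0
        hbt = rng.standard_normal(6000)
        labeled = [(t, "quiescent_awake") for t in [60.0, 120.0, 180.0, 240.0]]
        split = evoked_by_state(hbt, fs, labeled)
        assert np.array_equal(split["all"].peri.mean, split["quiescent_awake"].peri.mean)

    def test_pooled_is_count_weighted_mean_of_states(self, rng):
        fs = 10.0
        hbt = rng.standard_normal(8000)
        labeled = [(60.0 + 40 * k, "NREM" if k % 3 else "quiescent_awake")
                   for k in range(12)]
        split = evoked_by_state(hbt, fs, labeled)
        states = [s for s in split if s != "all"]
        weighted = sum(
            split[s].n_stimuli * split[s].peri.mean for s in states
        ) / sum(split[s].n_stimuli for s in states)
        assert np.allclose(split["all"].peri.mean, weighted, atol=1e-12)

    def test_small_groups_flagged_not_reported(self, rng):
        fs = 10.0
        hbt = rng.standard_normal(4000)
        labeled = [(100.0, "REM"), (150.0, "NREM"), (200.0, "NREM"),
                   (250.0, "NREM")]
        split = evoked_by_state(hbt, fs, labeled)
        assert not split["REM"].reported
        assert split["NREM"].reported
        assert split["all"].n_stimuli == 3  # REM excluded from the pool

    def test_awake_positive_sleep_negative_on_p15(self, p15_stim_scored):
        _, session, _, hyp = p15_stim_scored
        labeled = split_stimuli_by_state(session.stim_onsets, hyp)
        split = evoked_by_state(session.hbt, session.fs_hbt, labeled)
        post = lambda peri: peri.mean[(peri.time >= 2) & (peri.time < 15)]
        if "quiescent_awake" in split and split["quiescent_awake"].reported:
            assert post(split["quiescent_awake"].peri).max() > 0
        assert split["NREM"].reported
        assert post(split["NREM"].peri).min() < -5.0  # awakening constriction


class TestAwakeProbability:
    def test_all_awake_probability_is_one(self):
        hyp = _hyp(["active_awake"] * 40)
        prob = peristim_awake_probability(hyp, [60.0, 100.0, 140.0])
        assert np.all(prob.p_awake == 1.0)

    def test_complementarity_at_every_lag(self, p15_stim_scored):
        _, session, _, hyp = p15_stim_scored
        prob = peristim_awake_probability(hyp, session.stim_onsets)
        assert np.allclose(prob.p_awake + prob.p_asleep, 1.0)

    def test_stimulation_raises_awake_probability(self, p15_stim_scored):
        _, session, _, hyp = p15_stim_scored
        prob = peristim_awake_probability(hyp, session.stim_onsets)
        pre = prob[prob.lag_s < -5].p_awake.mean()
        post = prob[(prob.lag_s > 0) & (prob.lag_s < 10)].p_awake.mean()
        assert post > pre + 0.15
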