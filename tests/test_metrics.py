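"""Behavioral metrics: PF normalization, P_oc, VD, learning-time rule, RT tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conseq.agent import LOG_COLUMNS, BehavioralLog
from conseq.errors import MetricUndefinedError
from conseq.metrics import (
    episode_performance,
    episode_performance_frame,
    learning_time,
    optimal_choice_indicator,
    rt_ecdf,
    rt_summaries,
    scan_learning_stream,
    visual_discrimination,
)
from conseq.task import BIG, SMALL


def synthetic_log(episodes, horizon=1, gain=0.3, block=0, rt=500.0):
    """Build a log from explicit (m1, delta, choices) tuples; choices may be
    None for no-decision trials."""
    rows = []
    for e, (m1, delta, choices) in enumerate(episodes, start=1):
        mean = m1
        for t, choice in enumerate(choices, start=1):
            s_small, s_big = mean - delta / 2, mean + delta / 2
            nd = choice is None
            chosen_value = (
                math.nan if nd else (s_big if choice == BIG else s_small)
            )
            rows.append(
                {
                    "block": block,
                    "horizon": horizon,
                    "episode": e,
                    "trial_in_episode": t,
                    "delta": delta,
                    "gain": gain,
                    "M": mean,
                    "s_left": s_big,
                    "s_right": s_small,
                    "side_of_big": "left",
                    "shown_first": "left",
                    "psi0": 0.5,
                    "psi_tilde": 0 if choice == SMALL else 1,
                    "chosen_side": None if nd else "left",
                    "chosen_value": chosen_value,
                    "choice_class": choice,
                    "decision_time": math.nan if nd else rt,
                    "rt": math.nan if nd else rt,
                    "no_decision": nd,
                }
            )
            if choice == SMALL:
                mean += gain
            elif choice == BIG:
                mean -= gain
    return BehavioralLog(frame=pd.DataFrame(rows, columns=LOG_COLUMNS))


class TestPerformance:
    def test_optimal_sequence_pf_one(self):
        log = synthetic_log([(0.5, 0.2, (SMALL, BIG))])
        assert episode_performance(log, 1) == 1.0

    def test_worst_sequence_pf_zero(self):
        log = synthetic_log([(0.5, 0.2, (BIG, SMALL))])
        assert episode_performance(log, 1) == 0.0

    def test_greedy_sequence_pf_delta_over_2g(self):
        log = synthetic_log([(0.5, 0.2, (BIG, BIG))])
        assert episode_performance(log, 1) == pytest.approx(0.2 / 0.6)

    def test_incomplete_episode_undefined(self):
        log = synthetic_log([(0.5, 0.2, (SMALL,))])  # missing second trial
        with pytest.raises(MetricUndefinedError):
            episode_performance(log, 1)

    def test_no_decision_trial_contributes_zero(self):
        log = synthetic_log([(0.5, 0.2, (None, BIG))])
        pf = episode_performance(log, 1)
        # achieved = 0 + (0.5 + 0.1); worst path total is 0.7 -> clamped at 0
        assert pf == 0.0


class TestOptimalChoice:
    def test_horizon0_big_is_optimal(self):
        assert optimal_choice_indicator(BIG, 1, 0) == 1
        assert optimal_choice_indicator(SMALL, 1, 0) == 0

    def test_inhibition_required_before_final(self):
        assert optimal_choice_indicator(BIG, 2, 2) == 0
        assert optimal_choice_indicator(SMALL, 2, 2) == 1
        assert optimal_choice_indicator(BIG, 3, 2) == 1

    def test_optimal_sequence_all_ones(self):
        log = synthetic_log([(0.5, 0.1, (SMALL, BIG))])
        frame = episode_performance_frame(log)
        assert frame["optimal"].all()


class TestVisualDiscrimination:
    def test_perfect_chooser(self):
        eps = [(0.5, 0.01, (BIG,)) for _ in range(30)]
        log = synthetic_log(eps, horizon=0)
        assert visual_discrimination(log) == 1.0

    def test_random_chooser_near_half(self):
        rng = np.random.default_rng(0)
        eps = [
            (0.5, 0.01, (BIG if rng.integers(2) else SMALL,)) for _ in range(400)
        ]
        log = synthetic_log(eps, horizon=0)
        assert abs(visual_discrimination(log, last_n_episodes=400) - 0.5) < 0.1

    def test_only_hardest_trials_count(self):
        eps = [(0.5, 0.01, (SMALL,)), (0.5, 0.2, (BIG,))]
        log = synthetic_log(eps, horizon=0)
        assert visual_discrimination(log) == 0.0  # easy episode ignored

    def test_requires_horizon0(self):
        log = synthetic_log([(0.5, 0.2, (SMALL, BIG))], horizon=1)
        with pytest.raises(MetricUndefinedError):
            visual_discrimination(log)


class TestLearningTimeRule:
    def brute_force(self, stream, window=10, hits=9, tail_frac=0.75):
        n = len(stream)
        for i in range(n):
            if not stream[i]:
                continue
            win = stream[i : i + window]
            need = hits if len(win) == window else math.ceil(hits / window * len(win))
            tail = stream[i + window :]
            tail_ok = (not tail) or (sum(tail) / len(tail) >= tail_frac)
            if sum(win) >= need and tail_ok:
                return i + 1
        return None

    def test_late_learner(self):
        stream = [0] * 11 + [1] * 39
        assert scan_learning_stream(stream) == 12

    def test_never_learns(self):
        assert scan_learning_stream([0] * 50) is None

    def test_immediate_learner(self):
        assert scan_learning_stream([1] * 50) == 1

    def test_tail_violation_defers_learning(self):
        # perfect 10-window early, but a weak tail blocks the criterion
        stream = [1] * 10 + [0] * 10 + [1] * 10
        assert scan_learning_stream(stream) == self.brute_force(stream)

    @settings(max_examples=300, deadline=None)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
    def test_matches_brute_force(self, stream):
        assert scan_learning_stream(stream) == self.brute_force(stream)

    def test_hardest_episodes_excluded_and_numbering_original(self):
        # episodes alternate hardest / easy; easy ones optimal from the start
        eps = []
        for i in range(20):
            if i % 2 == 0:
                eps.append((0.5, 0.01, (BIG, SMALL)))  # hardest, never optimal
            else:
                eps.append((0.5, 0.2, (SMALL, BIG)))
        log = synthetic_log(eps)
        assess = learning_time(log)
        assert assess.learned
        assert assess.t_l == 2  # first easy episode, original numbering

    def test_invariant_appending_optimal_episodes(self):
        base = [(0.5, 0.2, (SMALL, BIG))] * 15
        extra = base + [(0.4, 0.15, (SMALL, BIG))] * 10
        assert learning_time(synthetic_log(base)).t_l == learning_time(
            synthetic_log(extra)
        ).t_l

    def test_prepending_bad_episodes_delays(self):
        good = [(0.5, 0.2, (SMALL, BIG))] * 20
        bad = [(0.5, 0.2, (BIG, BIG))] * 5
        assert learning_time(synthetic_log(bad + good)).t_l > learning_time(
            synthetic_log(good)
        ).t_l


class TestRtSummaries:
    def test_pure_function_of_log(self, example_agent):
        from conseq.agent import simulate_horizon_block

        log = simulate_horizon_block(1, 10, example_agent, 21)
        a = rt_summaries(log)
        b = rt_summaries(log)
        pd.testing.assert_frame_equal(a, b)

    def test_cells_indexed_by_condition(self):
        eps = [(0.5, 0.2, (SMALL, BIG)), (0.5, 0.01, (SMALL, BIG))]
        table = rt_summaries(synthetic_log(eps))
        assert set(table["delta"]) == {0.2, 0.01}
        assert set(table["trial_in_episode"]) == {1, 2}

    def test_ecdf_translation_by_shift(self):
        x, f = rt_ecdf([400.0, 500.0, 600.0])
        x2, f2 = rt_ecdf([300.0, 400.0, 500.0])
        assert np.allclose(x - 100.0, x2) and np.allclose(f, f2)
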