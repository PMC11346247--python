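"""Task generation: bounds, the gain/loss chain, enumeration, session layout."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from conseq.errors import ConfigurationError, StateError
from conseq.task import (
    BIG,
    SMALL,
    build_session,
    distinct_outcome_values,
    enumerate_episode_outcomes,
    next_trial_stimuli,
    outcome_range,
    sample_episode,
)


class TestMeanBounds:
    def test_horizon1_bounds(self, cfg):
        assert cfg.mean_bounds(1) == (0.4, pytest.approx(0.6))

    def test_horizon0_bounds(self, cfg):
        assert cfg.mean_bounds(0) == (0.1, pytest.approx(0.9))

    def test_degenerate_bounds_raise(self, cfg):
        bad = dataclasses.replace(cfg, G_by_horizon={0: 0.3, 1: 0.3, 2: 0.5})
        with pytest.raises(ConfigurationError):
            bad.mean_bounds(2)

    def test_block_not_divisible_raises(self, cfg):
        bad = dataclasses.replace(cfg, block_layout=((1, 101),))
        with pytest.raises(ConfigurationError):
            bad.validate()

    def test_m1_uniform_on_bounds(self, cfg, rng):
        draws = np.array(
            [sample_episode(1, cfg, rng).spec.m1 for _ in range(10_000)]
        )
        assert draws.min() >= 0.4 and draws.max() <= 0.6
        p = stats.kstest(draws, stats.uniform(loc=0.4, scale=0.2).cdf).pvalue
        assert p > 0.01


class TestEpisodeChain:
    def test_small_choice_raises_mean(self, cfg, rng):
        ep = sample_episode(1, cfg, rng)
        ep.spec = dataclasses.replace(ep.spec, m1=0.5, delta=0.2)
        ep.means = [0.5]
        pair = next_trial_stimuli(ep, SMALL)
        assert (pair.s_small, pair.s_big) == (pytest.approx(0.7), pytest.approx(0.9))

    def test_big_choice_lowers_mean(self, cfg, rng):
        ep = sample_episode(1, cfg, rng)
        ep.spec = dataclasses.replace(ep.spec, m1=0.5, delta=0.2)
        ep.means = [0.5]
        pair = next_trial_stimuli(ep, BIG)
        assert (pair.s_small, pair.s_big) == (pytest.approx(0.1), pytest.approx(0.3))

    def test_delta_constant_within_episode(self, cfg, rng):
        ep = sample_episode(2, cfg, rng)
        first = ep.current_pair()
        second = next_trial_stimuli(ep, SMALL)
        assert first.delta == second.delta

    def test_advancing_past_last_trial_raises(self, cfg, rng):
        ep = sample_episode(0, cfg, rng)
        ep.record_choice(BIG)
        with pytest.raises(StateError):
            next_trial_stimuli(ep, BIG)


class TestEnumeration:
    def test_horizon1_four_distinct_values(self):
        m, g, d = 0.47, 0.3, 0.1
        vals = distinct_outcome_values(1, m, d, g)
        expected = sorted(
            [2 * m + g, 2 * m + g - d, 2 * m - g + d, 2 * m - g], reverse=True
        )
        assert vals == pytest.approx(expected)
        assert len(vals) == 4

    def test_horizon1_extremes(self):
        lo, hi = outcome_range(1, 0.5, 0.2, 0.3)
        assert hi == pytest.approx(1.3)
        assert lo == pytest.approx(0.7)

    def test_degenerate_gain_and_delta(self):
        vals = distinct_outcome_values(1, 0.5, 0.0, 0.0)
        assert vals == pytest.approx([1.0])

    def test_path_count(self):
        assert len(enumerate_episode_outcomes(2, 0.5, 0.05, 0.19)) == 8

    @pytest.mark.parametrize("horizon", [1, 2])
    def test_always_big_never_optimal(self, cfg, rng, horizon):
        # the design property: greedy choice can never attain the maximum
        for _ in range(50):
            spec = sample_episode(horizon, cfg, rng).spec
            outcomes = dict(
                enumerate_episode_outcomes(horizon, spec.m1, spec.delta, spec.gain)
            )
            greedy = outcomes[(BIG,) * (horizon + 1)]
            assert greedy < max(outcomes.values())

    @pytest.mark.parametrize("horizon", [1, 2])
    def test_all_paths_stay_in_unit_interval(self, cfg, rng, horizon):
        import itertools

        for _ in range(50):
            spec = sample_episode(horizon, cfg, rng).spec
            for seq in itertools.product((SMALL, BIG), repeat=horizon + 1):
                mean = spec.m1
                for choice in seq:
                    assert 0.0 <= mean - spec.delta / 2 <= 1.0
                    assert 0.0 <= mean + spec.delta / 2 <= 1.0
                    mean += spec.gain if choice == SMALL else -spec.gain


class TestSessionPlan:
    def test_default_layout_counts(self, cfg):
        plan = build_session(cfg, 7)
        assert plan.episodes_per_horizon() == {0: 100, 1: 100, 2: 100}
        h2_trials = sorted(b.n_trials for b in plan.blocks if b.horizon == 2)
        assert h2_trials == [90, 105, 105]
        h1 = [b for b in plan.blocks if b.horizon == 1]
        assert all(e.horizon + 1 == 2 for b in h1 for e in b.episodes)

    def test_same_seed_identical_plans(self, cfg):
        assert build_session(cfg, 3).to_dict() == build_session(cfg, 3).to_dict()

    def test_different_seed_differs(self, cfg):
        assert build_session(cfg, 3).to_dict() != build_session(cfg, 4).to_dict()

    def test_scaled_config(self, cfg):
        small = cfg.scaled(10)
        plan = build_session(small, 5)
        assert plan.episodes_per_horizon() == {0: 10, 1: 10, 2: 10}

    def test_horizon_order_override(self, cfg):
        plan = build_session(cfg, 1, horizon_order=[2, 0, 1])
        seen = []
        for b in plan.blocks:
            if b.horizon not in seen:
                seen.append(b.horizon)
        assert seen == [2, 0, 1]

    def test_json_roundtrip(self, cfg, tmp_path):
        plan = build_session(cfg.scaled(5), 9)
        path = tmp_path / "plan.json"
        plan.to_json(path)
        from conseq.task import SessionPlan

        back = SessionPlan.from_json(path)
        assert back.to_dict() == plan.to_dict()

    def test_schedule_frame_columns(self, cfg):
        frame = build_session(cfg.scaled(3), 2).schedule_frame()
        assert {
            "block", "horizon", "episode", "trial_in_episode",
            "s_left", "s_right", "shown_first", "delta", "M",
        } <= set(frame.columns)
        first = frame[frame.trial_in_episode == 1]
        assert np.isclose(
            np.abs(first.s_left - first.s_right), first.delta
        ).all()
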