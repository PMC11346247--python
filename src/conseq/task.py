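"""Consequential-task session generation.

The task presents two partially filled containers per trial; the reward is
the fill fraction s in [0, 1] of the chosen container. Trials are grouped
into episodes of ``horizon + 1`` dependent trials: choosing the smaller
(larger) stimulus raises (lowers) the mean of the next trial's pair by the
gain G, so the greedy policy is suboptimal for horizon >= 1. Stimulus pairs
are ``M -/+ delta/2`` with per-episode difficulty delta and a base mean M
drawn uniformly from bounds that keep every reachable stimulus inside [0, 1].
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StateError

SMALL = "small"
BIG = "big"
LEFT = "left"
RIGHT = "right"

#: difficulty levels used in the study
DEFAULT_DELTA_LEVELS = (0.01, 0.05, 0.1, 0.15, 0.2)
#: one horizon-0 block, two horizon-1 blocks, three horizon-2 blocks
DEFAULT_BLOCK_LAYOUT = ((0, 100), (1, 100), (1, 100), (2, 105), (2, 105), (2, 90))
DEFAULT_GAINS = {0: 0.3, 1: 0.3, 2: 0.19}


def _as_generator(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class TaskConfig:
    """Session-level task parameters.

    ``block_layout`` lists (horizon, n_trials) pairs; each block must divide
    into whole episodes of ``horizon + 1`` trials. ``G_by_horizon`` maps each
    horizon to its gain/loss G in stimulus units.
    """

    horizon_set: tuple[int, ...] = (0, 1, 2)
    episodes_per_horizon: int = 100
    block_layout: tuple[tuple[int, int], ...] = DEFAULT_BLOCK_LAYOUT
    G_by_horizon: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_GAINS))
    delta_levels: tuple[float, ...] = DEFAULT_DELTA_LEVELS
    seed: int | None = None

    @property
    def delta_max(self) -> float:
        return max(self.delta_levels)

    def gain(self, horizon: int) -> float:
        try:
            return self.G_by_horizon[horizon]
        except KeyError:
            raise ConfigurationError(f"no gain G configured for horizon {horizon}")

    def mean_bounds(self, horizon: int) -> tuple[float, float]:
        """Uniform bounds for the episode base mean M_1 at the given horizon."""
        g = self.gain(horizon)
        lo = horizon * g + self.delta_max / 2
        hi = 1.0 - horizon * g - self.delta_max / 2
        if not lo < hi:
            raise ConfigurationError(
                f"degenerate mean bounds for horizon {horizon}: "
                f"[{lo:.3f}, {hi:.3f}] (G={g}, delta_max={self.delta_max})"
            )
        return lo, hi

    def validate(self) -> None:
        if not self.delta_levels:
            raise ConfigurationError("delta_levels is empty")
        for d in self.delta_levels:
            if not 0 < d < 1:
                raise ConfigurationError(f"delta level {d} outside (0, 1)")
        for h, g in self.G_by_horizon.items():
            if not 0 < g < 1:
                raise ConfigurationError(f"gain G={g} for horizon {h} outside (0, 1)")
        for h, n_trials in self.block_layout:
            if n_trials % (h + 1):
                raise ConfigurationError(
                    f"block of {n_trials} trials does not divide into "
                    f"whole horizon-{h} episodes"
                )
            self.mean_bounds(h)

    def scaled(self, episodes_per_horizon: int) -> "TaskConfig":
        """Return a config with the default layout rescaled to a smaller session."""
        layout = []
        for h in sorted(set(h for h, _ in self.block_layout)):
            layout.append((h, episodes_per_horizon * (h + 1)))
        return replace(
            self,
            episodes_per_horizon=episodes_per_horizon,
            block_layout=tuple(layout),
        )


@dataclass(frozen=True)
class StimulusPair:
    """One trial's two offers; values are fill fractions in [0, 1]."""

    s_small: float
    s_big: float
    M: float
    delta: float
    side_of_big: str
    shown_first: str
    episode_index: int
    trial_in_episode: int  # 1-based

    @property
    def s_left(self) -> float:
        return self.s_big if self.side_of_big == LEFT else self.s_small

    @property
    def s_right(self) -> float:
        return self.s_big if self.side_of_big == RIGHT else self.s_small


@dataclass(frozen=True)
class EpisodeSpec:
    """Replayable per-episode randomness: base mean, difficulty, coin flips."""

    horizon: int
    gain: float
    delta: float
    m1: float
    side_of_big: tuple[str, ...]
    shown_first: tuple[str, ...]
    episode_index: int = 0


@dataclass
class EpisodeState:
    """Mutable within-episode state: the mean chain and the choices made."""

    spec: EpisodeSpec
    means: list[float] = field(default_factory=list)
    choices: list[str | None] = field(default_factory=list)

    def __post_init__(self):
        if not self.means:
            self.means = [self.spec.m1]

    @property
    def horizon(self) -> int:
        return self.spec.horizon

    @property
    def n_trials(self) -> int:
        return self.spec.horizon + 1

    @property
    def trial_index(self) -> int:
        """1-based index of the current (not yet chosen) trial."""
        return len(self.choices) + 1

    @property
    def finished(self) -> bool:
        return len(self.choices) >= self.n_trials

    def current_pair(self) -> StimulusPair:
        if self.finished:
            raise StateError("episode already finished")
        t = self.trial_index
        m = self.means[t - 1]
        d = self.spec.delta
        return StimulusPair(
            s_small=m - d / 2,
            s_big=m + d / 2,
            M=m,
            delta=d,
            side_of_big=self.spec.side_of_big[t - 1],
            shown_first=self.spec.shown_first[t - 1],
            episode_index=self.spec.episode_index,
            trial_in_episode=t,
        )

    def record_choice(self, choice: str | None) -> None:
        """Record the executed choice and advance the mean chain.

        ``None`` marks a no-decision trial: the chain mean carries over
        unchanged (no choice exists to apply the gain rule to).
        """
        if self.finished:
            raise StateError("episode already finished")
        self.choices.append(choice)
        if len(self.choices) < self.n_trials:
            m = self.means[-1]
            if choice == SMALL:
                m += self.spec.gain
            elif choice == BIG:
                m -= self.spec.gain
            self.means.append(m)


def sample_episode(
    horizon: int, cfg: TaskConfig, rng, episode_index: int = 0
) -> EpisodeState:
    """Draw one episode: M_1 ~ U(mean bounds), delta ~ U(delta_levels), coin flips."""
    rng = _as_generator(rng)
    lo, hi = cfg.mean_bounds(horizon)
    m1 = float(rng.uniform(lo, hi))
    delta = float(cfg.delta_levels[rng.integers(len(cfg.delta_levels))])
    n = horizon + 1
    sides = tuple(LEFT if b else RIGHT for b in rng.integers(0, 2, n))
    firsts = tuple(LEFT if b else RIGHT for b in rng.integers(0, 2, n))
    spec = EpisodeSpec(
        horizon=horizon,
        gain=cfg.gain(horizon),
        delta=delta,
        m1=m1,
        side_of_big=sides,
        shown_first=firsts,
        episode_index=episode_index,
    )
    return EpisodeState(spec)


def next_trial_stimuli(state: EpisodeState, prev_choice: str, rng=None) -> StimulusPair:
    """Advance the episode after ``prev_choice`` and return the next pair.

    The new pair mean is M + G after a small choice and M - G after a big one;
    difficulty is constant within the episode. Side and presentation order
    come from the episode's pre-sampled coin flips (``rng`` is accepted for
    interface symmetry and ignored when flips are pre-sampled, which they
    always are for episodes built by this module).
    """
    if state.trial_index >= state.n_trials:
        raise StateError("no further trial in this episode")
    state.record_choice(prev_choice)
    return state.current_pair()


def enumerate_episode_outcomes(
    horizon: int, m: float, delta: float, gain: float
) -> list[tuple[tuple[str, ...], float]]:
    """Exhaustively enumerate all 2^(horizon+1) choice paths and their totals.

    Serves as the oracle for performance normalization; the cumulative value
    of a path sums the chosen stimulus at each trial while chaining the mean
    by +/- G.
    """
    if horizon < 0:
        raise ConfigurationError("horizon must be >= 0")
    out = []
    for seq in itertools.product((SMALL, BIG), repeat=horizon + 1):
        mean = m
        total = 0.0
        for choice in seq:
            total += mean + (delta / 2 if choice == BIG else -delta / 2)
            mean += gain if choice == SMALL else -gain
        out.append((seq, total))
    return out


def distinct_outcome_values(
    horizon: int, m: float, delta: float, gain: float, tol: float = 1e-12
) -> list[float]:
    """Distinct cumulative values, sorted descending."""
    totals = sorted((t for _, t in enumerate_episode_outcomes(horizon, m, delta, gain)))
    distinct: list[float] = []
    for t in totals:
        if not distinct or t - distinct[-1] > tol:
            distinct.append(t)
    return distinct[::-1]


def outcome_range(horizon: int, m: float, delta: float, gain: float) -> tuple[float, float]:
    totals = [t for _, t in enumerate_episode_outcomes(horizon, m, delta, gain)]
    return min(totals), max(totals)


@dataclass(frozen=True)
class BlockPlan:
    index: int
    horizon: int
    episodes: tuple[EpisodeSpec, ...]

    @property
    def n_trials(self) -> int:
        return len(self.episodes) * (self.horizon + 1)

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)


@dataclass(frozen=True)
class SessionPlan:
    """A fully pre-sampled, replayable session."""

    config: TaskConfig
    seed: int | None
    blocks: tuple[BlockPlan, ...]

    def episodes_per_horizon(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for b in self.blocks:
            counts[b.horizon] = counts.get(b.horizon, 0) + b.n_episodes
        return counts

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "conseq-plan-v1",
            "seed": self.seed,
            "config": {
                "horizon_set": list(self.config.horizon_set),
                "episodes_per_horizon": self.config.episodes_per_horizon,
                "block_layout": [list(b) for b in self.config.block_layout],
                "G_by_horizon": {str(k): v for k, v in self.config.G_by_horizon.items()},
                "delta_levels": list(self.config.delta_levels),
            },
            "blocks": [
                {
                    "index": b.index,
                    "horizon": b.horizon,
                    "episodes": [
                        {
                            "delta": e.delta,
                            "m1": e.m1,
                            "gain": e.gain,
                            "side_of_big": list(e.side_of_big),
                            "shown_first": list(e.shown_first),
                        }
                        for e in b.episodes
                    ],
                }
                for b in self.blocks
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionPlan":
        cfg = TaskConfig(
            horizon_set=tuple(d["config"]["horizon_set"]),
            episodes_per_horizon=d["config"]["episodes_per_horizon"],
            block_layout=tuple(tuple(b) for b in d["config"]["block_layout"]),
            G_by_horizon={int(k): v for k, v in d["config"]["G_by_horizon"].items()},
            delta_levels=tuple(d["config"]["delta_levels"]),
            seed=d.get("seed"),
        )
        blocks = []
        for b in d["blocks"]:
            eps = tuple(
                EpisodeSpec(
                    horizon=b["horizon"],
                    gain=e["gain"],
                    delta=e["delta"],
                    m1=e["m1"],
                    side_of_big=tuple(e["side_of_big"]),
                    shown_first=tuple(e["shown_first"]),
                    episode_index=i,
                )
                for i, e in enumerate(b["episodes"])
            )
            blocks.append(BlockPlan(index=b["index"], horizon=b["horizon"], episodes=eps))
        return cls(config=cfg, seed=d.get("seed"), blocks=tuple(blocks))

    @classmethod
    def from_json(cls, path) -> "SessionPlan":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def schedule_frame(self) -> pd.DataFrame:
        """One row per trial. M and stimuli are choice-dependent beyond the
        first trial of an episode and are left missing there."""
        rows = []
        for b in self.blocks:
            for e_idx, e in enumerate(b.episodes, start=1):
                for t in range(1, e.horizon + 2):
                    known = t == 1
                    m = e.m1 if known else np.nan
                    s_big = m + e.delta / 2 if known else np.nan
                    s_small = m - e.delta / 2 if known else np.nan
                    left_is_big = e.side_of_big[t - 1] == LEFT
                    rows.append(
                        {
                            "block": b.index,
                            "horizon": b.horizon,
                            "episode": e_idx,
                            "trial_in_episode": t,
                            "s_left": s_big if left_is_big else s_small,
                            "s_right": s_small if left_is_big else s_big,
                            "shown_first": e.shown_first[t - 1],
                            "delta": e.delta,
                            "M": m,
                        }
                    )
        return pd.DataFrame(rows)


def build_block(
    horizon: int, n_episodes: int, cfg: TaskConfig, rng, index: int = 0
) -> BlockPlan:
    rng = _as_generator(rng)
    eps = tuple(
        replace(sample_episode(horizon, cfg, rng, episode_index=i).spec, episode_index=i)
        for i in range(n_episodes)
    )
    return BlockPlan(index=index, horizon=horizon, episodes=eps)


def build_session(
    cfg: TaskConfig,
    rng=None,
    horizon_order: Sequence[int] | None = None,
) -> SessionPlan:
    """Build a replayable session plan.

    Blocks sharing a horizon stay in layout order; the order of horizon
    groups is a seeded random permutation unless ``horizon_order`` overrides
    it. Identical (cfg, seed) yield bit-identical plans.
    """
    cfg.validate()
    seed = cfg.seed
    if rng is None:
        rng = np.random.default_rng(seed)
    elif not isinstance(rng, np.random.Generator):
        seed = rng
        rng = np.random.default_rng(rng)
    groups: dict[int, list[tuple[int, int]]] = {}
    for h, n_trials in cfg.block_layout:
        groups.setdefault(h, []).append((h, n_trials))
    horizons = list(groups)
    if horizon_order is None:
        order = [horizons[i] for i in rng.permutation(len(horizons))]
    else:
        if sorted(horizon_order) != sorted(horizons):
            raise ConfigurationError(
                f"horizon_order {horizon_order} does not match layout horizons {horizons}"
            )
        order = list(horizon_order)
    blocks = []
    idx = 0
    for h in order:
        for _, n_trials in groups[h]:
            n_eps = n_trials // (h + 1)
            blocks.append(build_block(h, n_eps, cfg, rng, index=idx))
            idx += 1
    plan = SessionPlan(config=cfg, seed=seed, blocks=tuple(blocks))
    for h in cfg.horizon_set:
        got = plan.episodes_per_horizon().get(h, 0)
        if got != cfg.episodes_per_horizon:
            raise ConfigurationError(
                f"layout yields {got} horizon-{h} episodes, "
                f"expected {cfg.episodes_per_horizon}"
            )
    return plan
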