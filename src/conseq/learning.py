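"""Reinforcement-comparison strategy learning.

The strategy function phi(E, T_E) holds, per trial position within an
episode, the bias in [0, 1] with which the intention process is seeded
(psi(0) = phi). After each episode every position is updated by

    phi' = phi + k * R * (2*psi_tilde - 1) * (phi - 1)^2 * phi^2

where R is the subjective reward of the choice at that position. The
boundary factor (phi-1)^2 phi^2 vanishes at 0 and 1, which keeps phi in
[0, 1] and makes the endpoints absorbing; k = 0 freezes the strategy.

Reward signal. Between consecutive trials the only performance cue the
task offers is the shift of the pair mean, R = M(T_E+1) - M(T_E) = +G after
a small choice and -G after a big one. The final trial of an episode has no
successor, so the paper-level definition is silent there; this package
defines the terminal signal symmetrically, with the same magnitude G and
its sign set by the immediate value comparison (+G iff the larger stimulus
was taken) -- at the last trial no future consequence remains, so taking
the larger container is exactly as "correct" as the small choice is
earlier. With this convention the optimal policy (small ... small, big) is
reinforced at every position at the same rate. Two weaker alternatives are
kept for comparison: "half_delta" (chosen value minus the pair mean,
+/- delta/2) and "delta" (chosen minus foregone value, +/- delta); both move
phi an order of magnitude more slowly and do not reach the learned regime
within a 50-episode block at learning rates ~0.4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .task import BIG, EpisodeState

FINAL_REWARD_MODES = ("gain", "half_delta", "delta")


@dataclass(frozen=True)
class LearningParams:
    """k: learning rate (>= 0); phi0: initial bias, a scalar broadcast over
    trial positions or one value per position; final_reward: terminal-trial
    reward convention (see module docstring)."""

    k: float = 0.4
    phi0: float | tuple[float, ...] = 0.5
    final_reward: str = "gain"

    def __post_init__(self):
        if self.k < 0:
            raise ConfigurationError("learning rate k must be >= 0")
        vals = self.phi0 if isinstance(self.phi0, tuple) else (self.phi0,)
        for v in vals:
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"phi0 value {v} outside [0, 1]")
        if self.final_reward not in FINAL_REWARD_MODES:
            raise ConfigurationError(
                f"final_reward must be one of {FINAL_REWARD_MODES}"
            )

    def initial_phi(self, n_positions: int) -> np.ndarray:
        if isinstance(self.phi0, tuple):
            if len(self.phi0) != n_positions:
                raise ConfigurationError(
                    f"phi0 has {len(self.phi0)} entries for {n_positions} trial positions"
                )
            return np.array(self.phi0, dtype=float)
        return np.full(n_positions, float(self.phi0))


@dataclass
class StrategyState:
    """Current phi vector, one entry per trial position (resets per block)."""

    phi: np.ndarray

    @classmethod
    def initialize(cls, horizon: int, params: LearningParams) -> "StrategyState":
        return cls(phi=params.initial_phi(horizon + 1))

    def seed_intention(self, t_e: int) -> float:
        """psi(0) = phi(T_E); t_e is 1-based."""
        if not 1 <= t_e <= len(self.phi):
            raise ConfigurationError(f"trial position {t_e} out of range")
        return float(self.phi[t_e - 1])


def reward_signal(
    episode: EpisodeState, t_e: int, mode: str = "gain"
) -> float | None:
    """Subjective reward for the choice made at position ``t_e`` (1-based).

    Non-final trials: M(T_E+1) - M(T_E), i.e. +/- G. Final trial: per the
    convention in ``mode``. Returns None for no-decision trials (no choice
    to evaluate).
    """
    if t_e < 1 or t_e > len(episode.choices):
        raise ConfigurationError(f"episode has no completed trial at position {t_e}")
    choice = episode.choices[t_e - 1]
    if choice is None:
        return None
    if t_e < episode.n_trials:
        return episode.means[t_e] - episode.means[t_e - 1]
    sign = 1.0 if choice == BIG else -1.0
    if mode == "gain":
        return sign * episode.spec.gain
    if mode == "half_delta":
        return sign * episode.spec.delta / 2
    if mode == "delta":
        return sign * episode.spec.delta
    raise ConfigurationError(f"unknown final reward mode {mode!r}")


def update_strategy(
    state: StrategyState,
    psi_tilde: int,
    reward: float,
    t_e: int,
    params: LearningParams,
) -> StrategyState:
    """Apply one reinforcement-comparison update to position ``t_e``."""
    if psi_tilde not in (0, 1):
        raise ConfigurationError("psi_tilde must be 0 or 1")
    phi = state.phi.copy()
    p = phi[t_e - 1]
    p = p + params.k * reward * (2 * psi_tilde - 1) * (p - 1.0) ** 2 * p**2
    # the boundary factor keeps phi in [0,1] for the parameter ranges in use;
    # clip guards pathological k*R products
    phi[t_e - 1] = min(1.0, max(0.0, p))
    return StrategyState(phi=phi)


def update_after_episode(
    state: StrategyState,
    episode: EpisodeState,
    psi_tildes: Sequence[int | None],
    params: LearningParams,
) -> StrategyState:
    """End-of-episode batch update of every decided trial position.

    All updates read the pre-episode phi (positions are disjoint, so batch
    and sequential application coincide).
    """
    new = StrategyState(phi=state.phi.copy())
    for t_e in range(1, episode.n_trials + 1):
        if t_e > len(episode.choices):
            break
        psi = psi_tildes[t_e - 1]
        if psi is None:
            continue
        r = reward_signal(episode, t_e, mode=params.final_reward)
        if r is None:
            continue
        upd = update_strategy(StrategyState(phi=state.phi), psi, r, t_e, params)
        new.phi[t_e - 1] = upd.phi[t_e - 1]
    return new
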