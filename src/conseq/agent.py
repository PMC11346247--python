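"""Closed-loop agent: strategy -> intention -> neural dynamics -> choice.

Each trial seeds the intention process with the current strategy bias
phi(T_E), routes the rescaled stimulus drives through the mean-field layer
according to the intention, executes the perceptual choice, and advances
the episode's mean chain. Strategy updates are applied at the end of each
episode. One master seed is split into independent substreams for the
intention and neural layers so the two layers' draw counts cannot
interfere -- a requirement for stable parameter recovery.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seeds import as_seedseq
from .errors import ConfigurationError, NumericalError
from .intention import IntentionParams, simulate_intention
from .learning import LearningParams, StrategyState, update_after_episode
from .neural import NeuralParams, StimulusDrive, simulate_trial
from .rescale import RescaleParams
from .task import (
    BIG,
    LEFT,
    SMALL,
    BlockPlan,
    EpisodeState,
    SessionPlan,
    TaskConfig,
    build_block,
)

LOG_FORMAT = "conseq-log-v1"

LOG_COLUMNS = [
    "block",
    "horizon",
    "episode",
    "trial_in_episode",
    "delta",
    "gain",
    "M",
    "s_left",
    "s_right",
    "side_of_big",
    "shown_first",
    "psi0",
    "psi_tilde",
    "chosen_side",
    "chosen_value",
    "choice_class",
    "decision_time",
    "rt",
    "no_decision",
]


@dataclass(frozen=True)
class AgentParams:
    neural: NeuralParams = field(default_factory=NeuralParams)
    intention: IntentionParams = field(default_factory=IntentionParams)
    learning: LearningParams = field(default_factory=LearningParams)
    rescale: RescaleParams = field(default_factory=RescaleParams)
    rt_shift: float = 0.0  # ms added to decision time (anticipation < 0)


@dataclass
class BehavioralLog:
    """Ordered trial records plus the provenance needed to replay them."""

    frame: pd.DataFrame
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in LOG_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ConfigurationError(f"log frame missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def decided(self) -> pd.DataFrame:
        return self.frame[~self.frame["no_decision"]]

    def block(self, index: int) -> "BehavioralLog":
        return BehavioralLog(
            frame=self.frame[self.frame["block"] == index].reset_index(drop=True),
            seed=self.seed,
            meta=self.meta,
        )

    @property
    def block_indices(self) -> list[int]:
        return sorted(self.frame["block"].unique().tolist())

    def to_csv(self, path) -> None:
        header = {"format": LOG_FORMAT, "seed": self.seed, **self.meta}
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            self.frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "BehavioralLog":
        with open(path) as fh:
            first = fh.readline()
            meta = {}
            if first.startswith("#"):
                try:
                    meta = json.loads(first.lstrip("# ").strip())
                except json.JSONDecodeError:
                    pass
                body = fh.read()
            else:
                body = first + fh.read()
        frame = pd.read_csv(io.StringIO(body))
        missing = [c for c in LOG_COLUMNS if c not in frame.columns]
        if missing:
            raise ConfigurationError(f"not a {LOG_FORMAT} file; missing {missing}")
        for col in ("chosen_side", "choice_class"):
            frame[col] = frame[col].where(pd.notna(frame[col]), None)
        frame["no_decision"] = frame["no_decision"].astype(bool)
        seed = meta.pop("seed", None)
        meta.pop("format", None)
        return cls(frame=frame, seed=seed, meta=meta)

    @classmethod
    def concat(cls, logs: Sequence["BehavioralLog"], seed=None, meta=None) -> "BehavioralLog":
        frame = pd.concat([l.frame for l in logs], ignore_index=True)
        return cls(frame=frame, seed=seed, meta=meta or {})


def _run_trial(
    episode: EpisodeState,
    strategy: StrategyState,
    agent: AgentParams,
    intention_rng: np.random.Generator,
    neural_rng: np.random.Generator,
) -> dict:
    t_e = episode.trial_index
    pair = episode.current_pair()
    psi0 = strategy.seed_intention(t_e)
    intent = simulate_intention(psi0, agent.intention, intention_rng)
    drive = StimulusDrive(
        lambda_l=float(agent.rescale.apply(pair.s_left)),
        lambda_r=float(agent.rescale.apply(pair.s_right)),
    )
    try:
        res = simulate_trial(drive, intent.psi_tilde, agent.neural, neural_rng)
    except NumericalError as err:
        raise NumericalError(
            f"episode {pair.episode_index}, trial {t_e}: {err}"
        ) from err
    if res.winner == "none":
        chosen_side = None
        chosen_value = np.nan
        choice_class = None
        decision_time = np.nan
        rt = np.nan
    else:
        chosen_side = res.winner
        chosen_value = pair.s_left if chosen_side == LEFT else pair.s_right
        choice_class = BIG if chosen_side == pair.side_of_big else SMALL
        decision_time = res.decision_time
        rt = decision_time + agent.rt_shift
    episode.record_choice(choice_class)
    return {
        "trial_in_episode": t_e,
        "delta": pair.delta,
        "gain": episode.spec.gain,
        "M": pair.M,
        "s_left": pair.s_left,
        "s_right": pair.s_right,
        "side_of_big": pair.side_of_big,
        "shown_first": pair.shown_first,
        "psi0": psi0,
        "psi_tilde": intent.psi_tilde,
        "chosen_side": chosen_side,
        "chosen_value": chosen_value,
        "choice_class": choice_class,
        "decision_time": decision_time,
        "rt": rt,
        "no_decision": res.winner == "none",
    }


def run_block(
    block: BlockPlan,
    agent: AgentParams,
    rng,
    block_index: int | None = None,
) -> BehavioralLog:
    """Simulate one block; the strategy state is initialized from
    agent.learning.phi0 and updated after every episode."""
    ss = as_seedseq(rng)
    intention_rng, neural_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    strategy = StrategyState.initialize(block.horizon, agent.learning)
    rows = []
    idx = block.index if block_index is None else block_index
    for e_num, spec in enumerate(block.episodes, start=1):
        episode = EpisodeState(spec)
        psi_tildes: list[int | None] = []
        for _ in range(episode.n_trials):
            row = _run_trial(episode, strategy, agent, intention_rng, neural_rng)
            psi_tildes.append(None if row["no_decision"] else row["psi_tilde"])
            row.update(block=idx, horizon=block.horizon, episode=e_num)
            rows.append(row)
        strategy = update_after_episode(strategy, episode, psi_tildes, agent.learning)
    frame = pd.DataFrame(rows, columns=LOG_COLUMNS)
    return BehavioralLog(frame=frame, meta={"final_phi": strategy.phi.tolist()})


def run_session(plan: SessionPlan, agent: AgentParams, seed) -> BehavioralLog:
    """Simulate a full session; phi resets at every block boundary."""
    ss = as_seedseq(seed)
    children = ss.spawn(len(plan.blocks))
    logs = [run_block(b, agent, child) for b, child in zip(plan.blocks, children)]
    log = BehavioralLog.concat(logs, seed=_seed_int(seed))
    log.meta["final_phi_by_block"] = {
        str(b.index): l.meta["final_phi"] for b, l in zip(plan.blocks, logs)
    }
    return log


def _seed_int(seed) -> int | None:
    return int(seed) if np.isscalar(seed) else None


def simulate_horizon_block(
    horizon: int,
    n_episodes: int,
    agent: AgentParams,
    seed,
    cfg: TaskConfig | None = None,
) -> BehavioralLog:
    """Build a fresh single-block plan for ``horizon`` and simulate it."""
    cfg = cfg or TaskConfig()
    ss = as_seedseq(seed)
    task_ss, sim_ss = ss.spawn(2)
    block = build_block(horizon, n_episodes, cfg, np.random.default_rng(task_ss))
    log = run_block(block, agent, sim_ss)
    log.seed = _seed_int(seed)
    return log


def _set_param(agent: AgentParams, name: str, value: float) -> AgentParams:
    if name in ("tau", "sigma", "delta_thr"):
        return replace(agent, neural=replace(agent.neural, **{name: value}))
    if name in ("sigma_psi", "tau_psi"):
        return replace(agent, intention=replace(agent.intention, **{name: value}))
    if name == "k":
        return replace(agent, learning=replace(agent.learning, k=value))
    if name == "phi0":
        return replace(agent, learning=replace(agent.learning, phi0=value))
    if name == "beta":
        return replace(agent, rescale=replace(agent.rescale, beta=value))
    if name == "rt_shift":
        return replace(agent, rt_shift=value)
    raise ConfigurationError(f"unknown sweep parameter {name!r}")


def sweep_parameter_space(
    grid: dict[str, Iterable[float]],
    base: AgentParams,
    reps: int,
    seed,
    horizon: int = 1,
    n_episodes: int = 50,
    cfg: TaskConfig | None = None,
) -> pd.DataFrame:
    """Full-factorial sweep; one row per (cell, rep) with RT/PF/t_L summaries.

    Metrics per run: mean and sd of RT over decided trials, mean episode
    performance, and the learning time t_L (NOT_LEARNED imputed as
    n_episodes + 1).
    """
    from .metrics import episode_performance_frame, learning_time

    names = list(grid)
    values = [np.atleast_1d(np.asarray(grid[n], dtype=float)) for n in names]
    mesh = np.meshgrid(*values, indexing="ij") if names else []
    cells = (
        np.stack([m.ravel() for m in mesh], axis=1) if names else np.zeros((1, 0))
    )
    ss = as_seedseq(seed)
    rows = []
    for cell in cells:
        a = base
        for n, v in zip(names, cell):
            a = _set_param(a, n, float(v))
        for rep, child in enumerate(ss.spawn(reps)):
            log = _simulate_from_seedseq(horizon, n_episodes, a, child, cfg)
            decided = log.decided
            assess = learning_time(log)
            pf = episode_performance_frame(log)["pf"].mean()
            rows.append(
                {
                    **{n: float(v) for n, v in zip(names, cell)},
                    "rep": rep,
                    "mean_rt": decided["rt"].mean(),
                    "sd_rt": decided["rt"].std(),
                    "mean_pf": pf,
                    "t_l": assess.t_l if assess.learned else n_episodes + 1,
                    "learned": assess.learned,
                }
            )
    return pd.DataFrame(rows)


def _simulate_from_seedseq(horizon, n_episodes, agent, ss, cfg):
    cfg = cfg or TaskConfig()
    task_ss, sim_ss = ss.spawn(2)
    block = build_block(horizon, n_episodes, cfg, np.random.default_rng(task_ss))
    return run_block(block, agent, sim_ss)
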