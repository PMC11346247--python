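"""Behavioral summaries computed from a BehavioralLog.

All metrics are pure functions of the log: performance (PF) normalizes each
episode's cumulative value between the worst (0) and best (1) attainable
path from the enumeration oracle; P_oc marks per-trial optimal choices
(small on every non-final trial, big on the final one); VD is the accuracy
on the hardest horizon-0 discriminations; the learning time t_L is the
first episode from which the optimal strategy is employed in at least 9 of
the next 10 episodes and 75% of the episodes after that window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agent import BehavioralLog
from .errors import MetricUndefinedError
from .task import BIG, SMALL, outcome_range


@dataclass(frozen=True)
class EpisodeSummary:
    block: int
    episode: int
    horizon: int
    delta: float
    pf: float
    choices: tuple[Optional[str], ...]
    optimal: bool
    complete: bool


@dataclass(frozen=True)
class LearningAssessment:
    t_l: Optional[int]  # episode index (1-based, within the learning block)
    learned: bool
    block: Optional[int]
    window: int
    hits: int
    tail_frac: float

    NOT_LEARNED = None


def optimal_choice_indicator(choice_class: Optional[str], trial_in_episode: int, horizon: int) -> int:
    """1 iff the choice is optimal: big on the final trial, small before it."""
    if choice_class is None:
        return 0
    final = trial_in_episode == horizon + 1
    return int(choice_class == (BIG if final else SMALL))


def episode_performance_frame(log: BehavioralLog) -> pd.DataFrame:
    """Per-episode summary with min-max normalized performance.

    No-decision trials contribute 0 to the achieved value (task scoring);
    PF is clamped to [0, 1] in that degenerate case. Episodes with missing
    trial rows are marked incomplete and get NaN PF.
    """
    rows = []
    for (block, episode), g in log.frame.groupby(["block", "episode"], sort=True):
        g = g.sort_values("trial_in_episode")
        horizon = int(g["horizon"].iloc[0])
        n_expected = horizon + 1
        complete = len(g) == n_expected and list(g["trial_in_episode"]) == list(
            range(1, n_expected + 1)
        )
        delta = float(g["delta"].iloc[0])
        gain = float(g["gain"].iloc[0])
        m1 = float(g.loc[g["trial_in_episode"] == 1, "M"].iloc[0]) if complete else np.nan
        choices = tuple(g["choice_class"])
        indicators = [
            optimal_choice_indicator(c, int(t), horizon)
            for c, t in zip(g["choice_class"], g["trial_in_episode"])
        ]
        if complete:
            achieved = float(np.nansum(g["chosen_value"].to_numpy(dtype=float)))
            worst, best = outcome_range(horizon, m1, delta, gain)
            pf = (achieved - worst) / (best - worst) if best > worst else 1.0
            pf = min(1.0, max(0.0, pf))
        else:
            pf = np.nan
        rows.append(
            {
                "block": block,
                "episode": episode,
                "horizon": horizon,
                "delta": delta,
                "gain": gain,
                "m1": m1,
                "pf": pf,
                "complete": complete,
                "all_decided": complete and not g["no_decision"].any(),
                "optimal": bool(complete and all(indicators)),
                "n_optimal_choices": int(sum(indicators)),
            }
        )
    return pd.DataFrame(rows)


def episode_performance(log: BehavioralLog, episode: int, block: int | None = None) -> float:
    """PF of one episode; incomplete episodes raise MetricUndefinedError."""
    frame = episode_performance_frame(log)
    sel = frame["episode"] == episode
    if block is not None:
        sel &= frame["block"] == block
    rows = frame[sel]
    if rows.empty:
        raise MetricUndefinedError(f"episode {episode} not in log")
    row = rows.iloc[0]
    if not row["complete"]:
        raise MetricUndefinedError(f"episode {episode} is incomplete")
    return float(row["pf"])


def optimal_choice_column(log: BehavioralLog) -> pd.Series:
    """Per-trial P_oc data (no-decision trials excluded as NaN)."""
    f = log.frame
    vals = [
        np.nan
        if nd
        else optimal_choice_indicator(c, int(t), int(h))
        for c, t, h, nd in zip(
            f["choice_class"], f["trial_in_episode"], f["horizon"], f["no_decision"]
        )
    ]
    return pd.Series(vals, index=f.index, name="optimal_choice")


def visual_discrimination(
    log: BehavioralLog,
    last_n_episodes: int = 80,
    hardest: float | None = None,
) -> float:
    """Accuracy on the hardest discriminations of the horizon-0 block.

    Fraction of trials in the last ``last_n_episodes`` horizon-0 episodes
    with the smallest stimulus difference in which the larger stimulus was
    selected (decided trials only).
    """
    f = log.frame
    h0 = f[f["horizon"] == 0]
    if h0.empty:
        raise MetricUndefinedError("log contains no horizon-0 block")
    if hardest is None:
        hardest = float(h0["delta"].min())
    episodes = sorted(h0["episode"].unique())
    tail = set(episodes[-last_n_episodes:])
    sel = h0[(h0["episode"].isin(tail)) & (np.isclose(h0["delta"], hardest)) & (~h0["no_decision"])]
    if sel.empty:
        raise MetricUndefinedError(
            f"no decided trials at delta={hardest} in the last {last_n_episodes} episodes"
        )
    return float((sel["choice_class"] == BIG).mean())


def scan_learning_stream(
    stream: Sequence[int],
    window: int = 10,
    hits: int = 9,
    tail_frac: float = 0.75,
) -> Optional[int]:
    """First 1-based index i at which the learning criterion holds.

    Criterion: the episode at i is itself optimal, among the ``window``
    indicators starting at i at least ``hits`` are 1 (windows truncated by
    the stream end require the same proportion, rounded up), and at least
    ``tail_frac`` of the indicators after the window are 1 (vacuous for an
    empty tail). Anchoring at an optimal episode makes t_L the first episode
    of sustained optimal play (a stream of 11 zeros then ones yields 12).
    """
    s = np.asarray(stream, dtype=int)
    n = len(s)
    for i in range(n):
        if not s[i]:
            continue
        win = s[i : i + window]
        need = hits if len(win) == window else math.ceil(hits / window * len(win))
        if win.sum() < need:
            continue
        tail = s[i + window :]
        if len(tail) and tail.mean() < tail_frac:
            continue
        return i + 1
    return None


def learning_time(
    log: BehavioralLog,
    window: int = 10,
    hits: int = 9,
    tail_frac: float = 0.75,
    exclude_hardest: bool = True,
) -> LearningAssessment:
    """Session learning time: first block in which the criterion is met.

    Episode-level indicator: every trial of the episode was an optimal
    choice. Episodes at the hardest difficulty level are excluded from the
    stream (perceptual errors, not strategy); t_L is reported in the
    original episode numbering of its block.
    """
    frame = episode_performance_frame(log)
    for block in sorted(frame["block"].unique()):
        fb = frame[frame["block"] == block].sort_values("episode")
        # drop hardest-difficulty episodes (perceptual errors, not strategy);
        # a single-difficulty block has no perceptual gradient to exclude
        if exclude_hardest and fb["delta"].nunique() > 1:
            fb = fb[~np.isclose(fb["delta"], float(fb["delta"].min()))]
        if fb.empty:
            continue
        stream = fb["optimal"].astype(int).tolist()
        pos = scan_learning_stream(stream, window=window, hits=hits, tail_frac=tail_frac)
        if pos is not None:
            t_l = int(fb["episode"].iloc[pos - 1])
            return LearningAssessment(
                t_l=t_l, learned=True, block=int(block),
                window=window, hits=hits, tail_frac=tail_frac,
            )
    return LearningAssessment(
        t_l=None, learned=False, block=None,
        window=window, hits=hits, tail_frac=tail_frac,
    )


def assign_learning_groups(
    t_ls: Sequence[Optional[int]], quantiles: tuple[float, float] = (1 / 3, 2 / 3)
) -> list[str]:
    """Label learners fast/medium/slow by t_L quantiles; NL for non-learners."""
    learned = np.array([t for t in t_ls if t is not None], dtype=float)
    if learned.size:
        lo, hi = np.quantile(learned, quantiles)
    labels = []
    for t in t_ls:
        if t is None:
            labels.append("NL")
        elif t <= lo:
            labels.append("fast")
        elif t <= hi:
            labels.append("medium")
        else:
            labels.append("slow")
    return labels


def rt_summaries(
    log: BehavioralLog,
    by: Sequence[str] = ("horizon", "trial_in_episode", "delta"),
) -> pd.DataFrame:
    """Per-cell RT mean/sd/count over decided trials (negative RTs allowed)."""
    decided = log.decided
    if decided.empty:
        raise MetricUndefinedError("no decided trials in log")
    out = (
        decided.groupby(list(by))["rt"]
        .agg(mean_rt="mean", sd_rt="std", n="count")
        .reset_index()
    )
    return out


def rt_ecdf(rts: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF sample points (x sorted, F(x))."""
    x = np.sort(np.asarray(rts, dtype=float))
    if x.size == 0:
        raise MetricUndefinedError("empty RT sample")
    return x, np.arange(1, x.size + 1) / x.size
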