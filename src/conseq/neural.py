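"""Two-population mean-field decision dynamics.

The firing rates r_L, r_R of two mutually inhibiting, self-exciting
excitatory pools integrate the stimulus drives lambda_L, lambda_R through a
sigmoid transfer function until the rate difference |r_L - r_R| crosses the
decision threshold. The intention bit psi_tilde routes each drive to the
pool whose win expresses that intention: with psi_tilde = 1 the pool seeing
the larger drive is favored (the plain competitive system), with
psi_tilde = 0 the drives are swapped so the smaller stimulus tends to win.

Units: rates, drives and thresholds in ms^-1 (0.025 ms^-1 == 25 Hz), times
in ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .errors import ConfigurationError, NumericalError

LEFT = "left"
RIGHT = "right"
NONE = "none"

_WINNER_NAMES = {_kernels.WIN_LEFT: LEFT, _kernels.WIN_RIGHT: RIGHT, _kernels.WIN_NONE: NONE}


def hz_to_per_ms(value_hz: float) -> float:
    """Convert a rate given in Hz to the internal ms^-1 scale (25 Hz -> 0.025)."""
    return value_hz / 1000.0


@dataclass(frozen=True)
class NeuralParams:
    """Parameters of the mean-field layer.

    tau: membrane/population time constant (ms).
    sigma: additive noise amplitude (ms^-1).
    delta_thr: decision threshold on |r_L - r_R| (ms^-1).
    w_plus / w_minus: recurrent excitation / mutual inhibition (dimensionless).
    f_max, theta, k_sig: sigmoid saturation, midpoint and slope (ms^-1).
    dt: Euler-Maruyama step (ms); t_max: trial cutoff (ms), mirroring the
    task's 4 s response window.
    """

    tau: float = 80.0
    sigma: float = 0.003
    delta_thr: float = 0.025
    w_plus: float = 1.4
    w_minus: float = 1.5
    f_max: float = 0.04
    theta: float = 0.015
    k_sig: float = 0.022
    dt: float = 0.5
    t_max: float = 4000.0

    def __post_init__(self):
        if self.tau <= 0 or self.dt <= 0 or self.t_max <= 0:
            raise ConfigurationError("tau, dt and t_max must be positive")
        if self.dt > self.tau / 10:
            raise ConfigurationError(f"dt={self.dt} too coarse for tau={self.tau}")
        if not 0 < self.delta_thr < self.f_max:
            raise ConfigurationError("delta_thr must lie in (0, f_max)")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max / self.dt))

    @classmethod
    def with_threshold_hz(cls, delta_thr_hz: float, **kwargs) -> "NeuralParams":
        return cls(delta_thr=hz_to_per_ms(delta_thr_hz), **kwargs)


@dataclass(frozen=True)
class StimulusDrive:
    """Input intensities (ms^-1) for the left and right pools."""

    lambda_l: float
    lambda_r: float

    def __post_init__(self):
        if self.lambda_l < 0 or self.lambda_r < 0:
            raise ConfigurationError("drives must be >= 0")


@dataclass(frozen=True)
class DynamicsResult:
    winner: str  # left | right | none
    decision_time: Optional[float]  # ms, None when winner == "none"
    traces: Optional[tuple[np.ndarray, np.ndarray, np.ndarray]] = None  # (t, r_L, r_R)


def transfer(x, params: NeuralParams):
    """Sigmoid transfer f(x) = F_max / (1 + exp(-(x - theta)/k_sig))."""
    return params.f_max / (1.0 + np.exp(-(np.asarray(x, dtype=float) - params.theta) / params.k_sig))


def _mixed_drives(drive: StimulusDrive, psi_tilde: int) -> tuple[float, float]:
    p = float(psi_tilde)
    lam_l = p * drive.lambda_l + (1.0 - p) * drive.lambda_r
    lam_r = p * drive.lambda_r + (1.0 - p) * drive.lambda_l
    return lam_l, lam_r


def _seed_from(rng) -> int:
    if isinstance(rng, np.random.Generator):
        return int(rng.integers(0, 2**31))
    return int(rng) % 2**31


def simulate_trial(
    drive: StimulusDrive,
    psi_tilde: int,
    params: NeuralParams,
    rng,
    record_traces: bool = False,
) -> DynamicsResult:
    """Integrate one trial; stop at the first strict threshold crossing.

    With psi_tilde = 1 the system is the plain two-pool competition; with
    psi_tilde = 0 the drives are exchanged between pools. Raises
    NumericalError if the state blows up.
    """
    if psi_tilde not in (0, 1):
        raise ConfigurationError("psi_tilde must be 0 or 1")
    lam_l, lam_r = _mixed_drives(drive, psi_tilde)
    seed = _seed_from(rng)
    args = (
        lam_l,
        lam_r,
        params.tau,
        params.sigma,
        params.delta_thr,
        params.w_plus,
        params.w_minus,
        params.f_max,
        params.theta,
        params.k_sig,
        params.dt,
        params.n_steps,
        seed,
    )
    if record_traces:
        winner, steps, r_l, r_r = _kernels.mean_field_trace(*args)
        t = np.arange(steps + 1) * params.dt
        traces = (t, r_l, r_r)
    else:
        winner, t_dec = _kernels.mean_field_trial(*args)
        traces = None
    if winner == _kernels.WIN_BLOWUP:
        raise NumericalError(
            f"non-finite firing rate (lambda=({lam_l:.4g},{lam_r:.4g}), "
            f"tau={params.tau}, dt={params.dt})"
        )
    if record_traces:
        t_dec = steps * params.dt
    name = _WINNER_NAMES[winner]
    return DynamicsResult(
        winner=name,
        decision_time=None if name == NONE else float(t_dec),
        traces=traces,
    )


def simulate_trials(
    lam_l: np.ndarray,
    lam_r: np.ndarray,
    psi_tilde: np.ndarray | int,
    params: NeuralParams,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized batch of independent trials.

    Returns (winners, decision_times); winners are +1 (left), -1 (right) or
    0 (no decision before t_max), decision times in ms (t_max for none).
    """
    lam_l = np.asarray(lam_l, dtype=float)
    lam_r = np.asarray(lam_r, dtype=float)
    psi = np.broadcast_to(np.asarray(psi_tilde), lam_l.shape)
    mixed_l = np.where(psi == 1, lam_l, lam_r)
    mixed_r = np.where(psi == 1, lam_r, lam_l)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    seeds = rng.integers(0, 2**31, size=lam_l.shape[0])
    winners, times = _kernels.mean_field_batch(
        np.ascontiguousarray(mixed_l),
        np.ascontiguousarray(mixed_r),
        params.tau,
        params.sigma,
        params.delta_thr,
        params.w_plus,
        params.w_minus,
        params.f_max,
        params.theta,
        params.k_sig,
        params.dt,
        params.n_steps,
        seeds,
    )
    if np.any(winners == _kernels.WIN_BLOWUP):
        raise NumericalError("non-finite firing rate in batch simulation")
    return winners, times


def estimate_vd(
    delta: float,
    params: NeuralParams,
    rescale,
    n_runs: int,
    rng,
    m_bounds: tuple[float, float] = (0.1, 0.9),
) -> float:
    """Fraction of trials in which the larger-stimulus pool wins.

    Simulates ``n_runs`` independent psi_tilde = 1 trials with stimulus pairs
    M -/+ delta/2, M ~ U(m_bounds) (the horizon-0 base-mean range), mapped to
    drives by ``rescale``. No-decision trials count as failures.
    """
    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    m = rng.uniform(m_bounds[0], m_bounds[1], size=n_runs)
    s_big = m + delta / 2
    s_small = m - delta / 2
    big_left = rng.integers(0, 2, size=n_runs).astype(bool)
    lam_big = rescale.apply(s_big)
    lam_small = rescale.apply(s_small)
    lam_l = np.where(big_left, lam_big, lam_small)
    lam_r = np.where(big_left, lam_small, lam_big)
    winners, _ = simulate_trials(lam_l, lam_r, 1, params, rng)
    chose_big = (winners == _kernels.WIN_LEFT) == big_left
    chose_big &= winners != _kernels.WIN_NONE
    return float(np.mean(chose_big))
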