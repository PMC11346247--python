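"""Double-well intended-decision process.

A scalar state psi evolves in the potential E(psi) = psi^2 (psi - 1)^2,
whose basins at 0 and 1 stand for intending the smaller / bigger stimulus.
The strategy bias seeds the initial condition; Gaussian noise scaled by the
decisional uncertainty sigma_psi acts mainly at onset (its amplitude decays
as 1/(1 + t_ms)^2), so the basin is chosen early and the late dynamics are
quasi-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .errors import ConfigurationError

#: integration clamp keeping noise-driven excursions near [0, 1]
CLAMP = (-0.2, 1.2)


@dataclass(frozen=True)
class IntentionParams:
    """tau_psi in ms, sigma_psi in ms^-1; eps is the basin half-width used to
    classify settlement."""

    tau_psi: float = 10.0
    sigma_psi: float = 0.4
    dt: float = 1.0
    eps: float = 0.02
    t_max: float = 500.0

    def __post_init__(self):
        if self.tau_psi <= 0 or self.dt <= 0 or self.t_max <= 0:
            raise ConfigurationError("tau_psi, dt and t_max must be positive")
        if not 0 < self.eps < 0.5:
            raise ConfigurationError("eps must lie in (0, 0.5)")
        if self.sigma_psi < 0:
            raise ConfigurationError("sigma_psi must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max / self.dt))


@dataclass(frozen=True)
class IntentionResult:
    psi_tilde: int  # 0 = small, 1 = big
    settle_time: float  # ms
    settled: bool  # False when classified by nearest basin at cutoff
    trace: Optional[np.ndarray] = None


def _seed_from(rng) -> int:
    if isinstance(rng, np.random.Generator):
        return int(rng.integers(0, 2**31))
    return int(rng) % 2**31


def _resolve_separatrix(psi0: float, params: IntentionParams, rng) -> float:
    # noiseless start exactly on the separatrix: break the tie with one
    # seeded fair coin flip (degenerate case, documented)
    if params.sigma_psi == 0.0 and psi0 == 0.5:
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        return 0.5 + (1e-9 if rng.integers(0, 2) else -1e-9)
    return psi0


def simulate_intention(
    psi0: float,
    params: IntentionParams,
    rng,
    record_trace: bool = False,
) -> IntentionResult:
    """Run the intention process from the bias psi0 in [0, 1]."""
    if not 0.0 <= psi0 <= 1.0:
        raise ConfigurationError(f"psi0={psi0} outside [0, 1]")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    psi0 = _resolve_separatrix(psi0, params, rng)
    seed = _seed_from(rng)
    args = (
        psi0,
        params.tau_psi,
        params.sigma_psi,
        params.dt,
        params.eps,
        params.n_steps,
        CLAMP[0],
        CLAMP[1],
        seed,
    )
    if record_trace:
        psi_tilde, steps, settled, path = _kernels.intention_trace(*args)
        return IntentionResult(int(psi_tilde), steps * params.dt, bool(settled), path)
    psi_tilde, t, settled = _kernels.intention_trial(*args)
    return IntentionResult(int(psi_tilde), float(t), bool(settled))


def simulate_intentions(
    psi0s: np.ndarray, params: IntentionParams, rng
) -> np.ndarray:
    """Vectorized batch; returns the psi_tilde array."""
    psi0s = np.asarray(psi0s, dtype=float)
    if np.any((psi0s < 0) | (psi0s > 1)):
        raise ConfigurationError("psi0 outside [0, 1]")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    resolved = np.array([_resolve_separatrix(p, params, rng) for p in psi0s])
    seeds = rng.integers(0, 2**31, size=resolved.shape[0])
    out, _ = _kernels.intention_batch(
        np.ascontiguousarray(resolved),
        params.tau_psi,
        params.sigma_psi,
        params.dt,
        params.eps,
        params.n_steps,
        CLAMP[0],
        CLAMP[1],
        seeds,
    )
    return out


def intention_probability(
    psi0: float, params: IntentionParams, n_runs: int, rng
) -> float:
    """Monte-Carlo estimate of P(psi_tilde = 1 | psi0)."""
    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    out = simulate_intentions(np.full(n_runs, psi0), params, rng)
    return float(np.mean(out))
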