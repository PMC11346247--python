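"""Numba kernels for the stochastic integrators.

Both layers are integrated with Euler--Maruyama. All rates, drives and
thresholds are expressed in ms^-1 and all times in ms. Each kernel seeds
numba's internal RNG from an explicit 32-bit seed so that every trial is an
independently reproducible stream.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# winner codes returned by the mean-field kernel
WIN_LEFT = 1
WIN_RIGHT = -1
WIN_NONE = 0
WIN_BLOWUP = -2


@njit(cache=True, fastmath={'contract', 'reassoc', 'nsz', 'arcp'})
def _sigmoid(x, f_max, theta, k_sig):
    return f_max / (1.0 + np.exp(-(x - theta) / k_sig))


@njit(cache=True, fastmath={'contract', 'reassoc', 'nsz', 'arcp'})
def mean_field_trial(
    lam_l,
    lam_r,
    tau,
    sigma,
    delta_thr,
    w_plus,
    w_minus,
    f_max,
    theta,
    k_sig,
    dt,
    n_max,
    seed,
):
    """Integrate the two-population rate equations until |r_L - r_R| > delta_thr.

    Returns (winner, time_ms); winner is WIN_LEFT/WIN_RIGHT/WIN_NONE, or
    WIN_BLOWUP if the state became non-finite.
    """
    np.random.seed(seed)
    r_l = 0.0
    r_r = 0.0
    amp = sigma * np.sqrt(dt) / tau
    for i in range(n_max):
        f_l = _sigmoid(lam_l + w_plus * r_l - w_minus * r_r, f_max, theta, k_sig)
        f_r = _sigmoid(lam_r + w_plus * r_r - w_minus * r_l, f_max, theta, k_sig)
        r_l += dt / tau * (f_l - r_l) + amp * np.random.normal()
        r_r += dt / tau * (f_r - r_r) + amp * np.random.normal()
        if not (np.isfinite(r_l) and np.isfinite(r_r)):
            return WIN_BLOWUP, (i + 1) * dt
        d = r_l - r_r
        if d > delta_thr:
            return WIN_LEFT, (i + 1) * dt
        if d < -delta_thr:
            return WIN_RIGHT, (i + 1) * dt
    return WIN_NONE, n_max * dt


@njit(cache=True, fastmath={'contract', 'reassoc', 'nsz', 'arcp'})
def mean_field_batch(
    lam_l,
    lam_r,
    tau,
    sigma,
    delta_thr,
    w_plus,
    w_minus,
    f_max,
    theta,
    k_sig,
    dt,
    n_max,
    seeds,
):
    n = lam_l.shape[0]
    winners = np.empty(n, dtype=np.int64)
    times = np.empty(n, dtype=np.float64)
    for j in range(n):
        w, t = mean_field_trial(
            lam_l[j],
            lam_r[j],
            tau,
            sigma,
            delta_thr,
            w_plus,
            w_minus,
            f_max,
            theta,
            k_sig,
            dt,
            n_max,
            seeds[j],
        )
        winners[j] = w
        times[j] = t
    return winners, times


@njit(cache=True, fastmath={'contract', 'reassoc', 'nsz', 'arcp'})
def mean_field_trace(
    lam_l,
    lam_r,
    tau,
    sigma,
    delta_thr,
    w_plus,
    w_minus,
    f_max,
    theta,
    k_sig,
    dt,
    n_max,
    seed,
):
    """As mean_field_trial but records the full (r_L, r_R) path.

    Returns (winner, n_steps, r_l_path, r_r_path); paths include the initial
    state at index 0 and are truncated at the crossing step.
    """
    np.random.seed(seed)
    r_l_path = np.zeros(n_max + 1)
    r_r_path = np.zeros(n_max + 1)
    r_l = 0.0
    r_r = 0.0
    amp = sigma * np.sqrt(dt) / tau
    winner = WIN_NONE
    steps = n_max
    for i in range(n_max):
        f_l = _sigmoid(lam_l + w_plus * r_l - w_minus * r_r, f_max, theta, k_sig)
        f_r = _sigmoid(lam_r + w_plus * r_r - w_minus * r_l, f_max, theta, k_sig)
        r_l += dt / tau * (f_l - r_l) + amp * np.random.normal()
        r_r += dt / tau * (f_r - r_r) + amp * np.random.normal()
        r_l_path[i + 1] = r_l
        r_r_path[i + 1] = r_r
        if not (np.isfinite(r_l) and np.isfinite(r_r)):
            winner = WIN_BLOWUP
            steps = i + 1
            break
        d = r_l - r_r
        if d > delta_thr:
            winner = WIN_LEFT
            steps = i + 1
            break
        if d < -delta_thr:
            winner = WIN_RIGHT
            steps = i + 1
            break
    return winner, steps, r_l_path[: steps + 1], r_r_path[: steps + 1]


@njit(cache=True, fastmath={'contract', 'reassoc', 'nsz', 'arcp'})
def intention_trial(psi0, tau_psi, sigma_psi, dt, eps, n_max, clamp_lo, clamp_hi, seed):
    """Integrate the double-well intention process from psi0.

    Drift -4*psi*(psi-1)*(psi-1/2); noise sigma_psi * xi / (1 + t/(2 tau_psi))^2.
    Returns (psi_tilde, time_ms, settled) where settled is False when the
    cutoff was hit and the nearest basin was imputed.
    """
    np.random.seed(seed)
    psi = psi0
    if psi <= eps:
        return 0, 0.0, True
    if psi >= 1.0 - eps:
        return 1, 0.0, True
    sq = np.sqrt(dt)
    t = 0.0
    for _ in range(n_max):
        drift = -4.0 * psi * (psi - 1.0) * (psi - 0.5)
        u = 1.0 + t / (2.0 * tau_psi)
        decay = 1.0 / (u * u)
        psi += dt / tau_psi * drift + sigma_psi * decay * sq / tau_psi * np.random.normal()
        t += dt
        if psi < clamp_lo:
            psi = clamp_lo
        elif psi > clamp_hi:
            psi = clamp_hi
        if psi <= eps:
            return 0, t, True
        if psi >= 1.0 - eps:
            return 1, t, True
    return (1 if psi >= 0.5 else 0), t, False


@njit(cache=True, fastmath={'contract', 'reassoc', 'nsz', 'arcp'})
def intention_batch(psi0s, tau_psi, sigma_psi, dt, eps, n_max, clamp_lo, clamp_hi, seeds):
    n = psi0s.shape[0]
    out = np.empty(n, dtype=np.int64)
    times = np.empty(n, dtype=np.float64)
    for j in range(n):
        p, t, _ = intention_trial(
            psi0s[j], tau_psi, sigma_psi, dt, eps, n_max, clamp_lo, clamp_hi, seeds[j]
        )
        out[j] = p
        times[j] = t
    return out, times


@njit(cache=True, fastmath={'contract', 'reassoc', 'nsz', 'arcp'})
def intention_trace(psi0, tau_psi, sigma_psi, dt, eps, n_max, clamp_lo, clamp_hi, seed):
    """As intention_trial but records the psi(t) path."""
    np.random.seed(seed)
    path = np.empty(n_max + 1)
    path[0] = psi0
    psi = psi0
    if psi <= eps:
        return 0, 0, True, path[:1]
    if psi >= 1.0 - eps:
        return 1, 0, True, path[:1]
    sq = np.sqrt(dt)
    t = 0.0
    settled = False
    psi_tilde = 1 if psi >= 0.5 else 0
    steps = n_max
    for i in range(n_max):
        drift = -4.0 * psi * (psi - 1.0) * (psi - 0.5)
        u = 1.0 + t / (2.0 * tau_psi)
        decay = 1.0 / (u * u)
        psi += dt / tau_psi * drift + sigma_psi * decay * sq / tau_psi * np.random.normal()
        t += dt
        if psi < clamp_lo:
            psi = clamp_lo
        elif psi > clamp_hi:
            psi = clamp_hi
        path[i + 1] = psi
        if psi <= eps:
            psi_tilde, settled, steps = 0, True, i + 1
            break
        if psi >= 1.0 - eps:
            psi_tilde, settled, steps = 1, True, i + 1
            break
    if not settled:
        psi_tilde = 1 if psi >= 0.5 else 0
    return psi_tilde, steps, settled, path[: steps + 1]
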