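"""Mean-field layer: transfer function, threshold dynamics, discrimination."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from conseq.errors import ConfigurationError
from conseq.neural import (
    NeuralParams,
    StimulusDrive,
    estimate_vd,
    hz_to_per_ms,
    simulate_trial,
    simulate_trials,
    transfer,
)
from conseq.rescale import RescaleParams


def euler_reference(lam_l, lam_r, p: NeuralParams, dt, t_max):
    """Independent plain-Python noiseless integrator (reference oracle)."""
    f = lambda x: p.f_max / (1.0 + math.exp(-(x - p.theta) / p.k_sig))
    r_l = r_r = 0.0
    t = 0.0
    path = [(0.0, 0.0, 0.0)]
    while t < t_max:
        fl = f(lam_l + p.w_plus * r_l - p.w_minus * r_r)
        fr = f(lam_r + p.w_plus * r_r - p.w_minus * r_l)
        r_l, r_r = r_l + dt / p.tau * (fl - r_l), r_r + dt / p.tau * (fr - r_r)
        t += dt
        path.append((t, r_l, r_r))
        if abs(r_l - r_r) > p.delta_thr:
            break
    return path


class TestTransfer:
    def test_midpoint_is_half_saturation(self):
        p = NeuralParams()
        assert transfer(p.theta, p) == pytest.approx(0.02)

    def test_saturation(self):
        p = NeuralParams()
        assert transfer(10.0, p) == pytest.approx(p.f_max)
        assert transfer(-10.0, p) == pytest.approx(0.0, abs=1e-12)

    def test_one_slope_unit_above_midpoint(self):
        p = NeuralParams()
        expected = p.f_max * math.e / (1 + math.e)  # ~0.02924 ms^-1
        assert transfer(p.theta + p.k_sig, p) == pytest.approx(expected, rel=1e-9)

    def test_strictly_increasing(self):
        p = NeuralParams()
        x = np.linspace(-0.05, 0.1, 300)
        assert np.all(np.diff(transfer(x, p)) > 0)

    def test_hz_conversion(self):
        assert hz_to_per_ms(25) == pytest.approx(0.025)


class TestNoiselessDynamics:
    def test_matches_dense_reference_crossing(self):
        p = NeuralParams(sigma=0.0)
        res = simulate_trial(StimulusDrive(0.0227, 0.0203), 1, p, 0)
        ref = euler_reference(0.0227, 0.0203, p, dt=0.05, t_max=4000)
        assert res.winner == "left"
        assert res.decision_time == pytest.approx(ref[-1][0], abs=10.0)

    def test_convergence_toward_dense_step(self):
        base = NeuralParams(sigma=0.0, t_max=300.0)
        ref = euler_reference(0.024, 0.020, base, 0.01, 300)
        errs = []
        for dt in (2.0, 1.0, 0.5):
            p = dataclasses.replace(base, dt=dt)
            res = simulate_trial(StimulusDrive(0.024, 0.020), 1, p, 0, record_traces=True)
            t, rl, rr = res.traces
            stride = int(round(dt / 0.01))
            n = min(len(rl), (len(ref) - 1) // stride + 1)
            e = max(
                abs(rl[i] - ref[i * stride][1]) + abs(rr[i] - ref[i * stride][2])
                for i in range(n)
            )
            errs.append(e)
        assert errs[0] > errs[1] > errs[2]  # first-order convergence

    def test_symmetric_drives_no_decision(self):
        p = NeuralParams(sigma=0.0, t_max=1000.0)
        res = simulate_trial(StimulusDrive(0.02, 0.02), 1, p, 0)
        assert res.winner == "none"
        assert res.decision_time is None

    def test_rates_bounded_by_f_max(self):
        p = NeuralParams(sigma=0.003)
        res = simulate_trial(StimulusDrive(0.03, 0.01), 1, p, 3, record_traces=True)
        _, rl, rr = res.traces
        slack = 5 * p.sigma * math.sqrt(p.dt) / p.tau
        assert rl.max() <= p.f_max + slack and rr.max() <= p.f_max + slack
        assert rl.min() >= -slack and rr.min() >= -slack


class TestIntentionRouting:
    def test_psi0_flips_majority_winner(self):
        # with the intention set to "small", the weaker drive's pool should win
        p = NeuralParams(tau=80.0, sigma=0.003, delta_thr=0.025)
        n = 500
        winners, _ = simulate_trials(
            np.full(n, 0.0227), np.full(n, 0.0203), 0, p, 42
        )
        n_right = int((winners == -1).sum())
        n_decided = int((winners != 0).sum())
        assert stats.binomtest(n_right, n_decided, 0.5, alternative="greater").pvalue < 0.01

    def test_psi1_majority_follows_larger_drive(self):
        p = NeuralParams(tau=80.0, sigma=0.003, delta_thr=0.025)
        winners, _ = simulate_trials(
            np.full(300, 0.0227), np.full(300, 0.0203), 1, p, 43
        )
        assert (winners == 1).sum() > (winners == -1).sum()

    def test_invalid_psi_raises(self):
        with pytest.raises(ConfigurationError):
            simulate_trial(StimulusDrive(0.02, 0.02), 2, NeuralParams(), 0)


class TestVisualDiscriminationCurve:
    def test_noiseless_large_delta_perfect(self):
        # pair means kept where both drives are positive so every trial decides
        p = NeuralParams(sigma=0.0)
        vd = estimate_vd(0.2, p, RescaleParams(beta=0.08), 50, 0, m_bounds=(0.4, 0.6))
        assert vd == 1.0

    def test_zero_delta_is_chance(self):
        p = NeuralParams(sigma=0.003)
        vd = estimate_vd(0.0, p, RescaleParams(beta=0.05), 400, 1)
        assert abs(vd - 0.5) < 0.1  # ~4 sigma binomial envelope

    def test_monotone_in_delta(self):
        p = NeuralParams(tau=67.0, sigma=0.001, delta_thr=0.0248)
        resc = RescaleParams(beta=0.057)
        vds = [estimate_vd(d, p, resc, 300, 5) for d in (0.01, 0.05, 0.15)]
        assert vds[0] <= vds[1] <= vds[2]
        assert vds[2] > vds[0]

    def test_rt_increases_with_tau_and_threshold(self):
        drives = (np.full(200, 0.024), np.full(200, 0.018))
        t_means = []
        for tau in (40.0, 80.0):
            p = NeuralParams(tau=tau, sigma=0.001, delta_thr=0.025)
            w, t = simulate_trials(*drives, 1, p, 7)
            t_means.append(t[w != 0].mean())
        assert t_means[1] > t_means[0]
        d_means = []
        for thr in (0.015, 0.03):
            p = NeuralParams(tau=60.0, sigma=0.001, delta_thr=thr)
            w, t = simulate_trials(*drives, 1, p, 8)
            d_means.append(t[w != 0].mean())
        assert d_means[1] > d_means[0]
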