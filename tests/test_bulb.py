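"""Bulb circuit: initialization, trial dynamics, adaptive plasticity, ablations."""

from dataclasses import replace

import numpy as np
import pytest

from olfbayes.bulb import (BulbState, SimConfig, ablation_fixed_rate,
                           effective_lambda, init_bulb, run_trial_dynamics,
                           steady_state_moments, update_plasticity)
from olfbayes.environment import glomeruli_response, make_world, sample_odors

from helpers import picard_fixed_point, weight_update_closed_form

CFG = SimConfig(M=10, N=40, c_o=0.3, steady_tol=1e-7)


def _short_training(cfg, seed, n_trials):
    rng = np.random.default_rng(seed)
    rw, ro, rn, _ = rng.spawn(4)
    world = make_world(cfg.M, cfg.N, cfg.c_o, cfg.sigma_x, rw)
    st = init_bulb(cfg, rw)
    for _ in range(n_trials):
        c = sample_odors(world.prior, ro)
        x = glomeruli_response(world, c, rn)
        m, cb = run_trial_dynamics(st, x)
        st = update_plasticity(st, m, cb)
    return world, st, x, m, cb


class TestInit:
    def test_precision_initialization(self, rng):
        cfg = SimConfig(M=100, N=400, c_o=0.03, Z_rho=0.5, sigma_x=1.0)
        st = init_bulb(cfg, rng)
        assert np.all(st.rho == pytest.approx(0.06))
        assert st.t == cfg.t_min

    def test_lateral_is_transpose_of_feedforward(self, rng):
        st = init_bulb(CFG, rng)
        assert np.array_equal(st.wL, st.wF.T)

    def test_lognormal_weight_mean(self, rng):
        cfg = SimConfig(M=100, N=100, c_o=0.03)
        st = init_bulb(cfg, rng, size=100)   # 1e6 draws
        expected = np.exp(0.5) / (cfg.c_o * cfg.M)
        assert st.wF.mean() == pytest.approx(expected, rel=2e-3)

    @pytest.mark.parametrize("kwargs", [dict(dt=60.0), dict(T_max=0.5),
                                        dict(c_o=0.0),
                                        dict(gain_mode="fixed"),
                                        dict(rate_mode="fixed")])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(M=10, N=20, **kwargs)


class TestDynamics:
    def test_zero_weights_decouple(self, rng):
        st = init_bulb(CFG, rng)
        st = replace(st, wF=np.zeros_like(st.wF), wL=np.zeros_like(st.wL))
        x = rng.normal(size=CFG.N)
        m, cbar = run_trial_dynamics(st, x)
        assert np.allclose(m, x, atol=1e-5)
        # with zero input, all granule cells share the same constant drive
        assert np.allclose(cbar, cbar[0])

    def test_steady_state_satisfies_fixed_point(self, rng):
        """Euler steady state obeys both circuit equations and matches an
        independent damped Picard solve."""
        world, st, x, m, cbar = _short_training(CFG, seed=2, n_trials=50)
        m, cbar = run_trial_dynamics(st, x)   # weights frozen for the check
        resid_m = np.max(np.abs(m - (x - st.wL @ cbar)))
        F, _, _ = steady_state_moments(st, m, cbar)
        resid_c = np.max(np.abs(cbar - F))
        assert resid_m < 1e-4 and resid_c < 1e-4
        m_p, c_p = picard_fixed_point(st, x)
        assert np.max(np.abs(m - m_p)) < 1e-3
        assert np.max(np.abs(cbar - c_p)) < 1e-3

    def test_initial_conditions(self, rng):
        st = init_bulb(CFG, rng)
        x = rng.normal(size=CFG.N)
        m, cbar, trace = run_trial_dynamics(st, x, record_every=10_000)
        tau0, m0, c0 = trace[0]
        assert tau0 == 0.0
        assert np.all(m0 == 0.0)
        assert np.all(c0 == CFG.c_o)

    def test_rate_floors_respected(self, rng):
        world, st, x, m, cbar = _short_training(CFG, seed=3, n_trials=20)
        assert np.all(m >= -CFG.m_sp)
        assert np.all(cbar >= 0.0)


class TestPlasticity:
    def test_update_matches_closed_form(self, rng):
        """The discounted Hebbian rule equals the precision-rescaled
        running-average form elementwise, on random states."""
        for _ in range(100):
            cfg = SimConfig(M=6, N=9, c_o=0.2)
            wF = rng.lognormal(0.0, 0.5, size=(6, 9))
            st = BulbState(wF=wF, wL=wF.T.copy(),
                           rho=rng.uniform(0.05, 2.0, size=6),
                           t=int(rng.integers(100, 500)), config=cfg)
            m = rng.normal(size=9)
            cbar = rng.uniform(0.0, 2.0, size=6)
            new = update_plasticity(st, m, cbar)
            ref = weight_update_closed_form(st.wF, st.rho, new.rho, new.t,
                                            cbar, m, cfg.sigma_x)
            assert np.max(np.abs(new.wF - ref)) < 1e-12

    def test_silent_granule_row_only_rescales(self, rng):
        st = init_bulb(CFG, rng)
        m = rng.normal(size=CFG.N)
        cbar = rng.uniform(0.5, 1.0, size=CFG.M)
        cbar[3] = 0.0
        new = update_plasticity(st, m, cbar)
        ratio = new.wF[3] / st.wF[3]
        assert np.allclose(ratio, ratio[0], rtol=1e-12)

    def test_precision_running_average_closed_form(self, rng):
        """rho_j trajectory equals the unrolled running average of G/sigma^2
        seeded at t_min."""
        cfg = CFG
        rng2 = np.random.default_rng(5)
        rw, ro, rn, _ = rng2.spawn(4)
        world = make_world(cfg.M, cfg.N, cfg.c_o, cfg.sigma_x, rw)
        st = init_bulb(cfg, rw)
        t0, rho0 = st.t, st.rho.copy()
        g_sum = np.zeros(cfg.M)
        for _ in range(30):
            c = sample_odors(world.prior, ro)
            x = glomeruli_response(world, c, rn)
            m, cb = run_trial_dynamics(st, x)
            _, G, _ = steady_state_moments(st, m, cb)
            g_sum += G / cfg.sigma_x ** 2
            st = update_plasticity(st, m, cb)
        expected = (t0 * rho0 + g_sum) / st.t
        assert np.max(np.abs(st.rho - expected)) < 1e-10

    def test_constant_G_is_precision_fixed_point(self):
        """If G/sigma^2 always equals the current precision, rho never moves."""
        cfg = SimConfig(M=3, N=4, c_o=0.2)
        rho = np.array([0.4, 0.4, 0.4])
        t = 100
        for _ in range(10):
            t += 1
            rho = (1 - 1 / t) * rho + (0.4 * cfg.sigma_x ** 2) / (t * cfg.sigma_x ** 2)
        assert np.allclose(rho, 0.4, rtol=1e-14)

    def test_symmetry_preserved(self, rng):
        world, st, *_ = _short_training(CFG, seed=7, n_trials=100)
        assert np.array_equal(st.wF, st.wL.T)


class TestAblations:
    def test_zero_rate_leaves_weights_unchanged(self, rng):
        st = init_bulb(CFG, rng)
        new = ablation_fixed_rate(st, rng.normal(size=CFG.N),
                                  rng.uniform(size=CFG.M), eta=0.0)
        assert np.array_equal(new.wF, st.wF)

    def test_fixed_rate_lambda_adds_N_eta(self, rng):
        cfg = replace(CFG, rate_mode="fixed", rate_eta=0.1)
        st = init_bulb(cfg, rng)
        lam_fixed = effective_lambda(st)
        base = np.sum(st.wF ** 2, axis=-1) / cfg.sigma_x ** 2
        assert np.allclose(lam_fixed, base + cfg.N * 0.1 / cfg.sigma_x ** 2)
        # eta = 0 reduces to the diversity term alone (no precision correction)
        cfg0 = replace(CFG, rate_mode="fixed", rate_eta=0.0)
        st0 = replace(st, config=cfg0)
        assert np.allclose(effective_lambda(st0), base)

    def test_ablation_sweep_values_exposed(self):
        from olfbayes.bulb import FIXED_GAIN_LAMBDAS, FIXED_RATE_ETAS
        assert FIXED_RATE_ETAS == (0.01, 0.1, 1.0)
        assert FIXED_GAIN_LAMBDAS == (200.0, 342.0)

    @pytest.mark.parametrize("lam_fixed", [200.0, 342.0])
    def test_fixed_gain_pins_lambda(self, rng, lam_fixed):
        cfg = replace(CFG, gain_mode="fixed", gain_lambda=lam_fixed)
        st = init_bulb(cfg, rng)
        assert np.all(effective_lambda(st) == lam_fixed)
        # plasticity pathway is untouched: rho still updates through G
        m, cb = run_trial_dynamics(st, np.zeros(cfg.N))
        new = update_plasticity(st, m, cb)
        assert new.t == st.t + 1
        assert not np.array_equal(new.rho, st.rho)


class TestLearning:
    def test_learning_improves_inference(self, small_runs):
        """After 1500 trials the weight error has fallen by more than half
        and decoding correlates with the true concentrations (5-seed median)."""
        d_w = small_runs["metrics"]["d_w"]
        drop = 1.0 - np.median(d_w[-1]) / np.median(d_w[0])
        assert drop > 0.5
        assert np.median(small_runs["correlation"]) > 0.8

    def test_gain_decreases_with_learning(self, small_runs, rng):
        """The effective lambda rises over training (a rightward shift /
        lower gain of the granule transfer function)."""
        st = small_runs["bulb"]
        cfg = st.config
        init = init_bulb(cfg, rng, size=5)
        lam0 = np.median(effective_lambda(init))
        lam1 = np.median(effective_lambda(st))
        assert lam1 > lam0
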