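"""Piriform readout: variant equivalences, plasticity, lateral inhibition,
top-down modulated granule transfer."""

from dataclasses import replace

import numpy as np
import pytest

from olfbayes.bulb import SimConfig, init_bulb, steady_state_moments
from olfbayes.environment import glomeruli_response, make_world, sample_odors
from olfbayes.piriform import (J_INIT, PBAR_EPS, granule_topdown_transfer,
                               init_piriform, piriform_lambda,
                               run_circuit_trial, run_joint_dynamics,
                               update_lateral_inhibition,
                               update_piriform_plasticity)
from olfbayes.transfer import quadrature_moments, spike_slab_fgh

CFG = SimConfig(M=10, N=40, c_o=0.3, steady_tol=1e-7)


def _fresh(seed=0, variant="local_lateral", cfg=CFG):
    rng = np.random.default_rng(seed)
    rw, ro, rn, _ = rng.spawn(4)
    world = make_world(cfg.M, cfg.N, cfg.c_o, cfg.sigma_x, rw)
    bstate = init_bulb(cfg, rw)
    pstate = init_piriform(bstate, rw, variant=variant)
    return world, bstate, pstate, ro, rn


class TestDynamics:
    def test_copy_variant_reproduces_bulb_posterior(self):
        """With copied weights, matched precisions and no lateral term, the
        piriform rate is exactly the bulb's own presence probability."""
        world, bstate, pstate, ro, rn = _fresh(variant="bayes_copy")
        x = glomeruli_response(world, sample_odors(world.prior, ro), rn)
        m, cbar, pbar = run_joint_dynamics(bstate, pstate, x)
        _, _, H = steady_state_moments(bstate, m, cbar)
        assert np.max(np.abs(pbar - H)) < 1e-4

    def test_pbar_is_a_probability(self):
        world, bstate, pstate, ro, rn = _fresh(variant="local_lateral")
        for _ in range(3):
            x = glomeruli_response(world, sample_odors(world.prior, ro), rn)
            bstate, pstate, m, cbar, pbar = run_circuit_trial(bstate, pstate, x)
            assert np.all((pbar >= 0.0) & (pbar <= 1.0))

    def test_stronger_lateral_inhibition_lowers_drive(self, rng):
        """At fixed rates, raising kappa_J weakly decreases every cell's
        standardized drive and hence its presence estimate (the lateral term
        enters alpha^p negatively).  The self-consistent steady state can
        disinhibit, so the guarantee is one-step."""
        from olfbayes.piriform import _piriform_alpha

        world, bstate, pstate, ro, rn = _fresh(variant="local_lateral", seed=4)
        m = rng.normal(size=CFG.N)
        pbar = rng.uniform(0.0, 1.0, size=CFG.M)
        lamP = piriform_lambda(pstate, bstate)
        s2P = np.sum(pstate.wP ** 2, axis=-1)
        prev = None
        for kappa in (0.0, 0.5, 1.0, 2.0):
            p = replace(pstate, kappa_J=kappa, J=pstate.J.copy())
            alphaP = _piriform_alpha(p, CFG, lamP, s2P, m, pbar)
            _, _, H = spike_slab_fgh(alphaP, lamP, CFG.c_o)
            if prev is not None:
                assert np.all(H <= prev + 1e-12)
            prev = H


class TestPlasticity:
    def test_update_matches_closed_form(self, rng):
        """Readout update obeys the same precision-rescaled running-average
        identity as the bulb rule, with F in place of the granule rate."""
        from helpers import weight_update_closed_form

        world, bstate, pstate, ro, rn = _fresh(variant="local", seed=2)
        x = glomeruli_response(world, sample_odors(world.prior, ro), rn)
        m, cbar, pbar = run_joint_dynamics(bstate, pstate, x)
        lamP = piriform_lambda(pstate, bstate)
        s2P = np.sum(pstate.wP ** 2, axis=-1)
        from olfbayes.piriform import _piriform_alpha
        alphaP = _piriform_alpha(pstate, CFG, lamP, s2P, m, pbar)
        Fp, _, _ = spike_slab_fgh(alphaP, lamP, CFG.c_o)
        new = update_piriform_plasticity(pstate, bstate, m, pbar)
        ref = weight_update_closed_form(pstate.wP, pstate.rhoP, new.rhoP,
                                        bstate.t + 1, Fp, m, CFG.sigma_x)
        assert np.max(np.abs(new.wP - ref)) < 1e-12

    def test_precision_running_average(self):
        world, bstate, pstate, ro, rn = _fresh(variant="local", seed=3)
        t0, rho0 = bstate.t, pstate.rhoP.copy()
        g_sum = np.zeros(CFG.M)
        from olfbayes.piriform import _piriform_alpha
        for _ in range(20):
            x = glomeruli_response(world, sample_odors(world.prior, ro), rn)
            m, cbar, pbar = run_joint_dynamics(bstate, pstate, x)
            lamP = piriform_lambda(pstate, bstate)
            s2P = np.sum(pstate.wP ** 2, axis=-1)
            alphaP = _piriform_alpha(pstate, CFG, lamP, s2P, m, pbar)
            _, Gp, _ = spike_slab_fgh(alphaP, lamP, CFG.c_o)
            g_sum += Gp / CFG.sigma_x ** 2
            bstate, pstate, *_ = run_circuit_trial(bstate, pstate, x)
        expected = (t0 * rho0 + g_sum) / bstate.t
        assert np.max(np.abs(pstate.rhoP - expected)) < 1e-10

    def test_silent_cell_row_only_decays(self):
        """A cell whose estimated first moment is (numerically) zero gets no
        Hebbian term; its row just rescales."""
        world, bstate, pstate, ro, rn = _fresh(variant="local", seed=5)
        m = np.full(CFG.N, -5.0)       # strong inhibition: alpha^p << 0
        pbar = np.zeros(CFG.M)
        new = update_piriform_plasticity(pstate, bstate, m, pbar)
        ratio = new.wP / pstate.wP
        assert np.allclose(ratio, ratio[:, :1], rtol=1e-8)


class TestLateralInhibition:
    def test_initialized_off_diagonal(self):
        _, bstate, pstate, *_ = _fresh(variant="local_lateral")
        assert np.all(np.diag(pstate.J) == 0.0)
        off = pstate.J[~np.eye(CFG.M, dtype=bool)]
        assert np.all(off == J_INIT)

    def test_silent_population_leaves_J_unchanged(self, rng):
        J = rng.uniform(0.0, 0.1, size=(5, 5)) * (1 - np.eye(5))
        assert np.array_equal(update_lateral_inhibition(J, np.zeros(5), 0.1), J)

    def test_fixed_point(self, rng):
        """J_jk = pbar_j / (5 c_o) zeroes the update bracket."""
        c_o = 0.2
        pbar = rng.uniform(0.1, 0.9, size=6)
        J = np.tile(pbar[:, None] / (5.0 * c_o), (1, 6)) * (1 - np.eye(6))
        new = update_lateral_inhibition(J, pbar, c_o)
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(new[off], J[off], atol=1e-12)

    def test_nonnegative_zero_diagonal_invariant(self, rng):
        J = rng.uniform(0.0, 0.05, size=(8, 8)) * (1 - np.eye(8))
        for _ in range(50):
            J = update_lateral_inhibition(J, rng.uniform(0, 1, size=8), 0.05)
        assert np.all(J >= 0.0)
        assert np.all(np.diag(J) == 0.0)


class TestTopDownTransfer:
    def test_reduces_to_prior_at_pbar_equals_co(self):
        alpha, lam, c_o = np.linspace(-3, 5, 9), 25.0, 0.07
        Fd, Gd, Hd = granule_topdown_transfer(alpha, lam, np.full(9, c_o))
        F, G, H = spike_slab_fgh(alpha, lam, c_o)
        assert np.array_equal(Fd, F) and np.array_equal(Gd, G)

    def test_monotone_in_pbar(self):
        alpha, lam = 1.0, 30.0
        pbars = np.linspace(0.01, 0.99, 50)
        Fd, _, _ = granule_topdown_transfer(alpha, lam, pbars)
        assert np.all(np.diff(Fd) >= -1e-12)

    def test_full_confidence_matches_pure_slab_posterior(self):
        """pbar -> 1 removes the spike; compare to zero-spike quadrature."""
        lam, mu = 30.0, 1.2
        alpha = np.sqrt(lam) * mu - 3.0 / np.sqrt(lam)
        Fd, _, _ = granule_topdown_transfer(alpha, lam, 1.0)   # clamped inside
        q = quadrature_moments(mu, lam, 1.0 - PBAR_EPS)
        assert Fd == pytest.approx(q.first, rel=1e-4)

    def test_degenerate_pbar_clamped(self):
        out0 = granule_topdown_transfer(0.5, 10.0, 0.0)
        out1 = granule_topdown_transfer(0.5, 10.0, 1.0)
        assert np.all(np.isfinite(out0)) and np.all(np.isfinite(out1))


class TestPopulationProperties:
    def test_variant_ordering(self, variant_runs):
        """Decoding without lateral inhibition is worst; lateral inhibition
        recovers much of the ideal (copied-weight) performance."""
        med = {v: np.median(r["correlation"]) for v, r in variant_runs.items()}
        assert med["local"] < med["local_lateral"]
        assert med["local_lateral"] <= med["bayes_copy"] + 0.05

    def test_concentration_invariance_over_detected_range(self, gonogo_run):
        """Once an odor is above the circuit's detection threshold, the
        piriform presence code is nearly flat across concentrations while
        granule responses keep tracking concentration: the CV ratio over the
        detected range (>= 0.35) is tiny.  (At amplitude 0.1 the sparse
        prior correctly rejects the odor, so presence estimates collapse —
        the same failure the reward prediction shows at very small
        concentrations.)"""
        from olfbayes.experiments import concentration_sweep

        pre = gonogo_run["pretrained"]
        bstate, pstate, world = pre["bulb"], pre["piriform"], pre["world"]
        conc, g, p = concentration_sweep(bstate, pstate, world, n_members=5)
        det = conc >= 0.35

        def cv(a):
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.nanstd(a, axis=0) / np.nanmean(a, axis=0)

        ratios = (np.nanmedian(cv(p[det]), axis=-1)
                  / np.nanmedian(cv(g[det]), axis=-1))
        assert np.median(ratios) < 0.2
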