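"""Hybrid-method components: survival sampling, region splitting, stepping."""

import math

import numpy as np
import pytest
import scipy.integrate
import scipy.optimize
from hypothesis import given, settings, strategies as st

import rdhybrid as rh
import rdhybrid.hybrid as hy
from rdhybrid import (
    HybridConfig,
    SystemState,
    build_flux_ode,
    draw_next_reaction_time,
    hybrid_simulate,
    hybrid_step,
    integrated_propensities,
    select_reaction,
    solve_mean_flux,
    survival_probability,
)
from rdhybrid.hybrid import split_from_column_fluxes


def flux_solutions_for(model, state):
    out = {}
    for sp in model.diffusive_species():
        if model.n_compartments > 1:
            ode = build_flux_ode(model, sp, state)
            out[sp] = solve_mean_flux(ode, state.time)
    return out


class TestSurvival:
    def test_reaction_free_model_survives_forever(self):
        model, x0 = rh.build_example("pure_diffusion", K=4, conc=[1, 1, 0, 0])
        cfg = HybridConfig()
        sols = flux_solutions_for(model, x0)
        for t in (0.0, 0.5, 3.0):
            assert survival_probability(model, x0, sols, t, cfg) == 1.0

    def test_constant_propensity_is_homogeneous_exponential(self, birth_death_model):
        model, x0 = birth_death_model
        x0 = SystemState(np.array([[0]], dtype=np.int64))  # only production
        cfg = HybridConfig()
        a0 = 1e-2 * 1e3  # v * Lambda = 10 events/s
        for t in (0.01, 0.1, 0.3):
            p = survival_probability(model, x0, {}, t, cfg)
            assert p == pytest.approx(math.exp(-a0 * t), rel=1e-9)

    def test_integral_matches_adaptive_quadrature(self):
        """33-node trapezoid abar total vs scipy adaptive quadrature on a
        diffusing-decaying profile (time-varying propensity)."""
        model, x0 = rh.build_example("example1", K=12, D_M=40.0)
        cfg = HybridConfig()
        sols = flux_solutions_for(model, x0)
        t = 0.25
        _, tot = integrated_propensities(model, x0, sols, t, cfg)
        cm = model.compiled()
        sol = sols["M"]

        def a_of(tau):
            m = sol.ode.mean_concentration(tau)
            X = np.clip(cm.lam[0] * m, 0, None)
            prod = cm.pref[:, 0].sum()  # zero-order production
            return prod + 1e-2 * X.sum()

        ref, _ = scipy.integrate.quad(a_of, 0.0, t, epsrel=1e-10)
        assert tot == pytest.approx(ref, rel=1e-4)

    def test_monotone_non_increasing_on_random_models(self):
        rng = np.random.default_rng(9)
        cfg = HybridConfig()
        for _ in range(100):
            model = rh.fixture_generator(rng=rng)
            counts = rng.integers(0, 50, (model.n_compartments, model.n_species))
            state = SystemState(counts.astype(np.int64))
            sols = flux_solutions_for(model, state)
            times = np.sort(rng.uniform(0.0, 2.0, 4))
            ps = [survival_probability(model, state, sols, t, cfg) for t in times]
            assert all(ps[i] >= ps[i + 1] - 1e-12 for i in range(3))
            # P_R in (0, 1]; exp may underflow to 0 for huge propensities
            assert all(0.0 <= p <= 1.0 for p in ps)


class TestReactionTime:
    def test_constant_propensity_closed_form(self, birth_death_model):
        # a0 = 2: production-only system with v * Lambda = 2
        model, _ = rh.build_example("birth_death", v=2e-3, d=0.0, lam=1e3,
                                    conc=0.0)
        x0 = SystemState(np.zeros((1, 1), dtype=np.int64))
        cfg = HybridConfig(max_step=100.0)
        t, no_rx = draw_next_reaction_time(model, x0, {}, math.exp(-1.0), cfg)
        assert not no_rx
        assert t == pytest.approx(0.5, rel=1e-6)

    def test_reaction_free_returns_cap_with_flag(self):
        model, x0 = rh.build_example("pure_diffusion", K=3, conc=[1, 0, 0])
        cfg = HybridConfig(max_step=2.5)
        t, no_rx = draw_next_reaction_time(model, x0, flux_solutions_for(model, x0),
                                           0.5, cfg)
        assert no_rx and t == pytest.approx(2.5)

    def test_time_varying_propensity_against_independent_root(self):
        """Degradation of a diffusing pulse: a(tau) = d Lambda m_1(tau) with
        m_1 = (c/2)(1 + e^{-2 r tau}); root of the closed-form integral."""
        c, r, d, lam = 1.0, 5.0, 0.8, 1e4
        model, _ = rh.build_example("pure_diffusion", K=2, D=5.0, h=1.0, lam=lam,
                                    conc=[c, 0.0])
        model = rh.ReactionDiffusionModel(
            species=model.species, grid=model.grid,
            reactions=[rh.ReactionSpec({"X": 1}, {}, d,
                                       profile=np.array([1.0, 0.0]))],
            name="decaying-pulse")
        x0 = SystemState(np.array([[int(lam * c)], [0]], dtype=np.int64))
        sols = flux_solutions_for(model, x0)
        cfg = HybridConfig(max_step=10.0)
        r1 = 0.2
        target = -math.log(r1)

        def cum(T):  # closed form of d*lam*int m1
            return d * lam * (c / 2) * (T + (1 - math.exp(-2 * r * T)) / (2 * r))

        t_ref = scipy.optimize.brentq(lambda T: cum(T) - target, 1e-9, 10.0,
                                      xtol=1e-14)
        t, no_rx = draw_next_reaction_time(model, x0, sols, r1, cfg)
        assert not no_rx
        assert t == pytest.approx(t_ref, rel=2e-4)  # quadrature + root tol

    def test_invalid_r1_rejected(self, birth_death_model):
        model, x0 = birth_death_model
        with pytest.raises(ValueError):
            draw_next_reaction_time(model, x0, {}, 1.5, HybridConfig(max_step=1))


class TestRegionSplit:
    def test_printed_cutoff_example(self):
        # per-compartment expected jumps [100, 50, 12, 8, 2], T_A = 10 -> kg = 4
        v = np.array([100.0, 50, 12, 8, 2])
        g1, g2 = split_from_column_fluxes(v, v, 10.0, "monotone")
        assert (g1, g2) == (0, 2)  # Gaussian compartments 1..3, kg = 4
        assert rh.RegionSplit("x", (g1, g2), 5).kg == 4

    def test_all_above_threshold_is_gaussian_everywhere(self):
        v = np.full(6, 50.0)
        g1, g2 = split_from_column_fluxes(v, v, 10.0, "monotone")
        assert (g1, g2) == (0, 5)
        assert rh.RegionSplit("x", (g1, g2), 6).kg == 7  # K + 1

    def test_all_below_threshold_is_ssa_everywhere(self):
        v = np.full(6, 1.0)
        g1, g2 = split_from_column_fluxes(v, v, 10.0, "monotone")
        assert g1 > g2
        assert rh.RegionSplit("x", (g1, g2), 6).kg == 1

    def test_central_peak_interval(self):
        v = np.array([1.0, 5, 30, 80, 25, 4, 1])
        g1, g2 = split_from_column_fluxes(v, v, 10.0, "central_peak")
        assert (g1, g2) == (2, 4)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_ssa_region_grows_with_ta(self, seed):
        # for fixed fluxes, kg is non-increasing in T_A
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 100, rng.integers(2, 12))
        tas = [1.0, 5.0, 10.0, 30.0]
        kgs = []
        for ta in tas:
            g1, g2 = split_from_column_fluxes(v, v, ta, "monotone")
            kgs.append(rh.RegionSplit("x", (g1, g2), v.size).kg)
        assert all(kgs[i] >= kgs[i + 1] for i in range(len(kgs) - 1))

    def test_adaptive_cutoff_from_flux_solution(self):
        model, x0 = rh.build_example("example1", K=30, D_M=40.0)
        ode = build_flux_ode(model, "M", x0)
        sol = solve_mean_flux(ode, 0.04)
        split = rh.adaptive_cutoff(sol, 1.8e4, 0.04, HybridConfig(),
                                   mode="monotone")
        assert not split.is_empty
        assert 2 <= split.kg <= 31  # production head stays Gaussian
        none = rh.adaptive_cutoff(sol, 1.8e4, 0.04, HybridConfig(), mode="none")
        assert none.is_full
        ssa = rh.adaptive_cutoff(sol, 1.8e4, 0.04, HybridConfig(), mode="ssa")
        assert ssa.is_empty


class TestSelectReaction:
    def test_printed_example(self):
        abar = np.array([[0.2, 0.3, 0.5]])
        assert select_reaction(abar, 0.6) == (0, 2)  # cumsum 0.2, 0.5, 1.0

    def test_small_r2_picks_first_active_channel(self):
        abar = np.array([[0.0, 0.4], [0.6, 0.0]])
        assert select_reaction(abar, 1e-12) == (0, 1)

    def test_compartment_major_order(self):
        abar = np.array([[0.25, 0.25], [0.25, 0.25]])
        assert select_reaction(abar, 0.55) == (1, 0)

    def test_uniform_frequencies(self):
        abar = np.ones((2, 5))
        rng = np.random.default_rng(3)
        counts = np.zeros(10)
        n = 10**5
        for u in rng.random(n):
            q, r = select_reaction(abar, min(max(u, 1e-12), 1 - 1e-12))
            counts[q * 5 + r] += 1
        assert np.all(np.abs(counts / n - 0.1) < 0.005)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            select_reaction(np.zeros((2, 2)), 0.5)


class TestHybridStep:
    def test_zero_noise_step_is_rounded_mean_flux(self, monkeypatch):
        # with Xi forced to 0 the Gaussian update equals Lambda * net flux
        model, x0 = rh.build_example("pure_diffusion", K=5, D=1.0, h=1.0,
                                     lam=1e4, conc=[1.0, 0.5, 0.2, 0.1, 0.0])
        monkeypatch.setattr(hy, "sample_flux_noise",
                            lambda cov, rng, size=None: np.zeros(
                                np.atleast_2d(cov.rho if hasattr(cov, "rho")
                                              else cov).shape[0]))
        cfg = HybridConfig(adaptivity_mode="none", max_step=0.05)
        state, info = hybrid_step(model, x0, cfg, np.random.default_rng(0),
                                  horizon=0.05)
        assert info.no_reaction
        ode = build_flux_ode(model, "X", x0)
        sol = solve_mean_flux(ode, 0.05)
        expect = np.maximum(
            np.round(x0.counts[:, 0] + 1e4 * sol.net_mean_flux(0.05)), 0)
        assert np.array_equal(state.counts[:, 0], expect)

    def test_single_compartment_reduces_to_homogeneous_ssa(self, birth_death_model):
        # K = 1: no diffusion machinery; waiting times and updates are SSA's
        model, x0 = birth_death_model
        runs = 400
        fin_h, fin_s = [], []
        for r in range(runs):
            t = hybrid_simulate(model, x0, 30.0, [30.0],
                                config=HybridConfig(),
                                rng=np.random.SeedSequence((61, r)))
            fin_h.append(t.states[-1, 0, 0])
            t = rh.ssa_simulate(model, x0, 30.0, [30.0],
                                rng=np.random.SeedSequence((62, r)))
            fin_s.append(t.states[-1, 0, 0])
        fin_h, fin_s = np.array(fin_h), np.array(fin_s)
        se = np.sqrt(fin_h.var(ddof=1) / runs + fin_s.var(ddof=1) / runs)
        assert abs(fin_h.mean() - fin_s.mean()) < 3 * se
        # stationary Poisson(100): variances also agree
        assert abs(fin_h.var(ddof=1) - fin_s.var(ddof=1)) < \
            3 * 100.0 * np.sqrt(4.0 / runs)

    def test_zero_initial_state_with_production_grows(self):
        # the adaptive split handles an initially empty domain (SSA first)
        model, _ = rh.build_example("birth_death", K=3, D=1.0, lam=1e3,
                                    v=1e-2, d=1e-1, conc=0.0)
        x0 = SystemState(np.zeros((3, 1), dtype=np.int64))
        runs = 150
        fin = []
        for r in range(runs):
            t = hybrid_simulate(model, x0, 60.0, [60.0], config=HybridConfig(),
                                rng=np.random.SeedSequence((63, r)))
            fin.append(t.states[-1, :, 0])
        fin = np.array(fin, dtype=float)
        se = fin.std(axis=0, ddof=1) / np.sqrt(runs)
        assert np.all(np.abs(fin.mean(axis=0) - 100.0) < 3 * se)

    def test_reaction_free_total_mass_conserved(self):
        # criterion-style conservation audit at Lambda = 1e3 with an
        # interface: rounding loss stays under 1% of the total
        conc = np.array([1.0, 0.6, 0.3, 0.1, 0.03, 0.01])
        model, x0 = rh.build_example("pure_diffusion", K=6, D=1.0, h=1.0,
                                     lam=1e3, conc=conc)
        total0 = x0.counts.sum()
        cfg = HybridConfig(adaptivity_mode="monotone", max_step=0.02)
        runs = 300
        totals = []
        loss = 0.0
        for r in range(runs):
            t = hybrid_simulate(model, x0, 0.5, [0.5], config=cfg,
                                rng=np.random.SeedSequence((64, r)))
            totals.append(t.states[-1].sum())
            loss += t.clamp_loss + abs(t.diagnostics["rounding_net"])
        totals = np.array(totals, dtype=float)
        se = totals.std(ddof=1) / np.sqrt(runs)
        assert abs(totals.mean() - total0) < max(3 * se, loss / runs + 1e-9)
        assert loss / runs <= 0.01 * total0

    def test_compiled_and_reference_engines_agree(self):
        # same algorithm, two implementations (edge-space vs reduced
        # compartment-space Gaussian): ensemble means within 3 SE
        model, x0 = rh.build_example("example1", K=8, D_M=40.0, prod_hi=6.0)
        cfg = HybridConfig()
        runs = 120
        fin_c, fin_r = [], []
        rng = np.random.default_rng(65)
        for r in range(runs):
            t = hybrid_simulate(model, x0, 3.0, [3.0], config=cfg,
                                rng=np.random.SeedSequence((66, r)))
            fin_c.append(t.states[-1, :, 0])
            t = hybrid_simulate(model, x0, 3.0, [3.0], config=cfg, rng=rng,
                                engine="reference")
            fin_r.append(t.states[-1, :, 0])
        fin_c = np.array(fin_c, dtype=float)
        fin_r = np.array(fin_r, dtype=float)
        se = np.sqrt(fin_c.var(axis=0, ddof=1) / runs
                     + fin_r.var(axis=0, ddof=1) / runs)
        assert np.all(np.abs(fin_c.mean(0) - fin_r.mean(0)) < 3 * se + 1e-9)

    def test_2d_hybrid_matches_ssa_means(self):
        model, x0 = rh.build_example("example4_2d", Kx=12, Ky=3, D_M=40.0)
        cfg = HybridConfig(adaptivity_mode="monotone")
        runs = 30
        s = rh.run_ensemble(model, "ssa", runs, 2.0, [2.0], master_seed=67,
                            initial=x0)
        h = rh.run_ensemble(model, "hybrid", runs, 2.0, [2.0], config=cfg,
                            master_seed=68, initial=x0)
        se = np.sqrt(s.sd[0]**2 + h.sd[0]**2) / np.sqrt(runs)
        ok = np.abs(s.mean[0] - h.mean[0]) < 4 * se + 1e-9
        assert ok.mean() > 0.95  # a few 4-sigma outliers tolerated

    def test_reduced_gaussian_covariance_matches_edge_space(self):
        """The engine's (w, xi_interface) covariance from the augmented
        Lyapunov RK4 equals the projection of the adaptively integrated
        edge-space covariance rho."""
        from rdhybrid import _kernels
        from rdhybrid.flux import flux_covariance

        conc = np.array([1.0, 0.6, 0.3, 0.1, 0.03, 0.01])
        lam = 1e3
        model, x0 = rh.build_example("pure_diffusion", K=6, D=10.0, h=1.0,
                                     lam=lam, conc=conc)
        cm = model.compiled()
        ode = build_flux_ode(model, "X", x0)
        src, tgt = ode.index.src, ode.index.tgt
        E = src.size
        N = np.zeros((6, E))
        for e in range(E):
            N[src[e], e] -= 1.0
            N[tgt[e], e] += 1.0
        # Gaussian region columns 0..3: det edge 4->3, boundary edge 3->4
        det = [e for e in range(E) if src[e] == 4 and tgt[e] == 3]
        bnd = [e for e in range(E) if src[e] == 3 and tgt[e] == 4]
        bsrc = np.array([src[e] for e in det + bnd])
        btgt = np.array([tgt[e] for e in det + bnd])
        lam0, U = cm.eig()
        chat = U.T @ (x0.counts[:, 0] / lam)
        proj = np.vstack([N, np.eye(E)[det + bnd]])
        for dt in (0.02, 0.05, 0.2, 1.0):
            sol = solve_mean_flux(ode, dt)
            rho = flux_covariance(ode, sol, dt, rtol=1e-10).rho
            Sig = _kernels._augmented_lyapunov(
                dt, cm.jump_rate[0], U, lam0, chat, cm.nbr, cm.nbr_cnt,
                bsrc, btgt, lam0.min())
            exact = proj @ rho @ proj.T
            err = np.abs(Sig - exact).max() / np.abs(exact).max()
            assert err < 2e-3

    def test_trajectory_records_diagnostics(self):
        model, x0 = rh.build_example("example1", K=20, D_M=40.0)
        cfg = HybridConfig(trace_steps=10)
        t = hybrid_simulate(model, x0, 0.5, [0.5], config=cfg, rng=5)
        assert t.diagnostics["steps"] > 0
        assert "kg_trace" in t.diagnostics and "dt_trace" in t.diagnostics
        assert np.isfinite(t.diagnostics["dt_trace"][0])
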