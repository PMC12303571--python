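import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import poisson

from habinfo.params import InvalidParameterError, ModelParams, SignalProtocol, derive_energies
from habinfo.tss import (
    GridTooSmallError,
    JointDistribution,
    StepTooLargeError,
    TSSSolver,
)


@pytest.fixture(scope="module")
def small_solver():
    p = derive_energies(ModelParams(N_S=5, U_mean_passive=5.0, U_mean_active=20.0,
                                    beta=2.0, sigma=0.5, Gamma_S0=1.0,
                                    tau_R=0.01, tau_U=1e-3))
    return TSSSolver(p)


class TestConditionalLaws:
    def test_readout_stationary_is_poisson(self, default_solver):
        # term-by-term recurrence p(u+1) = p(u) * mean / (u+1) as the oracle
        for r, mean in ((0, 30.0), (1, 150.0)):
            pmf = default_solver.readout_stationary_given_r(r)
            orc = np.empty_like(pmf)
            orc[0] = math.exp(-mean)
            for u in range(1, len(orc)):
                orc[u] = orc[u - 1] * mean / u
            orc /= orc.sum()
            assert np.abs(pmf - orc).max() < 1e-12
            grid = default_solver.grid_u
            m = grid @ pmf
            assert m == pytest.approx(mean, rel=1e-6)
            var = (grid - m) ** 2 @ pmf
            assert var / m == pytest.approx(1.0, abs=1e-4)

    def test_direct_pmf_value(self, default_solver):
        pmf = default_solver.readout_stationary_given_r(0)
        assert pmf[30] == pytest.approx(poisson.pmf(30, 30.0), rel=1e-10)

    def test_truncation_guard(self):
        p = derive_energies(ModelParams())
        with pytest.raises(GridTooSmallError):
            TSSSolver(p, u_grid_sigmas=1.0)

    def test_receptor_stationary_symmetric_case(self):
        p = derive_energies(ModelParams(DeltaE=0.0, g=1.0))
        s = TSSSolver(p)
        assert s.receptor_stationary_given_sh(0.0, 0.0) == pytest.approx(0.5)

    def test_receptor_stationary_against_generator_nullspace(self, default_solver):
        # oracle: null space of the 2x2 generator built from the raw rates
        from habinfo.params import receptor_rates

        p = default_solver.params
        for s_val, h in ((20, 10.0), (5, 2.0), (0, 0.3)):
            spa, sap, ipa, iap = receptor_rates(p, s_val, h)
            kon, koff = spa + ipa, sap + iap
            W = np.array([[-kon, koff], [kon, -koff]])
            null = np.linalg.eig(W).eigenvectors[:, np.argmin(np.abs(np.linalg.eig(W).eigenvalues))]
            null = np.abs(null) / np.abs(null).sum()
            pa = default_solver.receptor_stationary_given_sh(float(s_val), h)
            assert pa == pytest.approx(null[1], rel=1e-9)
        # the printed closed form at the strongly-inhibited point
        assert default_solver.receptor_stationary_given_sh(20.0, 10.0) == \
            pytest.approx(1.0 / (1.0 + math.e ** 3), rel=1e-9)

    def test_receptor_saturates_at_strong_signal(self, default_solver):
        assert default_solver.receptor_stationary_given_sh(10.0, 400.0) > 1 - 1e-9

    def test_conditionals_normalized(self, default_solver):
        laws = default_solver.conditional_laws(10.0)
        assert laws.p_U_given_R.sum(axis=1) == pytest.approx([1.0, 1.0], abs=1e-10)
        assert laws.h_weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestStoragePropagator:
    def test_zero_time_is_identity(self, small_solver):
        col = small_solver.storage_propagator(u0=3, s0=2, dt=0.0)
        assert col[2] == 1.0 and col.sum() == 1.0

    def test_columns_are_distributions(self, small_solver):
        T = small_solver.propagator_tensor(small_solver.dt_max / 2)
        assert np.all(T >= 0)
        assert np.abs(T.sum(axis=2) - 1.0).max() < 1e-10

    def test_truncated_matches_dense_matrix_exponential(self, small_solver):
        # oracle: dense expm of the full 6-state generator (diagonal = minus
        # column sums), untruncated
        p = small_solver.params
        u0, s0, dt = 3, 2, 0.01
        W = np.zeros((6, 6))
        b = u0 * math.exp(-p.beta * p.sigma) * p.Gamma_S0
        for j in range(6):
            if j + 1 <= 5 and j < 5:
                W[j + 1, j] = b
            if j - 1 >= 0:
                W[j - 1, j] = j * p.Gamma_S0
        W[np.diag_indices(6)] -= W.sum(axis=0)
        exact = expm(W * dt)[:, s0]
        col = small_solver.storage_propagator(u0, s0, dt)
        assert 0.5 * np.abs(col - exact).sum() < 1e-5

    def test_support_restricted_to_neighbourhood(self, small_solver):
        col = small_solver.storage_propagator(u0=3, s0=2, dt=0.01)
        assert col[5] == 0.0  # |s - s0| = 3 > n = 2

    def test_step_rule_enforced(self, small_solver):
        with pytest.raises(StepTooLargeError):
            small_solver.storage_propagator(u0=50, s0=2, dt=1.0)
        with pytest.raises(StepTooLargeError):
            small_solver.propagator_tensor(10.0)


class TestStepJoint:
    def test_conserves_normalization(self, small_solver):
        q = small_solver.stationary_q(0.1)
        p = small_solver.joint_from_q(q, 0.1, time=0.0)
        p2 = small_solver.step_joint(p, 5.0, small_solver.dt_max)
        assert p2.values.sum() == pytest.approx(1.0, abs=1e-12)
        assert p2.time == pytest.approx(small_solver.dt_max)

    def test_general_table_input(self, small_solver):
        # a non-product-form joint is propagated and stays a distribution
        rng = np.random.default_rng(0)
        vals = rng.random((small_solver.U_max + 1, 6))
        vals /= vals.sum()
        p = JointDistribution(small_solver.grid_u, small_solver.grid_s, vals)
        p2 = small_solver.step_joint(p, 3.0, small_solver.dt_max / 2)
        assert p2.values.sum() == pytest.approx(1.0, abs=1e-10)
        assert (p2.values >= 0).all()

    def test_fixed_point_under_constant_signal(self, small_solver):
        q = small_solver.stationary_q(5.0)
        p = small_solver.joint_from_q(q, 5.0)
        p2 = small_solver.step_joint(p, 5.0, small_solver.dt_max)
        tv = 0.5 * np.abs(p2.values - p.values).sum()
        assert tv < 1e-9

    def test_no_feedback_means_identical_peaks(self):
        # with the inhibition switched off the receptor ignores the storage,
        # so every stimulus evokes the same response: no habituation
        p = derive_energies(ModelParams(kappa_override=0.0))
        s = TSSSolver(p)
        rec = s.evolve(SignalProtocol(n_stimuli=6), record=False)
        peaks = np.array([d["U"] for d in rec.stim_samples])
        assert np.abs(peaks - peaks[0]).max() / peaks[0] < 1e-6


class TestStationarySolve:
    def test_normalized_and_supported(self, small_solver):
        joint = small_solver.stationary_solve(5.0)
        joint.normalize_check()
        assert 0 <= joint.mean_S() <= small_solver.params.N_S

    def test_independent_of_initialization(self, small_solver):
        # oracle: long power iteration from two different starts
        M = small_solver.step_matrix(5.0, small_solver.dt_max)
        q_eig = small_solver.stationary_q(5.0)
        for q in (np.ones(6) / 6, np.eye(6)[0]):
            for _ in range(3000):
                q = q @ M
            assert 0.5 * np.abs(q - q_eig).sum() < 1e-8

    def test_matches_detailed_balance_chain_at_small_dt(self, small_solver):
        # oracle: the effective storage chain with birth rates
        # exp(-beta sigma) ubar(s) satisfies detailed balance; its closed-form
        # stationary law is the dt -> 0 limit of the solver's fixed point
        p = small_solver.params
        ub = small_solver.u_cond_mean(5.0)
        w = np.ones(p.N_S + 1)
        for k in range(p.N_S):
            w[k + 1] = w[k] * math.exp(-p.beta * p.sigma) * ub[k] / (k + 1)
        w /= w.sum()
        q = small_solver.stationary_q(5.0, dt=small_solver.dt_max / 20)
        assert 0.5 * np.abs(q - w).sum() < 2e-3


class TestEvolve:
    def test_single_background_stimulus_stays_stationary(self, default_solver):
        prot = SignalProtocol(H_min=0.1, H_max=0.1, n_stimuli=1)
        rec = default_solver.evolve(prot)
        assert np.abs(rec.U_mean - rec.U_mean[0]).max() / rec.U_mean[0] < 1e-6

    def test_habituation_course(self, default_solver, fig2_protocol):
        rec = default_solver.evolve(fig2_protocol, record=False)
        peaks = np.array([d["U"] for d in rec.stim_samples])
        S_ends = np.array([d["S"] for d in rec.stim_samples])
        n_early = 5
        assert np.all(np.diff(peaks[:n_early]) < 0), "response must decrease"
        assert np.all(np.diff(S_ends[:n_early]) > 0), "storage must accumulate"

    def test_step_halving_convergence(self, small_solver):
        prot = SignalProtocol(H_min=0.1, H_max=5.0, T_s=1.5, Delta_T=1.5,
                              n_stimuli=2)
        r1 = small_solver.evolve(prot, t_end=8.0, dt=small_solver.dt_max / 8)
        r2 = small_solver.evolve(prot, t_end=8.0, dt=small_solver.dt_max / 16)
        t = np.linspace(0.3, 7.5, 15)
        u1 = np.interp(t, r1.times, r1.U_mean)
        u2 = np.interp(t, r2.times, r2.U_mean)
        assert np.abs((u1 - u2) / u1).max() < 1e-4

    def test_sample_phase_snapshots(self, small_solver):
        prot = SignalProtocol(H_min=0.1, H_max=5.0, T_s=2.0, Delta_T=1.0,
                              n_stimuli=2)
        rec = small_solver.evolve(prot, sample_phase=0.5, record=False)
        assert [d["t"] for d in rec.stim_samples] == pytest.approx([1.0, 4.0])


class TestMeanFieldCollapse:
    def test_response_collapses_on_storage_fraction(self, default_solver):
        """(­<U> - <U>_A)/(<U>_A - <U>_P) against <S>/N_S falls on one curve
        across protocols when sampled at matched signal level."""
        curves = []
        for dT in (50.0, 100.0, 200.0):
            prot = SignalProtocol(Delta_T=dT, n_stimuli=12)
            rec = default_solver.evolve(prot, record=False)
            x = np.array([d["S"] for d in rec.stim_samples]) / default_solver.params.N_S
            y = (np.array([d["U"] for d in rec.stim_samples]) - default_solver.muU[1]) \
                / (default_solver.muU[1] - default_solver.muU[0])
            curves.append((x, y))
        xs = np.concatenate([c[0] for c in curves])
        ys = np.concatenate([c[1] for c in curves])
        order = np.argsort(xs)
        xs, ys = xs[order], ys[order]
        # pooled points must trace a single monotone curve: spread of y at
        # nearby x below 5% of the y range
        yr = ys.max() - ys.min()
        spread = 0.0
        for i in range(len(xs) - 1):
            if xs[i + 1] - xs[i] < 1e-3 * (xs.max() - xs.min() + 1e-12):
                spread = max(spread, abs(ys[i + 1] - ys[i]))
        assert spread < 0.05 * yr
        assert np.all(np.diff(ys) < 1e-9)  # monotone decreasing in <S>/N_S
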