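import math

import numpy as np
import pytest

from habinfo import info as I
from habinfo.params import ModelParams, SignalProtocol, derive_energies
from habinfo.tss import TSSSolver


class TestEntropy:
    def test_zero_cells_follow_convention(self):
        assert I.entropy(np.array([1.0, 0.0, 0.0])) == 0.0

    def test_perfectly_correlated_binary_channel(self):
        # I(X;Y) for a joint uniform on {(0,0),(1,1)} is ln 2 nats
        joint = np.array([[0.5, 0.0], [0.0, 0.5]])
        mi = I.entropy(joint.sum(0)) + I.entropy(joint.sum(1)) - I.entropy(joint.ravel())
        assert mi == pytest.approx(math.log(2.0), abs=1e-12)


class TestMutualInformation:
    def test_storage_carries_no_signal_information(self, default_solver):
        # the timescale-separation structure makes p(s | h) = p(s) exactly
        rng = np.random.default_rng(5)
        for mean in (0.1, 10.0):
            for _ in range(5):
                q = rng.random(default_solver.params.N_S + 1)
                q /= q.sum()
                assert abs(I.mutual_information_SH(default_solver, q, mean)) < 1e-10

    def test_signal_independent_receptor_gives_zero(self):
        # kappa = 0 and a flat sensing pathway: receptor ignores h, so the
        # readout carries no information either
        p = derive_energies(ModelParams(kappa_override=0.0))
        s = TSSSolver(p)
        # directly check the h -> activation map is flat at tiny beta*h range
        q = s.stationary_q(1e-6)
        assert I.mutual_information_UH(s, q, 1e-6) < 1e-6

    def test_matches_brute_force_integration(self, reduced_solver):
        # oracle: trapezoidal h-integration on a fine grid with the joint
        # conditional distributions assembled explicitly
        s = reduced_solver
        q = s.stationary_q(3.0)
        I_gl = I.mutual_information_UH(s, q, 3.0)
        I_ush_gl, dIf_gl = I.feedback_information(s, q, 3.0)
        h = np.linspace(1e-6, 120.0, 20001)
        lam = 1.0 / 3.0
        ph = lam * np.exp(-lam * h)
        ph /= np.trapezoid(ph, h)
        pa = s.receptor_stationary_given_sh(s.grid_s[:, None], h[None, :])
        pu_sh = (np.einsum("u,sj->usj", s.pU[1], q[:, None] * pa)
                 + np.einsum("u,sj->usj", s.pU[0], q[:, None] * (1 - pa)))
        pU_h = pu_sh.sum(axis=1)
        pU = np.trapezoid(pU_h * ph, h, axis=1)
        I_bf = I.entropy(pU) - np.trapezoid(ph * I.entropy(pU_h, axis=0), h)
        pUS = np.trapezoid(pu_sh * ph[None, None, :], h, axis=2)
        H_cond = I.entropy(pu_sh.reshape(-1, len(h)), axis=0)
        I_ush_bf = I.entropy(pUS.ravel()) - np.trapezoid(ph * H_cond, h)
        assert I_gl == pytest.approx(I_bf, abs=1e-4)
        assert I_ush_gl == pytest.approx(I_ush_bf, abs=1e-4)
        assert dIf_gl == pytest.approx(I_ush_bf - I_bf, abs=2e-4)

    def test_entropy_identity(self, default_solver):
        # k_B I_{U,H} = -Delta S_U: the conditional-vs-marginal entropy
        # difference recomputes the mutual information exactly
        q = default_solver.stationary_q(10.0)
        c = I._lam_cache(default_solver, 10.0)
        a_h = q @ c["pa"]
        H_marg = I._mix_entropy(default_solver, float(a_h @ c["w"]))[0]
        H_cond = float(I._mix_entropy(default_solver, a_h) @ c["w"])
        minus_dS_U = -(H_cond - H_marg)
        assert I.mutual_information_UH(default_solver, q, 10.0) == \
            pytest.approx(minus_dS_U, abs=1e-10)

    def test_quadrature_refinement_stable(self, default_params):
        s64 = TSSSolver(default_params, n_quad=64)
        s128 = TSSSolver(default_params, n_quad=128)
        q = s64.stationary_q(10.0)
        i64 = I.mutual_information_UH(s64, q, 10.0)
        i128 = I.mutual_information_UH(s128, q, 10.0)
        assert abs(i64 - i128) < 1e-6

    def test_feedback_information_nonnegative(self, default_solver):
        rng = np.random.default_rng(11)
        for _ in range(10):
            q = rng.random(default_solver.params.N_S + 1)
            q /= q.sum()
            _, dIf = I.feedback_information(default_solver, q, 10.0)
            assert dIf >= -1e-10


class TestFluxes:
    def test_single_term_flux(self):
        # everything at (u=5, s=0): only the first production term contributes
        p = derive_energies(ModelParams(N_S=5, U_mean_passive=5.0,
                                        U_mean_active=20.0, beta=2.0, sigma=0.5,
                                        Gamma_S0=1.0, tau_R=0.01, tau_U=1e-3))
        s = TSSSolver(p)
        vals = np.zeros((s.U_max + 1, 6))
        vals[5, 0] = 1.0
        from habinfo.tss import JointDistribution

        jd = JointDistribution(s.grid_u, s.grid_s, vals)
        assert I.internal_flux(p, jd) == pytest.approx(
            0.5 * 5 * math.exp(-1.0), rel=1e-12)

    def test_vanishes_at_detailed_balance_stationary_state(self, default_solver):
        # 1-D cut argument: each birth current balances the matching death
        # current at the stationary state of the effective storage chain
        p = default_solver.params
        ub = default_solver.u_cond_mean(10.0)
        q = np.ones(p.N_S + 1)
        for k in range(p.N_S):
            q[k + 1] = q[k] * math.exp(-p.beta * p.sigma) * ub[k] / (k + 1)
        q /= q.sum()
        jd = default_solver.joint_from_q(q, 10.0)
        assert abs(I.internal_flux(p, jd)) < 1e-8

    def test_receptor_dissipation_balance_point(self, default_params):
        p = default_params
        # at H = H_ref and <S>/N_S = alpha the feedback contributes exactly
        # another H_ref worth of affinity
        assert I.receptor_dissipation(p, p.H_ref, p.alpha * p.N_S) == \
            pytest.approx(2 * p.beta * p.H_ref, rel=1e-12)
        assert I.receptor_dissipation(p, 0.0, 0.0) == 0.0

    def test_receptor_dissipation_is_cycle_affinity(self, default_params):
        # oracle: the log ratio of forward and backward rate products around
        # the two-pathway cycle, from the raw rates
        from habinfo.params import receptor_rates

        p = default_params
        s_val, h = 12, 7.0
        spa, sap, ipa, iap = receptor_rates(p, s_val, h)
        affinity = math.log((spa * iap) / (sap * ipa))
        assert I.receptor_dissipation(p, h, s_val) == pytest.approx(affinity, rel=1e-9)

    def test_domain_checks(self, default_params):
        with pytest.raises(ValueError):
            I.receptor_dissipation(default_params, -1.0, 2.0)
        with pytest.raises(ValueError):
            I.receptor_dissipation(default_params, 1.0, 100.0)


class TestInfoGain:
    def test_habituated_state_gains_information(self, default_solver, fig2_protocol):
        g = I.info_gain(default_solver, fig2_protocol)
        assert g.DeltaI_UH > 0
        assert g.DeltaJ_int < 0
        assert g.DeltaU < 0
        assert g.DeltaI_f_in >= -1e-10 and g.DeltaI_f_hab >= -1e-10

    def test_identical_states_give_zero_deltas(self, default_solver):
        q = default_solver.stationary_q(10.0)
        i1 = I.mutual_information_UH(default_solver, q, 10.0)
        i2 = I.mutual_information_UH(default_solver, q.copy(), 10.0)
        assert i1 == i2

    def test_non_habituating_raises(self):
        from habinfo.hallmarks import NotHabituatingError

        p = derive_energies(ModelParams(kappa_override=0.0))
        s = TSSSolver(p)
        with pytest.raises(NotHabituatingError):
            I.info_gain(s, SignalProtocol(n_stimuli=6))
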