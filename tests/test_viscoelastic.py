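import numpy as np
import pytest
from scipy.integrate import solve_ivp

from histomech import (COMPRESSION_PROTOCOL, DomainError, StepProtocol,
                       ViscoParams, equilibrium_stress, fit_viscoelastic,
                       gen_relaxation, simulate_protocol, spring_strain)

PARAM_NAMES = ("c_a", "c_b", "c_m", "eta1", "eta2")


class TestEquilibriumStress:
    def test_zero_strain(self):
        assert equilibrium_stress(0.0, 1000.0, 5.0) == 0.0

    def test_linear_limit(self):
        eps = np.linspace(-0.2, 0.2, 9)
        np.testing.assert_allclose(equilibrium_stress(eps, 1000.0, 0.0),
                                   1000.0 * eps)

    def test_direct_evaluation(self):
        # c_a exp(c_b eps) eps at c_a=1000, c_b=5, eps=-0.2
        assert equilibrium_stress(-0.2, 1000.0, 5.0) == pytest.approx(
            1000.0 * np.exp(-1.0) * (-0.2), rel=1e-12)


class TestSpringStrain:
    def test_initial_value(self):
        assert spring_strain(10.0, 10.0, 0.05, 500.0, 4000.0) == pytest.approx(0.05)

    def test_zero_loading(self):
        t = np.linspace(0.0, 120.0, 50)
        np.testing.assert_array_equal(spring_strain(t, 0.0, 0.0, 500.0, 4000.0),
                                      np.zeros(50))

    def test_matches_ode_integration(self):
        # independent oracle: d(eps_s)/dt = -(c_m/eta) eps_s^2 over a 120 s hold
        c_m, eta, eps_hat, t_i = 500.0, 4000.0, 0.05, 10.0
        t = np.linspace(t_i, t_i + 120.0, 241)
        sol = solve_ivp(lambda _t, y: -(c_m / eta) * y ** 2, (t_i, t_i + 120.0),
                        [eps_hat], t_eval=t, rtol=1e-12, atol=1e-16)
        closed = spring_strain(t, t_i, eps_hat, c_m, eta)
        rel = np.abs(closed - sol.y[0]) / np.abs(sol.y[0])
        assert rel.max() < 1e-8

    def test_negative_strain_domain_error_reports_critical_time(self):
        # denominator zero at t* = t_i + eta/(-eps_hat c_m) = 160 s
        with pytest.raises(DomainError, match="160"):
            spring_strain(200.0, 0.0, -0.05, 500.0, 4000.0)


class TestSimulateProtocol:
    def test_elastic_limit(self):
        # c_m = 0: no transient, stress sits on the equilibrium curve
        p = ViscoParams(1500.0, 2.0, 0.0, 400.0, 4000.0)
        t = np.linspace(0.0, COMPRESSION_PROTOCOL.span, 500)
        sigma = simulate_protocol(p, COMPRESSION_PROTOCOL, t)
        step = np.minimum((t / 120.0).astype(int) + 1, 8)
        expected = equilibrium_stress(0.025 * step, 1500.0, 2.0)
        np.testing.assert_allclose(sigma, expected, rtol=1e-12)

    def test_single_step_asymptote(self, visco_truth):
        # one step, very long hold: Maxwell contribution decays to zero
        proto = StepProtocol(1, 0.025, 1e7)
        sigma_end = simulate_protocol(visco_truth, proto, [1e7])[0]
        sigma_eq = equilibrium_stress(0.025, visco_truth.c_a, visco_truth.c_b)
        assert sigma_end == pytest.approx(sigma_eq, rel=1e-3)

    def test_componentwise_reevaluation(self, visco_truth):
        # stress at each hold end minus the equilibrium part equals the sum
        # of c_m * spring_strain evaluated independently with the carry-over
        proto = COMPRESSION_PROTOCOL
        ends = np.array([hi for _, hi in proto.hold_windows()])
        ends[-1] = proto.span
        sigma = simulate_protocol(visco_truth, proto, ends - 1e-9)
        eps = 0.025 * np.arange(proto.n_steps + 1)
        prev = np.zeros(2)
        for i in range(proto.n_steps):
            eps_hat = eps[i + 1] - eps[i] + prev
            t0, t1 = i * 120.0, (i + 1) * 120.0
            maxwell = sum(
                visco_truth.c_m * spring_strain(t1 - 1e-9, t0, eps_hat[j],
                                                visco_truth.c_m,
                                                visco_truth.etas[j])
                for j in range(2))
            expected = equilibrium_stress(eps[i + 1], visco_truth.c_a,
                                          visco_truth.c_b) + maxwell
            assert sigma[i] == pytest.approx(expected, rel=1e-10)
            prev = np.array([spring_strain(t1, t0, eps_hat[j], visco_truth.c_m,
                                           visco_truth.etas[j])
                             for j in range(2)])

    def test_equal_viscosities_single_mode(self):
        # eta1 = eta2: the two Maxwell branches are identical
        p = ViscoParams(1500.0, 2.0, 500.0, 1000.0, 1000.0)
        proto = StepProtocol(1, 0.025, 120.0)
        t = np.linspace(0.0, 120.0, 121)
        sigma = simulate_protocol(p, proto, t)
        expected = equilibrium_stress(0.025, 1500.0, 2.0) + \
            2.0 * 500.0 * spring_strain(t, 0.0, 0.025, 500.0, 1000.0)
        np.testing.assert_allclose(sigma, expected, rtol=1e-12)

    def test_relaxation_monotone_within_holds(self, visco_truth):
        proto = COMPRESSION_PROTOCOL
        for lo, hi in proto.hold_windows():
            t = np.linspace(lo, min(hi, proto.span) - 1e-9, 200)
            sigma = simulate_protocol(visco_truth, proto, t)
            step = int(lo / 120.0) + 1
            sigma_eq = equilibrium_stress(0.025 * step, visco_truth.c_a,
                                          visco_truth.c_b)
            gap = np.abs(sigma - sigma_eq)
            assert np.all(np.diff(gap) <= 1e-12)

    @pytest.mark.parametrize("k", [0.5, 4.0])
    def test_stress_scale_equivariance(self, visco_truth, k):
        # scaling (c_a, c_m, eta1, eta2) by k scales sigma(t) by k
        t = np.linspace(0.0, COMPRESSION_PROTOCOL.span, 300)
        base = simulate_protocol(visco_truth, COMPRESSION_PROTOCOL, t)
        scaled = ViscoParams(k * visco_truth.c_a, visco_truth.c_b,
                             k * visco_truth.c_m, k * visco_truth.eta1,
                             k * visco_truth.eta2)
        np.testing.assert_allclose(
            simulate_protocol(scaled, COMPRESSION_PROTOCOL, t), k * base,
            rtol=1e-12)


class TestFitViscoelastic:
    def test_noiseless_self_consistency(self, visco_truth):
        series, _ = gen_relaxation(visco_truth, seed=1)
        fit = fit_viscoelastic(series, COMPRESSION_PROTOCOL)
        for name in PARAM_NAMES:
            assert getattr(fit.params, name) == pytest.approx(
                getattr(visco_truth, name), rel=1e-3), name
        assert fit.converged

    def test_null_nonlinearity_identifiable(self):
        # c_b = 0 truth: fitted c_b within +/- 0.05 across noisy replicates
        truth = ViscoParams(1500.0, 0.0, 500.0, 400.0, 4000.0)
        fitted = []
        for rep in range(50):
            series, _ = gen_relaxation(truth, noise_relative=0.01,
                                       seed=7000 + rep)
            fitted.append(fit_viscoelastic(series, COMPRESSION_PROTOCOL)
                          .params.c_b)
        assert abs(np.median(fitted)) <= 0.05

    def test_equilibrium_consistency(self, visco_truth):
        # fitted (c_a, c_b) reproduce the generator's equilibrium curve
        series, _ = gen_relaxation(visco_truth, seed=4)
        fit = fit_viscoelastic(series, COMPRESSION_PROTOCOL)
        eps = 0.025 * np.arange(1, 9)
        np.testing.assert_allclose(
            equilibrium_stress(eps, fit.params.c_a, fit.params.c_b),
            equilibrium_stress(eps, visco_truth.c_a, visco_truth.c_b),
            rtol=1e-4)

    def test_eta_ordering_enforced(self):
        p = ViscoParams(1000.0, 1.0, 500.0, 5000.0, 300.0)
        assert p.eta1 == 300.0 and p.eta2 == 5000.0
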