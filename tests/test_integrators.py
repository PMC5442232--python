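"""Single-step update rules, the exact linear oracle, and error measures."""

import numpy as np
import pytest

import ratenet as rn
from ratenet.integrators import FixedPointDivergence
from ratenet.network import ConfigurationError

ZERO = np.zeros(1)


class TestEulerMaruyama:
    def test_leak_only(self):
        x = rn.em_step(np.array([1.0]), ZERO, 0.1, 1.0, 0.0, 0.0, ZERO)
        assert x == pytest.approx(0.9)

    def test_mean_drive(self):
        x = rn.em_step(np.array([0.0]), ZERO, 0.1, 1.0, 2.0, 0.0, ZERO)
        assert x == pytest.approx(0.2)

    def test_small_step_limit(self):
        x0 = np.array([1.7])
        x = rn.em_step(x0, ZERO, 1e-12, 1.0, 0.0, 0.0, ZERO)
        assert x == pytest.approx(x0, abs=1e-11)

    def test_intrinsic_drift_replaces_leak(self):
        # a(x) = -x^3: non-leaky dynamics
        x = rn.em_step(np.array([2.0]), ZERO, 0.1, 1.0, 5.0, 0.0, ZERO, a=lambda v: -v**3)
        assert x == pytest.approx(2.0 - 0.8)  # mu ignored when a is supplied

    def test_rejects_bad_dt(self):
        with pytest.raises(ConfigurationError):
            rn.em_step(ZERO, ZERO, 0.0, 1.0, 0.0, 0.0, ZERO)


class TestImplicitEuler:
    def test_uncoupled_closed_form(self):
        x, n = rn.ie_fixed_point_step(
            np.array([1.0]), lambda y: ZERO, 0.1, 1.0, 0.0, 0.0, ZERO
        )
        assert x == pytest.approx(1 / 1.1)
        assert n == 2  # map independent of iterate: second sweep changes nothing

    def test_two_unit_oracle(self):
        # symmetric coupling w12 = w21 = -0.5; the fixed point equals the
        # direct solve of ((1+r) I - r W) x1 = x0
        W = np.array([[0.0, -0.5], [-0.5, 0.0]])
        x0 = np.array([1.0, 0.0])
        r = 0.1
        expected = np.linalg.solve((1 + r) * np.eye(2) - r * W, x0)
        x, _ = rn.ie_fixed_point_step(
            x0, lambda y: W @ y, 0.1, 1.0, 0.0, 0.0, np.zeros(2), fp_tol=1e-14
        )
        assert x == pytest.approx(expected, abs=1e-12)

    def test_divergence_reported(self):
        # contraction factor (r/(1+r))*|w| = (1/2)*4 = 2 > 1
        W = np.array([[4.0]])
        with pytest.raises(FixedPointDivergence, match="contract"):
            rn.ie_fixed_point_step(
                np.array([1.0]), lambda y: W @ y, 1.0, 1.0, 0.0, 0.0, ZERO,
                fp_max_iter=50,
            )


class TestExponentialEuler:
    def test_leak_only_exact(self):
        x = rn.exp_euler_step(np.array([1.0]), ZERO, 1.0, 1.0, 0.0, 0.0, ZERO)
        assert x == pytest.approx(np.exp(-1.0))

    def test_fixed_point_preserved(self):
        for dt in [0.01, 1.0, 100.0]:
            x = rn.exp_euler_step(np.array([5.0]), ZERO, dt, 1.0, 5.0, 0.0, ZERO)
            assert x == pytest.approx(5.0)

    def test_noise_variance_saturates(self):
        # coefficient^2 -> sigma^2/2 as dt -> inf
        sigma = 3.0
        coeff = rn.exp_euler_step(
            np.zeros(1), ZERO, 1e6, 1.0, 0.0, sigma, np.ones(1)
        )
        assert coeff**2 == pytest.approx(sigma**2 / 2, rel=1e-9)

    def test_intrinsic_and_coupling_hooks(self):
        # f(x) = x^2, H(x) = 2x scaling the drive
        x = rn.exp_euler_step(
            np.array([2.0]), np.array([3.0]), 1.0, 1.0, 1.0, 0.0, ZERO,
            f=lambda v: v**2, H=lambda v: 2 * v,
        )
        p = np.exp(-1.0)
        assert x == pytest.approx(p * 2 + (1 - p) * (1 + 4 + 4 * 3))


class TestOutputNoise:
    def test_published_scaling(self):
        pub = rn.opn_publish(np.array([1.0]), 0.1, 1.0, 2.0, np.array([1.5]))
        assert pub == pytest.approx(1.0 + np.sqrt(10.0) * 2.0 * 1.5)

    def test_zero_sigma_matches_exp_euler(self):
        x0 = np.array([0.7])
        inp = np.array([0.3])
        a = rn.opn_step(x0, inp, 0.2, 1.0, 0.5)
        b = rn.exp_euler_step(x0, inp, 0.2, 1.0, 0.5, 0.0, ZERO)
        assert a == pytest.approx(b)


class TestExactPropagator:
    def test_uncoupled_diagonal(self):
        net = rn.build_uncoupled(3, tau=2.0, sigma=1.5)
        prop = rn.exact_linear_propagator(net, 0.5)
        assert np.allclose(prop.P, np.exp(-0.25) * np.eye(3))
        cov = prop.S_noise @ prop.S_noise.T
        expected = 1.5**2 / 2 * (1 - np.exp(-0.5)) * np.eye(3)
        assert np.allclose(cov, expected)

    def test_all_to_all_uniform_mode(self):
        net = rn.build_all_to_all_inhibitory(400)
        prop = rn.exact_linear_propagator(net, 0.1)
        u = np.ones(400) / 20.0
        assert prop.P @ u == pytest.approx(np.exp(-2.1) * u, abs=1e-12)

    def test_mean_and_covariance_exact(self, rng):
        # one propagator application reproduces the analytic one-step law
        W = rng.normal(0, 0.1, (5, 5))
        units = [rn.UnitParams(tau=1.3, mu=0.7, sigma=0.9) for _ in range(5)]
        t, s = np.meshgrid(range(5), range(5), indexing="ij")
        net = rn.Network(units, s.ravel(), t.ravel(), W.ravel(), np.zeros(25))
        dt = 0.4
        prop = rn.exact_linear_propagator(net, dt)
        import scipy.linalg

        A = net.drift_matrix / 1.3
        assert np.allclose(prop.P, scipy.linalg.expm(A * dt), atol=1e-12)
        # covariance solves the step-Lyapunov identity
        Q = 0.9**2 / 1.3 * np.eye(5)
        Sig = prop.S_noise @ prop.S_noise.T
        lhs = A @ Sig + Sig @ A.T
        rhs = prop.P @ Q @ prop.P.T - Q
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_rejects_nonlinear(self, tanh_net):
        with pytest.raises(ConfigurationError):
            rn.exact_linear_propagator(tanh_net, 0.1)


class TestErrorMeasures:
    def test_rmse_identical_zero(self):
        a = np.ones((100, 4))
        assert rn.rmse(a, a) == 0.0

    def test_rmse_constant_offset(self):
        sol = np.full((2000, 3), 0.1)
        ref = np.zeros((2000, 3))
        assert rn.rmse(sol, ref) == pytest.approx(0.1)

    def test_rmse_single_point(self):
        assert rn.rmse(np.array([0.25]), np.array([0.0])) == pytest.approx(0.25)

    def test_rmse_grid_mismatch(self):
        with pytest.raises(ValueError, match="grid"):
            rn.rmse(np.zeros((5, 2)), np.zeros((6, 2)))

    @pytest.mark.parametrize("power, slope", [(1, 1.0), (2, 2.0)])
    def test_order_fit_exact_powers(self, power, slope):
        dts = np.array([0.1, 0.05, 0.025, 0.0125])
        assert rn.estimate_convergence_order(dts, 3.7 * dts**power) == pytest.approx(
            slope
        )

    def test_order_fit_from_table(self):
        got = rn.estimate_convergence_order(
            [0.1, 0.05, 0.025], [1e-2, 5e-3, 2.5e-3]
        )
        assert got == pytest.approx(1.0)

    def test_nonfinite_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluding"):
            got = rn.estimate_convergence_order(
                [0.2, 0.1, 0.05, 0.025], [np.inf, 1e-2, 5e-3, 2.5e-3]
            )
        assert got == pytest.approx(1.0)
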