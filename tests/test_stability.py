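"""Stability functions zeta, closed-form bounds, thresholds, crossover."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ratenet as rn
from ratenet.network import ConfigurationError


class TestZeta:
    def test_em_neutral_at_zero(self):
        assert rn.zeta("euler_maruyama", 0.0, 0.7) == pytest.approx(1.0)

    def test_ie_annihilates_pure_leak(self):
        for x in [0.01, 1.0, 100.0]:
            assert rn.zeta("implicit_euler", -1.0, x) == 0.0

    def test_em_boundary_all_to_all(self):
        assert rn.zeta("euler_maruyama", -21.0, 2 / 21) == pytest.approx(1.0)

    def test_exp_boundary(self):
        x = -np.log(19 / 21)
        assert rn.zeta("exponential_euler", -21.0, x) == pytest.approx(1.0)

    def test_unknown_method(self):
        with pytest.raises(ConfigurationError):
            rn.zeta("heun", -1.0, 0.1)

    @given(lam=st.floats(-30, -0.1), x=st.floats(0.001, 5.0))
    @settings(deadline=None, max_examples=60)
    def test_zeta_matches_scalar_step_amplification(self, lam, x):
        # one deterministic step on dx = lam*x dt/tau amplifies a
        # perturbation by exactly zeta (EM: full step; EXP: exact leak plus
        # piecewise-constant coupling part lam+1)
        d0 = 1e-3
        em = abs((1 + lam * x) * d0)
        assert em / d0 == pytest.approx(
            rn.zeta("euler_maruyama", lam, x), rel=1e-9
        )
        ex = abs((np.exp(-x) + (lam + 1) * (1 - np.exp(-x))) * d0)
        assert ex / d0 == pytest.approx(
            rn.zeta("exponential_euler", lam, x), rel=1e-9
        )

    @given(lam=st.floats(-30, -0.1), x=st.floats(0.001, 5.0))
    @settings(deadline=None, max_examples=60)
    def test_zeta_ie_is_fixed_point_contraction_factor(self, lam, x):
        # the single-unit implicit map Phi(y) = (x0 + x*(lam+1)*y)/(1+x)
        # contracts iterate perturbations by exactly zeta_IE
        phi = lambda y: (1.0 + x * (lam + 1) * y) / (1 + x)  # noqa: E731
        amp = abs(phi(1.3) - phi(0.3))  # Phi is affine: exact difference
        assert amp == pytest.approx(rn.zeta("implicit_euler", lam, x), rel=1e-9)


class TestClosedFormBounds:
    def test_all_to_all_analytic_spectrum(self):
        eigs = rn.all_to_all_eigenvalues(400)
        assert eigs[0] == pytest.approx(-21.0)
        assert np.all(eigs[1:] == -1.0)
        assert eigs.sum() == pytest.approx(-400 - 20.0)  # trace of A
        assert rn.all_to_all_eigenvalues(1) == pytest.approx([-2.0])

    def test_printed_bound_set_n400(self):
        eigs = rn.all_to_all_eigenvalues(400)
        em = rn.max_stable_ratio("euler_maruyama", eigs)
        ie = rn.max_stable_ratio("implicit_euler", eigs)
        ex = rn.max_stable_ratio("exponential_euler", eigs)
        assert em.x_max == pytest.approx(2 / 21)
        assert ie.x_max == pytest.approx(1 / 19)
        assert ex.x_max == pytest.approx(-np.log(19 / 21))
        assert round(ex.x_max, 1) == 0.1
        for rep in (em, ie, ex):
            assert rep.binding_eigenvalue == pytest.approx(-21.0)
            assert rn.zeta(rep.method, -21.0, rep.x_max) == pytest.approx(
                1.0, abs=1e-9
            )

    def test_unconditional_region(self):
        assert rn.max_stable_ratio("implicit_euler", [-1.5]).x_max == np.inf
        assert rn.max_stable_ratio("exponential_euler", [-2.0]).x_max == np.inf
        assert np.isfinite(rn.max_stable_ratio("euler_maruyama", [-0.5]).x_max)

    def test_positive_real_part_rejected(self):
        with pytest.raises(ConfigurationError):
            rn.max_stable_ratio("euler_maruyama", [-1.0, 0.5])

    @given(
        a=st.floats(-20, -0.2),
        b=st.floats(0, 15),
        method=st.sampled_from(
            ["euler_maruyama", "implicit_euler", "exponential_euler"]
        ),
    )
    @settings(deadline=None, max_examples=60)
    def test_bound_sits_on_stability_boundary(self, a, b, method):
        lam = complex(a, b)
        rep = rn.max_stable_ratio(method, [lam])
        if np.isinf(rep.x_max):
            assert rn.zeta(method, lam, 50.0) <= 1 + 1e-9
        else:
            assert rn.zeta(method, lam, rep.x_max) == pytest.approx(1.0, abs=1e-9)
            assert rn.zeta(method, lam, 0.99 * rep.x_max) < 1.0


class TestThresholdsAndCrossover:
    def test_unconditional_thresholds(self):
        assert rn.unconditional_stability_threshold("implicit_euler") == 2.0
        assert rn.unconditional_stability_threshold("exponential_euler") == 2.0
        assert rn.unconditional_stability_threshold("euler_maruyama") is None

    def test_crossover_bracketing_values(self):
        # at |lambda| = 2.5 implicit Euler allows the larger step
        assert 1 / (2.5 - 2) > -np.log(1 - 2 / 2.5)
        # at |lambda| = 3.0 the exponential Euler overtakes
        assert -np.log(1 - 2 / 3.0) > 1 / (3.0 - 2)
        raw, rounded = rn.ie_exp_crossover()
        assert 2.5 < raw < 3.0
        assert rounded == 2.8

    def test_crossover_is_a_root(self):
        raw, _ = rn.ie_exp_crossover()
        assert -np.log(1 - 2 / raw) == pytest.approx(1 / (raw - 2), abs=1e-9)


class TestEmpiricalBounds:
    def test_small_all_to_all_grid(self):
        # N=25: lambda_max = -6, bounds EM 1/3, IE 1/4, EXP -ln(1-1/3)=0.405
        net = rn.build_all_to_all_inhibitory(25)
        grid = [0.8, 0.4, 0.2, 0.1]
        expected = {"euler_maruyama": 0.2, "implicit_euler": 0.2,
                    "exponential_euler": 0.4}
        for method, want in expected.items():
            res = rn.empirical_stability_bound(net, method, grid, T=50.0, seed=0)
            assert res["largest_stable_dt"] == pytest.approx(want)
            # empirical bound never exceeds the closed-form bound
            closed = rn.max_stable_ratio(
                method, rn.all_to_all_eigenvalues(25)
            ).x_max
            assert res["largest_stable_dt"] <= closed + 1e-12

    def test_predictive_power_around_bound(self):
        # simulate at 0.9*x_max -> bounded; at 1.1*x_max -> blow-up
        net = rn.build_all_to_all_inhibitory(25)
        x_max = rn.max_stable_ratio(
            "exponential_euler", rn.all_to_all_eigenvalues(25)
        ).x_max
        from ratenet.accuracy import linear_rmse

        dt_ok = round(0.9 * x_max, 4)
        dt_bad = round(1.1 * x_max, 4)
        ok = linear_rmse(net, "exponential_euler", dt_ok, dt_ok * 100)
        bad = linear_rmse(net, "exponential_euler", dt_bad, dt_bad * 500)
        assert ok < 1e3
        assert not np.isfinite(bad) or bad > 1e10


class TestSparseEIScaling:
    def test_em_ratio_size_independent(self):
        # with 1/sqrt(N) weights the spectral radius of A, hence the EM
        # ratio, is N-independent within sampling error
        ratios = {}
        for N in [250, 500, 1000]:
            net = rn.build_sparse_balanced_ei(N, 0.2, seed=1)
            eigs = np.linalg.eigvals(net.drift_matrix)
            ratios[N] = rn.max_stable_ratio("euler_maruyama", eigs).x_max
        vals = np.array(list(ratios.values()))
        assert np.ptp(vals) / vals.mean() < 0.1
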