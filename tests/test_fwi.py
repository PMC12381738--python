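"""Inversion engine: source scaling, cost, gradient, NCG, fixed points."""

import numpy as np
import pytest

from ringfwi import (
    BornSeriesSettings,
    FWIConfig,
    Grid,
    RingArraySpec,
    SamplingOperator,
    SlownessField,
    TransmitSet,
    cost,
    estimate_source_scale,
    gradient,
    make_cylindrical_source,
    run_fwi,
    simulate_observed_data,
)
from ringfwi.fwi import forward_model
from ringfwi.optimize import backtracking_line_search, minimize_ncg, polak_ribiere_direction


class TestSourceScale:
    def test_identical_traces_give_unity(self, rng):
        p = rng.standard_normal(8) + 1j * rng.standard_normal(8)
        assert np.isclose(estimate_source_scale(p, p), 1.0 + 0j)

    def test_scaled_traces_recover_scale(self, rng):
        p = rng.standard_normal(8) + 1j * rng.standard_normal(8)
        assert np.isclose(estimate_source_scale(p, 2j * p), 2j)

    def test_hand_worked_projection(self):
        gamma = estimate_source_scale(np.array([1.0, 1j]), np.array([2.0, 0.0]))
        assert np.isclose(gamma, 1.0 + 0j)

    def test_zero_trace_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_source_scale(np.zeros(4, complex), np.ones(4, complex))

    def test_projection_minimizes_misfit_over_complex_plane(self, rng):
        """gamma from the projection beats every gamma on a dense complex grid."""
        p = rng.standard_normal(16) + 1j * rng.standard_normal(16)
        p_obs = rng.standard_normal(16) + 1j * rng.standard_normal(16)
        gamma = estimate_source_scale(p, p_obs)
        best = 0.5 * np.sum(np.abs(gamma * p - p_obs) ** 2)
        re = np.linspace(gamma.real - 2, gamma.real + 2, 41)
        im = np.linspace(gamma.imag - 2, gamma.imag + 2, 41)
        gg = re[:, None] + 1j * im[None, :]
        grid_costs = 0.5 * np.sum(
            np.abs(gg[..., None] * p[None, None, :] - p_obs[None, None, :]) ** 2, axis=-1
        )
        assert best <= grid_costs.min() + 1e-12


class TestCost:
    def test_zero_misfit(self, rng):
        p = rng.standard_normal((3, 5)) + 1j * rng.standard_normal((3, 5))
        assert cost(p, p) == 0.0

    def test_single_sample_half(self):
        assert cost(np.array([[1.0 + 0j]]), np.array([[0.0 + 0j]])) == 0.5

    def test_matches_elementwise_sum(self, rng):
        p = rng.standard_normal((4, 6)) + 1j * rng.standard_normal((4, 6))
        q = rng.standard_normal((4, 6)) + 1j * rng.standard_normal((4, 6))
        brute = 0.5 * sum(
            abs(p[i, j] - q[i, j]) ** 2 for i in range(4) for j in range(6)
        )
        assert np.isclose(cost(p, q), brute, rtol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cost(np.zeros((2, 3)), np.zeros((3, 2)))


def _toy_setup(rng, shape=(16, 16), n_el=4, c_inc=1520.0):
    grid = Grid.centered(shape, 1.5e-3)
    spec = RingArraySpec(radius=8e-3, n_rows=1, n_elements_per_row=n_el, row_pitch=1.0)
    K = SamplingOperator.for_array(spec, grid)
    src = make_cylindrical_source(spec, 0, grid).values[None]
    settings = BornSeriesSettings(pad_width=6, tolerance=1e-10, max_iterations=6000)
    X, Y = grid.meshgrid()
    c = 1500 + (c_inc - 1500) * np.exp(-(X**2 + Y**2) / (2 * (4e-3) ** 2))
    truth = SlownessField(grid, 1 / c)
    return grid, spec, K, src, settings, truth


class TestGradient:
    def test_zero_residual_zero_gradient(self, rng):
        grid, spec, K, src, settings, truth = _toy_setup(rng)
        omega = 2 * np.pi * 150e3
        u, p, solver = forward_model(truth, omega, src, K, settings, "direct")
        g = gradient(truth.values, omega, u, p - p, K, solver)
        assert np.all(g == 0)

    def test_matches_finite_differences_direct_oracle(self, rng):
        """Adjoint-state gradient vs central differences of the misfit."""
        grid, spec, K, src, settings, truth = _toy_setup(rng, shape=(12, 12))
        omega = 2 * np.pi * 150e3
        _, p_obs, _ = forward_model(truth, omega, src, K, settings, "direct")
        s0 = SlownessField.homogeneous(grid, 1510.0)
        u, p, solver = forward_model(s0, omega, src, K, settings, "direct")
        g = gradient(s0.values, omega, u, p - p_obs, K, solver)

        def misfit(svals):
            _, pp, _ = forward_model(SlownessField(grid, svals), omega, src, K, settings, "direct")
            return cost(pp, p_obs)

        idx = [(3, 4), (6, 6), (8, 3), (5, 9), (9, 8)]
        for i, j in idx:
            sv = s0.values.copy()
            d = 1e-7 * sv[i, j]
            sv[i, j] += d
            fp = misfit(sv)
            sv[i, j] -= 2 * d
            fm = misfit(sv)
            fd = (fp - fm) / (2 * d)
            assert abs(g[i, j] - fd) < 1e-3 * abs(fd)

    def test_mirror_symmetric_configuration(self, rng):
        """Symmetric medium/source/receivers give a mirror-symmetric gradient."""
        grid = Grid.centered((17, 17), 1.5e-3)
        X, Y = grid.meshgrid()
        c = 1500 + 20 * np.exp(-(X**2 + Y**2) / (2 * (4e-3) ** 2))
        s = SlownessField(grid, 1 / c)
        settings = BornSeriesSettings(pad_width=6, tolerance=1e-10, max_iterations=6000)
        # receivers mirror-symmetric about the x axis; source on the axis
        pos = np.array([[9e-3, 6e-3], [9e-3, -6e-3], [-9e-3, 0.0]])
        K = SamplingOperator(pos, grid)
        src = np.zeros(grid.shape, complex)
        src[8, 8] = 1.0  # grid center (odd extent): on the mirror axis
        omega = 2 * np.pi * 150e3
        u, p, solver = forward_model(s, omega, src[None], K, settings, "direct")
        p_obs = 0.9 * p  # symmetric residual
        g = gradient(s.values, omega, u, p - p_obs, K, solver)
        sym = g[:, ::-1]
        assert np.abs(g - sym).max() <= 1e-6 * np.abs(g).max()


class TestNCGMachinery:
    def test_first_direction_is_steepest_descent(self):
        g = np.array([1.0, -2.0])
        assert np.allclose(polak_ribiere_direction(g, np.zeros(2), np.zeros(2)), -g)

    def test_beta_vanishes_for_repeated_gradient(self):
        g = np.array([1.0, 2.0])
        d_prev = np.array([0.5, 0.5])
        assert np.allclose(polak_ribiere_direction(g, g, d_prev), -g)

    def test_quadratic_converges_in_two_exact_steps(self):
        """PR-NCG with exact line search is CG: n steps on an n-dim quadratic."""
        A = np.array([[3.0, 0.5], [0.5, 1.0]])
        b = np.array([1.0, -2.0])
        x_star = np.linalg.solve(A, b)

        def objective(x):
            return 0.5 * x @ A @ x - b @ x, None

        def grad(x, aux):
            return A @ x - b

        def exact_ls(phi, f0, slope, alpha0):
            # analytic minimizer along d for the quadratic: alpha = -slope/(d A d)
            # recovered by sampling phi at two points (phi is quadratic in alpha)
            f1, aux1 = phi(1.0)
            f2, aux2 = phi(2.0)
            curv = f2 - 2 * f1 + f0
            alpha = (0.5 * curv - (f1 - f0)) / curv
            fa, aux = phi(alpha)
            from ringfwi.optimize import _LSResult

            return _LSResult(True, alpha, fa, aux, 3)

        info = minimize_ncg(
            objective, grad, np.zeros(2), 2, initial_step=lambda x, d, k: 1.0,
            line_search=exact_ls,
        )
        assert np.allclose(info.x, x_star, atol=1e-8)

    def test_backtracking_accepts_descent(self):
        phi = lambda a: ((a - 1.0) ** 2, None)
        res = backtracking_line_search(phi, f0=1.0, slope=-2.0, alpha0=1.0)
        assert res.success and res.f <= 1.0

    def test_backtracking_fails_on_ascent(self):
        phi = lambda a: (1.0 + a, None)
        res = backtracking_line_search(phi, f0=1.0, slope=-1.0, alpha0=1.0, max_backtracks=3)
        assert not res.success


class TestRunFWI:
    def test_fixed_point_homogeneous_data(self, rng):
        """Data from the starting model leave the model untouched."""
        grid = Grid.centered((32, 32), 1.5e-3)
        truth = SlownessField.homogeneous(grid, 1500.0)
        spec = RingArraySpec(radius=18e-3, n_rows=1, n_elements_per_row=16, row_pitch=1.0)
        tx = TransmitSet((0, 4, 8, 12))
        st = BornSeriesSettings(pad_width=10, tolerance=1e-7, max_iterations=8000)
        data = simulate_observed_data(truth, spec, tx, (150e3,), st)
        config = FWIConfig(frequencies=(150e3,), iterations_per_frequency=3, solver=st)
        res = run_fwi(data, grid, config)
        assert np.abs(res.sound_speed - 1500.0).max() / 1500.0 < 1e-6
        # at the fixed point the optimizer either sees a zero gradient or
        # refuses every trial step; both leave the model untouched
        assert all(
            r in ("stationary", "line_search_failed")
            for r in res.flags["stop_reasons"].values()
        )

    def test_cost_non_increasing_within_each_frequency(self, rng):
        grid = Grid.centered((32, 32), 1.5e-3)
        X, Y = grid.meshgrid()
        c = 1500 * (1 + 0.02 * np.exp(-((X - 3e-3) ** 2 + Y**2) / (2 * (5e-3) ** 2)))
        truth = SlownessField(grid, 1 / c)
        spec = RingArraySpec(radius=18e-3, n_rows=1, n_elements_per_row=16, row_pitch=1.0)
        tx = TransmitSet((0, 8))
        st = BornSeriesSettings(pad_width=10, tolerance=1e-6, max_iterations=8000)
        data = simulate_observed_data(truth, spec, tx, (150e3, 200e3), st)
        config = FWIConfig(frequencies=(150e3, 200e3), iterations_per_frequency=3, solver=st)
        res = run_fwi(data, grid, config)
        for f, costs in res.cost_history.items():
            assert all(b <= a * (1 + 1e-12) for a, b in zip(costs, costs[1:]))
            assert costs[-1] <= costs[0]

    def test_forward_linearity_in_source(self, rng):
        grid, spec, K, src, settings, truth = _toy_setup(rng)
        omega = 2 * np.pi * 150e3
        _, p1, _ = forward_model(truth, omega, src, K, settings, "direct")
        _, p2, _ = forward_model(truth, omega, 2 * src, K, settings, "direct")
        assert np.allclose(p2, 2 * p1, rtol=1e-12)

    def test_reciprocity_between_elements(self, rng):
        """Swap a point source and a point receiver: same sampled field."""
        grid, spec, K, _, settings, truth = _toy_setup(rng)
        omega = 2 * np.pi * 150e3
        pos = K.positions
        Ka = SamplingOperator(pos[:1], grid)
        Kb = SamplingOperator(pos[2:3], grid)
        src_a = Ka.inject(np.ones(1, complex))
        src_b = Kb.inject(np.ones(1, complex))
        _, p_ab, _ = forward_model(truth, omega, src_a[None], Kb, settings, "direct")
        _, p_ba, _ = forward_model(truth, omega, src_b[None], Ka, settings, "direct")
        assert abs(p_ab[0, 0] - p_ba[0, 0]) / abs(p_ab[0, 0]) < 1e-6

    def test_schedule_must_be_subset_of_data(self, rng):
        grid = Grid.centered((32, 32), 1.5e-3)
        truth = SlownessField.homogeneous(grid, 1500.0)
        spec = RingArraySpec(radius=18e-3, n_rows=1, n_elements_per_row=8, row_pitch=1.0)
        tx = TransmitSet((0,))
        st = BornSeriesSettings(pad_width=10, tolerance=1e-6, max_iterations=6000)
        data = simulate_observed_data(truth, spec, tx, (150e3,), st)
        config = FWIConfig(frequencies=(150e3, 300e3), iterations_per_frequency=1, solver=st)
        with pytest.raises(KeyError):
            run_fwi(data, grid, config)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            FWIConfig(frequencies=(300e3, 200e3))
        with pytest.raises(ValueError, match="mode"):
            FWIConfig(mode="4d")
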