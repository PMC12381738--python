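"""Helmholtz solvers: discretization identities, oracle equivalence, adjoints."""

import numpy as np
import pytest

from ringfwi import (
    BornSeriesSettings,
    BornSeriesSolver,
    ConvergenceError,
    DirectSolver,
    Grid,
    SlownessField,
    SourceField,
    assemble_direct_operator,
    solve_helmholtz,
    solve_helmholtz_adjoint,
)
from conftest import smooth_medium


def point_source(grid, index, amplitude=1.0):
    values = np.zeros(grid.shape, complex)
    values[index] = amplitude
    return SourceField(grid, values)


class TestDirectOperator:
    def test_interior_diagonal_is_stencil_center_plus_k2(self, oracle_settings):
        grid = Grid.centered((16, 16), 1e-3)
        s = SlownessField.homogeneous(grid, 1500.0)
        omega = 2 * np.pi * 200e3
        op = assemble_direct_operator(s, omega, oracle_settings)
        h = grid.h
        d = grid.ndim
        # any interior row: Laplacian center -2d/h^2, plus omega^2 s^2
        a = op.matrix.toarray() if op.matrix.shape[0] < 5000 else None
        diag = op.matrix.diagonal().reshape(op.padded_shape)
        pad = op.pad
        interior = diag[pad + 1 : -pad - 1, pad + 1 : -pad - 1]
        expected = -2 * d / h**2 + omega**2 * (1 / 1500.0) ** 2
        assert np.allclose(interior, expected, rtol=1e-12)
        if a is not None:
            # Laplacian row sums vanish, so interior row sums reduce to k^2
            rowsums = a.sum(axis=1).reshape(op.padded_shape)
            inner = rowsums[pad : -pad, pad : -pad]
            k2 = omega**2 * (1 / 1500.0) ** 2
            assert np.allclose(inner, k2, atol=1e-9 / h**2)

    def test_operator_is_complex_symmetric(self, medium2d, oracle_settings):
        op = assemble_direct_operator(medium2d, 2 * np.pi * 200e3, oracle_settings)
        diff = (op.matrix - op.matrix.T).tocoo()
        assert diff.nnz == 0 or np.abs(diff.data).max() == 0.0

    def test_direct_solve_residual_tiny(self, rng, oracle_settings):
        grid = Grid.centered((32, 32), 1.5e-3)
        s = smooth_medium(grid, rng)
        omega = 2 * np.pi * 200e3
        solver = DirectSolver(s, omega, oracle_settings)
        delta = solver._pad_rhs(point_source(grid, (16, 16)).values)
        u = solver.solve_padded(delta)
        res = np.linalg.norm(solver.operator.matrix @ u.ravel() - delta.ravel())
        assert res / np.linalg.norm(delta) < 1e-10

    def test_refuses_large_grids(self, oracle_settings):
        grid = Grid.centered((128, 128, 64), 1.5e-3)
        s = SlownessField.homogeneous(grid, 1500.0)
        with pytest.raises(ValueError, match="oracle"):
            assemble_direct_operator(s, 2 * np.pi * 100e3, oracle_settings)

    def test_rejects_anisotropic_spacing(self, oracle_settings):
        grid = Grid((16, 16), (1e-3, 2e-3), (0.0, 0.0))
        s = SlownessField.homogeneous(grid, 1500.0)
        with pytest.raises(ValueError, match="anisotropic"):
            assemble_direct_operator(s, 2 * np.pi * 100e3, oracle_settings)


class TestBornSeries:
    def test_zero_source_gives_zero_solution(self, medium2d, oracle_settings):
        src = SourceField(medium2d.grid, np.zeros(medium2d.grid.shape, complex))
        sol = solve_helmholtz(medium2d, 2 * np.pi * 200e3, src, oracle_settings)
        assert np.all(sol.values == 0)

    def test_linearity_in_source_amplitude(self, medium2d, oracle_settings):
        src = point_source(medium2d.grid, (16, 16))
        src2 = point_source(medium2d.grid, (16, 16), amplitude=2.0)
        omega = 2 * np.pi * 200e3
        u1 = solve_helmholtz(medium2d, omega, src, oracle_settings).values
        u2 = solve_helmholtz(medium2d, omega, src2, oracle_settings).values
        assert np.array_equal(u2, 2.0 * u1)

    @pytest.mark.parametrize("shape,index", [((32, 32), (16, 12)), ((10, 10, 10), (5, 5, 5))])
    def test_matches_direct_oracle(self, rng, shape, index):
        settings = BornSeriesSettings(tolerance=1e-10, max_iterations=8000, pad_width=6)
        grid = Grid.centered(shape, 2e-3)
        s = smooth_medium(grid, rng, amplitude=60.0)
        omega = 2 * np.pi * 150e3
        src = point_source(grid, index)
        u_series = solve_helmholtz(s, omega, src, settings, method="born").values
        u_direct = solve_helmholtz(s, omega, src, settings, method="direct").values
        rel = np.linalg.norm(u_series - u_direct) / np.linalg.norm(u_direct)
        assert rel < 1e-6

    def test_gmres_accelerator_matches_plain_series(self, medium2d, rng):
        omega = 2 * np.pi * 200e3
        src = point_source(medium2d.grid, (10, 20))
        plain = BornSeriesSettings(tolerance=1e-8, max_iterations=6000, pad_width=10)
        accel = BornSeriesSettings(
            tolerance=1e-8, max_iterations=6000, pad_width=10, accelerator="gmres"
        )
        u0 = solve_helmholtz(medium2d, omega, src, plain).values
        u1 = solve_helmholtz(medium2d, omega, src, accel).values
        assert np.linalg.norm(u1 - u0) / np.linalg.norm(u0) < 1e-6

    def test_residual_monotone_under_contraction(self, medium2d):
        settings = BornSeriesSettings(
            tolerance=1e-8, max_iterations=6000, pad_width=10, check_every=1
        )
        solver = BornSeriesSolver(medium2d, 2 * np.pi * 200e3, settings)
        delta = solver._pad_rhs(point_source(medium2d.grid, (16, 16)).values)
        solver.solve_padded(delta, collect_history=True)
        hist = np.asarray(solver.residual_history)
        assert len(hist) > 5
        assert np.all(np.diff(hist) <= hist[:-1] * 1e-9 + 1e-14)

    def test_nonconvergence_raises_with_residual(self, medium2d):
        settings = BornSeriesSettings(tolerance=1e-12, max_iterations=3, pad_width=10)
        src = point_source(medium2d.grid, (16, 16))
        with pytest.raises(ConvergenceError) as err:
            solve_helmholtz(medium2d, 2 * np.pi * 200e3, src, settings)
        assert err.value.last_residual is not None and err.value.last_residual > 0

    def test_nan_source_rejected(self, medium2d, oracle_settings):
        values = np.zeros(medium2d.grid.shape, complex)
        values[0, 0] = np.nan
        with pytest.raises(ValueError):
            SourceField(medium2d.grid, values)

    def test_warns_when_undersampled(self):
        grid = Grid.centered((32, 32), 3e-3)
        s = SlownessField.homogeneous(grid, 1500.0)
        settings = BornSeriesSettings(pad_width=8)
        with pytest.warns(UserWarning, match="wavelength"):
            BornSeriesSolver(s, 2 * np.pi * 300e3, settings)


class TestAdjoint:
    def test_adjoint_inner_product_identity(self, rng):
        grid = Grid.centered((24, 24), 1.5e-3)
        s = smooth_medium(grid, rng)
        omega = 2 * np.pi * 200e3
        settings = BornSeriesSettings(tolerance=1e-10, max_iterations=8000, pad_width=8)
        fwd = BornSeriesSolver(s, omega, settings)
        for _ in range(5):
            x = rng.standard_normal(grid.shape) + 1j * rng.standard_normal(grid.shape)
            y = rng.standard_normal(grid.shape) + 1j * rng.standard_normal(grid.shape)
            ax = fwd.solve(x)
            ay = fwd.solve_adjoint(y)
            lhs = np.vdot(y, ax)  # <y, A^-1 x>
            rhs = np.vdot(ay, x)  # <A^-H y, x>
            assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_adjoint_is_conjugate_for_real_homogeneous_medium(self, oracle_settings):
        grid = Grid.centered((24, 24), 1.5e-3)
        s = SlownessField.homogeneous(grid, 1500.0)
        omega = 2 * np.pi * 200e3
        rhs = point_source(grid, (12, 12), amplitude=1 + 2j)
        fwd = solve_helmholtz(s, omega, SourceField(grid, np.conj(rhs.values)), oracle_settings)
        adj = solve_helmholtz_adjoint(s, omega, rhs, oracle_settings)
        assert np.abs(adj.values - np.conj(fwd.values)).max() < 1e-10

    def test_zero_rhs_gives_zero_adjoint(self, medium2d, oracle_settings):
        rhs = SourceField(medium2d.grid, np.zeros(medium2d.grid.shape, complex))
        sol = solve_helmholtz_adjoint(medium2d, 2 * np.pi * 200e3, rhs, oracle_settings)
        assert np.all(sol.values == 0)


def test_reciprocity_point_source_receiver_swap(rng):
    """Complex-symmetric A implies G(a, b) = G(b, a) in any fixed medium."""
    grid = Grid.centered((24, 24), 1.5e-3)
    s = smooth_medium(grid, rng, amplitude=40.0)
    omega = 2 * np.pi * 200e3
    settings = BornSeriesSettings(tolerance=1e-9, max_iterations=8000, pad_width=8)
    a, b = (6, 9), (17, 14)
    u_ab = solve_helmholtz(s, omega, point_source(grid, a), settings).values[b]
    u_ba = solve_helmholtz(s, omega, point_source(grid, b), settings).values[a]
    assert abs(u_ab - u_ba) / abs(u_ab) < 1e-6
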