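"""Heterogeneous Helmholtz solvers: convergent Born series + sparse direct oracle.

The time-harmonic pressure field u at angular frequency omega in a medium of
slowness s obeys (laplacian + omega^2 s^2) u = delta. Discretizing with
second-order central differences on a padded grid gives a complex-symmetric
sparse system A u = delta. Two solvers address the *same* discrete operator:

* :class:`BornSeriesSolver` — a preconditioned fixed-point iteration whose
  background Green's operator is applied by FFT. The FFT diagonalizes the
  periodic finite-difference Laplacian exactly, so the series converges to
  the solution of the identical discrete system the direct solver factorizes.
  Convergence is guaranteed by choosing the damping ``epsilon`` at least as
  large as the scattering-potential magnitude max |k^2 - k0^2|.
* :class:`DirectSolver` — sparse LU factorization of A, intended as a
  small-grid oracle (refuses systems beyond ~2e5 unknowns).

Outgoing-wave behavior is emulated by an absorbing pad: the squared
wavenumber acquires a smoothly rising positive imaginary part (cosine-squared
taper) toward the boundary, which damps the field before the periodic
wrap-around can matter.

The adjoint system A^H lam = r is solved through the complex symmetry of A
(A^T = A, hence A^H = conj(A)): lam = conj(A^{-1} conj(r)). One forward code
path therefore serves both the forward and the adjoint solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.fft as sfft
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grids import Grid, HelmholtzSolution, SlownessField, SourceField

__all__ = [
    "BornSeriesSettings",
    "BornSeriesSolver",
    "DirectSolver",
    "ConvergenceError",
    "assemble_direct_operator",
    "make_solver",
    "solve_helmholtz",
    "solve_helmholtz_adjoint",
]

_DIRECT_MAX_UNKNOWNS = 200_000


class ConvergenceError(RuntimeError):
    """Born series failed to reach the residual tolerance."""

    def __init__(self, message, last_residual=None, iterations=None):
        super().__init__(message)
        self.last_residual = last_residual
        self.iterations = iterations


@dataclass(frozen=True)
class BornSeriesSettings:
    """Parameters of the convergent Born series and its absorbing pad.

    k0 and epsilon default to the guaranteed-convergent choice
    k0^2 = midpoint of min/max Re(k^2) and
    epsilon = epsilon_margin * max |k^2 - k0^2| (pad included).

    pad_width defaults to ~1.25 wavelengths (at the lowest medium wavenumber)
    in voxels. absorption_strength alpha sets the peak Im(k^2) = alpha*k^2 in
    the pad; larger alpha absorbs harder but inflates epsilon and hence the
    iteration count. dtype may be complex64 for speed at coarse tolerance.
    """

    k0: Optional[float] = None
    epsilon: Optional[float] = None
    max_iterations: int = 2000
    tolerance: float = 1e-6
    pad_width: Optional[int] = None
    boundary_profile: str = "cos2"
    absorption_strength: float = 1.0
    epsilon_margin: float = 1.02
    dtype: str = "complex128"
    check_every: int = 4
    accelerator: str = "none"
    gmres_restart: int = 40

    def __post_init__(self):
        if self.accelerator not in ("none", "gmres"):
            raise ValueError(f"unknown accelerator {self.accelerator!r}")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.pad_width is not None and self.pad_width < 1:
            raise ValueError("pad_width must be >= 1 voxel")
        if self.boundary_profile not in ("cos2", "none"):
            raise ValueError(f"unknown boundary_profile {self.boundary_profile!r}")
        if np.dtype(self.dtype).kind != "c":
            raise ValueError("dtype must be complex")


def _auto_pad(slowness: SlownessField, omega: float) -> int:
    h = slowness.grid.h
    k_min = omega * slowness.values.min()
    wavelength = 2 * np.pi / k_min
    return int(np.ceil(1.25 * wavelength / h))


def _check_sampling(slowness: SlownessField, omega: float) -> None:
    h = slowness.grid.h
    k_max = omega * slowness.values.max()
    ppw = 2 * np.pi / k_max / h
    if ppw < 4:
        warnings.warn(
            f"grid severely undersampled: {ppw:.2f} points per minimum wavelength (< 4)",
            stacklevel=3,
        )
    elif ppw < 6:
        warnings.warn(
            f"grid marginally sampled: {ppw:.2f} points per minimum wavelength (4-6)",
            stacklevel=3,
        )


def _padded_k2(slowness: SlownessField, omega: float, settings: BornSeriesSettings):
    """Complex squared wavenumber on the padded grid, and the pad width.

    Slowness is edge-replicated into the pad; the absorbing taper multiplies
    k^2 by (1 + i*alpha*w) with w rising smoothly from 0 to 1 over the pad.
    """
    grid = slowness.grid
    pad = settings.pad_width if settings.pad_width is not None else _auto_pad(slowness, omega)
    s_pad = np.pad(slowness.values, pad, mode="edge")
    k2 = (omega * s_pad) ** 2
    if settings.boundary_profile == "cos2" and settings.absorption_strength > 0:
        w = np.zeros(s_pad.shape)
        for d in range(grid.ndim):
            n_int = grid.shape[d]
            depth = np.zeros(s_pad.shape[d])
            i = np.arange(s_pad.shape[d])
            depth = np.maximum(pad - i, i - (pad + n_int - 1)).clip(min=0) / pad
            shape = [1] * grid.ndim
            shape[d] = -1
            w = np.maximum(w, np.sin(0.5 * np.pi * depth.reshape(shape)) ** 2)
        k2 = k2 * (1.0 + 1j * settings.absorption_strength * w)
    else:
        k2 = k2.astype(complex)
    return k2, pad


def _fd_laplacian_symbol(shape, h):
    """Fourier symbol of the periodic second-order FD Laplacian."""
    lam = np.zeros(shape)
    for d, n in enumerate(shape):
        lam_d = (2.0 * np.cos(2 * np.pi * np.fft.fftfreq(n)) - 2.0) / h**2
        s = [1] * len(shape)
        s[d] = -1
        lam = lam + lam_d.reshape(s)
    return lam


def _resolve_k0_eps(k2, settings: BornSeriesSettings):
    re = k2.real
    k02 = settings.k0**2 if settings.k0 is not None else 0.5 * (re.min() + re.max())
    v_max = float(np.abs(k2 - k02).max())
    eps = settings.epsilon if settings.epsilon is not None else settings.epsilon_margin * v_max
    if eps < v_max:
        warnings.warn(
            f"epsilon {eps:.3g} below contraction bound max|k^2-k0^2| = {v_max:.3g}; "
            "convergence is not guaranteed",
            stacklevel=3,
        )
    return k02, eps


class BornSeriesSolver:
    """Convergent Born series for one medium and frequency; batched right-hand sides.

    The iteration is u <- u + (i/eps) V (G(delta - V u) - u) with
    V = k^2 - k0^2 - i*eps and G = (L + k0^2 + i*eps)^{-1} applied via FFT,
    L being the periodic FD Laplacian. The true discrete residual
    ||A u - delta|| is evaluated every ``check_every`` iterations from the
    identity delta - A u = (L + k0^2 + i*eps)(G(delta - V u) - u).
    """

    def __init__(self, slowness: SlownessField, omega: float, settings: BornSeriesSettings):
        if omega <= 0:
            raise ValueError("omega must be positive")
        _check_sampling(slowness, omega)
        self.grid = slowness.grid
        self.omega = float(omega)
        self.settings = settings
        self.dtype = np.dtype(settings.dtype)
        k2, self.pad = _padded_k2(slowness, omega, settings)
        self.padded_shape = k2.shape
        self.k02, self.epsilon = _resolve_k0_eps(k2, settings)
        lam = _fd_laplacian_symbol(self.padded_shape, self.grid.h)
        self._ghat = (1.0 / (lam + self.k02 + 1j * self.epsilon)).astype(self.dtype)
        self._bhat = (lam + self.k02 + 1j * self.epsilon).astype(self.dtype)
        self._V = (k2 - self.k02 - 1j * self.epsilon).astype(self.dtype)
        self._gamma = (1j / self.epsilon) * self._V
        self._axes = tuple(range(-self.grid.ndim, 0))
        self._interior = tuple(slice(self.pad, self.pad + n) for n in self.grid.shape)
        self.residual_history: list = []

    # -- padded-grid solves ------------------------------------------------

    def solve_padded(self, delta, collect_history=False, x0=None):
        """Solve A u = delta on the padded grid; delta may carry batch axes.

        ``x0`` (optional) warm-starts the iteration, e.g. with the solution
        for a nearby medium; the fixed-point map contracts from any start.
        """
        delta = np.asarray(delta, dtype=self.dtype)
        if delta.shape[-self.grid.ndim :] != self.padded_shape:
            raise ValueError("right-hand side does not match the padded grid")
        if not np.all(np.isfinite(delta)):
            raise ValueError("right-hand side contains non-finite values")
        axes = self._axes
        norm_d = np.sqrt(np.sum(np.abs(delta) ** 2, axis=axes))
        nonzero = norm_d > 0
        if not np.any(nonzero):
            return np.zeros_like(delta)
        if self.settings.accelerator == "gmres" and not collect_history:
            return self._solve_gmres(delta, x0)
        settings = self.settings
        u = (
            np.zeros_like(delta)
            if x0 is None
            else np.array(np.broadcast_to(x0, delta.shape), dtype=self.dtype)
        )
        history = []
        last_res = None
        n_total = float(np.prod(self.padded_shape))
        for it in range(settings.max_iterations):
            w = delta - self._V * u
            gw = sfft.ifftn(self._ghat * sfft.fftn(w, axes=axes), axes=axes)
            d = gw - u
            check = collect_history or (it % settings.check_every == 0)
            if check:
                dhat = sfft.fftn(d, axes=axes)
                res_norm = np.sqrt(
                    np.sum(np.abs(self._bhat * dhat) ** 2, axis=axes) / n_total
                )
                rel = np.where(nonzero, res_norm / np.where(nonzero, norm_d, 1.0), 0.0)
                last_res = float(np.max(rel))
                if collect_history:
                    history.append(last_res)
                if last_res <= settings.tolerance:
                    self._iterations = it
                    if collect_history:
                        self.residual_history = history
                    return u
            u = u + self._gamma * d
        raise ConvergenceError(
            f"Born series did not reach tolerance {settings.tolerance:g} in "
            f"{settings.max_iterations} iterations (last residual {last_res:.3g})",
            last_residual=last_res,
            iterations=settings.max_iterations,
        )

    def _solve_gmres(self, delta, x0=None):
        """Krylov-accelerated solve of the same preconditioned fixed point.

        Applies restarted GMRES to (I + G V) u = G delta per right-hand
        side; the final iterate is verified against the true discrete
        residual ||A u - delta|| / ||delta|| <= tolerance (one refinement
        retry at a tighter Krylov tolerance before giving up).
        """
        import scipy.sparse.linalg as spla

        settings = self.settings
        axes = self._axes
        shape = self.padded_shape
        n = int(np.prod(shape))
        ghat, V, bhat = self._ghat, self._V, self._bhat

        def matvec(x):
            u = x.reshape(shape)
            return (u + sfft.ifftn(ghat * sfft.fftn(u * V, axes=axes), axes=axes)).ravel()

        op = spla.LinearOperator((n, n), matvec=matvec, dtype=self.dtype)
        flat = delta.reshape(-1, *shape)
        x0_flat = None
        if x0 is not None:
            x0_flat = np.broadcast_to(np.asarray(x0, self.dtype), flat.shape)
        out = np.empty_like(flat)
        maxiter = max(1, settings.max_iterations // settings.gmres_restart)
        total_res = 0.0
        for b in range(flat.shape[0]):
            d = flat[b]
            nd = np.linalg.norm(d)
            if nd == 0:
                out[b] = 0
                continue
            rhs = sfft.ifftn(ghat * sfft.fftn(d, axes=axes), axes=axes).ravel()
            guess = None if x0_flat is None else x0_flat[b].ravel()
            rtol = 0.5 * settings.tolerance
            for attempt in range(2):
                x, _ = spla.gmres(
                    op, rhs, x0=guess, rtol=rtol, restart=settings.gmres_restart,
                    maxiter=maxiter,
                )
                u = x.reshape(shape)
                res = (
                    np.linalg.norm(sfft.ifftn(bhat * sfft.fftn(u, axes=axes), axes=axes) + V * u - d)
                    / nd
                )
                if res <= settings.tolerance:
                    break
                guess, rtol = x, rtol * 0.1
            else:
                raise ConvergenceError(
                    f"accelerated solve stalled at residual {res:.3g} "
                    f"(tolerance {settings.tolerance:g})",
                    last_residual=float(res),
                )
            total_res = max(total_res, float(res))
            out[b] = u
        self._iterations = None
        self._last_residual = total_res
        return out.reshape(delta.shape)

    def solve_adjoint_padded(self, rhs, x0=None):
        """Solve A^H lam = rhs via complex symmetry: lam = conj(A^{-1} conj(rhs))."""
        x0c = None if x0 is None else np.conj(x0)
        return np.conj(self.solve_padded(np.conj(np.asarray(rhs, dtype=self.dtype)), x0=x0c))

    # -- interior-grid solves ---------------------------------------------

    def _pad_rhs(self, values):
        values = np.asarray(values, dtype=self.dtype)
        batch = values.shape[: values.ndim - self.grid.ndim]
        out = np.zeros(batch + self.padded_shape, dtype=self.dtype)
        out[(Ellipsis,) + self._interior] = values
        return out

    @property
    def interior(self):
        """Slices extracting the interior (non-pad) region of padded arrays."""
        return self._interior

    def solve(self, source_values, x0_padded=None, return_padded=False):
        """Solve for interior-grid sources; returns interior fields (batched)."""
        u = self.solve_padded(self._pad_rhs(source_values), x0=x0_padded)
        if return_padded:
            return u
        return u[(Ellipsis,) + self._interior]

    def solve_adjoint(self, rhs_values, x0_padded=None, return_padded=False):
        lam = self.solve_adjoint_padded(self._pad_rhs(rhs_values), x0=x0_padded)
        if return_padded:
            return lam
        return lam[(Ellipsis,) + self._interior]

    @property
    def iterations(self):
        return getattr(self, "_iterations", None)


@dataclass(frozen=True)
class DiscreteOperator:
    """Sparse matrix A on the padded grid plus its geometry."""

    matrix: sp.spmatrix
    padded_shape: tuple
    pad: int
    grid: Grid
    omega: float


def _periodic_d2(n: int, h: float) -> sp.spmatrix:
    inv = 1.0 / h**2
    main = np.full(n, -2.0 * inv)
    off = np.full(n - 1, inv)
    d = sp.diags([off, main, off], [-1, 0, 1], format="lil")
    d[0, n - 1] += inv
    d[n - 1, 0] += inv
    return d.tocsr()


def assemble_direct_operator(
    slowness: SlownessField, omega: float, settings: BornSeriesSettings
) -> DiscreteOperator:
    """Assemble the sparse system A = L_periodic + diag(k^2) on the padded grid.

    This is the small-grid oracle the Born series is tested against; the
    padding, absorbing taper, and periodic FD Laplacian match the series
    solver exactly, so both address the same complex-symmetric matrix.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    h = slowness.grid.h  # raises on anisotropic spacing
    k2, pad = _padded_k2(slowness, omega, settings)
    shape = k2.shape
    n_unknowns = int(np.prod(shape))
    if n_unknowns > _DIRECT_MAX_UNKNOWNS:
        raise ValueError(
            f"padded grid has {n_unknowns} unknowns; the direct solver is an "
            f"oracle limited to {_DIRECT_MAX_UNKNOWNS}"
        )
    eyes = [sp.identity(n, format="csr") for n in shape]
    lap = sp.csr_matrix((n_unknowns, n_unknowns), dtype=float)
    for d in range(len(shape)):
        mats = list(eyes)
        mats[d] = _periodic_d2(shape[d], h)
        term = mats[0]
        for m in mats[1:]:
            term = sp.kron(term, m, format="csr")
        lap = lap + term
    a = (lap + sp.diags(k2.ravel())).tocsc()
    return DiscreteOperator(a, shape, pad, slowness.grid, float(omega))


class DirectSolver:
    """Sparse-LU oracle with the same interface as :class:`BornSeriesSolver`."""

    def __init__(self, slowness: SlownessField, omega: float, settings: BornSeriesSettings):
        _check_sampling(slowness, omega)
        self.operator = assemble_direct_operator(slowness, omega, settings)
        self.grid = slowness.grid
        self.omega = float(omega)
        self.settings = settings
        self.pad = self.operator.pad
        self.padded_shape = self.operator.padded_shape
        # symmetric-pattern ordering: much less fill than COLAMD on 3D stencils
        self._lu = spla.splu(self.operator.matrix, permc_spec="MMD_AT_PLUS_A")
        self._interior = tuple(slice(self.pad, self.pad + n) for n in self.grid.shape)

    def solve_padded(self, delta):
        delta = np.asarray(delta, dtype=complex)
        if delta.shape[-len(self.padded_shape) :] != self.padded_shape:
            raise ValueError("right-hand side does not match the padded grid")
        flat = delta.reshape(-1, int(np.prod(self.padded_shape)))
        out = np.stack([self._lu.solve(row) for row in flat])
        return out.reshape(delta.shape)

    def solve_adjoint_padded(self, rhs):
        return np.conj(self.solve_padded(np.conj(np.asarray(rhs, dtype=complex))))

    def _pad_rhs(self, values):
        values = np.asarray(values, dtype=complex)
        batch = values.shape[: values.ndim - self.grid.ndim]
        out = np.zeros(batch + self.padded_shape, dtype=complex)
        out[(Ellipsis,) + self._interior] = values
        return out

    @property
    def interior(self):
        return self._interior

    def solve(self, source_values, x0_padded=None, return_padded=False):
        u = self.solve_padded(self._pad_rhs(source_values))
        if return_padded:
            return u
        return u[(Ellipsis,) + self._interior]

    def solve_adjoint(self, rhs_values, x0_padded=None, return_padded=False):
        lam = self.solve_adjoint_padded(self._pad_rhs(rhs_values))
        if return_padded:
            return lam
        return lam[(Ellipsis,) + self._interior]


def make_solver(slowness, omega, settings, method="born"):
    if method == "born":
        return BornSeriesSolver(slowness, omega, settings)
    if method == "direct":
        return DirectSolver(slowness, omega, settings)
    raise ValueError(f"unknown solver method {method!r}")


def solve_helmholtz(
    slowness: SlownessField,
    omega: float,
    source: SourceField,
    settings: BornSeriesSettings,
    method: str = "born",
) -> HelmholtzSolution:
    """Solve (laplacian + omega^2 s^2) u = delta on the source's grid."""
    if source.grid != slowness.grid:
        raise ValueError("source and slowness must share a grid")
    solver = make_solver(slowness, omega, settings, method)
    values = solver.solve(source.values)
    info = {"method": method, "pad": solver.pad}
    if isinstance(solver, BornSeriesSolver):
        info.update(iterations=solver.iterations, epsilon=solver.epsilon, k0_sq=solver.k02)
    return HelmholtzSolution(slowness.grid, float(omega), values, info)


def solve_helmholtz_adjoint(
    slowness: SlownessField,
    omega: float,
    rhs: SourceField,
    settings: BornSeriesSettings,
    method: str = "born",
) -> HelmholtzSolution:
    """Solve the adjoint system A^H lam = rhs (same residual tolerance)."""
    if rhs.grid != slowness.grid:
        raise ValueError("rhs and slowness must share a grid")
    solver = make_solver(slowness, omega, settings, method)
    values = solver.solve_adjoint(rhs.values)
    return HelmholtzSolution(slowness.grid, float(omega), values, {"method": method, "adjoint": True})
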