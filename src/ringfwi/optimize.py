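"""Nonlinear conjugate gradient with backtracking line search.

Generic Polak-Ribiere+ NCG over flat real parameter vectors; the waveform
inversion supplies its cost and adjoint-state gradient as closures. Restarts
to steepest descent on the first iteration and whenever the computed
direction is not a descent direction; the line search enforces the Armijo
sufficient-decrease condition so accepted steps never increase the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "polak_ribiere_direction",
    "backtracking_line_search",
    "minimize_ncg",
    "NCGInfo",
]


def polak_ribiere_direction(grad, grad_prev, dir_prev):
    """PR+ conjugate direction: -g + max(0, <g, g - g_prev>/<g_prev, g_prev>) d_prev."""
    denom = float(np.dot(grad_prev, grad_prev))
    if denom == 0.0:
        return -grad
    beta = max(0.0, float(np.dot(grad, grad - grad_prev)) / denom)
    return -grad + beta * dir_prev


@dataclass
class _LSResult:
    success: bool
    alpha: float
    f: float
    aux: object
    n_evals: int


def backtracking_line_search(
    phi: Callable,
    f0: float,
    slope: float,
    alpha0: float,
    c: float = 1e-4,
    shrink: float = 0.5,
    max_backtracks: int = 20,
) -> _LSResult:
    """Armijo backtracking: accept alpha with phi(alpha) <= f0 + c*alpha*slope."""
    alpha = alpha0
    n = 0
    for _ in range(max_backtracks + 1):
        f, aux = phi(alpha)
        n += 1
        if f <= f0 + c * alpha * slope:
            return _LSResult(True, alpha, f, aux, n)
        alpha *= shrink
    return _LSResult(False, 0.0, f0, None, n)


@dataclass
class NCGInfo:
    x: np.ndarray
    costs: list = field(default_factory=list)
    n_cost_evals: int = 0
    n_grad_evals: int = 0
    stop_reason: str = "max_iterations"


def minimize_ncg(
    objective: Callable,
    gradient: Callable,
    x0: np.ndarray,
    n_iterations: int,
    initial_step: Callable,
    line_search: Optional[Callable] = None,
    project: Optional[Callable] = None,
    gtol: float = 0.0,
) -> NCGInfo:
    """Minimize with PR+ NCG.

    objective(x) -> (f, aux); gradient(x, aux) -> g (flat real array);
    initial_step(x, d, k) -> trial step length; project (optional) clips
    candidate points (projected line search); gtol stops on ||g|| <= gtol.
    """
    if line_search is None:
        line_search = backtracking_line_search
    project = project if project is not None else (lambda x: x)
    x = project(np.asarray(x0, float).copy())
    f, aux = objective(x)
    info = NCGInfo(x=x, costs=[f], n_cost_evals=1)
    g = gradient(x, aux)
    info.n_grad_evals += 1
    d = -g
    g_prev = None
    for k in range(n_iterations):
        gnorm = float(np.linalg.norm(g))
        if gnorm <= gtol:
            info.stop_reason = "stationary"
            break
        slope = float(np.dot(g, d))
        if slope >= 0.0:  # not a descent direction: restart
            d = -g
            slope = -gnorm**2
        alpha0 = initial_step(x, d, k)

        def phi(alpha):
            return objective(project(x + alpha * d))

        ls = line_search(phi, f, slope, alpha0)
        info.n_cost_evals += ls.n_evals
        if not ls.success:
            info.stop_reason = "line_search_failed"
            break
        x = project(x + ls.alpha * d)
        f, aux = ls.f, ls.aux
        info.costs.append(f)
        g_prev, g = g, gradient(x, aux)
        info.n_grad_evals += 1
        d = polak_ribiere_direction(g, g_prev, d)
    info.x = x
    return info
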