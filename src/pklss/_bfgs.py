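"""Minimal dense BFGS for very low-dimensional smooth objectives.

The MAP objective is evaluated millions of times across a full design
evaluation, on 2-4 dimensional problems where generic optimizer machinery
costs far more than the objective itself. This is a plain BFGS with
central-difference gradients and Armijo backtracking, written for that
regime; callers fall back to scipy on the rare non-converged start.
"""

from __future__ import annotations

from typing import Callable, Sequence

__all__ = ["minimize_bfgs_small"]

_FD_H = 1e-6


def _gradient(f: Callable, x: list[float], n: int) -> list[float]:
    g = [0.0] * n
    for i in range(n):
        xi = x[i]
        x[i] = xi + _FD_H
        fp = f(x)
        x[i] = xi - _FD_H
        fm = f(x)
        x[i] = xi
        g[i] = (fp - fm) / (2.0 * _FD_H)
    return g


def minimize_bfgs_small(
    f: Callable[[Sequence[float]], float],
    x0: Sequence[float],
    tol: float = 1e-8,
    gtol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[list[float], float, bool]:
    """Minimize f from x0; returns (x, f(x), converged).

    Convergence: relative objective change below ``tol`` with gradient
    infinity-norm below ``gtol``, or the gradient criterion alone.
    """
    x = [float(v) for v in x0]
    n = len(x)
    fx = f(x)
    g = _gradient(f, x, n)
    # inverse Hessian approximation, identity start
    H = [[1.0 if i == j else 0.0 for j in range(n)] for i in range(n)]

    for _ in range(max_iter):
        gmax = max(abs(v) for v in g)
        if gmax < gtol:
            return x, fx, True
        # direction d = -H g
        d = [-sum(H[i][j] * g[j] for j in range(n)) for i in range(n)]
        dg = sum(d[i] * g[i] for i in range(n))
        if dg >= 0.0:  # not a descent direction; reset
            H = [[1.0 if i == j else 0.0 for j in range(n)] for i in range(n)]
            d = [-v for v in g]
            dg = -sum(v * v for v in g)
        # Armijo backtracking
        step = 1.0
        x_new = None
        f_new = fx
        for _ls in range(40):
            cand = [x[i] + step * d[i] for i in range(n)]
            fc = f(cand)
            if fc <= fx + 1e-4 * step * dg:
                x_new, f_new = cand, fc
                break
            step *= 0.5
        if x_new is None:
            return x, fx, gmax < 10.0 * gtol
        g_new = _gradient(f, x_new, n)
        s = [x_new[i] - x[i] for i in range(n)]
        y = [g_new[i] - g[i] for i in range(n)]
        sy = sum(s[i] * y[i] for i in range(n))
        if sy > 1e-12:
            # BFGS inverse update: H <- (I - rho s y') H (I - rho y s') + rho s s'
            rho = 1.0 / sy
            Hy = [sum(H[i][j] * y[j] for j in range(n)) for i in range(n)]
            yHy = sum(y[i] * Hy[i] for i in range(n))
            for i in range(n):
                for j in range(n):
                    H[i][j] += (
                        (1.0 + rho * yHy) * rho * s[i] * s[j]
                        - rho * (s[i] * Hy[j] + Hy[i] * s[j])
                    )
        converged = abs(f_new - fx) <= tol * (1.0 + abs(fx))
        x, fx, g = x_new, f_new, g_new
        if converged and max(abs(v) for v in g) < gtol:
            return x, fx, True
    return x, fx, max(abs(v) for v in g) < 10.0 * gtol
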