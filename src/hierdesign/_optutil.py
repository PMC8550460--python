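"""Inner maximization of scalar fields over a box design space.

One-factor and two-factor problems use a deterministic dense grid followed
by a local polish, which makes criterion values reproducible to high
precision.  Higher-dimensional spaces fall back to a seeded competitive
swarm search plus polish.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import optimize

from .core import DesignSpace

DEFAULT_GRID_1D = 2001
DEFAULT_GRID_2D = 201


def default_grid(dim: int) -> int:
    return DEFAULT_GRID_1D if dim == 1 else DEFAULT_GRID_2D


def maximize_over_space(
    fun: Callable[[np.ndarray], np.ndarray],
    space: DesignSpace,
    grid_per_axis: int | None = None,
    polish: bool = True,
    seed: int = 0,
    n_starts: int = 4,
) -> tuple[float, np.ndarray]:
    """Maximize a batched scalar field ``fun`` over the box ``space``.

    ``fun`` maps an ``(N, dim)`` array of points to ``N`` values.  Returns
    ``(max value, argmax point)``.
    """
    dim = space.dim
    if dim <= 2:
        g = grid_per_axis or default_grid(dim)
        X = space.grid(g)
        vals = fun(X)
        best_idx = int(np.argmax(vals))
        best_x, best_v = X[best_idx], float(vals[best_idx])
        starts = [best_x]
        if polish:
            # a few runner-up grid cells guard against a sharper off-grid peak
            order = np.argsort(vals)[::-1]
            for idx in order[1 : 1 + n_starts]:
                starts.append(X[int(idx)])
    else:
        from .cso import CsoConfig, cso_minimize

        cfg = CsoConfig(swarm_size=64, max_iter=200, seed=seed)
        neg = lambda X: -fun(np.atleast_2d(X))
        best_x, bv, _ = cso_minimize(neg, list(zip(space.lower, space.upper)), cfg, batched=True)
        best_v = -bv
        starts = [best_x]
    if polish:
        bounds = list(zip(space.lower, space.upper))
        for x0 in starts:
            res = optimize.minimize(
                lambda x: -float(fun(x.reshape(1, -1))[0]),
                x0,
                method="L-BFGS-B",
                bounds=bounds,
            )
            if -res.fun > best_v:
                best_v, best_x = -float(res.fun), res.x
    return best_v, np.atleast_1d(best_x)


def local_maxima_on_grid(
    fun: Callable[[np.ndarray], np.ndarray],
    space: DesignSpace,
    grid_per_axis: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """All strict-or-plateau local maxima of a 1-d field on a dense grid."""
    if space.dim != 1:
        raise ValueError("local maxima scan is one-dimensional only")
    g = grid_per_axis or DEFAULT_GRID_1D
    xs = np.linspace(space.lower[0], space.upper[0], g)
    vals = fun(xs.reshape(-1, 1))
    left = np.r_[True, vals[1:] >= vals[:-1]]
    right = np.r_[vals[:-1] >= vals[1:], True]
    mask = left & right
    return xs[mask], vals[mask]
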