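"""Swarm-driven searches for G- and prediction-D-optimal designs.

The G-search is a nested min-max: an outer swarm moves candidate designs
(support coordinates plus raw weights mapped onto the simplex) while the
inner problem evaluates the maximum of the prediction variance over the
design space.  During the search the information matrix carries a tiny
ridge (1e-7 on the diagonal) for numerical stability; the returned design
is always re-evaluated and certified without it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from ._optutil import default_grid, maximize_over_space
from .core import ApproximateDesign, HierarchicalLinearModel, normalize_design
from .criteria import CriterionValue, d_pred_criterion, g_criterion, phi_profile
from .cso import CsoConfig, cso_minimize
from .equivalence import OptimalityReport, verify_g_optimality

__all__ = ["find_g_optimal", "find_d_optimal_pred", "OUTER_DEFAULTS", "INNER_DEFAULTS"]

#: outer design search: 128 particles, 200 iterations, gamma 0
OUTER_DEFAULTS = CsoConfig(swarm_size=128, gamma=0.0, max_iter=200, tol=1e-6)
#: inner phi maximization for three or more factors: 32 particles, 128 iterations
INNER_DEFAULTS = CsoConfig(swarm_size=32, gamma=0.0, max_iter=128, tol=1e-6)

_SEARCH_RIDGE = 1e-7


def _child_seeds(seed: int, n: int) -> list:
    states = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in states]


def _raw_to_weights(raw: np.ndarray) -> np.ndarray:
    raw = np.abs(raw)
    s = raw.sum()
    if s <= 0:
        return np.full(raw.size, 1.0 / raw.size)
    return raw / s


def _polish(objective, z, val, canonicalize=None, rounds: int = 4,
            improve_tol: float = 1e-10):
    """Restarted Nelder-Mead refinement of the swarm's best candidate.

    The min-max objective is flat near its optimum and a single simplex run
    often terminates prematurely; restarting from the canonicalized (sorted
    points, normalized weights) representation rescales the initial simplex
    and lets the search escape shallow stalls.
    """
    for i in range(rounds):
        start = canonicalize(z) if canonicalize is not None else z
        if objective(start.reshape(1, -1))[0] <= val + 1e-12:
            z = start
        res = optimize.minimize(
            lambda zz: float(objective(zz.reshape(1, -1))[0]), z,
            method="Nelder-Mead",
            options={"maxiter": 5000, "fatol": 1e-13, "xatol": 1e-11},
        )
        if res.fun <= val:
            improved = val - res.fun
            z, val = res.x, float(res.fun)
            if i > 0 and improved < improve_tol:
                break
        elif i > 0:
            break
    return z, val


def _design_from_z(z, k, dim, space, fixed_points=None):
    if fixed_points is None:
        pts = z[: k * dim].reshape(k, dim)
        raw = z[k * dim:]
        pts = space.clip(pts)
    else:
        pts = fixed_points
        raw = z
    return ApproximateDesign(pts, _raw_to_weights(raw))


def _g_objective_factory(model, k, fixed_points, inner_grid, inner_config, seed,
                         ridge=_SEARCH_RIDGE):
    space = model.space
    dim = space.dim
    if dim <= 2:
        X = space.grid(inner_grid or default_grid(dim))
        Fx = model.basis.batch(X)

        def inner_max(design):
            F = model.basis.batch(design.points)
            M = (F * design.weights[:, None]).T @ F + ridge * np.eye(model.p)
            if np.linalg.cond(M) > 1e12:
                return np.inf
            try:
                Mi = np.linalg.inv(M)
            except np.linalg.LinAlgError:
                return np.inf
            Delta = model.delta
            try:
                N = Delta - Delta @ np.linalg.solve(Mi + Delta, Delta)
            except np.linalg.LinAlgError:
                return np.inf
            vals = np.einsum("ij,jk,ik->i", Fx, Mi, Fx)
            if model.n > 1:
                vals = vals + (model.n - 1) * np.einsum("ij,jk,ik->i", Fx, N, Fx)
            v = vals.max()
            return v if np.isfinite(v) and v > 0 else np.inf
    else:
        cfg = inner_config or INNER_DEFAULTS

        def inner_max(design):
            try:
                v, _ = maximize_over_space(
                    lambda P: phi_profile(model, design, P, reg=ridge),
                    space, polish=False, seed=seed,
                )
            except np.linalg.LinAlgError:
                return np.inf
            return v

    def objective(Z):
        Z = np.atleast_2d(Z)
        out = np.empty(Z.shape[0])
        for i, z in enumerate(Z):
            out[i] = inner_max(_design_from_z(z, k, dim, space, fixed_points))
        return out

    return objective


def find_g_optimal(
    model: HierarchicalLinearModel,
    k: int | None = None,
    outer_config: CsoConfig | None = None,
    inner_config: CsoConfig | None = None,
    fixed_support: np.ndarray | None = None,
    restarts: int = 5,
    seed: int = 0,
    inner_grid: int | None = None,
    certify: bool = True,
    polish: bool = True,
    tol_factor: float = 0.02,
    return_info: bool = False,
):
    """Search for a G-optimal approximate design.

    ``k`` support-point slots (default ``p + 1``; near-duplicates merge and
    negligible weights are pruned afterwards).  With ``fixed_support`` only
    the weights are optimized.  Runs ``restarts`` independent seeded swarms
    and keeps the best final criterion; a Nelder-Mead polish then tightens
    the winning design.  Returns the normalized design and, if ``certify``,
    the equivalence-theorem report (a failed certificate is returned as a
    FAIL verdict, never hidden).
    """
    space = model.space
    dim = space.dim
    fixed_points = None
    if fixed_support is not None:
        fixed_points = np.atleast_2d(np.asarray(fixed_support, dtype=float))
        k = fixed_points.shape[0]
    elif k is None:
        k = model.p + 1
    if fixed_points is None and k < model.p:
        raise ValueError(f"k={k} support points cannot carry a nonsingular "
                         f"information matrix for p={model.p}")

    cfg = outer_config or OUTER_DEFAULTS
    objective = _g_objective_factory(model, k, fixed_points, inner_grid, inner_config, seed)

    if fixed_points is None:
        bounds = [(lo, hi) for lo, hi in zip(space.lower, space.upper)] * k
        bounds += [(0.0, 1.0)] * k
    else:
        bounds = [(0.0, 1.0)] * k

    best_z, best_val = None, np.inf
    histories = {}
    for s in _child_seeds(seed, restarts):
        z, val, hist = cso_minimize(objective, bounds, replace(cfg, seed=s), batched=True)
        histories[s] = hist
        if val < best_val:
            best_z, best_val = z, val

    if polish:
        def canonical(z):
            if fixed_points is not None:
                return _raw_to_weights(z)   # keep the fixed-support order
            d = _design_from_z(z, k, dim, space).sorted()
            return np.concatenate([d.points.ravel(), d.weights])

        # the ridge biases the criterion on ill-conditioned bases; the final
        # refinement therefore runs on the exact (unregularized) objective
        exact_objective = _g_objective_factory(
            model, k, fixed_points, inner_grid, inner_config, seed, ridge=0.0)
        best_z, best_val = _polish(
            exact_objective, best_z, float(exact_objective(best_z.reshape(1, -1))[0]),
            canonical)

    design = _design_from_z(best_z, k, dim, space, fixed_points)
    design = normalize_design(design, space)
    report = None
    if certify:
        report = verify_g_optimality(model, design, tol_factor=tol_factor, seed=seed,
                                     grid_per_axis=inner_grid)
    if return_info:
        return design, report, {"histories": histories}
    return design, report


def find_d_optimal_pred(
    model: HierarchicalLinearModel,
    k: int | None = None,
    config: CsoConfig | None = None,
    restarts: int = 5,
    seed: int = 0,
    polish: bool = True,
    return_info: bool = False,
):
    """Minimize the prediction D-criterion with a single-layer swarm."""
    space = model.space
    dim = space.dim
    if k is None:
        k = model.p + 1
    if k < model.p:
        raise ValueError(f"k={k} support points cannot carry a nonsingular "
                         f"information matrix for p={model.p}")
    cfg = config or CsoConfig(swarm_size=128, gamma=0.0, max_iter=350, tol=1e-6)

    def make_objective(ridge):
        def objective(Z):
            Z = np.atleast_2d(Z)
            out = np.empty(Z.shape[0])
            for i, z in enumerate(Z):
                design = _design_from_z(z, k, dim, space)
                try:
                    out[i] = d_pred_criterion(model, design, reg=ridge).value
                except (np.linalg.LinAlgError, ValueError):
                    out[i] = np.inf
            return out
        return objective

    objective = make_objective(_SEARCH_RIDGE)

    bounds = [(lo, hi) for lo, hi in zip(space.lower, space.upper)] * k
    bounds += [(0.0, 1.0)] * k

    best_z, best_val = None, np.inf
    histories = {}
    for s in _child_seeds(seed, restarts):
        z, val, hist = cso_minimize(objective, bounds, replace(cfg, seed=s), batched=True)
        histories[s] = hist
        if val < best_val:
            best_z, best_val = z, val
    if polish:
        def canonical(z):
            d = _design_from_z(z, k, dim, space).sorted()
            return np.concatenate([d.points.ravel(), d.weights])

        exact_objective = make_objective(0.0)
        best_z, best_val = _polish(
            exact_objective, best_z, float(exact_objective(best_z.reshape(1, -1))[0]),
            canonical)
    design = normalize_design(_design_from_z(best_z, k, dim, space), space)
    crit = d_pred_criterion(model, design)
    if return_info:
        return design, crit, {"histories": histories}
    return design, crit
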