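"""Locally D-optimal designs for Poisson regression with random coefficients.

Model: counts ``Y_ij ~ Poisson(lambda_ij)`` with log intensity
``f(x_ij)' b_i``, where the coefficient vector ``b_i`` has mean ``beta``
(the nominal values of the locally optimal design) and covariance ``D``;
zero rows/columns of ``D`` mark coefficients without random variation.

With normal random effects the marginal moments are explicit:

* mean        ``mu(x)   = exp(f' beta + f' D f / 2)``
* variance    ``mu + mu^2 (e^{f' D f} - 1)``
* covariance  ``mu(x) mu(y) (e^{f(x)' D f(y)} - 1)`` within an individual.

The quasi-information of an approximate design treats the weights as the
within-individual allocation: with ``G = diag(w mu) F`` and
``V = diag(w mu) + (w w') o S`` (``o`` elementwise,
``S_jk = mu_j mu_k (e^{f_j' D f_k} - 1)``), the quasi-information is
``M(xi) = G' V^{-1} G``.  When ``D = 0`` this collapses to the familiar
Poisson GLM information ``sum_l w_l lambda(x_l) f f'``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from ._optutil import maximize_over_space
from .core import ApproximateDesign, DesignSpace, RegressionBasis, normalize_design
from .cso import CsoConfig, cso_minimize
from .equivalence import d_efficiency_lower_bound

__all__ = [
    "PoissonMixedModel",
    "quasi_information",
    "d_criterion_poisson",
    "sensitivity_poisson",
    "find_locally_d_optimal_poisson",
]

#: cap on the linear predictor before exp() is declared unsafe
MAX_LINEAR_PREDICTOR = 50.0


class IntensityOverflowError(FloatingPointError):
    """The log intensity exceeded the safe range at some design point."""


@dataclass(frozen=True)
class PoissonMixedModel:
    """Poisson regression with (possibly correlated) random coefficients."""

    basis: RegressionBasis
    beta: np.ndarray
    D: np.ndarray
    space: DesignSpace
    m: int = 1

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=float)
        D = np.asarray(self.D, dtype=float)
        p = self.basis.p
        if beta.shape != (p,):
            raise ValueError("beta must have one coefficient per basis term")
        if D.shape != (p, p) or not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("D must be symmetric p x p")
        eig = np.linalg.eigvalsh(D)
        if eig.size and eig[0] < -1e-8 * max(1.0, abs(eig[-1])):
            raise ValueError("D must be positive semidefinite")
        # a coefficient with zero variance must not covary with anything
        zero = np.abs(np.diag(D)) < 1e-14
        if np.any(zero):
            off = D[zero, :]
            if np.any(np.abs(off) > 1e-12):
                raise ValueError("zero-variance coefficients must have zero covariances")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "D", D)

    @property
    def p(self) -> int:
        return self.basis.p


def _moment_pieces(model: PoissonMixedModel, points: np.ndarray):
    F = model.basis.batch(np.atleast_2d(points))
    eta = F @ model.beta
    Q = F @ model.D @ F.T
    q = np.diag(Q)
    log_mu = eta + 0.5 * q
    if np.any(np.abs(log_mu) > MAX_LINEAR_PREDICTOR):
        bad = np.atleast_2d(points)[int(np.argmax(np.abs(log_mu)))]
        raise IntensityOverflowError(
            f"log intensity {log_mu.max():.1f} exceeds +-{MAX_LINEAR_PREDICTOR} "
            f"at design point {bad}"
        )
    mu = np.exp(log_mu)
    return F, mu, Q


def quasi_information(model: PoissonMixedModel,
                      design: ApproximateDesign) -> np.ndarray:
    """Quasi-information matrix of an approximate design (p x p, PSD)."""
    w = design.weights / design.weights.sum()
    F, mu, Q = _moment_pieces(model, design.points)
    S = np.outer(mu, mu) * np.expm1(Q)
    V = np.outer(w, w) * S + np.diag(w * mu)
    G = (w * mu)[:, None] * F
    M = G.T @ np.linalg.solve(V, G)
    return 0.5 * (M + M.T)


def d_criterion_poisson(model: PoissonMixedModel,
                        design: ApproximateDesign) -> float:
    """``log |M(xi)|`` of the quasi-information; -inf for singular designs."""
    try:
        M = quasi_information(model, design)
    except np.linalg.LinAlgError:
        return -np.inf
    sign, logdet = np.linalg.slogdet(M)
    return float(logdet) if sign > 0 else -np.inf


def _logdet_mix(model, design, x, alpha):
    """log |M((1-alpha) xi + alpha delta_x)| with x appended to the support."""
    if alpha == 0.0:
        return d_criterion_poisson(model, design)
    pts = np.vstack([design.points, np.atleast_2d(x)])
    w = np.concatenate([(1 - alpha) * design.weights, [alpha]])
    return d_criterion_poisson(model, ApproximateDesign(pts, w))


def sensitivity_poisson(model: PoissonMixedModel, design: ApproximateDesign,
                        x) -> float:
    """Variance-function form of the D-sensitivity at ``x``.

    Defined as ``p`` plus the directional derivative of ``log |M|`` toward
    the one-point design at ``x``; at a D-optimal design it is at most
    ``p`` everywhere with equality on the support.  When ``D = 0`` it
    reduces to ``lambda(x) f' M^{-1} f``.  The derivative is taken
    numerically (second-order forward difference), since the weight
    dependence of the quasi-information is nonlinear.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    L0 = _logdet_mix(model, design, x, 0.0)
    h = 1e-6
    L1 = _logdet_mix(model, design, x, h)
    L2 = _logdet_mix(model, design, x, 2 * h)
    deriv = (4 * L1 - L2 - 3 * L0) / (2 * h)
    return float(deriv + model.p)


def sensitivity_poisson_profile(model, design, X) -> np.ndarray:
    X = np.atleast_2d(X)
    return np.array([sensitivity_poisson(model, design, x) for x in X])


def max_sensitivity_poisson(model: PoissonMixedModel, design: ApproximateDesign,
                            seed: int = 0, grid_per_axis: int | None = None) -> tuple:
    """Maximize the D-sensitivity over the design space (seeded search)."""
    val, arg = maximize_over_space(
        lambda X: sensitivity_poisson_profile(model, design, X),
        model.space, grid_per_axis=grid_per_axis or (51 if model.space.dim <= 2 else None),
        polish=True, seed=seed,
    )
    # the support points themselves are candidate peaks
    for pt in design.points:
        v = sensitivity_poisson(model, design, pt)
        if v > val:
            val, arg = v, pt
    return float(val), np.atleast_1d(arg)


def find_locally_d_optimal_poisson(
    model: PoissonMixedModel,
    k: int | None = None,
    config: CsoConfig | None = None,
    restarts: int = 5,
    seed: int = 0,
    polish: bool = True,
    prune_tol: float = 1e-3,
) -> tuple[ApproximateDesign, float, float]:
    """Single-layer swarm search maximizing ``log |M(xi)|``.

    ``k`` support slots (optima need not be minimally supported; default
    ``p + 2``).  Runs ``restarts`` seeded swarms; each run's design is
    scored by the Atwood-type efficiency floor ``p / max sensitivity``,
    and the reported bound is the minimum across runs (the best design and
    criterion value are still returned).  Returns
    ``(design, log-det value, minimum efficiency bound)``.
    """
    space = model.space
    dim = space.dim
    if k is None:
        k = model.p + 2
    cfg = config or CsoConfig(swarm_size=128, gamma=0.0, max_iter=350, tol=1e-6)

    def objective(Z):
        Z = np.atleast_2d(Z)
        out = np.empty(Z.shape[0])
        for i, z in enumerate(Z):
            pts = space.clip(z[: k * dim].reshape(k, dim))
            raw = np.abs(z[k * dim:])
            w = raw / raw.sum() if raw.sum() > 0 else np.full(k, 1.0 / k)
            try:
                out[i] = -d_criterion_poisson(model, ApproximateDesign(pts, w))
            except IntensityOverflowError:
                out[i] = np.inf
        return out

    bounds = [(lo, hi) for lo, hi in zip(space.lower, space.upper)] * k
    bounds += [(0.0, 1.0)] * k

    runs = []
    for s in np.random.SeedSequence(seed).generate_state(restarts):
        s = int(s) & 0x7FFFFFFF
        z, val, _ = cso_minimize(objective, bounds, replace(cfg, seed=s), batched=True)
        runs.append((val, z, s))
    runs.sort(key=lambda r: r[0])

    designs = []
    eff_bounds = []
    for val, z, s in runs:
        if polish and (val, z, s) == runs[0]:
            res = optimize.minimize(
                lambda zz: float(objective(zz.reshape(1, -1))[0]), z,
                method="Nelder-Mead",
                options={"maxiter": 3000, "fatol": 1e-12, "xatol": 1e-10},
            )
            if res.fun <= val:
                z = res.x
        pts = space.clip(z[: k * dim].reshape(k, dim))
        raw = np.abs(z[k * dim:])
        w = raw / raw.sum() if raw.sum() > 0 else np.full(k, 1.0 / k)
        design = normalize_design(ApproximateDesign(pts, w), space, prune_tol=prune_tol)
        dbar, _ = max_sensitivity_poisson(model, design, seed=s)
        eff_bounds.append(d_efficiency_lower_bound(model.p, max(dbar, model.p)))
        designs.append(design)

    best = designs[0]
    return best, d_criterion_poisson(model, best), float(min(eff_bounds))
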