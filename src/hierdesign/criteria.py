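"""Design criteria for prediction in hierarchical linear models.

Notation: ``M(xi) = sum_l w_l f(x_l) f(x_l)'`` is the standardized
information matrix of an approximate design, ``Delta = m D`` and

    ``N(xi, Delta) = Delta - Delta (M^{-1} + Delta)^{-1} Delta``

is the random-effects block of the prediction mean squared error.  The
prediction variance function

    ``phi(x, xi) = f' M^{-1} f + (n - 1) f' N f``

sums the expected squared prediction error over the ``n`` individuals; its
maximum over the design space is the G-criterion.  The prediction
D-criterion is the log product of the ``(n-1)q + p`` leading eigenvalues of
the MSE matrix (``q`` = rank of ``D``), reported here per observation
(divided by ``m``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._optutil import maximize_over_space
from .core import ApproximateDesign, DesignSpace, HierarchicalLinearModel

__all__ = [
    "CriterionValue",
    "MseMatrix",
    "information_matrix",
    "n_matrix",
    "mse_matrix",
    "phi",
    "phi_profile",
    "g_criterion",
    "g_lower_bound",
    "d_pred_criterion",
    "blup",
    "d_efficiency_fixed",
    "pred_efficiencies",
]


@dataclass(frozen=True)
class CriterionValue:
    """A criterion evaluation, tagged G_pred / D_pred / D_fixed.

    For the G-criterion ``argmax`` is the inner maximizer of ``phi``.  For
    the prediction D-criterion ``raw`` carries the unscaled log product of
    eigenvalues (``m`` times ``value``), which is what efficiency ratios
    are built from.
    """

    value: float
    tag: str
    argmax: np.ndarray | None = None
    raw: float | None = None


@dataclass(frozen=True)
class MseMatrix:
    """Eq-(5)-structured mean squared error matrix of all predictors."""

    full: np.ndarray        # np x np
    m_inv: np.ndarray       # M^{-1}(xi), p x p
    n_block: np.ndarray     # N(xi, Delta), p x p
    n: int
    m: int
    sigma2: float


def information_matrix(model: HierarchicalLinearModel,
                       design: ApproximateDesign) -> np.ndarray:
    """``M(xi) = sum_l w_l f(x_l) f(x_l)'`` (symmetric PSD)."""
    F = model.basis.batch(design.points)
    M = (F * design.weights[:, None]).T @ F
    return 0.5 * (M + M.T)


def _inv_m(model, design, reg: float = 0.0) -> np.ndarray:
    M = information_matrix(model, design)
    if reg:
        M = M + reg * np.eye(model.p)
    try:
        Mi = np.linalg.inv(M)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular information matrix; regularize or add support points"
        ) from err
    return 0.5 * (Mi + Mi.T)


def n_matrix(model: HierarchicalLinearModel, design: ApproximateDesign,
             reg: float = 0.0) -> np.ndarray:
    """``N(xi, Delta) = Delta - Delta (M^{-1} + Delta)^{-1} Delta``.

    Computed in the Delta form, which stays valid for singular ``D``.
    For nonsingular ``D`` it coincides with ``(M + Delta^{-1})^{-1}``.
    """
    Mi = _inv_m(model, design, reg)
    Delta = model.delta
    A = Mi + Delta
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(
            "M^{-1} + Delta is numerically singular; consider regularize()"
        )
    N = Delta - Delta @ np.linalg.solve(A, Delta)
    return 0.5 * (N + N.T)


def mse_matrix(model: HierarchicalLinearModel,
               design: ApproximateDesign, reg: float = 0.0) -> MseMatrix:
    """Full ``np x np`` MSE matrix of the stacked individual predictors.

    ``(sigma2/m) { (1/n) J_n (x) M^{-1} + (I_n - J_n/n) (x) N }`` where
    ``J_n`` is the all-ones matrix and ``(x)`` the Kronecker product.
    """
    Mi = _inv_m(model, design, reg)
    N = n_matrix(model, design, reg)
    n = model.n
    J = np.ones((n, n))
    I = np.eye(n)
    full = (model.sigma2 / model.m) * (
        np.kron(J / n, Mi) + np.kron(I - J / n, N)
    )
    return MseMatrix(full=0.5 * (full + full.T), m_inv=Mi, n_block=N,
                     n=n, m=model.m, sigma2=model.sigma2)


def _phi_parts(model, design, reg=0.0):
    Mi = _inv_m(model, design, reg)
    N = n_matrix(model, design, reg)
    return Mi, N


def phi(model: HierarchicalLinearModel, design: ApproximateDesign, x) -> float:
    """Prediction variance function ``phi(x, xi)`` at a single point."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not model.space.contains(x):
        raise ValueError(f"point {x} lies outside the design space")
    Mi, N = _phi_parts(model, design)
    f = model.basis(x)
    return float(f @ Mi @ f + (model.n - 1) * (f @ N @ f))


def phi_profile(model: HierarchicalLinearModel, design: ApproximateDesign,
                X: np.ndarray, reg: float = 0.0) -> np.ndarray:
    """Vectorized ``phi`` over rows of ``X``."""
    Mi, N = _phi_parts(model, design, reg)
    F = model.basis.batch(np.atleast_2d(X))
    vals = np.einsum("ij,jk,ik->i", F, Mi, F)
    if model.n > 1:
        vals = vals + (model.n - 1) * np.einsum("ij,jk,ik->i", F, N, F)
    return vals


def g_criterion(model: HierarchicalLinearModel, design: ApproximateDesign,
                grid_per_axis: int | None = None, polish: bool = True,
                seed: int = 0, reg: float = 0.0) -> CriterionValue:
    """``psi_G(xi) = max_x phi(x, xi)`` with its inner maximizer.

    The inner maximization uses a dense deterministic grid plus local
    polish for one- and two-factor spaces and a seeded swarm search above.
    """
    val, arg = maximize_over_space(
        lambda X: phi_profile(model, design, X, reg),
        model.space, grid_per_axis=grid_per_axis, polish=polish, seed=seed,
    )
    return CriterionValue(value=float(val), tag="G_pred", argmax=arg)


def g_lower_bound(model: HierarchicalLinearModel,
                  design: ApproximateDesign) -> float:
    """Design-dependent floor of the G-criterion:
    ``p + (n-1) tr{(M^{-1} + Delta)^{-1} Delta}``."""
    Mi = _inv_m(model, design)
    Delta = model.delta
    return float(model.p + (model.n - 1)
                 * np.trace(np.linalg.solve(Mi + Delta, Delta)))


def _n_eigenvalues(model, design, reg=0.0):
    N = n_matrix(model, design, reg)
    return np.sort(np.linalg.eigvalsh(N))[::-1]


def d_pred_criterion(model: HierarchicalLinearModel,
                     design: ApproximateDesign, reg: float = 0.0) -> CriterionValue:
    """Prediction D-criterion (per observation).

    ``(1/m) [ ln det M^{-1} + (n-1) ln prod_{l<=q} lambda_l(N) ]`` with
    ``q = rank(D)`` and ``lambda_l`` the leading eigenvalues of ``N``.
    The raw (unscaled) value is kept alongside for efficiency ratios.
    """
    M = information_matrix(model, design)
    if reg:
        M = M + reg * np.eye(model.p)
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular information matrix")
    raw = -logdet
    q = model.rank_d
    if q > 0:
        lam = _n_eigenvalues(model, design, reg)[:q]
        if np.any(lam <= 0):
            raise ValueError(
                "degenerate design: a leading eigenvalue of N(xi, Delta) is not positive"
            )
        raw += (model.n - 1) * float(np.sum(np.log(lam)))
    return CriterionValue(value=raw / model.m, tag="D_pred", raw=raw)


def blup(model: HierarchicalLinearModel, F: np.ndarray,
         Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Population BLUE and individual BLUPs from observed data.

    ``F`` is the common ``m x p`` individual design matrix, ``Y`` the
    ``n x m`` response array.  The population estimate is the least-squares
    fit to the average response; each individual predictor shrinks the
    individual least-squares estimate toward it:

    ``b_i = D (A + D)^{-1} b_{i;ind} + A (A + D)^{-1} b``,  ``A = (F'F)^{-1}``.
    """
    F = np.asarray(F, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != F.shape[0]:
        raise ValueError("Y must be n x m matching the design matrix rows")
    FtF = F.T @ F
    if np.linalg.matrix_rank(FtF) < F.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix F")
    A = np.linalg.inv(FtF)
    proj = A @ F.T
    beta_ind = Y @ proj.T                     # n x p individual LSEs
    beta_hat = beta_ind.mean(axis=0)
    S = np.linalg.inv(A + model.D)
    W_ind = model.D @ S                        # shrinkage toward individual fit
    W_pop = A @ S
    beta_i = beta_ind @ W_ind.T + beta_hat @ W_pop.T
    return beta_hat, beta_i


def d_efficiency_fixed(design: ApproximateDesign, reference: ApproximateDesign,
                       model: HierarchicalLinearModel) -> float:
    """Fixed-effects D-efficiency ``(|M(xi)| / |M(ref)|)^{1/p}``."""
    s1, l1 = np.linalg.slogdet(information_matrix(model, design))
    s2, l2 = np.linalg.slogdet(information_matrix(model, reference))
    if s2 <= 0:
        raise np.linalg.LinAlgError("reference design has singular information matrix")
    if s1 <= 0:
        return 0.0
    return float(np.exp((l1 - l2) / model.p))


def pred_efficiencies(design: ApproximateDesign, reference: ApproximateDesign,
                      model: HierarchicalLinearModel, kind: str = "G",
                      **crit_kwargs) -> float:
    """Efficiency of ``design`` relative to an optimal ``reference``.

    G: ratio of criterion values ``psi_G(ref) / psi_G(design)``.
    D: ``exp{ [psi_D(ref) - psi_D(design)] / ((n-1) q + p) }`` on the raw
    (unscaled) log-eigenvalue criterion.  Both equal 1 when the designs
    coincide.  These are package conventions for mixed models.
    """
    if kind.upper() == "G":
        ref = g_criterion(model, reference, **crit_kwargs).value
        val = g_criterion(model, design, **crit_kwargs).value
        return float(ref / val)
    if kind.upper() == "D":
        ref = d_pred_criterion(model, reference).raw
        val = d_pred_criterion(model, design).raw
        dof = (model.n - 1) * model.rank_d + model.p
        return float(np.exp((ref - val) / dof))
    raise ValueError("kind must be 'G' or 'D'")
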