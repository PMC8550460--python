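"""Equivalence-theorem machinery certifying G-optimality.

A design ``xi*`` is G-optimal if and only if there is a probability
measure ``mu*`` on the answering set

    ``A(xi*) = { x : phi(x, xi*) = max_z phi(z, xi*) }``

such that the sensitivity function

    ``phi_G(x) - tr{ M_A M^{-1} + (n-1) M N M_A N } <= 0``  for all x,

with ``phi_G(x) = f' M^{-1} M_A M^{-1} f + (n-1) f' N M_A N f`` and
``M_A(mu) = sum_a mu_a f(a) f(a)'``.  At the support points of an optimal
design the sensitivity vanishes, which is what the measure search below
exploits.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._optutil import local_maxima_on_grid, maximize_over_space
from .core import ApproximateDesign, DesignSpace, HierarchicalLinearModel, normalize_design
from .criteria import (
    g_criterion,
    g_lower_bound,
    information_matrix,
    n_matrix,
    phi_profile,
)
from .cso import CsoConfig, cso_minimize

__all__ = [
    "OptimalityReport",
    "answering_set",
    "ma_matrix",
    "sensitivity_g",
    "sensitivity_g_profile",
    "measure_loss",
    "find_mu",
    "verify_g_optimality",
    "sensitivity_d_fixed",
    "d_efficiency_lower_bound",
    "MU_SEARCH_DEFAULTS",
]

#: measure-search swarm settings (64 particles, gamma 0.05, 1200 iterations)
MU_SEARCH_DEFAULTS = CsoConfig(swarm_size=64, gamma=0.05, max_iter=1200, tol=1e-12)

#: relative tolerance for membership in the answering set
ANSWERING_EPS = 1e-4


def answering_set(model: HierarchicalLinearModel, design: ApproximateDesign,
                  n_splits: int = 2, eps: float = ANSWERING_EPS,
                  merge_tol: float = 1e-4, max_rounds: int = 5,
                  grid_per_axis: int | None = None, seed: int = 0) -> np.ndarray:
    """Locate all global maximizers of ``phi(. , xi)``.

    The design space is split into ``n_splits`` sub-boxes per axis, the
    prediction variance is maximized on each sub-box, and candidates within
    a relative ``eps`` of the overall maximum are kept.  Splitting doubles
    until the answering-set size is stable for two consecutive rounds.
    """
    space = model.space
    fun = lambda X: phi_profile(model, design, X)

    def candidates(splits: int) -> list:
        pts = []
        if space.dim == 1:
            # the dense scan already isolates every interior/boundary peak
            xs, vals = local_maxima_on_grid(fun, space, grid_per_axis)
            vmax = vals.max()
            for x, v in zip(xs, vals):
                if v >= vmax * (1 - 10 * eps):
                    sub = DesignSpace([max(space.lower[0], x - 0.05 * space.ranges[0])],
                                      [min(space.upper[0], x + 0.05 * space.ranges[0])])
                    v2, x2 = maximize_over_space(fun, sub, 201, seed=seed)
                    pts.append((x2, v2))
            return pts
        edges = [np.linspace(lo, hi, splits + 1) for lo, hi in zip(space.lower, space.upper)]
        index_grid = np.stack(np.meshgrid(*[np.arange(splits)] * space.dim,
                                          indexing="ij"), axis=-1).reshape(-1, space.dim)
        for idx in index_grid:
            lo = [edges[j][i] for j, i in enumerate(idx)]
            hi = [edges[j][i + 1] for j, i in enumerate(idx)]
            sub = DesignSpace(lo, hi)
            v, x = maximize_over_space(fun, sub, grid_per_axis or 51, seed=seed)
            pts.append((x, v))
        return pts

    prev_size = -1
    stable = 0
    splits = n_splits
    result = None
    for _ in range(max_rounds):
        cand = candidates(splits)
        vmax = max(v for _, v in cand)
        keep = [x for x, v in cand if v >= vmax * (1 - eps)]
        merged = normalize_design(
            ApproximateDesign(np.atleast_2d(np.array(keep)), np.ones(len(keep))),
            space, merge_tol=merge_tol, prune_tol=0.0,
        )
        result = merged.points
        if result.shape[0] == prev_size:
            stable += 1
            if stable >= 2 or space.dim == 1:
                break
        else:
            stable = 0
        prev_size = result.shape[0]
        splits *= 2
    return result


def ma_matrix(basis, measure: ApproximateDesign) -> np.ndarray:
    """``M_A(mu) = sum_a mu_a f(a) f(a)'`` over the answering set."""
    F = basis.batch(measure.points)
    w = measure.weights / measure.weights.sum()
    M = (F * w[:, None]).T @ F
    return 0.5 * (M + M.T)


def _sens_parts(model, design, measure):
    Mi = np.linalg.inv(information_matrix(model, design))
    N = n_matrix(model, design)
    MA = ma_matrix(model.basis, measure)
    M = information_matrix(model, design)
    trace = float(np.trace(MA @ Mi) + (model.n - 1) * np.trace(M @ N @ MA @ N))
    return Mi, N, MA, trace


def sensitivity_g_profile(model, design, measure, X) -> np.ndarray:
    """Vectorized G-sensitivity over rows of ``X``."""
    Mi, N, MA, trace = _sens_parts(model, design, measure)
    F = model.basis.batch(np.atleast_2d(X))
    G1 = F @ Mi
    vals = np.einsum("ij,jk,ik->i", G1, MA, G1)
    if model.n > 1:
        G2 = F @ N
        vals = vals + (model.n - 1) * np.einsum("ij,jk,ik->i", G2, MA, G2)
    return vals - trace


def sensitivity_g(model: HierarchicalLinearModel, design: ApproximateDesign,
                  measure: ApproximateDesign, x) -> float:
    """``phi_G(x, xi) - trace term``; nonpositive everywhere iff optimal."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return float(sensitivity_g_profile(model, design, measure, x.reshape(1, -1))[0])


def measure_loss(model: HierarchicalLinearModel, design: ApproximateDesign,
                 measure: ApproximateDesign, mode: str = "simple",
                 grid_per_axis: int | None = None, seed: int = 0) -> float:
    """Squared-residual objective driving the measure search.

    ``simple``: design-weighted squared sensitivity at the design's own
    support points (which must be roots of the sensitivity function at the
    optimum).  ``full`` adds the squared supremum of the sensitivity over
    the whole design space.
    """
    resid = sensitivity_g_profile(model, design, measure, design.points)
    loss = float(np.sum(design.weights * resid**2))
    if mode == "full":
        sup, _ = maximize_over_space(
            lambda X: sensitivity_g_profile(model, design, measure, X),
            model.space, grid_per_axis=grid_per_axis or 201, polish=True, seed=seed,
        )
        loss += float(sup**2)
    elif mode != "simple":
        raise ValueError("mode must be 'simple' or 'full'")
    return loss


def find_mu(model: HierarchicalLinearModel, design: ApproximateDesign,
            config: CsoConfig | None = None, answering: np.ndarray | None = None,
            loss_threshold: float = 1e-5, seed: int | None = None,
            refine_full: bool = True) -> tuple[ApproximateDesign, float, bool]:
    """Search for the equivalence-theorem measure on the answering set.

    Two stages: minimize the simple (support-residual) loss first, then
    polish with the full objective including the supremum term.  Returns
    ``(measure, full-mode loss, converged flag)``.
    """
    cfg = config or MU_SEARCH_DEFAULTS
    if seed is not None:
        cfg = CsoConfig(**{**cfg.__dict__, "seed": seed})
    A = answering if answering is not None else answering_set(model, design, seed=cfg.seed)
    A = np.atleast_2d(A)
    kA = A.shape[0]
    if kA == 1:
        mu = ApproximateDesign(A, [1.0])
        loss = measure_loss(model, design, mu, "full", seed=cfg.seed)
        return mu, loss, loss <= loss_threshold

    def raw_to_measure(r):
        r = np.abs(np.asarray(r, dtype=float))
        if r.sum() <= 0:
            r = np.ones(kA)
        return ApproximateDesign(A, r / r.sum())

    def simple_obj(R):
        return np.array([
            measure_loss(model, design, raw_to_measure(r), "simple") for r in np.atleast_2d(R)
        ])

    bounds = [(0.0, 1.0)] * kA
    best_r, _, _ = cso_minimize(simple_obj, bounds, cfg, batched=True)

    if refine_full:
        from scipy import optimize

        res = optimize.minimize(
            lambda r: measure_loss(model, design, raw_to_measure(r), "full", seed=cfg.seed),
            best_r, method="Nelder-Mead",
            options={"maxiter": 400, "fatol": 1e-14, "xatol": 1e-10},
        )
        if res.fun <= measure_loss(model, design, raw_to_measure(best_r), "full", seed=cfg.seed):
            best_r = res.x
    mu = raw_to_measure(best_r)
    loss = measure_loss(model, design, mu, "full", seed=cfg.seed)
    return mu, loss, loss <= loss_threshold


@dataclass
class OptimalityReport:
    """Certificate of the G-equivalence check for one design."""

    design: ApproximateDesign
    answering: np.ndarray
    measure: ApproximateDesign
    phi_bar: float
    max_sensitivity: float
    sensitivity_argmax: np.ndarray
    support_residuals: np.ndarray
    tol: float
    passed: bool
    efficiency_bound: float
    mu_loss: float
    mu_converged: bool

    def to_text(self) -> str:
        lines = [
            "G-optimality equivalence check",
            "==============================",
            f"verdict             : {'PASS' if self.passed else 'FAIL'}",
            f"G-criterion (phi_bar): {self.phi_bar:.6f}",
            f"tolerance            : {self.tol:.6g}",
            f"max sensitivity      : {self.max_sensitivity:.6g} at "
            f"{np.array2string(self.sensitivity_argmax, precision=4)}",
            f"G-efficiency bound   : {self.efficiency_bound:.4f}",
            f"measure loss         : {self.mu_loss:.3g}"
            + ("" if self.mu_converged else "  (WARNING: above threshold)"),
            "",
            "answering set and measure mu:",
        ]
        for pt, w in zip(self.measure.points, self.measure.weights):
            lines.append(f"  {np.array2string(pt, precision=4):>20s}  {w:.4f}")
        lines.append("")
        lines.append("sensitivity at design support:")
        for pt, r in zip(self.design.points, self.support_residuals):
            lines.append(f"  {np.array2string(pt, precision=4):>20s}  {r: .3e}")
        return "\n".join(lines)

    def sensitivity_csv(self, path, model: HierarchicalLinearModel,
                        grid_per_axis: int = 501, seed: int = 0) -> None:
        """Dump a plottable (x, phi, sensitivity) grid."""
        space = model.space
        if space.dim <= 2:
            X = space.grid(grid_per_axis)
        else:
            rng = np.random.default_rng(seed)
            X = rng.uniform(space.lower, space.upper, size=(10000, space.dim))
        phi_vals = phi_profile(model, self.design, X)
        sens = sensitivity_g_profile(model, self.design, self.measure, X)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([f"x{j + 1}" for j in range(space.dim)] + ["phi", "sensitivity"])
            for row, pv, sv in zip(X, phi_vals, sens):
                writer.writerow([f"{v:.6f}" for v in row] + [f"{pv:.8f}", f"{sv:.8e}"])


def verify_g_optimality(model: HierarchicalLinearModel, design: ApproximateDesign,
                        tol: float | None = None, tol_factor: float = 0.02,
                        mu_config: CsoConfig | None = None, seed: int = 0,
                        grid_per_axis: int | None = None) -> OptimalityReport:
    """Full equivalence-theorem certificate for a candidate design.

    Passes when the supremum of the sensitivity over the space and its
    absolute value at every support point stay below the tolerance
    (default ``0.02 * phi_bar``, matched to three-decimal design reporting).
    The efficiency bound is the Theorem-1 floor over the achieved
    G-criterion, a lower bound on the design's G-efficiency.
    """
    crit = g_criterion(model, design, grid_per_axis=grid_per_axis, seed=seed)
    phi_bar = crit.value
    if tol is None:
        tol = tol_factor * phi_bar
    # candidate maximizers within the certification tolerance all belong to
    # the answering set of the nearby exactly-optimal design; a tighter eps
    # would disqualify designs reported to finite precision
    eps = max(ANSWERING_EPS, tol / max(phi_bar, 1e-12))
    A = answering_set(model, design, eps=eps, seed=seed, grid_per_axis=grid_per_axis)
    mu, loss, converged = find_mu(model, design, config=mu_config, answering=A, seed=seed)
    sup, arg = maximize_over_space(
        lambda X: sensitivity_g_profile(model, design, mu, X),
        model.space, grid_per_axis=grid_per_axis, polish=True, seed=seed,
    )
    resid = sensitivity_g_profile(model, design, mu, design.points)
    passed = bool(sup <= tol and np.all(np.abs(resid) <= tol))
    eff = float(g_lower_bound(model, design) / phi_bar)
    return OptimalityReport(
        design=design, answering=A, measure=mu, phi_bar=phi_bar,
        max_sensitivity=float(sup), sensitivity_argmax=np.atleast_1d(arg),
        support_residuals=resid, tol=float(tol), passed=passed,
        efficiency_bound=eff, mu_loss=loss, mu_converged=converged,
    )


def sensitivity_d_fixed(model: HierarchicalLinearModel,
                        design: ApproximateDesign, x) -> float:
    """Fixed-effects D-sensitivity ``f' M^{-1} f - p`` (D plays no role)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    Mi = np.linalg.inv(information_matrix(model, design))
    f = model.basis(x)
    return float(f @ Mi @ f - model.p)


def d_efficiency_lower_bound(p: int, max_sensitivity: float) -> float:
    """Atwood-type D-efficiency floor ``p / dbar`` from the sensitivity peak.

    ``dbar`` is the maximum of the variance-function form of the
    D-sensitivity; it is at least ``p`` for any valid design, with equality
    exactly at the optimum.
    """
    if max_sensitivity < p * (1 - 1e-9):
        raise ValueError(f"max sensitivity {max_sensitivity} below p={p}: "
                         "not attainable for a valid design")
    return float(p / max(max_sensitivity, p))
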