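"""Model and design containers for optimal-design problems.

The objects here describe the ingredients of an approximate-design problem
for hierarchical (random-coefficient) linear models:

* a compact box design space :math:`\\mathcal{X}`,
* a regression basis ``f = (f_1, ..., f_p)``, possibly a fractional
  polynomial under the Box-Tidwell convention (power 0 means ``ln x``,
  a repeated power multiplies the previous term by ``ln x``),
* the dispersion matrix ``D`` of the individual coefficients (in units of
  the error variance; may be singular when some coefficients are fixed),
* the group structure: ``n`` individuals with ``m`` observations each,
* an approximate design: support points with weights summing to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DesignSpace",
    "BasisTerm",
    "RegressionBasis",
    "HierarchicalLinearModel",
    "ApproximateDesign",
    "basis_eval",
    "normalize_design",
    "round_to_exact",
    "random_model",
    "FP_POWERS",
]

#: conventional fractional-polynomial power set
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


class BasisDomainError(ValueError):
    """A basis term was evaluated outside its domain (log/fractional power
    of a non-positive coordinate)."""


@dataclass(frozen=True)
class DesignSpace:
    """Axis-aligned box of admissible experimental settings."""

    lower: np.ndarray
    upper: np.ndarray

    def __init__(self, lower: Sequence[float], upper: Sequence[float]):
        lower = np.atleast_1d(np.asarray(lower, dtype=float))
        upper = np.atleast_1d(np.asarray(upper, dtype=float))
        if lower.ndim != 1 or lower.shape != upper.shape:
            raise ValueError("lower and upper bounds must be 1-d and equal length")
        if lower.size < 1:
            raise ValueError("design space needs at least one factor")
        if not np.all(lower < upper):
            raise ValueError("each lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def ranges(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, x, tol: float = 1e-9) -> bool:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        slack = tol * np.maximum(self.ranges, 1.0)
        return bool(np.all(x >= self.lower - slack) and np.all(x <= self.upper + slack))

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def grid(self, points_per_axis: int) -> np.ndarray:
        """Dense product grid, shape ``(points_per_axis**dim, dim)``."""
        axes = [np.linspace(lo, hi, points_per_axis) for lo, hi in zip(self.lower, self.upper)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([m.ravel() for m in mesh])


@dataclass(frozen=True)
class BasisTerm:
    """One regression function.

    kind
        ``constant`` (1), ``power`` (``x_j**power``), ``log`` (``ln x_j``,
        the Box-Tidwell power 0) or ``product`` (interaction of two or more
        factors, each raised to a real power).
    factors, powers
        parallel tuples of factor indices and exponents.  A ``power``/``log``
        term uses a single factor; ``product`` needs at least two.
    ln_mult
        multiplicity of the repeated-power convention: the term is multiplied
        by ``(ln x_j)**ln_mult`` for its (first) factor.
    """

    kind: str
    factors: tuple = ()
    powers: tuple = ()
    ln_mult: int = 0

    def __post_init__(self):
        if self.kind not in ("constant", "power", "log", "product"):
            raise ValueError(f"unknown basis term kind {self.kind!r}")
        object.__setattr__(self, "factors", tuple(int(f) for f in self.factors))
        object.__setattr__(self, "powers", tuple(float(p) for p in self.powers))
        if self.kind == "constant" and self.factors:
            raise ValueError("constant term takes no factors")
        if self.kind in ("power", "log") and len(self.factors) != 1:
            raise ValueError(f"{self.kind} term needs exactly one factor")
        if self.kind == "power" and len(self.powers) != 1:
            raise ValueError("power term needs exactly one exponent")
        if self.kind == "product" and (len(self.factors) < 2 or len(self.factors) != len(self.powers)):
            raise ValueError("product term references >= 2 factors with matching powers")
        if self.ln_mult < 0:
            raise ValueError("ln multiplicity must be nonnegative")
        if self.ln_mult > 0 and self.kind == "constant":
            raise ValueError("ln multiplicity requires a base term with a factor")

    def _needs_positive(self) -> bool:
        if self.kind == "log" or self.ln_mult > 0:
            return True
        if self.kind in ("power", "product"):
            return any(p < 0 or p != int(p) for p in self.powers)
        return False

    def __call__(self, x: np.ndarray) -> float:
        x = np.atleast_1d(x)
        if self.kind == "constant":
            return 1.0
        if self._needs_positive():
            for f in self.factors:
                if x[f] <= 0:
                    raise BasisDomainError(
                        f"term {self.label()} requires x[{f}] > 0, got {x[f]}"
                    )
        if self.kind == "log":
            val = np.log(x[self.factors[0]])
        elif self.kind == "power":
            val = x[self.factors[0]] ** self.powers[0]
        else:  # product
            val = 1.0
            for f, p in zip(self.factors, self.powers):
                val *= x[f] ** p
        if self.ln_mult:
            val *= np.log(x[self.factors[0]]) ** self.ln_mult
        return float(val)

    def batch(self, X: np.ndarray) -> np.ndarray:
        """Vectorized evaluation over rows of ``X`` (shape ``(N, dim)``)."""
        X = np.atleast_2d(X)
        if self.kind == "constant":
            return np.ones(X.shape[0])
        if self._needs_positive():
            cols = X[:, list(self.factors)]
            if np.any(cols <= 0):
                bad = X[np.any(cols <= 0, axis=1)][0]
                raise BasisDomainError(
                    f"term {self.label()} requires positive coordinates, got point {bad}"
                )
        if self.kind == "log":
            val = np.log(X[:, self.factors[0]])
        elif self.kind == "power":
            val = X[:, self.factors[0]] ** self.powers[0]
        else:
            val = np.ones(X.shape[0])
            for f, p in zip(self.factors, self.powers):
                val = val * X[:, f] ** p
        if self.ln_mult:
            val = val * np.log(X[:, self.factors[0]]) ** self.ln_mult
        return val

    def label(self) -> str:
        if self.kind == "constant":
            core = "1"
        elif self.kind == "log":
            core = f"ln[x{self.factors[0] + 1}]"
        elif self.kind == "power":
            p = self.powers[0]
            core = f"x{self.factors[0] + 1}" + ("" if p == 1 else f"^{p:g}")
        else:
            core = "*".join(
                f"x{f + 1}" + ("" if p == 1 else f"^{p:g}")
                for f, p in zip(self.factors, self.powers)
            )
        if self.ln_mult:
            core += f"*ln[x{self.factors[0] + 1}]" + (
                f"^{self.ln_mult}" if self.ln_mult > 1 else ""
            )
        return core


def _validate_fp_power(p: float, allow_any: bool):
    if not allow_any and not any(abs(p - q) < 1e-12 for q in FP_POWERS):
        raise ValueError(
            f"power {p} outside the conventional fractional-polynomial set "
            f"{FP_POWERS}; pass allow_any_power=True for arbitrary exponents"
        )


@dataclass(frozen=True)
class RegressionBasis:
    """Ordered collection of basis terms; order matches the coefficients."""

    terms: tuple

    def __init__(self, terms: Iterable[BasisTerm]):
        terms = tuple(terms)
        if not terms:
            raise ValueError("basis needs at least one term")
        object.__setattr__(self, "terms", terms)

    @property
    def p(self) -> int:
        return len(self.terms)

    def __call__(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.array([t(x) for t in self.terms])

    def batch(self, X: np.ndarray) -> np.ndarray:
        """Design-matrix rows for every row of ``X``: shape ``(N, p)``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([t.batch(X) for t in self.terms])

    def labels(self) -> list:
        return [t.label() for t in self.terms]

    # -- constructors ------------------------------------------------------

    @staticmethod
    def polynomial(degree: int, intercept: bool = True) -> "RegressionBasis":
        """One-factor polynomial basis ``(1, x, ..., x^degree)``."""
        terms = [BasisTerm("constant")] if intercept else []
        terms += [BasisTerm("power", (0,), (d,)) for d in range(1, degree + 1)]
        return RegressionBasis(terms)

    @staticmethod
    def fractional(powers: Sequence[float], intercept: bool = True,
                   allow_any_power: bool = False) -> "RegressionBasis":
        """One-factor fractional polynomial with Box-Tidwell powers.

        A power of 0 yields ``ln x``; a power equal to its predecessor
        yields the previous term multiplied by another ``ln x``.
        """
        terms = [BasisTerm("constant")] if intercept else []
        prev = None
        mult = 0
        for p in powers:
            _validate_fp_power(float(p), allow_any_power)
            if prev is not None and p == prev:
                mult += 1
            else:
                mult = 0
            base = BasisTerm("log", (0,)) if p == 0 else BasisTerm("power", (0,), (p,))
            if mult:
                base = replace(base, ln_mult=mult)
            terms.append(base)
            prev = p
        return RegressionBasis(terms)

    @staticmethod
    def main_effects(dim: int, interactions: Sequence[tuple] = (),
                     intercept: bool = True) -> "RegressionBasis":
        """Multi-factor basis: intercept, main effects, pairwise products."""
        terms = [BasisTerm("constant")] if intercept else []
        terms += [BasisTerm("power", (j,), (1.0,)) for j in range(dim)]
        for pair in interactions:
            terms.append(BasisTerm("product", tuple(pair), (1.0,) * len(pair)))
        return RegressionBasis(terms)


def basis_eval(basis: RegressionBasis, x) -> np.ndarray:
    """Evaluate the regression vector ``f(x)``; length ``basis.p``."""
    return basis(x)


@dataclass(frozen=True)
class ApproximateDesign:
    """Support points and weights of an approximate design.

    Also serves as a probability measure on an answering set in the
    equivalence-theorem machinery.
    """

    points: np.ndarray
    weights: np.ndarray

    def __init__(self, points, weights):
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[0] == 1 and points.shape[1] > 1 and len(np.atleast_1d(weights)) > 1:
            points = points.T  # accept a 1-d list of scalar points
        weights = np.atleast_1d(np.asarray(weights, dtype=float))
        if points.shape[0] != weights.size:
            raise ValueError("number of points and weights differ")
        if np.any(weights < -1e-12):
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "weights", weights)

    @property
    def k(self) -> int:
        return self.weights.size

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    def total_weight(self) -> float:
        return float(self.weights.sum())

    def normalized(self) -> "ApproximateDesign":
        s = self.weights.sum()
        if s <= 0:
            raise ValueError("total weight must be positive")
        return ApproximateDesign(self.points, self.weights / s)

    def sorted(self) -> "ApproximateDesign":
        order = np.lexsort(self.points.T[::-1])
        return ApproximateDesign(self.points[order], self.weights[order])

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write one row per support point: ``x1..xd`` then ``weight``."""
        header = "\t".join([f"x{j + 1}" for j in range(self.dim)] + ["weight"])
        rows = [
            "\t".join(f"{v:.6f}" for v in np.append(pt, w))
            for pt, w in zip(self.points, self.weights)
        ]
        Path(path).write_text(header + "\n" + "\n".join(rows) + "\n")

    @staticmethod
    def from_tsv(path) -> "ApproximateDesign":
        lines = [ln for ln in Path(path).read_text().strip().splitlines() if ln.strip()]
        data = np.array([[float(v) for v in ln.split("\t")] for ln in lines[1:]])
        return ApproximateDesign(data[:, :-1], data[:, -1])

    def __repr__(self) -> str:
        rows = ", ".join(
            f"{np.array2string(pt, precision=4, floatmode='fixed')}:{w:.4f}"
            for pt, w in zip(self.points, self.weights)
        )
        return f"ApproximateDesign({rows})"


def design1d(points: Sequence[float], weights: Sequence[float]) -> ApproximateDesign:
    """Convenience constructor for one-factor designs."""
    pts = np.asarray(points, dtype=float).reshape(-1, 1)
    return ApproximateDesign(pts, weights)


def normalize_design(design: ApproximateDesign, space: DesignSpace | None = None,
                     merge_tol: float = 1e-4, prune_tol: float = 1e-4) -> ApproximateDesign:
    """Merge near-duplicate support points, drop negligible weights, rescale.

    ``merge_tol`` is relative to the factor ranges when a design space is
    given, absolute otherwise.  Merged points land at the weight-averaged
    location of their cluster.
    """
    if design.total_weight() <= 0:
        raise ValueError("design has no positive weight")
    scale = space.ranges if space is not None else np.ones(design.dim)
    pts, w = design.points.copy(), design.weights.copy()

    # greedy clustering: pull each point into the first cluster within tol
    centers: list[np.ndarray] = []
    masses: list[float] = []
    for pt, wi in zip(pts, w):
        for idx, c in enumerate(centers):
            if np.all(np.abs(pt - c) <= merge_tol * scale):
                new_mass = masses[idx] + wi
                if new_mass > 0:
                    centers[idx] = (c * masses[idx] + pt * wi) / new_mass
                masses[idx] = new_mass
                break
        else:
            centers.append(pt.astype(float))
            masses.append(float(wi))
    pts = np.array(centers)
    w = np.array(masses)
    w = w / w.sum()
    keep = w >= prune_tol
    if not np.any(keep):
        raise ValueError("all weights pruned; lower prune_tol")
    pts, w = pts[keep], w[keep]
    w = w / w.sum()
    if space is not None:
        pts = space.clip(pts)
    return ApproximateDesign(pts, w).sorted()


def round_to_exact(design: ApproximateDesign, N: int) -> list:
    """Apportion ``N`` runs to the support by largest remainders.

    Plain rounding of each ``N*w_j`` does not in general satisfy the total
    count constraint, so the fractional remainders arbitrate the leftover
    runs.  Ties go to the larger weight, then to the lower point index.
    Returns ``[(point, count), ...]`` with counts summing exactly to ``N``.
    """
    if N < design.k:
        raise ValueError(f"N={N} is below the support size {design.k}")
    quota = N * design.weights / design.weights.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    shortfall = N - counts.sum()
    order = sorted(
        range(design.k),
        key=lambda i: (-remainder[i], -design.weights[i], i),
    )
    for i in order[:shortfall]:
        counts[i] += 1
    return [(design.points[i].copy(), int(counts[i])) for i in range(design.k)]


@dataclass(frozen=True)
class HierarchicalLinearModel:
    """Random-coefficient linear model ``y_ij = f(x_j)' b_i + e_ij``.

    The individual coefficient vectors ``b_i`` have mean ``beta`` and
    covariance ``sigma2 * D``; the errors have variance ``sigma2``.  All
    ``n`` individuals share the same ``m``-observation regime.
    """

    basis: RegressionBasis
    D: np.ndarray
    n: int
    m: int
    space: DesignSpace
    sigma2: float = 1.0

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1] or D.shape[0] != self.basis.p:
            raise ValueError("D must be p x p for the basis dimension p")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("D must be symmetric")
        eig = np.linalg.eigvalsh(D)
        if eig.size and eig[0] < -1e-8 * max(1.0, abs(eig[-1])):
            raise ValueError("D must be positive semidefinite")
        if self.n < 1 or self.m < 1:
            raise ValueError("n and m must be >= 1")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        object.__setattr__(self, "D", D)

    @property
    def p(self) -> int:
        return self.basis.p

    @property
    def delta(self) -> np.ndarray:
        """The scaled dispersion ``m * D`` entering all design criteria."""
        return self.m * self.D

    @property
    def rank_d(self) -> int:
        eig = np.abs(np.linalg.eigvalsh(self.D))
        if eig.max() == 0:
            return 0
        return int(np.sum(eig > 1e-10 * eig.max()))


@dataclass
class RandomModelConfig:
    """Size limits for the random model-specification generator."""

    max_degree: int = 3
    max_n: int = 20
    max_m: int = 8
    d_scale: float = 1.0
    singular_prob: float = 0.3
    dim: int = 1


def random_model(seed: int, config: RandomModelConfig | None = None) -> HierarchicalLinearModel:
    """Draw a reproducible, valid hierarchical linear model specification.

    ``D`` is built as ``A A'`` (hence PSD); with probability
    ``singular_prob`` some rows/columns are zeroed to exercise singular
    dispersion matrices.
    """
    cfg = config or RandomModelConfig()
    rng = np.random.default_rng(seed)
    degree = int(rng.integers(1, cfg.max_degree + 1))
    basis = RegressionBasis.polynomial(degree)
    p = basis.p
    A = rng.normal(scale=np.sqrt(cfg.d_scale / p), size=(p, p))
    D = A @ A.T
    if rng.random() < cfg.singular_prob:
        kill = rng.integers(0, p)
        D[kill, :] = 0.0
        D[:, kill] = 0.0
    lo = rng.uniform(0.0, 0.5)
    hi = lo + rng.uniform(0.5, 2.0)
    return HierarchicalLinearModel(
        basis=basis,
        D=D,
        n=int(rng.integers(2, cfg.max_n + 1)),
        m=int(rng.integers(1, cfg.max_m + 1)),
        space=DesignSpace([lo], [hi]),
    )
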