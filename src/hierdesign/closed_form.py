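"""Closed-form results for simple random-effects models.

Random-slope model ``y_ij = b1 + b_i2 x_j + e_ij`` on [0, 1] with slope
variance ``d`` (so ``delta = m d``): the G-optimal design sits on {0, 1}
with a known weight ``w*`` at 1, the prediction variance is an explicit
quadratic, and the equivalence measure on {0, 1} has an explicit weight.
These formulas double as independent oracles for the swarm search.

Random-intercept models: the fixed-effects D-optimal design is also
G-optimal and its criterion value ``p + (n-1) delta / (1 + delta)`` does
not depend on the design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RandomSlopeSpec",
    "random_slope_weight",
    "random_slope_phi",
    "random_slope_mu_weight",
    "random_slope_sensitivity",
    "random_intercept_g_bound",
    "random_slope_model",
]


@dataclass(frozen=True)
class RandomSlopeSpec:
    """Counts and slope-variance factor of the random-slope model."""

    n: int
    m: int
    d: float

    def __post_init__(self):
        if self.n < 1 or self.m < 1:
            raise ValueError("n and m must be >= 1")
        if self.d < 0:
            raise ValueError("slope variance factor d must be >= 0")

    @property
    def delta(self) -> float:
        return self.m * self.d


def random_slope_weight(spec: RandomSlopeSpec) -> float:
    """Optimal weight ``w*`` at x = 1 of the two-point G-optimal design.

    ``w* = [sqrt(delta^2 n^2 + 4 delta + 4) + n delta - 2] / [2 delta (n+1)]``;
    the delta -> 0 limit is the balanced fixed-effects value 1/2.
    """
    delta, n = spec.delta, spec.n
    if delta == 0:
        return 0.5
    return (np.sqrt(delta**2 * n**2 + 4 * delta + 4) + n * delta - 2) / (2 * delta * (n + 1))


def random_slope_phi(spec: RandomSlopeSpec, w: float, x) -> float:
    """Prediction variance of the {0,1}-supported design with weight w at 1.

    ``(1/(w - w^2) + delta (n-1)/(delta w + 1)) x^2 + 2 x/(w-1) - 1/(w-1)``.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0) or np.any(w >= 1):
        raise ValueError("weight w must lie strictly inside (0, 1)")
    delta, n = spec.delta, spec.n
    x = np.asarray(x, dtype=float)
    quad = 1.0 / (w - w**2) + delta * (n - 1) / (delta * w + 1)
    return quad * x**2 + 2.0 * x / (w - 1) - 1.0 / (w - 1)


def random_slope_mu_weight(spec: RandomSlopeSpec, w_star: float | None = None) -> float:
    """Weight at 1 of the equivalence measure ``mu*`` on {0, 1}."""
    if w_star is None:
        w_star = random_slope_weight(spec)
    delta, n = spec.delta, spec.n
    if delta == 0:
        return 0.5
    w = w_star
    num = delta**2 * w**4 + 2 * delta * w**3 + w**2
    den = ((n + 1) * delta**2 * w**4 + (4 * delta - 2 * n * delta**2) * w**3
           + (2 - 4 * delta + n * delta**2) * w**2 + 2 * (delta - 1) * w + 1)
    return num / den


def random_slope_sensitivity(spec: RandomSlopeSpec, w_star: float | None = None,
                             w_mu: float | None = None, x=0.0) -> float:
    """Sensitivity function of the optimal two-point design.

    Quadratic in x with maximum ``(1 - w_mu) / (w* - 1)^2`` at both 0 and 1,
    where it equals the equivalence-theorem trace term.
    """
    if w_star is None:
        w_star = random_slope_weight(spec)
    if w_mu is None:
        w_mu = random_slope_mu_weight(spec, w_star)
    delta, n = spec.delta, spec.n
    w = w_star
    x = np.asarray(x, dtype=float)
    quad = ((w**2 - 2 * w * w_mu + w_mu) / (w**2 * (w - 1) ** 2)
            + delta**2 * w_mu * (n - 1) / (delta * w + 1) ** 2)
    return quad * x**2 + 2 * (w_mu - 1) / (w - 1) ** 2 * x + (1 - w_mu) / (w - 1) ** 2


def random_intercept_g_bound(p: int, n: int, delta: float) -> float:
    """G-criterion value ``p + (n-1) delta/(1+delta)`` of a random-intercept
    model at (any) fixed-effects D-optimal design; design-independent."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    return float(p + (n - 1) * delta / (1 + delta))


def random_slope_model(spec: RandomSlopeSpec):
    """The matching :class:`HierarchicalLinearModel` on [0, 1]."""
    from .core import DesignSpace, HierarchicalLinearModel, RegressionBasis

    return HierarchicalLinearModel(
        basis=RegressionBasis.polynomial(1),
        D=np.diag([0.0, spec.d]),
        n=spec.n, m=spec.m,
        space=DesignSpace([0.0], [1.0]),
    )
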