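"""Competitive swarm optimizer.

A swarm of particles is split into random pairs each iteration; the member
with the worse objective value (the loser) updates its velocity toward the
winner and, optionally, toward the swarm center:

    ``v <- R1*v + R2*(x_winner - x_loser) + gamma * R3*(xbar - x_loser)``
    ``x <- x + v``

with ``R1, R2, R3`` fresh U(0,1) vectors.  Winners are left untouched, so
the best objective value never deteriorates.  Positions are clipped to the
box bounds and the violating velocity components are zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "CsoConfig",
    "SwarmState",
    "compete_and_update",
    "cso_minimize",
    "regularize",
]


@dataclass(frozen=True)
class CsoConfig:
    """Tuning of the competitive swarm optimizer.

    Defaults follow the settings used throughout the design searches:
    ``gamma = 0`` for the main (outer) problems, 128 particles and
    convergence once successive best values differ by less than ``1e-6``.
    """

    swarm_size: int = 128
    gamma: float = 0.0
    max_iter: int = 350
    tol: float = 1e-6
    patience: int = 20
    seed: int = 0
    velocity_init: str = "zero"   # "zero" (reproducible) or "uniform"

    def __post_init__(self):
        if self.swarm_size < 4 or self.swarm_size % 2:
            raise ValueError("swarm size must be even and >= 4")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.gamma < 0:
            raise ValueError("social factor gamma must be >= 0")
        if self.velocity_init not in ("zero", "uniform"):
            raise ValueError("velocity_init must be 'zero' or 'uniform'")


@dataclass
class SwarmState:
    positions: np.ndarray
    velocities: np.ndarray
    values: np.ndarray
    best_position: np.ndarray
    best_value: float
    iteration: int = 0

    @property
    def center(self) -> np.ndarray:
        return self.positions.mean(axis=0)


def _clip_state(x: np.ndarray, v: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    out = np.clip(x, lo, hi)
    v = np.where(out != x, 0.0, v)
    return out, v


def compete_and_update(winner: np.ndarray, loser: np.ndarray,
                       loser_velocity: np.ndarray, center: np.ndarray,
                       bounds: np.ndarray, config: CsoConfig,
                       rng: np.random.Generator):
    """Update one loser particle; returns ``(position, velocity)``.

    The winner is untouched by the competition.  Fresh U(0,1) vectors are
    drawn per call; positions are clipped to bounds with the violating
    velocity component zeroed.
    """
    d = loser.size
    R1, R2, R3 = rng.random((3, d))
    v = R1 * loser_velocity + R2 * (winner - loser) + config.gamma * R3 * (center - loser)
    x = loser + v
    return _clip_state(x, v, bounds[:, 0], bounds[:, 1])


def cso_minimize(objective: Callable, bounds: Sequence, config: CsoConfig,
                 batched: bool = False,
                 return_state: bool = False):
    """Minimize ``objective`` over a box via competitive swarm optimization.

    ``bounds`` is a sequence of ``(lo, hi)`` pairs.  With ``batched=True``
    the objective maps an ``(n, d)`` array to ``n`` values.  Non-finite
    objective values are treated as +inf (the particle loses).  Returns
    ``(best_x, best_value, history)`` where ``history`` is the nonincreasing
    per-iteration best value.
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    d = bounds.shape[0]
    rng = np.random.default_rng(config.seed)
    n = config.swarm_size

    X = rng.uniform(lo, hi, size=(n, d))
    if config.velocity_init == "uniform":
        span = hi - lo
        V = rng.uniform(-span, span, size=(n, d))
    else:
        V = np.zeros((n, d))

    def evaluate(pts: np.ndarray) -> np.ndarray:
        if batched:
            vals = np.asarray(objective(pts), dtype=float)
        else:
            vals = np.array([objective(p) for p in pts], dtype=float)
        return np.where(np.isfinite(vals), vals, np.inf)

    vals = evaluate(X)
    ib = int(np.argmin(vals))
    state = SwarmState(X, V, vals, X[ib].copy(), float(vals[ib]))
    history = [state.best_value]
    stall = 0

    for it in range(1, config.max_iter + 1):
        perm = rng.permutation(n)
        a, b = perm[: n // 2], perm[n // 2:]
        a_wins = state.values[a] <= state.values[b]
        winners = np.where(a_wins, a, b)
        losers = np.where(a_wins, b, a)
        center = state.center

        R1, R2, R3 = rng.random((3, losers.size, d))
        Xl, Vl = state.positions[losers], state.velocities[losers]
        Vl = R1 * Vl + R2 * (state.positions[winners] - Xl) + config.gamma * R3 * (center - Xl)
        Xl = Xl + Vl
        Xl, Vl = _clip_state(Xl, Vl, lo, hi)
        state.positions[losers] = Xl
        state.velocities[losers] = Vl
        state.values[losers] = evaluate(Xl)

        ib = int(np.argmin(state.values))
        if state.values[ib] < state.best_value:
            state.best_value = float(state.values[ib])
            state.best_position = state.positions[ib].copy()
        state.iteration = it
        history.append(state.best_value)
        # converged once successive best values stay within tol for a
        # sustained stretch (a single stalled iteration is not convergence)
        if abs(history[-2] - history[-1]) < config.tol:
            stall += 1
            if stall >= config.patience:
                break
        else:
            stall = 0

    out = (state.best_position, state.best_value, np.array(history))
    return out + (state,) if return_state else out


def regularize(matrix: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """Ridge stabilization ``M + eps * I`` used during swarm search.

    Final certification always re-evaluates without the ridge.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("expected a square matrix")
    return matrix + eps * np.eye(matrix.shape[0])
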