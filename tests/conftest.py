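"""Shared fixtures: the worked example models and their published designs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import hierdesign as hd

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")


def linear_model(D, n, m, lo, hi, fp=False):
    basis = hd.RegressionBasis.fractional([0.5, 1, 2]) if fp else hd.RegressionBasis.polynomial(2)
    return hd.HierarchicalLinearModel(
        basis=basis, D=np.asarray(D, dtype=float), n=n, m=m,
        space=hd.DesignSpace([lo], [hi]),
    )


D_CORR3 = [[0.8, 0.3, 0.1], [0.3, 0.5, 0.08], [0.1, 0.08, 0.4]]
D_CORR4 = [[0.8, 0.3, 0.1, 0.05], [0.3, 0.5, 0.08, 0.04],
           [0.1, 0.08, 0.4, 0.02], [0.05, 0.04, 0.02, 0.3]]

#: the four published G-design case studies:
#: (model args, printed G design, printed G value, printed D design, printed D value)
CASES = {
    "quad-uncorr": dict(
        model=dict(D=np.diag([0.2, 0.2, 0.3]), n=10, m=5, lo=0, hi=2),
        g_pts=[0, 0.966, 2], g_w=[0.146, 0.140, 0.714], g_val=13.480,
        d_pts=[0, 0.946, 2], d_w=[0.157, 0.140, 0.703], d_val=-4.666,
        mu_w=[0.231, 0.175, 0.595],
    ),
    "quad-corr": dict(
        model=dict(D=D_CORR3, n=11, m=4, lo=0, hi=3),
        g_pts=[0, 1.274, 3], g_w=[0.165, 0.270, 0.565], g_val=19.000,
        d_pts=[0, 1.239, 3], d_w=[0.163, 0.272, 0.565], d_val=-8.798,
    ),
    "fp-uncorr": dict(
        model=dict(D=np.diag([0.3, 0.5, 0.8, 0.2]), n=10, m=5, lo=1, hi=3, fp=True),
        g_pts=[1, 1.440, 2.342, 3], g_w=[0.186, 0.190, 0.120, 0.504], g_val=17.939,
        d_pts=[1, 1.412, 2.361, 3], d_w=[0.230, 0.186, 0.122, 0.462], d_val=-2.116,
    ),
    "fp-corr": dict(
        model=dict(D=D_CORR4, n=8, m=4, lo=1, hi=3, fp=True),
        g_pts=[1, 1.419, 2.372, 3], g_w=[0.230, 0.186, 0.122, 0.462], g_val=15.546,
    ),
    "fp-corr-wide": dict(
        model=dict(D=D_CORR4, n=10, m=5, lo=1, hi=4, fp=True),
        g_pts=[1, 1.602, 2.914, 4], g_w=[0.206, 0.218, 0.109, 0.467], g_val=20.271,
        d_pts=[1, 1.599, 2.884, 4], d_w=[0.205, 0.217, 0.110, 0.468], d_val=-89.985,
    ),
}


def case_model(name):
    return linear_model(**CASES[name]["model"])


def case_design(name, which="g"):
    c = CASES[name]
    return hd.design1d(c[f"{which}_pts"], c[f"{which}_w"])


@pytest.fixture
def quad_model():
    return case_model("quad-uncorr")


@pytest.fixture
def quad_design():
    return case_design("quad-uncorr")


@pytest.fixture
def fixed_effects_quadratic_13():
    """Quadratic fixed-effects model on [1,3]; D-optimal design is equal
    weights at {1, 2, 3}."""
    return hd.HierarchicalLinearModel(
        basis=hd.RegressionBasis.polynomial(2), D=np.zeros((3, 3)),
        n=10, m=5, space=hd.DesignSpace([1], [3]),
    )


def poisson_table5():
    basis = hd.RegressionBasis.main_effects(2, interactions=[(0, 1)])
    model = hd.PoissonMixedModel(
        basis=basis, beta=[-0.5, 0.2, -0.3, 0.4], D=np.diag([0.3, 0.2, 0.5, 0.6]),
        space=hd.DesignSpace([-0.5, -1.0], [1.7, 0.6]),
    )
    design = hd.ApproximateDesign(
        [[-0.5, -1], [-0.5, 0.6], [1.218, -1], [1.7, -0.578], [1.7, 0.6]],
        [0.263, 0.382, 0.052, 0.144, 0.159],
    )
    return model, design


def poisson_table6():
    basis = hd.RegressionBasis.main_effects(2, interactions=[(0, 1)])
    D = np.array([[0.30, 0.02, 0.10, 0.0], [0.02, 1.10, 0.60, 0.0],
                  [0.10, 0.60, 1.20, 0.0], [0.0, 0.0, 0.0, 0.0]])
    model = hd.PoissonMixedModel(
        basis=basis, beta=[-0.9, 1.0, 1.2, -1.5], D=D,
        space=hd.DesignSpace([-0.8, -1.3], [1.4, 0.5]),
    )
    design = hd.ApproximateDesign(
        [[-0.8, 0.5], [0.528, -1.3], [0.701, 0.5], [1.179, -0.28],
         [1.4, -1.3], [1.4, 0.5]],
        [0.365, 0.320, 0.135, 0.095, 0.075, 0.010],
    )
    return model, design


def poisson_xi4():
    basis = hd.RegressionBasis.main_effects(4, interactions=[(0, 1), (0, 3), (1, 3)])
    model = hd.PoissonMixedModel(
        basis=basis, beta=[1, 2, 3, -3, -1, -2, 1, 3],
        D=np.diag([0.5, 2.2, 1, 1, 0, 0, 1.3, 0.7]),
        space=hd.DesignSpace([-1] * 4, [1] * 4),
    )
    pts = np.array([
        [0.056, -0.250, 0.474, 0.723, 0.369, -0.313, -0.322, 0.362, -0.220, 0.003, 0.321, -0.279],
        [0.025, 0.726, 0.893, -0.658, -0.504, 0.533, -0.491, 0.501, 0.042, -0.003, 0.422, 0.847],
        [-1.0, 0.379, -0.305, -0.263, -0.182, -0.214, -0.298, -0.014, -1.0, -1.0, -0.195, -0.455],
        [1.0, 0.789, 0.229, 0.176, -1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0, 0.407],
    ]).T
    w = [0.261, 0.049, 0.013, 0.047, 0.048, 0.079, 0.096, 0.048, 0.106, 0.138, 0.096, 0.019]
    return model, hd.ApproximateDesign(pts, w)


def poisson_xi5():
    basis = hd.RegressionBasis.main_effects(5, interactions=[(0, 1), (0, 2), (2, 4)])
    D1 = np.array([[1.3, 0.6, 0.1], [0.6, 1.0, 0.4], [0.1, 0.4, 1.2]])
    D = np.zeros((9, 9))
    D[:3, :3] = D1
    D[3:, 3:] = np.diag([1.0, 0.0, 0.0, 0.3, 0.5, 0.0])
    model = hd.PoissonMixedModel(
        basis=basis, beta=[1.0, 2.0, 3.0, -3.0, -1.0, -2.0, 0.2, 0.5, -0.5], D=D,
        space=hd.DesignSpace([-1] * 5, [1] * 5),
    )
    pts = np.array([
        [-0.021, 0.510, -0.021, 0.519, -0.021, 0.238, -1.0, -1.0, -0.910, 0.510, -0.141, 0.020],
        [1.0, 1.0, 1.0, -0.514, 1.0, -0.428, 0.625, 0.690, -0.176, 1.0, 0.534, 0.375],
        [-1.0, -0.299, -1.0, 0.341, -1.0, -0.546, 0.333, -0.485, -0.410, -0.299, -0.566, 0.360],
        [-1.0, -1.0, 1.0, -1.0, -1.0, -1.0, -1.0, -1.0, -1.0, -1.0, -1.0, -1.0],
        [0.589, -1.0, -1.0, -1.0, -1.0, -1.0, -1.0, -1.0, -1.0, 0.389, -1.0, -1.0],
    ]).T
    w = [0.224, 0.058, 0.208, 0.022, 0.091, 0.016, 0.063, 0.016, 0.062, 0.208, 0.009, 0.024]
    return model, hd.ApproximateDesign(pts, w)


def random_design_for(model, seed, k=None):
    """A valid random design on the model's space (nonsingular with high
    probability; resampled a few times if needed)."""
    rng = np.random.default_rng(seed)
    k = k or model.p + 1
    for _ in range(20):
        pts = rng.uniform(model.space.lower, model.space.upper, size=(k, model.space.dim))
        w = rng.dirichlet(np.ones(k))
        design = hd.ApproximateDesign(pts, w)
        M = hd.information_matrix(model, design)
        if np.linalg.cond(M) < 1e8:
            return design
    raise RuntimeError("could not draw a well-conditioned random design")


def brute_force_g_optimum(model, support_res=0.02, weight_res=0.005, k=2, phi_grid=101):
    """Exhaustive (support x simplex) grid minimization of the G-criterion
    for one-factor models -- an independent oracle for the swarm search."""
    import itertools

    lo, hi = model.space.lower[0], model.space.upper[0]
    supports = np.linspace(lo, hi, int(round(1.0 / support_res)) + 1)
    X = np.linspace(lo, hi, phi_grid).reshape(-1, 1)
    Fx = model.basis.batch(X)
    Delta = model.delta
    nw = int(round(1.0 / weight_res))
    if k == 2:
        W = np.array([[i / nw, 1 - i / nw] for i in range(1, nw)])
    elif k == 3:
        W = np.array([[i / nw, j / nw, (nw - i - j) / nw]
                      for i in range(1, nw) for j in range(1, nw - i)])
    else:
        raise ValueError("oracle supports k in {2, 3}")
    best = np.inf
    for pts in itertools.combinations(supports, k):
        F = model.basis.batch(np.array(pts).reshape(-1, 1))
        Ms = np.einsum("ki,ip,iq->kpq", W, F, F)
        ok = np.abs(np.linalg.det(Ms)) > 1e-12
        if not ok.any():
            continue
        Mi = np.linalg.inv(Ms[ok])
        inner = np.linalg.inv(Mi + Delta)
        N = Delta - np.einsum("pq,kqr,rs->kps", Delta, inner, Delta)
        vals = np.einsum("xp,kpq,xq->kx", Fx, Mi, Fx)
        vals += (model.n - 1) * np.einsum("xp,kpq,xq->kx", Fx, N, Fx)
        m = vals.max(axis=1).min()
        best = min(best, m)
    return best
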