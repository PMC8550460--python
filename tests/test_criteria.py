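import numpy as np
import pytest

import hierdesign as hd
from conftest import case_design, case_model, random_design_for


def two_param_model(D=None, n=10, m=5, lo=0.0, hi=1.0):
    return hd.HierarchicalLinearModel(
        basis=hd.RegressionBasis.polynomial(1),
        D=np.zeros((2, 2)) if D is None else np.asarray(D, dtype=float),
        n=n, m=m, space=hd.DesignSpace([lo], [hi]),
    )


class TestInformationMatrix:
    def test_two_point_arithmetic(self):
        model = two_param_model()
        d = hd.design1d([0, 1], [0.5, 0.5])
        assert np.allclose(hd.information_matrix(model, d), [[1, 0.5], [0.5, 0.5]])

    def test_single_point_is_rank_one(self):
        model = case_model("quad-uncorr")
        d = hd.design1d([1.0], [1.0])
        M = hd.information_matrix(model, d)
        assert np.linalg.matrix_rank(M) == 1

    def test_matches_direct_summation(self, quad_model, quad_design):
        M = sum(w * np.outer(quad_model.basis(x), quad_model.basis(x))
                for x, w in zip(quad_design.points, quad_design.weights))
        assert np.allclose(hd.information_matrix(quad_model, quad_design), M, atol=1e-12)


class TestNMatrix:
    def test_zero_dispersion_gives_zero(self):
        model = two_param_model()
        d = hd.design1d([0, 1], [0.5, 0.5])
        assert np.allclose(hd.n_matrix(model, d), 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_delta_form_equals_woodbury_form(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        model = hd.HierarchicalLinearModel(
            basis=hd.RegressionBasis.polynomial(2), D=A @ A.T + 0.1 * np.eye(3),
            n=8, m=4, space=hd.DesignSpace([0], [2]))
        d = random_design_for(model, seed)
        N = hd.n_matrix(model, d)
        M = hd.information_matrix(model, d)
        woodbury = np.linalg.inv(M + np.linalg.inv(model.delta))
        assert np.allclose(N, woodbury, atol=1e-8)

    def test_random_intercept_reduction(self):
        # constant first regressor: e1' N e1 = delta / (1 + delta)
        dvar, m = 0.2, 5
        model = hd.HierarchicalLinearModel(
            basis=hd.RegressionBasis.polynomial(2), D=np.diag([dvar, 0, 0]),
            n=10, m=m, space=hd.DesignSpace([0], [2]))
        d = hd.design1d([0, 1, 2], [0.3, 0.4, 0.3])
        delta = m * dvar
        N = hd.n_matrix(model, d)
        assert N[0, 0] == pytest.approx(delta / (1 + delta), abs=1e-10)


class TestMseMatrix:
    def test_single_individual_reduces_to_fixed_effects(self):
        model = hd.HierarchicalLinearModel(
            basis=hd.RegressionBasis.polynomial(1), D=np.diag([0.3, 0.4]),
            n=1, m=5, space=hd.DesignSpace([0], [1]))
        d = hd.design1d([0, 1], [0.5, 0.5])
        mse = hd.mse_matrix(model, d)
        assert np.allclose(mse.full, mse.sigma2 / model.m * mse.m_inv, atol=1e-12)

    def test_zero_dispersion_block_structure(self):
        model = two_param_model(n=4)
        d = hd.design1d([0, 1], [0.5, 0.5])
        mse = hd.mse_matrix(model, d)
        assert np.allclose(mse.n_block, 0.0)
        p = model.p
        # every p x p block equals (sigma2/m) M^{-1} / n
        for i in range(4):
            for j in range(4):
                block = mse.full[i * p:(i + 1) * p, j * p:(j + 1) * p]
                assert np.allclose(block, mse.m_inv / (model.m * 4), atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_eigenvalues_combine_blocks(self, seed):
        model = hd.random_model(seed + 40)
        d = random_design_for(model, seed)
        mse = hd.mse_matrix(model, d)
        got = np.sort(np.linalg.eigvalsh(mse.full))
        s = model.sigma2 / model.m
        expected = np.sort(np.concatenate(
            [s * np.linalg.eigvalsh(mse.m_inv)]
            + [s * np.linalg.eigvalsh(mse.n_block)] * (model.n - 1)))
        assert np.allclose(got, expected, atol=1e-8 * max(1, got.max()))


class TestPhi:
    def test_fixed_effects_reduction(self):
        model = two_param_model()
        d = hd.design1d([0, 1], [0.5, 0.5])
        assert hd.phi(model, d, 0.0) == pytest.approx(2.0)

    def test_matches_random_slope_closed_form(self):
        spec = hd.RandomSlopeSpec(n=10, m=5, d=0.2)
        model = hd.random_slope_model(spec)
        w = hd.random_slope_weight(spec)
        d = hd.design1d([0, 1], [1 - w, w])
        for x in np.linspace(0, 1, 11):
            assert hd.phi(model, d, x) == pytest.approx(
                float(hd.random_slope_phi(spec, w, x)), abs=1e-10)

    def test_outside_space_rejected(self, quad_model, quad_design):
        with pytest.raises(ValueError):
            hd.phi(quad_model, quad_design, 5.0)


class TestGCriterion:
    def test_three_point_quadratic_case_study(self, quad_model, quad_design):
        # exact maximum of the prediction variance at this published design
        # (the value re-derived by dense grid + polish in this package)
        crit = hd.g_criterion(quad_model, quad_design)
        assert crit.value == pytest.approx(14.0249, abs=5e-4)
        assert crit.argmax[0] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_never_below_lower_bound(self, seed):
        model = hd.random_model(seed + 100)
        d = random_design_for(model, seed)
        crit = hd.g_criterion(model, d, grid_per_axis=401, polish=False)
        assert crit.value >= hd.g_lower_bound(model, d) - 1e-9


class TestGLowerBound:
    def test_zero_dispersion_gives_p(self):
        model = two_param_model()
        d = hd.design1d([0, 1], [0.5, 0.5])
        assert hd.g_lower_bound(model, d) == pytest.approx(2.0)

    def test_random_intercept_value_design_independent(self):
        dvar, m, n = 0.2, 5, 10   # delta = 1
        model = hd.HierarchicalLinearModel(
            basis=hd.RegressionBasis.polynomial(1), D=np.diag([dvar, 0]),
            n=n, m=m, space=hd.DesignSpace([0], [1]))
        for w in (0.3, 0.5, 0.8):
            d = hd.design1d([0, 1], [1 - w, w])
            assert hd.g_lower_bound(model, d) == pytest.approx(6.5, abs=1e-9)


class TestDPredCriterion:
    def test_published_quadratic_d_design(self):
        model = case_model("quad-uncorr")
        crit = hd.d_pred_criterion(model, case_design("quad-uncorr", "d"))
        assert crit.value == pytest.approx(-4.666, abs=0.01)
        assert crit.raw == pytest.approx(crit.value * model.m)

    def test_zero_dispersion_reduces_to_logdet(self):
        model = two_param_model()
        d = hd.design1d([0, 1], [0.5, 0.5])
        crit = hd.d_pred_criterion(model, d)
        M = hd.information_matrix(model, d)
        assert crit.raw == pytest.approx(-np.log(np.linalg.det(M)), abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_equals_mse_leading_eigenvalue_product(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        model = hd.HierarchicalLinearModel(
            basis=hd.RegressionBasis.polynomial(2), D=A @ A.T + 0.05 * np.eye(3),
            n=6, m=4, space=hd.DesignSpace([0], [2]))
        d = random_design_for(model, seed)
        crit = hd.d_pred_criterion(model, d)
        mse = hd.mse_matrix(model, d)
        lam = np.sort(np.linalg.eigvalsh(model.m * mse.full / model.sigma2))[::-1]
        keep = (model.n - 1) * model.rank_d + model.p
        assert crit.raw == pytest.approx(float(np.sum(np.log(lam[:keep]))), abs=1e-6)


class TestBlup:
    def _data(self, model, seed=0):
        rng = np.random.default_rng(seed)
        xs = np.linspace(0, 1, model.m).reshape(-1, 1)
        F = model.basis.batch(xs)
        Y = rng.normal(size=(model.n, model.m))
        return F, Y

    def test_full_shrinkage_when_d_zero(self):
        model = two_param_model(n=6)
        F, Y = self._data(model)
        beta_hat, beta_i = hd.blup(model, F, Y)
        assert np.allclose(beta_i, np.tile(beta_hat, (6, 1)), atol=1e-10)

    def test_no_shrinkage_limit(self):
        model = two_param_model(D=1e8 * np.eye(2), n=6)
        F, Y = self._data(model)
        _, beta_i = hd.blup(model, F, Y)
        individual = Y @ (np.linalg.inv(F.T @ F) @ F.T).T
        assert np.allclose(beta_i, individual, atol=1e-6)

    def test_mean_of_predictors_is_population_estimate(self):
        model = two_param_model(D=[[0.5, 0.1], [0.1, 0.8]], n=9)
        F, Y = self._data(model, seed=3)
        beta_hat, beta_i = hd.blup(model, F, Y)
        assert np.allclose(beta_i.mean(axis=0), beta_hat, atol=1e-10)

    def test_rank_deficient_design_matrix_rejected(self):
        model = two_param_model()
        F = np.ones((4, 2))
        with pytest.raises(np.linalg.LinAlgError):
            hd.blup(model, F, np.zeros((3, 4)))


class TestEfficiencies:
    def test_identity_is_one(self, quad_model, quad_design):
        assert hd.d_efficiency_fixed(quad_design, quad_design, quad_model) == pytest.approx(1.0)
        for kind in ("G", "D"):
            assert hd.pred_efficiencies(quad_design, quad_design, quad_model,
                                        kind) == pytest.approx(1.0)

    def test_fixed_efficiency_reciprocal_pair(self, quad_model):
        a = hd.design1d([0, 1, 2], [1 / 3, 1 / 3, 1 / 3])
        b = hd.design1d([0, 0.9, 2], [0.25, 0.35, 0.4])
        prod = (hd.d_efficiency_fixed(a, b, quad_model)
                * hd.d_efficiency_fixed(b, a, quad_model))
        assert prod == pytest.approx(1.0, abs=1e-10)

    def test_fixed_efficiency_matches_determinants(self, quad_model):
        a = hd.design1d([0, 1, 2], [1 / 3, 1 / 3, 1 / 3])
        b = hd.design1d([0, 0.9, 2], [0.25, 0.35, 0.4])
        Ma = hd.information_matrix(quad_model, a)
        Mb = hd.information_matrix(quad_model, b)
        expected = (np.linalg.det(Ma) / np.linalg.det(Mb)) ** (1 / 3)
        assert hd.d_efficiency_fixed(a, b, quad_model) == pytest.approx(expected)

    def test_worse_design_scores_below_one(self, quad_model, quad_design):
        worse = hd.design1d([0, 0.966, 2], [0.05, 0.20, 0.75])
        assert hd.pred_efficiencies(worse, quad_design, quad_model, "D") < 1.0


class TestInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_phi_integral_trace_identity(self, seed):
        model = hd.random_model(seed + 7)
        d = random_design_for(model, seed)
        integral = float(np.sum(
            d.weights * hd.phi_profile(model, d, d.points)))
        M = hd.information_matrix(model, d)
        N = hd.n_matrix(model, d)
        expected = model.p + (model.n - 1) * float(np.trace(N @ M))
        assert integral == pytest.approx(expected, abs=1e-8 * max(1, abs(expected)))

    def test_permutation_and_merge_invariance(self, quad_model, quad_design):
        base = hd.g_criterion(quad_model, quad_design, polish=False).value
        perm = hd.ApproximateDesign(quad_design.points[::-1], quad_design.weights[::-1])
        assert hd.g_criterion(quad_model, perm, polish=False).value == pytest.approx(base)
        dup = hd.normalize_design(hd.ApproximateDesign(
            np.vstack([quad_design.points, quad_design.points[:1]]),
            np.append(quad_design.weights * [0.5, 1, 1], quad_design.weights[0] * 0.5)))
        assert hd.g_criterion(quad_model, dup, polish=False).value == pytest.approx(base)
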