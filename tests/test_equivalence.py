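import numpy as np
import pytest

import hierdesign as hd
from conftest import case_model, random_design_for

# the swarm-found optimum of the quadratic mixed model case study,
# frozen from a certified run (criterion 13.4448, certificate PASS)
OPT_QUAD_PTS = [0.0, 1.03441474, 2.0]
OPT_QUAD_W = [0.15859786, 0.14073338, 0.70066876]


@pytest.fixture
def certified_quad(quad_model):
    return hd.design1d(OPT_QUAD_PTS, OPT_QUAD_W)


def random_slope_setup(n=10, m=5, d=0.2):
    spec = hd.RandomSlopeSpec(n=n, m=m, d=d)
    model = hd.random_slope_model(spec)
    w = hd.random_slope_weight(spec)
    return spec, model, hd.design1d([0, 1], [1 - w, w]), w


class TestAnsweringSet:
    def test_random_slope_endpoints(self):
        _, model, design, _ = random_slope_setup()
        A = hd.answering_set(model, design)
        assert A.shape[0] == 2
        assert np.allclose(np.sort(A.ravel()), [0.0, 1.0], atol=1e-6)

    def test_quadratic_optimum_has_three_maximizers(self, quad_model, certified_quad):
        A = hd.answering_set(quad_model, certified_quad)
        assert A.shape[0] == 3
        assert np.allclose(np.sort(A.ravel()), [0.0, 0.926, 2.0], atol=5e-3)

    def test_single_peak_gives_singleton(self):
        model = hd.HierarchicalLinearModel(
            basis=hd.RegressionBasis.polynomial(1), D=np.zeros((2, 2)),
            n=5, m=3, space=hd.DesignSpace([0], [1]))
        design = hd.design1d([0, 1], [0.7, 0.3])   # lopsided: unique max at 1
        A = hd.answering_set(model, design)
        assert A.shape[0] == 1 and A[0, 0] == pytest.approx(1.0, abs=1e-6)


class TestMaMatrix:
    def test_point_mass(self):
        basis = hd.RegressionBasis.polynomial(1)
        mu = hd.design1d([0.5], [1.0])
        f = basis([0.5])
        assert np.allclose(hd.ma_matrix(basis, mu), np.outer(f, f))

    def test_uniform_two_points(self):
        basis = hd.RegressionBasis.polynomial(1)
        mu = hd.design1d([0, 1], [0.5, 0.5])
        assert np.allclose(hd.ma_matrix(basis, mu), [[1, 0.5], [0.5, 0.5]])

    def test_matches_information_matrix(self, quad_model, quad_design):
        MA = hd.ma_matrix(quad_model.basis, quad_design)
        assert np.allclose(MA, hd.information_matrix(quad_model, quad_design))


class TestSensitivityG:
    def test_matches_random_slope_closed_form(self):
        spec, model, design, w = random_slope_setup()
        wmu = hd.random_slope_mu_weight(spec, w)
        mu = hd.design1d([0, 1], [1 - wmu, wmu])
        for x in np.linspace(0, 1, 9):
            closed = hd.random_slope_sensitivity(spec, w, wmu, x) \
                - hd.random_slope_sensitivity(spec, w, wmu, 0.0)
            generic = hd.sensitivity_g(model, design, mu, x)
            assert generic == pytest.approx(float(closed), abs=1e-8)

    def test_zero_at_support_of_certified_design(self):
        spec, model, design, w = random_slope_setup(n=7, m=4, d=0.5)
        wmu = hd.random_slope_mu_weight(spec, w)
        mu = hd.design1d([0, 1], [1 - wmu, wmu])
        for x in (0.0, 1.0):
            assert abs(hd.sensitivity_g(model, design, mu, x)) < 1e-8

    def test_fixed_effects_reduction_vanishes_at_d_optimal_support(
            self, fixed_effects_quadratic_13):
        model = fixed_effects_quadratic_13
        xi_d = hd.design1d([1, 2, 3], [1 / 3, 1 / 3, 1 / 3])
        mu = xi_d  # for D = 0 the optimal measure rides on the same support
        for x in (1.0, 2.0, 3.0):
            assert abs(hd.sensitivity_g(model, xi_d, mu, x)) < 1e-9
        xs = np.linspace(1, 3, 101).reshape(-1, 1)
        assert np.max(hd.sensitivity_g_profile(model, xi_d, mu, xs)) < 1e-9


class TestMeasureLoss:
    def test_nonnegative_and_small_at_optimum(self):
        spec, model, design, w = random_slope_setup()
        wmu = hd.random_slope_mu_weight(spec, w)
        mu = hd.design1d([0, 1], [1 - wmu, wmu])
        loss = hd.measure_loss(model, design, mu, "full")
        assert 0 <= loss < 1e-5

    def test_wrong_measure_scores_worse(self):
        spec, model, design, w = random_slope_setup()
        wmu = hd.random_slope_mu_weight(spec, w)
        good = hd.design1d([0, 1], [1 - wmu, wmu])
        bad = hd.design1d([0, 1], [0.9, 0.1])
        assert (hd.measure_loss(model, design, bad, "simple")
                > hd.measure_loss(model, design, good, "simple"))


class TestFindMu:
    def test_single_point_answering_set_is_point_mass(self):
        model = hd.HierarchicalLinearModel(
            basis=hd.RegressionBasis.polynomial(1), D=np.zeros((2, 2)),
            n=5, m=3, space=hd.DesignSpace([0], [1]))
        design = hd.design1d([0, 1], [0.7, 0.3])
        mu, _, _ = hd.find_mu(model, design)
        assert mu.k == 1 and mu.weights[0] == pytest.approx(1.0)

    def test_recovers_random_slope_measure_weight(self):
        spec, model, design, w = random_slope_setup()
        wmu = hd.random_slope_mu_weight(spec, w)
        mu, loss, ok = hd.find_mu(model, design, seed=11)
        mu = mu.sorted()
        assert ok
        assert mu.weights[-1] == pytest.approx(wmu, abs=1e-3)


class TestVerifyGOptimality:
    def test_fixed_effects_quadratic_d_optimum_passes(self, fixed_effects_quadratic_13):
        xi_d = hd.design1d([1, 2, 3], [1 / 3, 1 / 3, 1 / 3])
        report = hd.verify_g_optimality(fixed_effects_quadratic_13, xi_d, seed=1)
        assert report.passed
        assert report.phi_bar == pytest.approx(3.0, abs=1e-6)

    def test_certified_quadratic_optimum_passes(self, quad_model, certified_quad):
        report = hd.verify_g_optimality(quad_model, certified_quad, seed=1)
        assert report.passed
        assert np.all(np.abs(report.support_residuals) <= report.tol)

    def test_perturbed_weights_fail(self, quad_model, certified_quad):
        w = np.array(OPT_QUAD_W)
        w[0] += 0.05
        w[2] -= 0.05
        bad = hd.design1d(OPT_QUAD_PTS, w / w.sum())
        report = hd.verify_g_optimality(quad_model, bad, seed=1)
        assert not report.passed

    def test_report_serializes(self, tmp_path, quad_model, certified_quad):
        report = hd.verify_g_optimality(quad_model, certified_quad, seed=1)
        text = report.to_text()
        assert "PASS" in text and "answering set" in text
        csv_path = tmp_path / "sens.csv"
        report.sensitivity_csv(csv_path, quad_model, grid_per_axis=101)
        header = csv_path.read_text().splitlines()[0]
        assert header == "x1,phi,sensitivity"


class TestSensitivityDFixed:
    def test_quadratic_d_optimum_nonpositive(self, fixed_effects_quadratic_13):
        xi_d = hd.design1d([1, 2, 3], [1 / 3, 1 / 3, 1 / 3])
        xs = np.linspace(1, 3, 301)
        vals = [hd.sensitivity_d_fixed(fixed_effects_quadratic_13, xi_d, x) for x in xs]
        assert max(vals) < 1e-8
        for x in (1.0, 2.0, 3.0):
            assert hd.sensitivity_d_fixed(fixed_effects_quadratic_13, xi_d,
                                          x) == pytest.approx(0.0, abs=1e-10)

    def test_balanced_two_point_line(self):
        model = hd.HierarchicalLinearModel(
            basis=hd.RegressionBasis.polynomial(1), D=np.zeros((2, 2)),
            n=5, m=3, space=hd.DesignSpace([0], [1]))
        d = hd.design1d([0, 1], [0.5, 0.5])
        for x in (0.0, 1.0):
            assert hd.sensitivity_d_fixed(model, d, x) == pytest.approx(0.0, abs=1e-12)


class TestEfficiencyLowerBound:
    def test_at_optimum_equals_one(self):
        assert hd.d_efficiency_lower_bound(4, 4.0) == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        vals = [hd.d_efficiency_lower_bound(4, x) for x in (4.0, 4.5, 5.0, 8.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_below_p_rejected(self):
        with pytest.raises(ValueError):
            hd.d_efficiency_lower_bound(4, 3.0)
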