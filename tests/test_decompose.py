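import numpy as np
import pytest
import scipy.optimize

from sersmix import (
    ComponentLibrary,
    Spectrum,
    SpectrumSet,
    WavenumberAxis,
    bootstrap_median_ci,
    figures_of_merit,
    fit_cohort,
    fit_decomposition,
    objective_ssr,
    shift_component,
)


def _gauss_component(axis, center, width=4.0):
    y = np.exp(-0.5 * ((axis.values - center) / width) ** 2)
    return y / np.linalg.norm(y)


@pytest.fixture
def toy_library(small_axis):
    return ComponentLibrary(
        ("a", "b"),
        np.vstack(
            [_gauss_component(small_axis, 18.0), _gauss_component(small_axis, 40.0)]
        ),
        small_axis,
    )


class TestShiftComponent:
    def test_zero_shift_is_identity(self, toy_library, small_axis):
        out = shift_component(toy_library.matrix[0], small_axis, 0.0)
        np.testing.assert_array_equal(out, toy_library.matrix[0])

    def test_exact_on_straight_lines(self, small_axis):
        line = 3.0 + 0.5 * small_axis.values
        out = shift_component(line, small_axis, 0.08)
        np.testing.assert_allclose(out[1:], 3.0 + 0.5 * (small_axis.values[1:] - 0.08))

    def test_interior_interpolation_weights(self, small_axis):
        rng = np.random.default_rng(0)
        x = rng.random(len(small_axis))
        out = shift_component(x, small_axis, 0.1)
        expected = 0.9 * x[1:] + 0.1 * x[:-1]
        np.testing.assert_allclose(out[1:], expected, atol=1e-12)

    def test_bound_enforced(self, toy_library, small_axis):
        with pytest.raises(ValueError):
            shift_component(toy_library.matrix[0], small_axis, 0.2, bound=0.1)


class TestObjective:
    def test_zero_at_exact_combination(self, toy_library):
        target = 2.0 * toy_library.matrix[0] + 3.0 * toy_library.matrix[1]
        assert objective_ssr([2.0, 3.0], [0.0, 0.0], target, toy_library) == 0.0

    def test_zero_amplitudes_give_target_power(self, toy_library):
        rng = np.random.default_rng(1)
        target = rng.random(len(toy_library.axis))
        ssr = objective_ssr([0.0, 0.0], [0.0, 0.0], target, toy_library)
        assert ssr == pytest.approx(float(target @ target), rel=1e-12)

    def test_matches_naive_loop_evaluation(self, toy_library, small_axis):
        rng = np.random.default_rng(2)
        target = rng.random(len(small_axis))
        a = [1.3, 0.4]
        s = [0.05, -0.07]
        ssr = objective_ssr(a, s, target, toy_library)
        # independent re-implementation: explicit python loops
        total = 0.0
        for i, nu in enumerate(small_axis.values):
            model = 0.0
            for k in range(2):
                model += a[k] * np.interp(
                    nu - s[k], small_axis.values, toy_library.matrix[k]
                )
            total += (target[i] - model) ** 2
        assert ssr == pytest.approx(total, rel=1e-12)


class TestFitDecomposition:
    def test_exact_combination_recovered(self, toy_library, small_axis):
        target = 2.0 * toy_library.matrix[0] + 3.0 * toy_library.matrix[1]
        r = fit_decomposition(Spectrum(small_axis, target), toy_library, noise_scale=1.0)
        np.testing.assert_allclose(r.amplitudes, [2.0, 3.0], atol=1e-6)
        assert np.all(np.abs(r.shifts) <= 0.1)
        assert r.fom.r2 >= 0.999999

    def test_absent_component_pinned_at_zero(self, toy_library, small_axis):
        target = 1.5 * toy_library.matrix[1]
        r = fit_decomposition(Spectrum(small_axis, target), toy_library, noise_scale=1.0)
        assert r.amplitudes[0] == pytest.approx(0.0, abs=1e-8)

    def test_subpixel_shift_recovered(self, toy_library, small_axis):
        target = shift_component(toy_library.matrix[0], small_axis, 0.1, bound=None)
        r = fit_decomposition(Spectrum(small_axis, target), toy_library, noise_scale=1.0)
        assert r.shifts[0] == pytest.approx(0.1, abs=0.02)
        assert r.fom.r2 >= 0.9999

    def test_amplitudes_scale_linearly_with_target(self, toy_library, small_axis):
        rng = np.random.default_rng(3)
        target = (
            1.2 * toy_library.matrix[0]
            + 0.7 * toy_library.matrix[1]
            + rng.normal(0, 0.002, len(small_axis))
        )
        r1 = fit_decomposition(Spectrum(small_axis, target), toy_library, noise_scale=0.002)
        r5 = fit_decomposition(
            Spectrum(small_axis, 5.0 * target), toy_library, noise_scale=0.01
        )
        np.testing.assert_allclose(r5.amplitudes, 5.0 * r1.amplitudes, rtol=1e-4)
        np.testing.assert_allclose(r5.shifts, r1.shifts, atol=1e-3)
        assert r5.fom.r2 == pytest.approx(r1.fom.r2, abs=1e-9)

    def test_never_worse_than_nnls_start(self, toy_library, small_axis):
        rng = np.random.default_rng(4)
        target = rng.random(len(small_axis))
        r = fit_decomposition(Spectrum(small_axis, target), toy_library, noise_scale=1.0)
        a0, _ = scipy.optimize.nnls(toy_library.matrix.T, target)
        ssr_fit = objective_ssr(r.amplitudes, r.shifts, target, toy_library)
        ssr_init = objective_ssr(a0, [0.0, 0.0], target, toy_library)
        assert ssr_fit <= ssr_init + 1e-12

    def test_zero_shift_bound_reduces_to_nnls(self, toy_library, small_axis):
        rng = np.random.default_rng(5)
        target = rng.random(len(small_axis))
        r = fit_decomposition(
            Spectrum(small_axis, target), toy_library, shift_bound=0.0, noise_scale=1.0
        )
        a, _ = scipy.optimize.nnls(toy_library.matrix.T, target)
        np.testing.assert_allclose(r.amplitudes, a, atol=1e-8)
        np.testing.assert_array_equal(r.shifts, 0.0)

    def test_optimizer_matches_grid_search(self, toy_library, small_axis):
        # exhaustive search over the shift grid with exact NNLS amplitudes
        # bounds the attainable SSR; the bounded optimizer must reach it
        rng = np.random.default_rng(6)
        target = (
            2.0 * shift_component(toy_library.matrix[0], small_axis, 0.07, bound=None)
            + 3.0 * shift_component(toy_library.matrix[1], small_axis, -0.04, bound=None)
            + rng.normal(0, 0.01, len(small_axis))
        )
        r = fit_decomposition(Spectrum(small_axis, target), toy_library, noise_scale=0.01)
        ssr_fit = objective_ssr(r.amplitudes, r.shifts, target, toy_library)
        grid = np.linspace(-0.1, 0.1, 41)
        best = np.inf
        for s1 in grid:
            for s2 in grid:
                m = np.vstack(
                    [
                        shift_component(toy_library.matrix[0], small_axis, s1, bound=None),
                        shift_component(toy_library.matrix[1], small_axis, s2, bound=None),
                    ]
                )
                a, _ = scipy.optimize.nnls(m.T, target)
                best = min(best, float(np.sum((target - a @ m) ** 2)))
        grid_resolution_slack = 1e-4 * best
        assert ssr_fit <= best + grid_resolution_slack


class TestFiguresOfMerit:
    def test_perfect_fit(self):
        y = np.arange(10.0)
        fom = figures_of_merit(y, y, n_params=2, noise_scale=1.0)
        assert (fom.r2, fom.nrmse, fom.red_chi2) == (1.0, 0.0, 0.0)

    def test_constant_fit_gives_zero_r2(self):
        y = np.arange(10.0)
        fom = figures_of_merit(y, np.full(10, y.mean()), n_params=1, noise_scale=1.0)
        assert fom.r2 == pytest.approx(0.0, abs=1e-12)

    def test_reduced_chi2_calibrated_on_gaussian_residuals(self):
        rng = np.random.default_rng(7)
        sigma = 0.3
        fitted = np.sin(np.linspace(0, 10, 1000))
        observed = fitted + rng.normal(0, sigma, 1000)
        fom = figures_of_merit(observed, fitted, n_params=6, noise_scale=sigma)
        assert 0.85 <= fom.red_chi2 <= 1.15

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            figures_of_merit(np.ones(10), np.ones(10), n_params=2, noise_scale=1.0)


class TestBootstrap:
    def test_degenerate_cohort_gives_point_interval(self):
        lo, hi = bootstrap_median_ci(np.full(20, 0.7), rng=0)
        assert (lo, hi) == (0.7, 0.7)

    def test_seeded_reproducibility(self):
        vals = np.random.default_rng(8).normal(0.9, 0.05, 40)
        assert bootstrap_median_ci(vals, rng=123) == bootstrap_median_ci(vals, rng=123)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_median_ci(np.array([1.0]))


class TestFitCohort:
    def test_exact_cohort_has_unit_median_r2(self, toy_library, small_axis):
        rng = np.random.default_rng(9)
        spectra = []
        for i in range(5):
            a = rng.uniform(0.5, 2.0, 2)
            y = a @ toy_library.matrix
            spectra.append(Spectrum(small_axis, y, {"sample": f"s{i}"}))
        sset = SpectrumSet(spectra, small_axis)
        fit = fit_cohort(sset, toy_library, b=100, seed=0, noise_scale=1.0)
        assert fit.summary["R2"]["median"] == pytest.approx(1.0, abs=1e-9)
        assert set(fit.table.columns) >= {"id", "a_a", "a_b", "s_a", "s_b", "R2"}

    def test_empty_cohort_rejected(self, toy_library, small_axis):
        with pytest.raises(ValueError):
            fit_cohort(SpectrumSet([], small_axis), toy_library)
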