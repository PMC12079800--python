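"""Savitzky-Golay density pipeline: CDFs, regridding, padding, derivatives."""

import numpy as np
import pytest

import pathppa as pp
from pathppa.density import DegenerateSupportError, IntegratedDistributions


def sampleset(cv, weights, reactive):
    return pp.SampleSet(
        values=np.asarray(cv, float),
        weights=np.asarray(weights, float),
        reactive=np.asarray(reactive, bool),
    )


class TestWeightedCdfs:
    def test_hand_example(self):
        s = sampleset([1.0, 2.0, 3.0], [1, 2, 1], [True, False, True])
        cv, R, U = pp.weighted_cdfs(s)
        np.testing.assert_allclose(cv, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(R, [0.25, 0.25, 0.5])
        np.testing.assert_allclose(U, [0.0, 0.5, 0.5])

    def test_no_reactive_samples(self):
        s = sampleset([0.0, 1.0], [1, 1], [False, False])
        _, R, U = pp.weighted_cdfs(s)
        np.testing.assert_allclose(R, 0.0)
        assert U[-1] == pytest.approx(1.0)

    def test_duplicate_values_merge(self):
        s = sampleset([1.0, 1.0, 2.0], [1, 1, 2], [True, True, False])
        cv, R, U = pp.weighted_cdfs(s)
        assert cv.size == 2
        np.testing.assert_allclose(R, [0.5, 0.5])

    def test_degenerate_support_rejected(self):
        s = sampleset([1.0, 1.0], [1, 1], [True, False])
        with pytest.raises(DegenerateSupportError):
            pp.weighted_cdfs(s)


class TestRegridAndPad:
    def test_grid_spacing_default(self):
        cv = np.array([0.0, 1.0])
        d = pp.regrid(cv, np.array([0.0, 0.3]), np.array([0.0, 0.7]), 2000)
        assert d.grid.size == 2000
        assert d.grid[1] - d.grid[0] == pytest.approx(1.0 / 1999)

    def test_two_point_support(self):
        d = pp.regrid(np.array([0.0, 1.0]), np.array([0, 1.0]), np.array([0, 0.0]), 16)
        np.testing.assert_allclose(d.grid[[0, -1]], [0.0, 1.0])

    def test_interpolation_hits_step_values(self):
        rng = np.random.default_rng(3)
        cv = np.sort(rng.uniform(0, 1, 40))
        R = np.cumsum(rng.uniform(0, 1, 40))
        R /= R[-1] * 2
        U = R.copy()  # any nondecreasing curve works here
        d = pp.regrid(cv, R, U, 2000)
        back = np.interp(cv, d.grid, d.R)
        cell_slope = np.max(np.abs(np.diff(d.R)))
        np.testing.assert_allclose(back, R, atol=cell_slope + 1e-12)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            pp.regrid(np.array([0.0, 1.0]), np.zeros(2), np.zeros(2), 8)

    def test_pad_counts_default(self):
        d = pp.regrid(np.array([0.0, 1.0]), np.array([0, 0.3]), np.array([0, 0.7]), 2000)
        padded = pp.pad_plateaus(d, 0.25)
        assert padded.n_pad == 500
        assert padded.grid.size == 3000
        assert padded.R[0] == 0.0
        assert padded.R[-1] == pytest.approx(0.3)
        assert np.all(np.diff(padded.R) >= -1e-15)

    def test_zero_pad_identity(self):
        d = pp.regrid(np.array([0.0, 1.0]), np.array([0, 0.3]), np.array([0, 0.7]), 100)
        padded = pp.pad_plateaus(d, 0.0)
        np.testing.assert_array_equal(padded.grid, d.grid)


class TestSGWindow:
    @pytest.mark.parametrize(
        "n_gp, frac, expected",
        [(2000, 1 / 16, 125), (16, 1 / 16, 5), (10_000, 1 / 16, 625)],
    )
    def test_rules(self, n_gp, frac, expected):
        assert pp.sg_window(n_gp, frac) == expected


class TestSGDerivative:
    def _ramp(self, slope=0.3, n=2000):
        grid = np.linspace(0.0, 1.0, n)
        R = slope * grid
        U = (1 - slope) * grid
        return IntegratedDistributions(grid, R, U)

    def test_linear_reproduction(self):
        padded = pp.pad_plateaus(self._ramp(), 0.0)
        est = pp.sg_derivative(padded)
        interior = slice(100, -100)
        np.testing.assert_allclose(est.r[interior], 0.3, atol=1e-10)
        np.testing.assert_allclose(est.t[interior], 1.0, atol=1e-10)

    def test_quadratic_reproduction(self):
        grid = np.linspace(0.0, 1.0, 2000)
        d = IntegratedDistributions(grid, grid**2 * 0.5, grid * 0.0)
        est = pp.sg_derivative(pp.pad_plateaus(d, 0.0))
        interior = slice(100, -100)
        np.testing.assert_allclose(est.r[interior], grid[interior], atol=1e-10)

    def test_gaussian_mixture_sup_norm(self):
        spec = pp.MixtureSpec(
            components_r=((0.0, 1.0, 0.5),),
            components_u=((2.0, 1.0, 0.5),),
            n=50_000,
            seed=8,
        )
        s = pp.sample_mixture(spec)
        est = pp.estimate_densities(s)
        truth = spec.r_density(est.grid)
        peak = truth.max()
        assert np.max(np.abs(est.r - truth)) <= 0.05 * peak


class TestEstimateDensities:
    def test_uninformative_labels_give_r_proportional_t(self):
        spec = pp.MixtureSpec(
            components_r=((0.0, 1.0, 0.3),),
            components_u=((0.0, 1.0, 0.7),),
            n=20_000,
            seed=2,
        )
        est = pp.estimate_densities(pp.sample_mixture(spec))
        peak = est.r.max()
        assert np.max(np.abs(est.r - 0.3 * est.t)) <= 0.05 * peak / 0.3

    def test_all_reactive_gives_zero_u(self):
        rng = np.random.default_rng(0)
        s = sampleset(rng.normal(size=500), np.ones(500), np.ones(500, bool))
        est = pp.estimate_densities(s)
        np.testing.assert_allclose(est.u, 0.0, atol=1e-12)

    def test_disjoint_supports_have_negligible_product(self):
        rng = np.random.default_rng(1)
        cv = np.concatenate([rng.uniform(0, 1, 5000), rng.uniform(2, 3, 5000)])
        reactive = np.concatenate([np.ones(5000, bool), np.zeros(5000, bool)])
        est = pp.estimate_densities(sampleset(cv, np.ones(10_000), reactive))
        product = np.abs(est.r * est.u)
        assert product.max() <= 0.01 * est.r.max() * est.u.max() + 1e-9

    def test_mass_conservation(self, gaussian_sampleset):
        s, _ = gaussian_sampleset
        est = pp.estimate_densities(s)
        assert est.integrate(est.t) == pytest.approx(1.0, abs=1e-3)
        assert est.integrate(est.r) == pytest.approx(
            s.reactive_weight / s.total_weight, abs=1e-3
        )

    def test_affine_equivariance(self, gaussian_sampleset):
        """CV -> a*CV + b rescales the grid with the data; the overlap
        integral is invariant to floating-point level."""
        s, _ = gaussian_sampleset
        o1 = pp.overlap_integral(pp.estimate_densities(s))
        s2 = pp.SampleSet(
            values=2.5 * s.cv_array() - 7.0, weights=s.weights, reactive=s.reactive
        )
        o2 = pp.overlap_integral(pp.estimate_densities(s2))
        assert o1 == pytest.approx(o2, abs=1e-12)

    def test_convergence_with_n(self):
        errs = []
        for n in (2_000, 20_000):
            spec = pp.MixtureSpec(
                components_r=((0.0, 1.0, 0.5),),
                components_u=((2.0, 1.0, 0.5),),
                n=n,
                seed=13,
            )
            est = pp.estimate_densities(pp.sample_mixture(spec))
            truth = spec.r_density(est.grid)
            errs.append(np.max(np.abs(est.r - truth)) / truth.max())
        assert errs[1] < errs[0]

    def test_window_robustness(self, gaussian_sampleset):
        s, _ = gaussian_sampleset
        overlaps = [
            pp.overlap_integral(
                pp.estimate_densities(s, pp.SGSettings(window_fraction=f))
            )
            for f in (1 / 32, 1 / 16, 1 / 8)
        ]
        assert max(overlaps) - min(overlaps) < 0.02


class TestBinned:
    def test_hand_countable_masses(self):
        s = sampleset([0.0, 0.4, 0.6, 1.0], [1, 1, 1, 1], [True, True, False, False])
        est = pp.binned_densities(s, 2)
        # bin width 0.5, W=4: r counts [2, 0], u counts [0, 2]
        np.testing.assert_allclose(est.r, [2 / (4 * 0.5), 0.0])
        np.testing.assert_allclose(est.u, [0.0, 2 / (4 * 0.5)])
        assert est.integrate(est.t) == pytest.approx(1.0)

    def test_alternating_sparse_bins_zero_overlap(self):
        """One point per bin with alternating labels: r*u = 0 everywhere —
        the sparse-binning failure mode."""
        cv = np.arange(10, dtype=float)
        s = sampleset(cv, np.ones(10), (np.arange(10) % 2).astype(bool))
        est = pp.binned_densities(s, 10)
        np.testing.assert_allclose(est.r * est.u, 0.0)

    def test_total_mass_conserved(self, gaussian_sampleset):
        s, _ = gaussian_sampleset
        for n_bins in (10, 1000):
            est = pp.binned_densities(s, n_bins)
            assert est.integrate(est.t) == pytest.approx(1.0, rel=1e-9)

    def test_min_bins(self, gaussian_sampleset):
        s, _ = gaussian_sampleset
        with pytest.raises(ValueError):
            pp.binned_densities(s, 1)


class TestSettings:
    def test_high_polyorder_needs_override(self):
        with pytest.raises(ValueError, match="polyorder"):
            pp.SGSettings(polyorder=3)
        assert pp.SGSettings(polyorder=3, allow_higher_order=True).polyorder == 3
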