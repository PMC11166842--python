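"""Multivariate-normal parameter sampling, prediction bands, coverage."""

import numpy as np
import pytest

from cb1lag import (
    CovarianceSpec,
    co_addition_schedule,
    coverage_report,
    demo_covariance,
    observe_trace,
    prediction_band,
    sample_parameters,
    simulate_timecourse,
)
from cb1lag.simulate import CampTrace


@pytest.fixture(scope="module")
def spec(ref_params_module):
    return demo_covariance(ref_params_module)


@pytest.fixture(scope="module")
def ref_params_module():
    from cb1lag import reference_parameters

    return reference_parameters()


class TestCovarianceSpec:
    def test_demo_spec_loads_and_centres_on_reference(self, spec, ref_params_module):
        assert set(spec.labels) == {"k_int", "kon3", "koff3", "k_out", "kon_A"}
        i = spec.labels.index("kon3")
        assert np.exp(spec.mean[i]) == pytest.approx(ref_params_module.allosteric.kon3)

    def test_asymmetric_matrix_rejected(self):
        cov = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            CovarianceSpec(("a_unused", "b_unused"), np.zeros(2), cov)

    def test_negative_eigenvalue_rejected(self):
        cov = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="positive semi-definite"):
            CovarianceSpec(("k_int", "kon3"), np.zeros(2), cov)


class TestSampleParameters:
    def test_zero_covariance_returns_the_mean(self, spec, ref_params_module):
        frozen = CovarianceSpec(spec.labels, spec.mean, np.zeros_like(spec.cov), spec.scale_map)
        draws, rejected = sample_parameters(frozen, 5, seed=1, base=ref_params_module)
        assert rejected == 0
        for d in draws:
            assert d.allosteric.kon3 == pytest.approx(ref_params_module.allosteric.kon3)
            assert d.agonist.k_int == pytest.approx(ref_params_module.agonist.k_int)

    def test_moments_match_within_monte_carlo_error(self, spec, ref_params_module):
        """Empirical mean/covariance of 10k draws on the estimation scale
        match the spec within 3 Monte-Carlo standard errors per entry."""
        n = 10_000
        draws, _ = sample_parameters(spec, n, seed=2, base=ref_params_module)
        z = np.log(
            np.array(
                [[d.get(label) for label in spec.labels] for d in draws]
            )
        )
        emp_mean = z.mean(axis=0)
        emp_cov = np.cov(z.T)
        sd = np.sqrt(np.diag(spec.cov))
        assert np.all(np.abs(emp_mean - spec.mean) <= 3.0 * sd / np.sqrt(n))
        # diagonal entries: var of sample variance ~ 2 sigma^4 / n
        mc_se = np.sqrt(2.0 / n) * np.diag(spec.cov)
        assert np.all(np.abs(np.diag(emp_cov) - np.diag(spec.cov)) <= 3.0 * mc_se + 1e-12)

    def test_seeded_reproducibility(self, spec, ref_params_module):
        a, _ = sample_parameters(spec, 50, seed=7, base=ref_params_module)
        b, _ = sample_parameters(spec, 50, seed=7, base=ref_params_module)
        assert all(x == y for x, y in zip(a, b))


class TestPredictionBand:
    def test_single_draw_without_noise_collapses(self, ref_params_module):
        sch = co_addition_schedule(1.0, 0.1, horizon=10.0)
        band = prediction_band([ref_params_module], sch, residual_sigma=0.0, seed=0)
        assert np.allclose(band.lower, band.median)
        assert np.allclose(band.median, band.upper)

    def test_residual_only_band_width_matches_gaussian_quantiles(self, ref_params_module):
        """With frozen parameters the 95% band half-width is ~1.96 sigma."""
        sch = co_addition_schedule(1.0, 0.1, horizon=5.0)
        sigma = 0.05
        band = prediction_band(
            [ref_params_module] * 2000, sch, residual_sigma=sigma, seed=3, grid_step=1.0
        )
        half = 0.5 * (band.upper - band.lower)
        assert np.median(half) == pytest.approx(1.96 * sigma, rel=0.08)

    def test_band_nesting_across_levels(self, spec, ref_params_module):
        draws, _ = sample_parameters(spec, 150, seed=2, base=ref_params_module)
        sch = co_addition_schedule(1.0, 0.1, horizon=10.0)
        wide = prediction_band(draws, sch, level=0.95, residual_sigma=0.01, seed=5, grid_step=0.5)
        narrow = prediction_band(draws, sch, level=0.5, residual_sigma=0.01, seed=5, grid_step=0.5)
        assert np.all(wide.lower <= narrow.lower + 1e-12)
        assert np.all(narrow.upper <= wide.upper + 1e-12)

    def test_band_widens_with_residual_sigma(self, ref_params_module):
        sch = co_addition_schedule(1.0, 0.1, horizon=5.0)
        widths = []
        for sigma in (0.0, 0.01, 0.05):
            band = prediction_band(
                [ref_params_module] * 400, sch, residual_sigma=sigma, seed=4, grid_step=1.0
            )
            widths.append(np.mean(band.upper - band.lower))
        assert widths[0] < widths[1] < widths[2]


class TestCoverage:
    def test_median_observations_are_fully_covered(self, spec, ref_params_module):
        draws, _ = sample_parameters(spec, 100, seed=6, base=ref_params_module)
        sch = co_addition_schedule(1.0, 0.1, horizon=10.0)
        band = prediction_band(draws, sch, residual_sigma=0.01, seed=6, grid_step=0.5)
        obs = CampTrace(times=band.times, values=band.median, condition="median")
        report = coverage_report([obs], band)
        overall = report.loc[report["condition"] == "overall", "fraction_inside"].item()
        assert overall == 1.0

    def test_self_generated_observations_covered_at_nominal_rate(
        self, spec, ref_params_module
    ):
        """Observations simulated at the mean parameters plus residual noise
        fall inside the 95% band at roughly the nominal rate."""
        sigma = 0.01
        sch = co_addition_schedule(1.0, 0.1, horizon=20.0)
        draws, _ = sample_parameters(spec, 150, seed=11, base=ref_params_module)
        band = prediction_band(draws, sch, residual_sigma=sigma, seed=11, grid_step=0.5)
        clean = observe_trace(simulate_timecourse(ref_params_module, sch, grid_step=0.5))
        fractions = []
        for seed in range(1, 6):
            rng = np.random.default_rng(seed)
            obs = CampTrace(
                times=clean.times,
                values=clean.values + rng.normal(0, sigma, clean.values.shape),
                condition=f"seed{seed}",
            )
            rep = coverage_report([obs], band)
            fractions.append(
                rep.loc[rep["condition"] == "overall", "fraction_inside"].item()
            )
        assert 0.92 <= np.mean(fractions) <= 1.0

    def test_misspecified_observations_lose_coverage(self, spec, ref_params_module):
        """Observations generated with kon3 x10 fall materially outside."""
        sch = co_addition_schedule(1.0, 0.1, horizon=20.0)
        draws, _ = sample_parameters(spec, 150, seed=12, base=ref_params_module)
        band = prediction_band(draws, sch, residual_sigma=0.01, seed=12, grid_step=0.5)
        wrong = ref_params_module.with_overrides(
            kon3=ref_params_module.allosteric.kon3 * 10.0
        )
        obs = observe_trace(simulate_timecourse(wrong, sch, grid_step=0.5))
        rep = coverage_report([obs], band)
        overall = rep.loc[rep["condition"] == "overall", "fraction_inside"].item()
        assert overall < 0.9

    def test_empty_observations_error(self, spec, ref_params_module):
        draws, _ = sample_parameters(spec, 2, seed=1, base=ref_params_module)
        band = prediction_band(draws, co_addition_schedule(1.0, 0.1, horizon=5.0), seed=1)
        with pytest.raises(ValueError, match="no observations"):
            coverage_report([], band)
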