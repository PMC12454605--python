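"""Chi-square cost, Levenberg-Marquardt, recovery and validation metrics."""

import numpy as np
import pytest
from scipy import stats

from vesselgrow.growth_engine import DomainPartition, SimulationConfig
from vesselgrow.parameter_fitting import (
    FitConfig,
    ForwardModel,
    chi_square,
    delta_l,
    delta_r,
    fit_growth_constants,
    levenberg_marquardt,
    linear_projection_baseline,
    mean_delta_r,
    nested_f_test,
    validation_rings,
)


class TestChiSquare:
    def test_zero_at_perfect_prediction(self):
        x = np.array([1.0, 2.0, 3.0])
        assert chi_square(x, x, 0.1) == 0.0

    def test_hand_value(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.array([1.1, 2.0, 2.8])
        assert chi_square(pred, obs, 0.1) == pytest.approx(5.0)

    def test_inverse_square_sigma_scaling(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.array([1.1, 2.0, 2.8])
        assert chi_square(pred, obs, 0.05) == pytest.approx(
            4 * chi_square(pred, obs, 0.1))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            chi_square([1.0], [1.0, 2.0], 0.1)


class TestLevenbergMarquardt:
    def test_linear_model_exact_slope(self):
        x = np.linspace(0, 1, 20)
        y = 2.0 * x

        def resid(p):
            return y - p[0] * x

        fit = levenberg_marquardt(resid, np.array([1.0]))
        assert fit.params[0] == pytest.approx(2.0, abs=1e-8)
        assert fit.converged

    def test_start_at_optimum_stays(self):
        x = np.linspace(0, 1, 20)
        y = 2.0 * x

        def resid(p):
            return y - p[0] * x

        fit = levenberg_marquardt(resid, np.array([2.0]))
        assert fit.params[0] == pytest.approx(2.0, abs=1e-10)
        assert fit.iterations <= 2

    def test_rosenbrock_valley(self):
        def resid(p):
            return np.array([10.0 * (p[1] - p[0] ** 2), 1.0 - p[0]])

        fit = levenberg_marquardt(resid, np.array([-1.2, 1.0]),
                                  FitConfig(max_iter=200))
        assert np.allclose(fit.params, [1.0, 1.0], atol=1e-4)

    def test_nonfinite_initial_residual_rejected(self):
        with pytest.raises(ValueError):
            levenberg_marquardt(lambda p: np.array([np.nan]),
                                np.array([1.0]))


@pytest.fixture(scope="module")
def forward_models(tube_spec, conditions, baseline_metrics):
    sim = SimulationConfig(dt=10.0, horizon=60.0)
    common = dict(
        initial_metrics=baseline_metrics, wall=conditions.wall,
        mu_kpa=conditions.mu_kpa, pressure_pa=conditions.pressure_pa,
        flow_mean=conditions.flow_mean, sim_config=sim,
        target_fraction=conditions.target_fraction, T_r=conditions.T_r)
    single = ForwardModel(**common)
    multi = ForwardModel(partition=DomainPartition.equal_axial(6, 4),
                         **common)
    return single, multi


class TestGrowthConstantRecovery:
    def test_noiseless_single_domain_within_2pct(self, forward_models):
        single, _ = forward_models
        obs = single.predict([150.0, 300.0])
        fit = fit_growth_constants(single, obs)
        assert fit.T_theta == pytest.approx(150.0, rel=0.02)
        assert fit.T_s == pytest.approx(300.0, rel=0.02)

    def test_noisy_recovery_within_3_standard_errors(self, forward_models):
        """Monte-Carlo coverage of the LM covariance estimate."""
        single, _ = forward_models
        clean = single.predict([150.0, 300.0])
        sigma = 0.00125  # ring-average of 0.01 mm vertex noise
        cfg = FitConfig(sigma_meas=sigma)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            obs = clean + rng.normal(0, sigma, clean.shape)
            fit = fit_growth_constants(single, obs, cfg)
            se = fit.standard_errors
            ok = (abs(fit.T_theta - 150.0) <= 3 * se[0]
                  and abs(fit.T_s - 300.0) <= 3 * se[1])
            hits += ok
        assert hits >= 18

    def test_chi2_at_fit_not_above_truth(self, forward_models):
        single, _ = forward_models
        clean = single.predict([150.0, 300.0])
        rng = np.random.default_rng(11)
        sigma = 0.002
        obs = clean + rng.normal(0, sigma, clean.shape)
        cfg = FitConfig(sigma_meas=sigma)
        fit = fit_growth_constants(single, obs, cfg)
        chi2_truth = chi_square(clean, obs, sigma)
        assert fit.chi2 <= chi2_truth + 1e-9

    def test_multi_domain_fit_never_increases_sse(self, forward_models):
        single, multi = forward_models
        truth = np.r_[[120.0, 180.0, 260.0, 380.0],
                      [200.0, 300.0, 150.0, 400.0]]
        clean = multi.predict(truth)
        rng = np.random.default_rng(21)
        obs = clean + rng.normal(0, 0.00125, clean.shape)
        cfg = FitConfig(sigma_meas=0.00125)
        f1 = fit_growth_constants(single, obs, cfg)
        f4 = fit_growth_constants(multi, obs, cfg)
        assert f4.sse <= f1.sse + 1e-12
        assert f4.n_domains == 4 and len(f4.params) == 8


class TestValidationMetrics:
    def test_delta_r_zero_on_identical(self):
        r = np.array([1.0, 1.1, 1.2])
        assert np.all(delta_r(r, r) == 0.0)

    def test_delta_r_uniform_ten_percent(self):
        m = np.array([1.0, 2.0, 3.0])
        assert np.allclose(delta_r(1.1 * m, m), 0.1)

    def test_delta_r_signs_match_definition(self, rng):
        m = rng.uniform(0.5, 1.5, 6)
        p = m * rng.uniform(0.8, 1.2, 6)
        d = delta_r(p, m)
        assert np.allclose(d, (p - m) / m)
        assert np.all((d > 0) == (p > m))

    def test_mean_delta_r_uses_interior_rings_only(self):
        m = np.ones(6)
        p = np.array([2.0, 1.1, 1.1, 1.1, 1.1, 2.0])
        assert mean_delta_r(p, m) == pytest.approx(0.1)
        assert len(validation_rings(6)) == 4

    def test_delta_l_hand_values(self):
        assert delta_l(5.5, 5.0) == pytest.approx(0.10)
        assert delta_l(5.0, 5.5) == pytest.approx(-0.090909, abs=1e-6)
        assert delta_l(4.2, 4.2) == 0.0

    def test_nonpositive_measurement_rejected(self):
        with pytest.raises(ValueError):
            delta_r([1.0], [0.0])


class TestLinearProjectionBaseline:
    def test_equal_spacing_extrapolation(self):
        assert linear_projection_baseline(1.0, 1.2) == pytest.approx(1.4)

    def test_constant_radii_project_flat(self):
        assert linear_projection_baseline(0.6, 0.6) == 0.6

    def test_underpredicts_exponential_growth(self):
        k = 0.2
        r0, r1, r2 = np.exp([0.0, k, 2 * k])
        assert linear_projection_baseline(r0, r1) < r2


class TestNestedFTest:
    def test_equal_sse_gives_null(self):
        F, p = nested_f_test(5.0, 2, 5.0, 8, 11)
        assert F == 0.0 and p == 1.0

    def test_hand_value(self):
        F, p = nested_f_test(10.0, 2, 5.0, 8, 11)
        assert F == pytest.approx(0.5)
        assert p == pytest.approx(float(stats.f.sf(0.5, 6, 3)))

    def test_invalid_dof_rejected(self):
        with pytest.raises(ValueError):
            nested_f_test(10.0, 8, 5.0, 2, 11)
        with pytest.raises(ValueError):
            nested_f_test(10.0, 2, 5.0, 8, 8)

    def test_detects_heterogeneous_domains(self, forward_models):
        """4-domain truth: the 8-parameter model wins the F-test."""
        single, multi = forward_models
        truth = np.r_[[120.0, 180.0, 260.0, 380.0],
                      [200.0, 300.0, 150.0, 400.0]]
        clean = multi.predict(truth)
        rng = np.random.default_rng(33)
        obs = clean + rng.normal(0, 0.00125, clean.shape)
        cfg = FitConfig(sigma_meas=0.00125)
        f1 = fit_growth_constants(single, obs, cfg)
        f4 = fit_growth_constants(multi, obs, cfg)
        _, p = nested_f_test(f1.sse, 2, f4.sse, 8, len(obs))
        assert p < 0.05
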