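"""Growth law, growth tensor and forward geometry evolution."""

import numpy as np
import pytest

from vesselgrow.growth_engine import (
    BoundaryMotion,
    DomainPartition,
    GrowthParams,
    GrowthState,
    SimulationConfig,
    assemble_growth_tensor,
    forward_simulate,
    growth_rates,
    homeostatic_targets,
    step_growth,
    update_geometry,
)
from vesselgrow.hemodynamic_stress import StressField, thin_wall_stresses
from vesselgrow.mesh_geometry import WallSpec
from vesselgrow.synthetic_cohort import initial_ring_metrics


def _stress(sigma_t=100.0, sigma_s=50.0, tau=2.0, n=3):
    return StressField(sigma_theta=np.full(n, sigma_t),
                       sigma_ss=np.full(n, sigma_s),
                       tau_w=np.full(n, tau))


def _params(**kw):
    defaults = dict(T_theta=100.0, T_s=200.0, T_r=500.0,
                    sigma_theta_hat=100.0, sigma_ss_hat=50.0, tau_w_hat=2.0)
    defaults.update(kw)
    return GrowthParams(**defaults)


class TestGrowthRates:
    def test_homeostasis_is_exact_fixed_point(self):
        state = GrowthState.initial(3)
        rates = growth_rates(state, _stress(), _params())
        for r in rates:
            assert np.all(r == 0.0)

    def test_hand_value_circumferential(self):
        """20 % stress excess, T_theta=100 d -> 0.002/day at lambda=1."""
        state = GrowthState.initial(3)
        rates = growth_rates(state, _stress(sigma_t=120.0), _params())
        assert np.allclose(rates[1], 0.002)

    def test_rates_scale_with_lambda(self):
        state = GrowthState.initial(3)
        doubled = GrowthState(*(2 * np.ones(3) for _ in range(3)))
        r1 = growth_rates(state, _stress(sigma_t=120.0, sigma_s=60.0),
                          _params())
        r2 = growth_rates(doubled, _stress(sigma_t=120.0, sigma_s=60.0),
                          _params())
        for a, b in zip(r1, r2):
            assert np.allclose(b, 2 * a)

    def test_wall_shear_term_engages_when_finite(self):
        state = GrowthState.initial(3)
        p = _params(T_tau=50.0)
        rates = growth_rates(state, _stress(tau=3.0), p)
        assert np.allclose(rates[1], (3.0 / 2.0 - 1.0) / 50.0)

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            _params(sigma_theta_hat=0.0)


class TestGrowthTensor:
    def test_identity_at_start(self):
        G = assemble_growth_tensor(GrowthState.initial(2))
        assert np.allclose(G, np.eye(3))

    def test_determinant_is_product(self):
        state = GrowthState(np.array([1.1]), np.array([1.2]),
                            np.array([1.3]))
        G = assemble_growth_tensor(state)
        assert np.linalg.det(G[0]) == pytest.approx(1.716, rel=1e-12)

    def test_total_deformation_equals_G_for_identity_elastic(self):
        state = GrowthState(np.array([1.1]), np.array([1.2]),
                            np.array([1.3]))
        G = assemble_growth_tensor(state)[0]
        F = np.eye(3) @ G
        assert np.allclose(F, G)


class TestStepGrowth:
    def test_zero_rates_leave_state_unchanged(self):
        state = GrowthState.initial(3)
        new = step_growth(state, _stress(), _params(), dt=10.0)
        assert np.allclose(new.lambda_gtheta, 1.0)

    def test_single_euler_step_hand_value(self):
        state = GrowthState.initial(1)
        new = step_growth(state, _stress(sigma_t=120.0, n=1),
                          _params(), dt=10.0)
        assert new.lambda_gtheta[0] == pytest.approx(1.02)

    def test_matches_closed_form_with_fine_substeps(self):
        """Constant stress ratio: lambda(t) = exp((rho-1) t / T)."""
        state = GrowthState.initial(1)
        stress = _stress(sigma_t=120.0, n=1)
        for _ in range(12):  # 120 days at dt=10, 1-day substeps
            state = step_growth(state, stress, _params(), 10.0, substeps=10)
        exact = np.exp(0.2 * 120.0 / 100.0)
        assert abs(state.lambda_gtheta[0] / exact - 1) < 1e-3

    def test_first_order_convergence(self):
        errs = []
        for sub in (1, 2, 4):
            state = GrowthState.initial(1)
            stress = _stress(sigma_t=150.0, n=1)
            for _ in range(6):
                state = step_growth(state, stress, _params(), 10.0,
                                    substeps=sub)
            exact = np.exp(0.5 * 60.0 / 100.0)
            errs.append(abs(state.lambda_gtheta[0] - exact))
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.2)
        assert errs[1] / errs[2] == pytest.approx(2.0, rel=0.2)


class TestUpdateGeometry:
    def test_identity_increment_no_change(self):
        radii, seg, wall = update_geometry(
            np.array([0.5, 0.5]), np.array([1.0]), WallSpec(0.06),
            np.ones(2), np.ones(2), np.ones(2))
        assert np.allclose(radii, 0.5) and seg[0] == 1.0
        assert wall.thickness == 0.06

    def test_uniform_circumferential_scaling(self):
        radii, _, _ = update_geometry(
            np.array([0.5, 0.6]), np.array([1.0]), WallSpec(0.06),
            np.ones(2), np.full(2, 1.1), np.ones(2))
        assert np.allclose(radii, [0.55, 0.66])

    def test_nonuniform_axial_uses_pair_means(self):
        _, seg, _ = update_geometry(
            np.array([0.5, 0.5, 0.5]), np.array([1.0, 2.0]), WallSpec(0.06),
            np.ones(3), np.ones(3), np.array([1.0, 1.2, 1.4]))
        assert np.allclose(seg, [1.1, 2 * 1.3])


class TestForwardSimulate:
    def test_homeostatic_start_is_stationary(self, tube_spec, conditions,
                                             baseline_metrics):
        stress0 = thin_wall_stresses(
            baseline_metrics.radii, conditions.wall_thickness,
            conditions.pressure_pa, conditions.flow_mean)
        params = GrowthParams(T_theta=100.0, T_s=200.0,
                              **homeostatic_targets(stress0, 1.0))
        traj = forward_simulate(
            baseline_metrics, conditions.wall, conditions.mu_kpa,
            conditions.pressure_pa, conditions.flow_mean, params,
            SimulationConfig(dt=10.0, horizon=120.0))
        for m in traj.metrics:
            assert np.allclose(m.radii, traj.metrics[0].radii, rtol=1e-9)
            assert np.allclose(m.total_length,
                               traj.metrics[0].total_length, rtol=1e-9)

    def test_frozen_stress_matches_exponential(self, conditions,
                                               baseline_metrics):
        """10 % stress excess, T_theta=200 d, 60 d -> ~3.05 % growth."""
        stress0 = thin_wall_stresses(
            baseline_metrics.radii, conditions.wall_thickness,
            conditions.pressure_pa, conditions.flow_mean)
        targets = homeostatic_targets(stress0, 1.0 / 1.1)
        params = GrowthParams(T_theta=200.0, T_s=200.0, T_r=1e9, **targets)
        traj = forward_simulate(
            baseline_metrics, conditions.wall, conditions.mu_kpa,
            conditions.pressure_pa, conditions.flow_mean, params,
            SimulationConfig(dt=10.0, horizon=60.0, substeps=100),
            freeze_stress=True)
        growth = traj.states[-1].lambda_gtheta.mean() - 1.0
        assert growth == pytest.approx(np.exp(0.03) - 1, rel=1e-3)

    def test_smaller_T_theta_grows_strictly_more(self, conditions,
                                                 baseline_metrics):
        finals = []
        for tt in (100.0, 150.0, 250.0, 400.0):
            stress0 = thin_wall_stresses(
                baseline_metrics.radii, conditions.wall_thickness,
                conditions.pressure_pa, conditions.flow_mean)
            params = GrowthParams(T_theta=tt, T_s=200.0,
                                  **homeostatic_targets(stress0, 0.9))
            traj = forward_simulate(
                baseline_metrics, conditions.wall, conditions.mu_kpa,
                conditions.pressure_pa, conditions.flow_mean, params,
                SimulationConfig(dt=10.0, horizon=60.0))
            finals.append(traj.final_metrics.radii.mean())
        assert np.all(np.diff(finals) < 0)

    def test_positive_feedback_accelerates_growth(self, conditions,
                                                  baseline_metrics):
        stress0 = thin_wall_stresses(
            baseline_metrics.radii, conditions.wall_thickness,
            conditions.pressure_pa, conditions.flow_mean)
        params = GrowthParams(T_theta=150.0, T_s=200.0,
                              **homeostatic_targets(stress0, 0.9))
        traj = forward_simulate(
            baseline_metrics, conditions.wall, conditions.mu_kpa,
            conditions.pressure_pa, conditions.flow_mean, params,
            SimulationConfig(dt=10.0, horizon=120.0))
        lam = np.array([s.lambda_gtheta.mean() for s in traj.states])
        increments = np.diff(lam)
        assert np.all(np.diff(increments) > 0)

    def test_det_G_positive_and_tracks_volume(self, conditions,
                                              baseline_metrics):
        stress0 = thin_wall_stresses(
            baseline_metrics.radii, conditions.wall_thickness,
            conditions.pressure_pa, conditions.flow_mean)
        params = GrowthParams(T_theta=150.0, T_s=250.0,
                              **homeostatic_targets(stress0, 0.9))
        traj = forward_simulate(
            baseline_metrics, conditions.wall, conditions.mu_kpa,
            conditions.pressure_pa, conditions.flow_mean, params,
            SimulationConfig(dt=10.0, horizon=60.0))
        st = traj.states[-1]
        G = assemble_growth_tensor(st)
        dets = np.linalg.det(G)
        assert np.all(dets > 0)
        assert np.allclose(
            dets, st.lambda_gr * st.lambda_gtheta * st.lambda_gs)

    def test_boundary_motion_translates_end_rings(self, conditions,
                                                  baseline_metrics):
        stress0 = thin_wall_stresses(
            baseline_metrics.radii, conditions.wall_thickness,
            conditions.pressure_pa, conditions.flow_mean)
        params = GrowthParams(T_theta=150.0, T_s=200.0,
                              **homeostatic_targets(stress0, 1.0))
        bm = BoundaryMotion(inlet_total=np.array([0.0, 0.0, -0.2]),
                            outlet_total=np.array([0.0, 0.0, 0.2]),
                            total_time=120.0)
        traj = forward_simulate(
            baseline_metrics, conditions.wall, conditions.mu_kpa,
            conditions.pressure_pa, conditions.flow_mean, params,
            SimulationConfig(dt=10.0, horizon=120.0), boundary_motion=bm)
        start = baseline_metrics.centroids
        end = traj.final_metrics.centroids
        assert np.allclose(end[0] - start[0], [0, 0, -0.2])
        assert np.allclose(end[-1] - start[-1], [0, 0, 0.2])


class TestDomainPartition:
    def test_six_rings_four_domains(self):
        part = DomainPartition.equal_axial(6, 4)
        assert part.ring_domain.tolist() == [0, 0, 1, 2, 3, 3]

    def test_expand_maps_domain_values_to_rings(self):
        part = DomainPartition.equal_axial(6, 4)
        vals = part.expand([10.0, 20.0, 30.0, 40.0])
        assert vals.tolist() == [10.0, 10.0, 20.0, 30.0, 40.0, 40.0]

    def test_every_ring_assigned_and_contiguous(self):
        part = DomainPartition.equal_axial(9, 4)
        assert len(part.ring_domain) == 9
        assert np.all(np.diff(part.ring_domain) >= 0)
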