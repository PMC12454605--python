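"""Inverse fitting of growth time constants and validation metrics.

The tuning stage matches the forward growth model to the observed geometry
at the first follow-up: the observation vector holds the n ring radii
followed by the n-1 segment lengths (2n-1 entries), and the chi-square
cost sum(((obs - pred)/sigma)^2) is minimized over (T_theta, T_s) — or the
per-domain (T_theta^k, T_s^k) — with a Levenberg-Marquardt damped
least-squares iteration.  Time constants are optimized in log space so
positivity is structural.

Validation compares the 120-day forward prediction with the second
follow-up through relative differences: Delta_r per ring (mean over the
interior rings 2..5 of a 6-ring set; the inlet and outlet rings are
excluded to avoid boundary bias) and Delta_l on the full inlet-to-outlet
length.  A linear projection of the first two time points provides the
baseline the growth model must beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .growth_engine import (
    DomainPartition,
    GrowthParams,
    SimulationConfig,
    forward_simulate,
    homeostatic_targets,
)
from .hemodynamic_stress import ViscosityModel, thin_wall_stresses, \
    invert_inflation, membrane_inflation
from .mesh_geometry import RingMetrics, WallSpec


@dataclass
class FitConfig:
    """Levenberg-Marquardt settings for the tuning stage."""

    sigma_meas: float = 0.02          # mm, measurement scale in the cost
    initial_T_theta: float = 200.0    # days
    initial_T_s: float = 200.0        # days
    lm_lambda0: float = 1e-3
    lm_up: float = 10.0
    lm_down: float = 10.0
    tol_chi2: float = 1e-10
    tol_params: float = 1e-8
    max_iter: int = 100
    fd_step: float = 1e-6

    def __post_init__(self):
        if self.sigma_meas <= 0:
            raise ValueError("sigma_meas must be positive")


@dataclass
class FitResult:
    params: np.ndarray                 # fitted time constants, days
    chi2: float
    sse: float
    iterations: int
    converged: bool
    covariance: np.ndarray | None = None
    n_domains: int = 1

    @property
    def T_theta(self):
        k = len(self.params) // 2
        return self.params[0] if k == 1 else self.params[:k]

    @property
    def T_s(self):
        k = len(self.params) // 2
        return self.params[1] if k == 1 else self.params[k:]

    @property
    def standard_errors(self):
        if self.covariance is None:
            return None
        return np.sqrt(np.diag(self.covariance))


def chi_square(predicted, observed, sigma_meas: float) -> float:
    """Chi-square cost: sum(((obs - pred)/sigma)^2)."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("observation vectors must have equal length")
    return float(np.sum(((o - p) / sigma_meas) ** 2))


def levenberg_marquardt(residual_fn, initial_params,
                        config: FitConfig | None = None) -> FitResult:
    """Damped least squares with forward-difference Jacobian.

    Damping increases on a rejected step and decreases on an accepted one
    (Marquardt diagonal scaling).  Stops when the relative chi-square
    change or the parameter step falls below tolerance.
    """
    cfg = config or FitConfig()
    x = np.asarray(initial_params, dtype=float).copy()
    r = np.asarray(residual_fn(x), dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("residuals not finite at the initial point")
    chi2 = float(r @ r)
    lam = cfg.lm_lambda0
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        J = _fd_jacobian(residual_fn, x, r, cfg.fd_step)
        JtJ = J.T @ J
        g = J.T @ r
        accepted = False
        for _ in range(30):
            A = JtJ + lam * np.diag(np.maximum(np.diag(JtJ), 1e-12))
            try:
                step = np.linalg.solve(A, -g)
            except np.linalg.LinAlgError:
                lam *= cfg.lm_up
                continue
            x_new = x + step
            try:
                r_new = np.asarray(residual_fn(x_new), dtype=float)
            except Exception:
                lam *= cfg.lm_up
                continue
            if not np.all(np.isfinite(r_new)):
                lam *= cfg.lm_up
                continue
            chi2_new = float(r_new @ r_new)
            if chi2_new <= chi2:
                accepted = True
                break
            lam *= cfg.lm_up
        if not accepted:
            converged = True  # damping exhausted: local minimum at x
            break
        rel_dchi = (chi2 - chi2_new) / max(chi2, 1e-300)
        rel_dx = np.max(np.abs(step) / np.maximum(np.abs(x), 1e-12))
        x, r, chi2 = x_new, r_new, chi2_new
        lam = max(lam / cfg.lm_down, 1e-14)
        if rel_dchi < cfg.tol_chi2 or rel_dx < cfg.tol_params:
            converged = True
            break
    J = _fd_jacobian(residual_fn, x, r, cfg.fd_step)
    cov = None
    dof = len(r) - len(x)
    try:
        JtJ_inv = np.linalg.inv(J.T @ J)
        s2 = chi2 / dof if dof > 0 else np.nan
        cov = JtJ_inv * s2
    except np.linalg.LinAlgError:
        pass
    return FitResult(params=x, chi2=chi2, sse=chi2, iterations=it,
                     converged=converged, covariance=cov)


def _fd_jacobian(fn, x, r0, rel_step):
    J = np.empty((len(r0), len(x)))
    for j in range(len(x)):
        h = rel_step * max(abs(x[j]), 1.0)
        xp = x.copy()
        xp[j] += h
        J[:, j] = (np.asarray(fn(xp)) - r0) / h
    return J


@dataclass
class ForwardModel:
    """Maps growth time constants to the predicted observation vector.

    Wraps the ring-level growth engine with fixed material, loading and
    homeostatic-target settings so the optimizer sees a clean function of
    the fitted parameters.
    """

    initial_metrics: RingMetrics
    wall: WallSpec
    mu_kpa: float
    pressure_pa: float
    flow_mean: float
    sim_config: SimulationConfig
    target_fraction: float = 0.9
    T_r: float = 500.0
    partition: DomainPartition | None = None
    viscosity: ViscosityModel = field(default_factory=ViscosityModel)

    def __post_init__(self):
        R_u = [invert_inflation(r, self.wall.thickness, self.mu_kpa,
                                self.pressure_pa)
               for r in self.initial_metrics.radii]
        r0 = [membrane_inflation(R, self.wall.thickness, self.mu_kpa,
                                 self.pressure_pa)[1] for R in R_u]
        stress0 = thin_wall_stresses(np.asarray(r0), self.wall.thickness,
                                     self.pressure_pa, self.flow_mean,
                                     self.viscosity)
        self._targets = homeostatic_targets(stress0, self.target_fraction)

    @property
    def n_params(self) -> int:
        k = self.partition.n_domains if self.partition is not None else 1
        return 2 * k

    def make_params(self, theta_vec) -> GrowthParams:
        k = self.n_params // 2
        if self.partition is not None and k > 1:
            T_theta = self.partition.expand(theta_vec[:k])
            T_s = self.partition.expand(theta_vec[k:])
        else:
            T_theta, T_s = float(theta_vec[0]), float(theta_vec[1])
        return GrowthParams(T_theta=T_theta, T_s=T_s, T_r=self.T_r,
                            **self._targets)

    def predict(self, time_constants) -> np.ndarray:
        params = self.make_params(np.asarray(time_constants, dtype=float))
        traj = forward_simulate(self.initial_metrics, self.wall, self.mu_kpa,
                                self.pressure_pa, self.flow_mean, params,
                                self.sim_config, viscosity=self.viscosity)
        return traj.final_metrics.observation_vector()


def fit_growth_constants(model: ForwardModel, observed: np.ndarray,
                         config: FitConfig | None = None) -> FitResult:
    """Fit (T_theta, T_s) — or their per-domain variants — to an observation.

    Optimization runs in log space; the returned covariance is transformed
    back to the time-constant scale via the delta method.
    """
    cfg = config or FitConfig()
    observed = np.asarray(observed, dtype=float)
    k = model.n_params // 2
    x0 = np.log(np.r_[np.full(k, cfg.initial_T_theta),
                      np.full(k, cfg.initial_T_s)])

    def residuals(logx):
        pred = model.predict(np.exp(logx))
        return (observed - pred) / cfg.sigma_meas

    res = levenberg_marquardt(residuals, x0, cfg)
    T = np.exp(res.params)
    cov = None
    if res.covariance is not None:
        # delta method: d T / d log T = T
        cov = res.covariance * np.outer(T, T)
    return FitResult(params=T, chi2=res.chi2,
                     sse=res.chi2 * cfg.sigma_meas ** 2,
                     iterations=res.iterations, converged=res.converged,
                     covariance=cov, n_domains=k)


# ---------------------------------------------------------------------------
# Validation metrics

def delta_r(predicted_radii, measured_radii) -> np.ndarray:
    """Relative radius difference (r_pred - r_meas)/r_meas per ring."""
    p = np.asarray(predicted_radii, dtype=float)
    m = np.asarray(measured_radii, dtype=float)
    if p.shape != m.shape:
        raise ValueError("ring counts differ")
    if np.any(m <= 0):
        raise ValueError("measured radii must be positive")
    return (p - m) / m


def mean_delta_r(predicted_radii, measured_radii,
                 exclude_ends: bool = True) -> float:
    """Mean relative radius error over the interior rings (2..n-1).

    The inlet and outlet rings are excluded to avoid boundary-condition
    bias; for the default 6-ring set this is rings 2-5.
    """
    d = delta_r(predicted_radii, measured_radii)
    return float(d[1:-1].mean()) if exclude_ends else float(d.mean())


def validation_rings(n_rings: int = 6) -> np.ndarray:
    """Indices of the rings entering the radial validation (interior only)."""
    return np.arange(1, n_rings - 1)


def delta_l(predicted_length: float, measured_length: float) -> float:
    """Relative total-length difference (l_pred - l_meas)/l_meas."""
    if predicted_length <= 0 or measured_length <= 0:
        raise ValueError("lengths must be positive")
    return (predicted_length - measured_length) / measured_length


def linear_projection_baseline(r_t0, r_t1):
    """Linear extrapolation to the third equally spaced time point."""
    r0 = np.asarray(r_t0, dtype=float)
    r1 = np.asarray(r_t1, dtype=float)
    return r1 + (r1 - r0)


@dataclass
class ValidationMetrics:
    delta_r_per_ring: np.ndarray
    mean_delta_r: float
    delta_l: float


def validate_prediction(predicted: RingMetrics,
                        measured: RingMetrics) -> ValidationMetrics:
    d = delta_r(predicted.radii, measured.radii)
    return ValidationMetrics(
        delta_r_per_ring=d,
        mean_delta_r=float(d[1:-1].mean()),
        delta_l=delta_l(predicted.total_length, measured.total_length),
    )


def nested_f_test(sse_reduced: float, p_reduced: int, sse_full: float,
                  p_full: int, n_obs: int):
    """F-test for nested least-squares models on their SSE difference.

    F = ((SSE_r - SSE_f)/(p_f - p_r)) / (SSE_f/(n - p_f)); a full model
    that fails to reduce the SSE clips F at zero (p = 1).
    """
    if p_full <= p_reduced:
        raise ValueError("full model must have more parameters")
    if n_obs <= p_full:
        raise ValueError("need more observations than full-model parameters")
    num = max(sse_reduced - sse_full, 0.0) / (p_full - p_reduced)
    den = sse_full / (n_obs - p_full)
    if den <= 0:
        return np.inf, 0.0
    F = num / den
    p = float(stats.f.sf(F, p_full - p_reduced, n_obs - p_full))
    return float(F), p
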