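"""Workflow orchestration: tune on t0->t1, validate at t2, correlate.

The tuning stage measures both meshes with the harmonic ring machinery,
fits (T_theta, T_s) over a 60-day simulated horizon, and reports predicted
vs observed ring observables.  The validation stage re-runs the forward
model for 120 days with the fitted constants and scores the prediction
against the second follow-up with the relative-difference metrics and the
linear-projection baseline.  The correlation stage assembles the cohort
variable map and Tobit fits of lifespan.  Every run writes a manifest
(config snapshot, seed, versions, timings) sufficient to re-execute it.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .coordinate_mapping import parameterize
from .growth_engine import DomainPartition, SimulationConfig
from .mesh_geometry import (
    RingMetrics,
    SurfaceMesh,
    extract_rings,
    read_mesh,
    ring_metrics,
)
from .outcome_statistics import (
    CorrelationMap,
    TobitResult,
    mz_pseudo_r2,
    pearson_map,
    tobit_fit,
)
from .parameter_fitting import (
    FitConfig,
    FitResult,
    ForwardModel,
    ValidationMetrics,
    fit_growth_constants,
    linear_projection_baseline,
    validate_prediction,
)
from .synthetic_cohort import StudyConditions

DAYS_PER_MONTH = 30.0  # 2->4 months == 60 simulated days


def measure_mesh(mesh: SurfaceMesh | str | Path, n_rings: int = 6):
    """Harmonic parameterization + ring metrics of a surface mesh."""
    if not isinstance(mesh, SurfaceMesh):
        mesh = read_mesh(mesh)
    coords = parameterize(mesh)
    rings = extract_rings(mesh, coords.s, n_rings=n_rings)
    return coords, ring_metrics(rings)


@dataclass
class RunManifest:
    stage: str
    seed: int | None
    config: dict
    version: str = __version__
    timings_s: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    def write(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


@dataclass
class TuningReport:
    fit: FitResult
    observed: np.ndarray
    predicted: np.ndarray
    metrics_t0: RingMetrics
    metrics_t1: RingMetrics

    def to_dict(self) -> dict:
        return {
            "T_theta": np.asarray(self.fit.T_theta).tolist(),
            "T_s": np.asarray(self.fit.T_s).tolist(),
            "chi2": self.fit.chi2,
            "sse": self.fit.sse,
            "iterations": self.fit.iterations,
            "converged": self.fit.converged,
            "n_domains": self.fit.n_domains,
            "observed": self.observed.tolist(),
            "predicted": self.predicted.tolist(),
        }


def run_tuning(t0_mesh, t1_mesh, conditions: StudyConditions | None = None,
               n_rings: int = 6, fit_config: FitConfig | None = None,
               n_domains: int = 1, dt: float = 10.0,
               substeps: int = 1) -> TuningReport:
    """Fit the growth constants to the 60-day (first follow-up) geometry."""
    conditions = conditions or StudyConditions()
    fit_config = fit_config or FitConfig()
    _, m0 = measure_mesh(t0_mesh, n_rings)
    _, m1 = measure_mesh(t1_mesh, n_rings)
    partition = None
    if n_domains > 1:
        partition = DomainPartition.equal_axial(n_rings, n_domains)
    model = ForwardModel(
        initial_metrics=m0, wall=conditions.wall, mu_kpa=conditions.mu_kpa,
        pressure_pa=conditions.pressure_pa, flow_mean=conditions.flow_mean,
        sim_config=SimulationConfig(dt=dt, horizon=60.0, substeps=substeps),
        target_fraction=conditions.target_fraction, T_r=conditions.T_r,
        partition=partition, viscosity=conditions.viscosity,
    )
    observed = m1.observation_vector()
    fit = fit_growth_constants(model, observed, fit_config)
    predicted = model.predict(fit.params)
    return TuningReport(fit=fit, observed=observed, predicted=predicted,
                        metrics_t0=m0, metrics_t1=m1)


@dataclass
class ValidationReport:
    metrics: ValidationMetrics
    baseline_delta_r: np.ndarray
    model_abs_error: float
    baseline_abs_error: float
    n_validation_rings: int

    def to_dict(self) -> dict:
        return {
            "delta_r_per_ring": self.metrics.delta_r_per_ring.tolist(),
            "mean_delta_r": self.metrics.mean_delta_r,
            "delta_l": self.metrics.delta_l,
            "baseline_delta_r": self.baseline_delta_r.tolist(),
            "model_abs_error": self.model_abs_error,
            "baseline_abs_error": self.baseline_abs_error,
            "n_validation_rings": self.n_validation_rings,
        }


def run_validation(t0_mesh, t1_mesh, t2_mesh, tuning: TuningReport,
                   conditions: StudyConditions | None = None,
                   n_rings: int = 6, dt: float = 10.0,
                   substeps: int = 1) -> ValidationReport:
    """Score the 120-day prediction against the second follow-up.

    Reports the interior-ring relative radius errors, the full-length
    relative error, and the linear-projection baseline computed from the
    measured t0/t1 radii.
    """
    conditions = conditions or StudyConditions()
    m0 = tuning.metrics_t0
    m1 = tuning.metrics_t1
    _, m2 = measure_mesh(t2_mesh, n_rings)
    partition = None
    if tuning.fit.n_domains > 1:
        partition = DomainPartition.equal_axial(n_rings, tuning.fit.n_domains)
    model = ForwardModel(
        initial_metrics=m0, wall=conditions.wall, mu_kpa=conditions.mu_kpa,
        pressure_pa=conditions.pressure_pa, flow_mean=conditions.flow_mean,
        sim_config=SimulationConfig(dt=dt, horizon=120.0, substeps=substeps),
        target_fraction=conditions.target_fraction, T_r=conditions.T_r,
        partition=partition, viscosity=conditions.viscosity,
    )
    pred_vec = model.predict(tuning.fit.params)
    pred = RingMetrics(radii=pred_vec[:n_rings], centroids=m0.centroids,
                       segment_lengths=pred_vec[n_rings:])
    metrics = validate_prediction(pred, m2)
    base_radii = linear_projection_baseline(m0.radii, m1.radii)
    baseline_d = (base_radii - m2.radii) / m2.radii
    interior = slice(1, n_rings - 1)
    return ValidationReport(
        metrics=metrics,
        baseline_delta_r=baseline_d,
        model_abs_error=float(np.abs(metrics.delta_r_per_ring[interior]).mean()),
        baseline_abs_error=float(np.abs(baseline_d[interior]).mean()),
        n_validation_rings=n_rings - 2,
    )


DEFAULT_CORRELATION_VARIABLES = [
    "lifespan", "ATI", "D_max_6mo", "delta_D", "E_asc", "E_desc",
    "T_theta", "T_s", "T_theta_over_sigma",
]


def run_correlation(frame, variables=None,
                    predictors=("T_theta", "T_s", "T_theta_over_sigma"),
                    y_max: float = 25.0):
    """Pearson map plus Tobit fits of (censored) lifespan on each predictor."""
    if len(frame) < 3:
        raise ValueError("need at least 3 subjects for correlation analysis")
    variables = [v for v in (variables or DEFAULT_CORRELATION_VARIABLES)
                 if v in frame.columns]
    cmap: CorrelationMap = pearson_map(frame, variables)
    tobit: dict[str, tuple[TobitResult, float]] = {}
    for pred in predictors:
        if pred not in frame.columns:
            continue
        X = frame[[pred]].to_numpy()
        fit = tobit_fit(X, frame["lifespan"].to_numpy(), y_max=y_max)
        tobit[pred] = (fit, mz_pseudo_r2(fit, X))
    return cmap, tobit


def run_all(t0_mesh, t1_mesh, t2_mesh, out_dir, seed: int = 0,
            conditions: StudyConditions | None = None,
            n_rings: int = 6) -> dict:
    """Tune + validate a single subject, writing JSON reports + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(stage="all", seed=seed,
                           config={"n_rings": n_rings},
                           inputs={"t0": str(t0_mesh), "t1": str(t1_mesh),
                                   "t2": str(t2_mesh)})
    t_start = time.perf_counter()
    tuning = run_tuning(t0_mesh, t1_mesh, conditions, n_rings=n_rings)
    manifest.timings_s["tune"] = time.perf_counter() - t_start
    t_start = time.perf_counter()
    validation = run_validation(t0_mesh, t1_mesh, t2_mesh, tuning,
                                conditions, n_rings=n_rings)
    manifest.timings_s["validate"] = time.perf_counter() - t_start
    (out / "fit_result.json").write_text(
        json.dumps(tuning.to_dict(), indent=2))
    (out / "validation.json").write_text(
        json.dumps(validation.to_dict(), indent=2))
    manifest.write(out / "manifest.json")
    return {"tuning": tuning, "validation": validation}
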