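"""Synthetic longitudinal vessel geometries and outcome-linked cohorts.

No imaging data accompany the study design this package analyses, so this
module generates the inputs every other stage consumes, with known ground
truth: tubular surface meshes whose ring radii and segment lengths evolve
under the growth law with chosen (T_theta, T_s); surface measurement noise
along vertex normals (mimicking segmentation error); independent
remeshing between time points (exercising the harmonic correspondence);
and cohorts whose lifespans depend noisily on the growth driving force
T_theta / sigma_theta_bar with right-censoring at 25 months.

Default study conditions: a 0.6 mm radius, 3 mm long ascending-aorta-like
tube with 0.06 mm wall, Neo-Hookean wall at E = 722 kPa and nu = 0.44,
90 mmHg mean pressure from the calibrated Windkessel bank, scan times at
0/60/120 days (the 2/4/6-month schedule at 30 days per month), and
homeostatic targets at 90 % of the baseline stresses so growth is active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .growth_engine import (
    DomainPartition,
    GrowthParams,
    GrowthTrajectory,
    SimulationConfig,
    forward_simulate,
    homeostatic_targets,
)
from .hemodynamic_stress import (
    MMHG_TO_PA,
    ViscosityModel,
    calibrated_mean_inflow,
    thin_wall_stresses,
)
from .mesh_geometry import RingMetrics, SurfaceMesh, WallSpec


@dataclass
class StudyConditions:
    """Material, loading and simulation settings shared across subjects."""

    wall_thickness: float = 0.06          # mm
    E_kpa: float = 722.0
    nu: float = 0.44
    pressure_pa: float = 90.0 * MMHG_TO_PA
    flow_mean: float = field(default_factory=calibrated_mean_inflow)  # mm^3/s
    target_fraction: float = 0.9
    T_r: float = 500.0                    # days, fixed (not fitted)
    viscosity: ViscosityModel = field(default_factory=ViscosityModel)

    @property
    def mu_kpa(self) -> float:
        return self.E_kpa / (2.0 * (1.0 + self.nu))

    @property
    def wall(self) -> WallSpec:
        return WallSpec(thickness=self.wall_thickness)


@dataclass
class TubeSpec:
    """Idealized vessel segment: straight or curved tube, optional bulge."""

    radius: float = 0.6          # mm, base loaded radius
    length: float = 3.0          # mm
    curvature: float = 0.0       # 1/mm of the centerline (0 = straight)
    n_axial: int = 40            # axial vertex rows (n_axial + 1 rings)
    n_circ: int = 64
    bulge_amp: float = 0.0       # mm, aneurysm-like Gaussian bulge
    bulge_center: float = 0.5    # in s
    bulge_width: float = 0.15    # in s

    def __post_init__(self):
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("radius and length must be positive")
        if self.n_axial < 8 or self.n_circ < 8:
            raise ValueError("mesh resolution must be at least 8")
        if self.curvature * (self.radius + self.bulge_amp) >= 1.0:
            raise ValueError("curvature too large: tube self-intersects")

    def radius_profile(self, s):
        s = np.asarray(s, dtype=float)
        bump = self.bulge_amp * np.exp(
            -0.5 * ((s - self.bulge_center) / self.bulge_width) ** 2
        )
        return self.radius + bump

    def centerline(self, s):
        """Centerline points and local (normal1, normal2) frame at s."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if self.curvature == 0.0:
            pts = np.column_stack([np.zeros_like(s), np.zeros_like(s),
                                   s * self.length])
            e1 = np.tile([1.0, 0.0, 0.0], (len(s), 1))
            e2 = np.tile([0.0, 1.0, 0.0], (len(s), 1))
            return pts, e1, e2
        Rc = 1.0 / self.curvature
        ang = s * self.length / Rc
        pts = np.column_stack([Rc * (1 - np.cos(ang)), np.zeros_like(s),
                               Rc * np.sin(ang)])
        e1 = np.column_stack([np.cos(ang), np.zeros_like(s), -np.sin(ang)])
        e2 = np.tile([0.0, 1.0, 0.0], (len(s), 1))
        return pts, e1, e2


def make_tube_mesh(spec: TubeSpec,
                   radius_of_s=None, length: float | None = None) -> SurfaceMesh:
    """Structured triangulated tube with two open boundary loops.

    ``radius_of_s``/``length`` override the spec profile (used when
    building grown time points from a simulated radius profile).
    """
    n_ax, n_c = spec.n_axial, spec.n_circ
    s = np.linspace(0.0, 1.0, n_ax + 1)
    prof = spec.radius_profile(s) if radius_of_s is None else radius_of_s(s)
    if np.any(prof <= 0):
        raise ValueError("radius profile must be positive")
    eff = spec if length is None else TubeSpec(
        radius=spec.radius, length=length, curvature=spec.curvature,
        n_axial=n_ax, n_circ=n_c)
    centers, e1, e2 = eff.centerline(s)
    ang = 2.0 * np.pi * np.arange(n_c) / n_c
    verts = (
        centers[:, None, :]
        + prof[:, None, None] * (np.cos(ang)[None, :, None] * e1[:, None, :]
                                 + np.sin(ang)[None, :, None] * e2[:, None, :])
    ).reshape(-1, 3)
    tris = []
    for i in range(n_ax):
        for j in range(n_c):
            a = i * n_c + j
            b = i * n_c + (j + 1) % n_c
            c = (i + 1) * n_c + j
            d = (i + 1) * n_c + (j + 1) % n_c
            tris.append([a, b, d])
            tris.append([a, d, c])
    mesh = SurfaceMesh(
        vertices=verts, triangles=np.array(tris, dtype=np.int64),
        inlet_loop=list(range(n_c)),
        outlet_loop=list(range(n_ax * n_c, (n_ax + 1) * n_c)),
    )
    return mesh


def _vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    v, t = mesh.vertices, mesh.triangles
    fn = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    normals = np.zeros_like(v)
    for k in range(3):
        np.add.at(normals, t[:, k], fn)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return normals / norms


def add_surface_noise(mesh: SurfaceMesh, sigma_mm: float,
                      rng: np.random.Generator) -> SurfaceMesh:
    """Gaussian measurement noise along vertex normals."""
    if sigma_mm == 0:
        return mesh
    offsets = rng.normal(0.0, sigma_mm, size=len(mesh.vertices))
    verts = mesh.vertices + offsets[:, None] * _vertex_normals(mesh)
    return SurfaceMesh(vertices=verts, triangles=mesh.triangles.copy(),
                       inlet_loop=list(mesh.inlet_loop),
                       outlet_loop=list(mesh.outlet_loop))


def initial_ring_metrics(spec: TubeSpec, n_rings: int = 6) -> RingMetrics:
    """Analytic ring metrics of the baseline tube (loaded configuration)."""
    s = np.linspace(0.0, 1.0, n_rings)
    radii = spec.radius_profile(s)
    centers, _, _ = spec.centerline(s)
    seg = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    return RingMetrics(radii=radii, centroids=centers, segment_lengths=seg)


def simulate_ring_trajectory(spec: TubeSpec, conditions: StudyConditions,
                             T_theta, T_s, horizon: float = 120.0,
                             n_rings: int = 6, dt: float = 10.0,
                             substeps: int = 1,
                             partition: DomainPartition | None = None
                             ) -> GrowthTrajectory:
    """Forward growth of the analytic baseline rings under known constants."""
    m0 = initial_ring_metrics(spec, n_rings)
    stress0 = thin_wall_stresses(m0.radii, conditions.wall_thickness,
                                 conditions.pressure_pa, conditions.flow_mean,
                                 conditions.viscosity)
    targets = homeostatic_targets(stress0, conditions.target_fraction)
    if partition is not None:
        T_theta = partition.expand(np.atleast_1d(T_theta)) \
            if np.ndim(T_theta) else partition.expand([T_theta] * partition.n_domains)
        T_s = partition.expand(np.atleast_1d(T_s)) \
            if np.ndim(T_s) else partition.expand([T_s] * partition.n_domains)
    params = GrowthParams(T_theta=T_theta, T_s=T_s, T_r=conditions.T_r,
                          **targets)
    cfg = SimulationConfig(dt=dt, horizon=horizon, substeps=substeps)
    return forward_simulate(m0, conditions.wall, conditions.mu_kpa,
                            conditions.pressure_pa, conditions.flow_mean,
                            params, cfg, viscosity=conditions.viscosity)


def generate_longitudinal_geometries(spec: TubeSpec,
                                     conditions: StudyConditions,
                                     T_theta, T_s,
                                     times=(0.0, 60.0, 120.0),
                                     noise: float = 0.0,
                                     remesh: bool = False,
                                     seed: int = 0,
                                     n_rings: int = 6,
                                     partition: DomainPartition | None = None):
    """Baseline + grown meshes at the requested times (days).

    Grown meshes are rebuilt from the simulated ring-radius profile
    (linear interpolation in s through the ring values) and the grown
    total length; with ``remesh`` the follow-ups use different mesh
    resolutions, forcing the cross-time mapping to do real work.  Returns
    (meshes, truth) where truth holds the generating constants and the
    ring trajectory.
    """
    rng = np.random.default_rng(seed)
    horizon = max(times)
    traj = None
    if horizon > 0:
        traj = simulate_ring_trajectory(spec, conditions, T_theta, T_s,
                                        horizon=horizon, n_rings=n_rings,
                                        partition=partition)
    s_rings = np.linspace(0.0, 1.0, n_rings)
    meshes = []
    for k, t in enumerate(times):
        if t == 0 or traj is None:
            radii, length = None, None
            sub_spec = spec
        else:
            idx = int(np.argmin(np.abs(traj.times - t)))
            m = traj.metrics[idx]
            radii = m.radii
            length = float(m.total_length)
            sub_spec = spec
        if remesh and k > 0:
            sub_spec = TubeSpec(
                radius=spec.radius, length=spec.length,
                curvature=spec.curvature,
                n_axial=spec.n_axial + 7 * k, n_circ=spec.n_circ + 11 * k,
                bulge_amp=spec.bulge_amp, bulge_center=spec.bulge_center,
                bulge_width=spec.bulge_width,
            )
        if radii is None:
            mesh = make_tube_mesh(sub_spec)
        else:
            prof = lambda s, r=radii: np.interp(s, s_rings, r)
            mesh = make_tube_mesh(sub_spec, radius_of_s=prof, length=length)
        meshes.append(add_surface_noise(mesh, noise, rng))
    truth = {
        "T_theta": T_theta, "T_s": T_s, "times": list(times),
        "trajectory": traj,
    }
    return meshes, truth


# ---------------------------------------------------------------------------
# Cohort generation

@dataclass
class CohortSpec:
    """Cohort with lifespans linked to the growth driving force.

    True constants are log-normal; lifespan follows
    LS = a + b * (T_theta / sigma_theta_bar[kPa]) + eps, censored at the
    cutoff.  Defaults give roughly the 4-in-10 censoring of the study
    design this emulates.
    """

    n_subjects: int = 10
    T_theta_median: float = 120.0   # days
    T_theta_log_sd: float = 0.25
    T_s_median: float = 200.0       # days
    T_s_log_sd: float = 0.25
    T_floor: float = 70.0           # days; keeps trajectories below the
                                    # membrane limit point over 120 days
    lifespan_intercept: float = 12.0     # months
    lifespan_slope: float = 12.0         # months per (day/kPa)
    lifespan_noise_sd: float = 2.5       # months
    censor_cutoff: float = 25.0          # months
    noise_mesh: float = 0.0              # mm
    seed: int = 0

    def __post_init__(self):
        if min(self.T_theta_median, self.T_s_median,
               self.lifespan_noise_sd) <= 0:
            raise ValueError("scales must be positive")


@dataclass
class SyntheticSubject:
    id: int
    T_theta_true: float
    T_s_true: float
    sigma_theta_bar: float    # Pa, time-averaged over the tuning horizon
    latent_lifespan: float
    lifespan: float
    censored: bool
    trajectory: GrowthTrajectory
    D_max_2mo: float
    D_max_6mo: float
    ATI: float
    E_asc: float
    E_desc: float
    sex: str

    @property
    def driving_ratio(self) -> float:
        """T_theta over sigma_theta_bar in day/kPa — the growth driving force."""
        return self.T_theta_true / (self.sigma_theta_bar / 1e3)


def generate_cohort(spec: CohortSpec,
                    tube: TubeSpec | None = None,
                    conditions: StudyConditions | None = None) -> list:
    """Sample a cohort of synthetic subjects with known ground truth.

    Each subject gets true (T_theta, T_s), a 120-day ring trajectory, the
    time-averaged circumferential stress over the tuning horizon, and a
    lifespan drawn from the linear model, censored at the cutoff.  ATI is
    generated with a negative dependence on T_s; moduli are log-normal
    around murine aortic values.  Identical seeds reproduce the cohort
    bit for bit.
    """
    tube = tube or TubeSpec()
    conditions = conditions or StudyConditions()
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for i in range(spec.n_subjects):
        T_theta = max(spec.T_floor, spec.T_theta_median * np.exp(
            rng.normal(0.0, spec.T_theta_log_sd)))
        T_s = max(spec.T_floor,
                  spec.T_s_median * np.exp(rng.normal(0.0, spec.T_s_log_sd)))
        traj = simulate_ring_trajectory(tube, conditions, T_theta, T_s,
                                        horizon=120.0)
        tuning = [s for s, t in zip(traj.stresses, traj.times) if t <= 60.0]
        sigma_bar = float(np.mean([s.sigma_theta.mean() for s in tuning]))
        ratio_kpa = T_theta / (sigma_bar / 1e3)
        latent = (spec.lifespan_intercept
                  + spec.lifespan_slope * ratio_kpa
                  + rng.normal(0.0, spec.lifespan_noise_sd))
        censored = latent >= spec.censor_cutoff
        d2 = 2.0 * float(traj.metrics[0].radii.max())
        d6 = 2.0 * float(traj.final_metrics.radii.max())
        ati = 45.0 - 0.05 * (T_s - spec.T_s_median) + rng.normal(0.0, 4.0)
        subjects.append(SyntheticSubject(
            id=i + 1,
            T_theta_true=float(T_theta), T_s_true=float(T_s),
            sigma_theta_bar=sigma_bar,
            latent_lifespan=float(latent),
            lifespan=float(min(latent, spec.censor_cutoff)),
            censored=bool(censored),
            trajectory=traj,
            D_max_2mo=d2, D_max_6mo=d6,
            ATI=float(ati),
            E_asc=float(800.0 * np.exp(rng.normal(0.0, 0.35))),
            E_desc=float(1500.0 * np.exp(rng.normal(0.0, 0.6))),
            sex="M" if rng.random() < 0.5 else "F",
        ))
    return subjects


def expected_censor_fraction(subjects, spec: CohortSpec) -> float:
    """Analytic censoring probability averaged over the sampled subjects.

    Conditional on each subject's driving ratio, the latent lifespan is
    normal, so P(censored) = 1 - Phi((cutoff - a - b x)/s).
    """
    zs = [
        (spec.censor_cutoff - spec.lifespan_intercept
         - spec.lifespan_slope * s.driving_ratio) / spec.lifespan_noise_sd
        for s in subjects
    ]
    return float(np.mean(stats.norm.sf(zs)))


def cohort_to_frame(subjects) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            dict(id=s.id, sex=s.sex, lifespan=s.lifespan,
                 censored=s.censored, T_theta_true=s.T_theta_true,
                 T_s_true=s.T_s_true, sigma_theta_bar=s.sigma_theta_bar,
                 driving_ratio=s.driving_ratio, D_max_2mo=s.D_max_2mo,
                 D_max_6mo=s.D_max_6mo, delta_D=s.D_max_6mo - s.D_max_2mo,
                 ATI=s.ATI, E_asc=s.E_asc, E_desc=s.E_desc)
            for s in subjects
        ]
    )
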