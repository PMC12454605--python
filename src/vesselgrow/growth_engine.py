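"""Kinematic growth law and forward time-stepping of the vessel geometry.

Growth is modeled as anisotropic kinematic growth driven by deviation of
the wall stresses from homeostatic targets (Alford-Taber form):

    d(lam_gr)/dt     = 1/T_r     (sigma_theta/sigma_theta_hat - 1) lam_gr
    d(lam_gtheta)/dt = [1/T_theta (sigma_theta/sigma_theta_hat - 1)
                        + 1/T_tau (tau_w/tau_w_hat - 1)]            lam_gtheta
    d(lam_gs)/dt     = 1/T_s     (sigma_ss/sigma_ss_hat - 1)        lam_gs

The growth tensor G = diag(lam_gr, lam_gtheta, lam_gs) in the local
(radial, circumferential, axial) frame, and the total deformation splits
as F = F_e * G.  At homeostasis (stresses equal to targets) all rates
vanish exactly.

The finite-element equilibrium step of a full G&R solver is replaced here
by a ring-wise kinematic update: per time step the unloaded ring radii
scale by the circumferential growth increment, segment lengths by the
ring-pair mean axial increment, and the wall thickness by the mean radial
increment; the loaded configuration used for the next stress evaluation
comes from the incompressible membrane inflation.  Residual stresses
between rings are not represented.

"Elements" in this surrogate are the rings themselves; all growth arrays
are per ring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hemodynamic_stress import (
    StressField,
    ViscosityModel,
    membrane_inflation,
    invert_inflation,
    thin_wall_stresses,
)
from .mesh_geometry import RingMetrics, WallSpec


@dataclass
class DomainPartition:
    """Assignment of rings to K contiguous axial domains.

    Domains are the equal axial quarters of the vessel; ring j at axial
    coordinate s_j belongs to domain floor(K * s_j), clipped to K-1.
    """

    ring_domain: np.ndarray  # per-ring domain index in 0..K-1
    n_domains: int

    @classmethod
    def equal_axial(cls, n_rings: int, n_domains: int = 4) -> "DomainPartition":
        s = np.linspace(0.0, 1.0, n_rings)
        dom = np.minimum((s * n_domains).astype(int), n_domains - 1)
        return cls(ring_domain=dom, n_domains=n_domains)

    def expand(self, per_domain_values) -> np.ndarray:
        vals = np.asarray(per_domain_values, dtype=float)
        if len(vals) != self.n_domains:
            raise ValueError("one value per domain required")
        return vals[self.ring_domain]


@dataclass
class GrowthParams:
    """Time constants (days) and homeostatic stress targets (Pa).

    ``T_theta`` and ``T_s`` may be scalars (single domain) or per-ring
    arrays (multi-domain, via :meth:`DomainPartition.expand`).  The wall
    shear term is off by default (``T_tau`` infinite), since its target is
    rarely identifiable from geometry alone.
    """

    T_theta: float | np.ndarray
    T_s: float | np.ndarray
    T_r: float = 500.0
    T_tau: float = np.inf
    sigma_theta_hat: float | np.ndarray = 1.0
    sigma_ss_hat: float | np.ndarray = 1.0
    tau_w_hat: float | np.ndarray = 1.0

    def __post_init__(self):
        for name in ("T_theta", "T_s", "T_r", "T_tau"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"time constant {name} must be positive")
        for name in ("sigma_theta_hat", "sigma_ss_hat", "tau_w_hat"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"target {name} must be positive")


@dataclass
class GrowthState:
    """Per-ring growth stretch ratios, initialized at 1."""

    lambda_gr: np.ndarray
    lambda_gtheta: np.ndarray
    lambda_gs: np.ndarray

    @classmethod
    def initial(cls, n_rings: int) -> "GrowthState":
        return cls(*(np.ones(n_rings) for _ in range(3)))

    def copy(self) -> "GrowthState":
        return GrowthState(self.lambda_gr.copy(), self.lambda_gtheta.copy(),
                           self.lambda_gs.copy())


def growth_rates(state: GrowthState, stress: StressField,
                 params: GrowthParams):
    """Per-ring growth rates (1/day) of the three stretch ratios."""
    rho_t = stress.sigma_theta / params.sigma_theta_hat - 1.0
    rho_s = stress.sigma_ss / params.sigma_ss_hat - 1.0
    rho_w = stress.tau_w / params.tau_w_hat - 1.0
    d_gr = rho_t / params.T_r * state.lambda_gr
    d_gtheta = (rho_t / params.T_theta + rho_w / params.T_tau) * state.lambda_gtheta
    d_gs = rho_s / params.T_s * state.lambda_gs
    return d_gr, d_gtheta, d_gs


def assemble_growth_tensor(state: GrowthState) -> np.ndarray:
    """(n, 3, 3) diagonal growth tensors in the local (r, theta, s) frame."""
    n = len(state.lambda_gr)
    G = np.zeros((n, 3, 3))
    G[:, 0, 0] = state.lambda_gr
    G[:, 1, 1] = state.lambda_gtheta
    G[:, 2, 2] = state.lambda_gs
    return G


def step_growth(state: GrowthState, stress: StressField, params: GrowthParams,
                dt: float, substeps: int = 1) -> GrowthState:
    """Explicit Euler update over dt days (optionally substepped)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    new = state.copy()
    h = dt / substeps
    for _ in range(substeps):
        d_gr, d_gtheta, d_gs = growth_rates(new, stress, params)
        new.lambda_gr = new.lambda_gr + h * d_gr
        new.lambda_gtheta = new.lambda_gtheta + h * d_gtheta
        new.lambda_gs = new.lambda_gs + h * d_gs
    for arr in (new.lambda_gr, new.lambda_gtheta, new.lambda_gs):
        if np.any(arr <= 0):
            raise ValueError("growth stretch became non-positive; reduce dt")
    return new


def update_geometry(unloaded_radii: np.ndarray, segment_lengths: np.ndarray,
                    wall: WallSpec, incr_gr: np.ndarray,
                    incr_gtheta: np.ndarray, incr_gs: np.ndarray):
    """Apply multiplicative growth increments to the unloaded geometry.

    Radii scale per ring by the circumferential increment; each segment by
    the mean axial increment of its two end rings; the (uniform) thickness
    by the ring-mean radial increment.
    """
    radii = unloaded_radii * incr_gtheta
    pair_mean = 0.5 * (incr_gs[:-1] + incr_gs[1:])
    seg = segment_lengths * pair_mean
    wall_new = WallSpec(thickness=wall.thickness * float(np.mean(incr_gr)))
    return radii, seg, wall_new


@dataclass
class SimulationConfig:
    """Time-stepping settings: dt in days, horizon in days."""

    dt: float = 10.0
    horizon: float = 60.0
    substeps: int = 1

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n = self.horizon / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("horizon must be a multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon / self.dt))


@dataclass
class BoundaryMotion:
    """Linear-in-time inlet/outlet centroid displacements (mm over days)."""

    inlet_total: np.ndarray = field(default_factory=lambda: np.zeros(3))
    outlet_total: np.ndarray = field(default_factory=lambda: np.zeros(3))
    total_time: float = 120.0

    def displacement(self, t: float):
        frac = np.clip(t / self.total_time, 0.0, 1.0)
        return frac * np.asarray(self.inlet_total), \
            frac * np.asarray(self.outlet_total)


@dataclass
class GrowthTrajectory:
    """Loaded ring metrics, growth states and stresses at every step."""

    times: np.ndarray
    metrics: list        # RingMetrics per stored time (loaded configuration)
    states: list         # GrowthState per stored time
    stresses: list       # StressField per stored time
    wall: WallSpec       # final wall spec

    @property
    def final_metrics(self) -> RingMetrics:
        return self.metrics[-1]

    def mean_sigma_theta(self) -> float:
        """Time average of the ring-mean circumferential stress (Pa)."""
        return float(np.mean([s.sigma_theta.mean() for s in self.stresses]))


def homeostatic_targets(stress0: StressField, fraction: float = 0.9):
    """Targets as a fraction (<1) of the baseline stresses.

    With fraction below one, the baseline state carries stresses above
    target and growth is positive from the start, reproducing the positive
    feedback of an aneurysmal wall.
    """
    return dict(
        sigma_theta_hat=stress0.sigma_theta * fraction,
        sigma_ss_hat=stress0.sigma_ss * fraction,
        tau_w_hat=stress0.tau_w,
    )


def _rebuild_centroids(centroids0: np.ndarray, seg: np.ndarray,
                       disp_in, disp_out) -> np.ndarray:
    """Chain centroids along the initial segment directions with new lengths."""
    d = np.diff(centroids0, axis=0)
    norms = np.linalg.norm(d, axis=1)
    norms[norms == 0] = 1.0
    dirs = d / norms[:, None]
    out = np.empty_like(centroids0)
    out[0] = centroids0[0]
    for j in range(len(seg)):
        out[j + 1] = out[j] + dirs[j] * seg[j]
    # imposed displacements act on the end rings only
    out[0] = out[0] + disp_in
    out[-1] = out[-1] + disp_out
    return out


def forward_simulate(initial_metrics: RingMetrics, wall: WallSpec,
                     mu_kpa: float, pressure_pa: float, flow_mean: float,
                     params: GrowthParams, config: SimulationConfig,
                     boundary_motion: BoundaryMotion | None = None,
                     viscosity: ViscosityModel | None = None,
                     freeze_stress: bool = False) -> GrowthTrajectory:
    """Run the growth loop from a measured (loaded) baseline geometry.

    Per step: evaluate stresses on the loaded configuration, advance the
    growth ODEs, scale the unloaded geometry by the growth increments and
    re-inflate to the next loaded configuration.  ``freeze_stress`` holds
    the stimulus at its baseline value (used to compare against the
    closed-form exponential, where stress feedback is disabled).
    """
    viscosity = viscosity or ViscosityModel()
    n = initial_metrics.n_rings
    # unloaded configuration consistent with the measured loaded radii
    R_u = np.array([
        invert_inflation(r, wall.thickness, mu_kpa, pressure_pa)
        for r in initial_metrics.radii
    ])
    seg = initial_metrics.segment_lengths.copy()
    centroids0 = initial_metrics.centroids.copy()
    wall_cur = WallSpec(thickness=wall.thickness)
    state = GrowthState.initial(n)

    def loaded(R_unloaded, w):
        lam = np.empty(n)
        r = np.empty(n)
        for j, R in enumerate(R_unloaded):
            lam[j], r[j] = membrane_inflation(R, w.thickness, mu_kpa,
                                              pressure_pa)
        return lam, r

    _, r_loaded = loaded(R_u, wall_cur)
    stress = thin_wall_stresses(r_loaded, wall_cur.thickness, pressure_pa,
                                flow_mean, viscosity)
    stress0 = stress
    times = [0.0]
    metrics = [RingMetrics(radii=r_loaded.copy(), centroids=centroids0.copy(),
                           segment_lengths=seg.copy())]
    states = [state.copy()]
    stresses = [stress]
    bm = boundary_motion
    t = 0.0
    for _ in range(config.n_steps):
        stim = stress0 if freeze_stress else stress
        new_state = step_growth(state, stim, params, config.dt,
                                config.substeps)
        incr_gr = new_state.lambda_gr / state.lambda_gr
        incr_gtheta = new_state.lambda_gtheta / state.lambda_gtheta
        incr_gs = new_state.lambda_gs / state.lambda_gs
        R_u, seg, wall_cur = update_geometry(R_u, seg, wall_cur, incr_gr,
                                             incr_gtheta, incr_gs)
        state = new_state
        t += config.dt
        _, r_loaded = loaded(R_u, wall_cur)
        stress = thin_wall_stresses(r_loaded, wall_cur.thickness, pressure_pa,
                                    flow_mean, viscosity)
        if bm is not None:
            disp_in, disp_out = bm.displacement(t)
        else:
            disp_in = disp_out = np.zeros(3)
        cents = _rebuild_centroids(centroids0, seg, disp_in, disp_out)
        seg_out = np.linalg.norm(np.diff(cents, axis=0), axis=1)
        times.append(t)
        metrics.append(RingMetrics(radii=r_loaded.copy(), centroids=cents,
                                   segment_lengths=seg_out))
        states.append(state.copy())
        stresses.append(stress)
    return GrowthTrajectory(times=np.array(times), metrics=metrics,
                            states=states, stresses=stresses, wall=wall_cur)
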