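"""Lumped-parameter hemodynamics and thin-wall stress surrogate.

Instead of a 3-D fluid-solid interaction simulation, the wall stresses that
drive growth are computed from a desk-scale surrogate:

* a three-element Windkessel (RCR) circuit converts the periodic inflow
  waveform into a pressure trace whose period mean is the loading pressure;
* Laplace's law for a thin-walled cylinder gives the circumferential and
  axial Cauchy stresses, sigma_theta = p r / h and sigma_ss = p r / (2 h);
* Poiseuille flow with a Carreau-Yasuda shear-thinning viscosity gives the
  wall shear stress tau_w = mu(gamma_w) * gamma_w with gamma_w = 4 Q / (pi r^3);
* an incompressible Neo-Hookean membrane balance provides the elastic
  circumferential stretch of the pressurized wall.

Units: pressure and stress in Pa, lengths in mm, flow in mm^3/s,
resistances in Pa*s/mm^3, compliance in mm^3/Pa, moduli in kPa (converted
to Pa where they meet pressures).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

MMHG_TO_PA = 133.322

# Outflow RCR values for the four thoracic branch outlets (left subclavian,
# left common carotid, brachiocephalic trunk, distal aorta).  Compliance is
# stored in mm^3/Pa as the RCR ordinary differential equation requires.
DEFAULT_OUTLETS = {
    "left_subclavian": (19.58, 5.5e-4, 286.2),
    "left_common_carotid": (44.70, 3.23e-4, 488.0),
    "brachiocephalic_trunk": (21.55, 3.54e-4, 443.2),
    "distal_aorta": (10.30, 5.41e-4, 443.2),
}


@dataclass
class WindkesselParams:
    """Three-element RCR outlet: proximal R, compliance, distal R."""

    Rp: float  # Pa*s/mm^3
    C: float   # mm^3/Pa
    Rd: float  # Pa*s/mm^3

    def __post_init__(self):
        if min(self.Rp, self.C, self.Rd) <= 0:
            raise ValueError("Windkessel parameters must be positive")

    @property
    def total_resistance(self) -> float:
        return self.Rp + self.Rd


@dataclass
class FlowWaveform:
    """Periodic inflow: sample times (s) over one period and Q (mm^3/s)."""

    period: float
    times: np.ndarray
    samples: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.mean_flow <= 0:
            raise ValueError("waveform mean flow must be positive")

    @property
    def mean_flow(self) -> float:
        return float(np.trapezoid(self.samples, self.times) / self.period)

    def __call__(self, t):
        return np.interp(np.mod(t, self.period), self.times, self.samples,
                         period=self.period)


def parabolic_waveform(period: float = 0.1, mean_flow: float = 100.0,
                       systolic_fraction: float = 0.35,
                       n_samples: int = 200) -> FlowWaveform:
    """Parameterized parabolic-systole inflow pulse.

    Systole is a parabola over ``systolic_fraction`` of the cycle; diastole
    carries zero flow.  The peak is scaled so the period mean equals
    ``mean_flow``.  Defaults approximate a murine aortic inflow (cycle
    ~0.1 s at ~600 bpm).
    """
    t = np.linspace(0.0, period, n_samples, endpoint=False)
    ts = systolic_fraction * period
    q = np.where(t < ts, 4.0 * (t / ts) * (1.0 - t / ts), 0.0)
    mean_unit = np.trapezoid(q, t) / period
    return FlowWaveform(period=period, times=t, samples=q * mean_flow / mean_unit)


@dataclass
class MaterialParams:
    """Compressible Neo-Hookean wall: E and nu with derived Lame constants (kPa)."""

    E: float
    nu: float
    mu: float = field(init=False)
    lame_lambda: float = field(init=False)

    def __post_init__(self):
        if self.E < 0:
            raise ValueError("E must be non-negative")
        if not 0 <= self.nu < 0.5:
            raise ValueError("nu must satisfy 0 <= nu < 0.5 (incompressible limit)")
        self.mu = self.E / (2.0 * (1.0 + self.nu))
        self.lame_lambda = (
            self.nu * self.E / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))
        )


def lame_from_E_nu(E: float, nu: float) -> MaterialParams:
    """Lame parameters from elastic modulus and Poisson's ratio (kPa)."""
    return MaterialParams(E=E, nu=nu)


def neo_hookean_energy(F_e: np.ndarray, material: MaterialParams) -> float:
    """Strain energy density W = mu/2 (I1 - 3) - mu ln J + lambda/2 (ln J)^2."""
    F = np.asarray(F_e, dtype=float)
    J = np.linalg.det(F)
    if J <= 0:
        raise ValueError("deformation gradient must have positive determinant")
    I1 = float(np.trace(F.T @ F))
    lnJ = np.log(J)
    return (material.mu / 2.0) * (I1 - 3.0) - material.mu * lnJ \
        + (material.lame_lambda / 2.0) * lnJ ** 2


# ---------------------------------------------------------------------------
# Windkessel

def solve_windkessel(waveform: FlowWaveform, params: WindkesselParams,
                     n_periods: int = 20, steps_per_period: int = 1000):
    """Integrate the RCR circuit to periodic steady state.

    dPc/dt = (Q - Pc/Rd)/C,  P = Q*Rp + Pc.  Integration is RK4 starting
    from the steady distal pressure; convergence requires the last two
    period means to drift by < 0.1 % (warning otherwise).

    Returns (times, P(t)) over the final period and the period-mean pressure.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    dt = waveform.period / steps_per_period
    pc = waveform.mean_flow * params.Rd  # asymptotic distal pressure

    def dpc(t, p):
        return (waveform(t) - p / params.Rd) / params.C

    means = []
    t = 0.0
    for _ in range(n_periods):
        trace = np.empty(steps_per_period + 1)
        times = np.empty(steps_per_period + 1)
        trace[0] = waveform(t) * params.Rp + pc
        times[0] = t
        for i in range(steps_per_period):
            k1 = dpc(t, pc)
            k2 = dpc(t + dt / 2, pc + dt / 2 * k1)
            k3 = dpc(t + dt / 2, pc + dt / 2 * k2)
            k4 = dpc(t + dt, pc + dt * k3)
            pc += dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
            trace[i + 1] = waveform(t) * params.Rp + pc
            times[i + 1] = t
        means.append(np.trapezoid(trace, times) / waveform.period)
    drift = abs(means[-1] - means[-2]) / abs(means[-1]) if len(means) > 1 else 0.0
    if drift > 1e-3:
        warnings.warn(
            f"Windkessel not at periodic steady state: drift {drift:.2e}",
            RuntimeWarning,
        )
    return times, trace, float(means[-1])


def parallel_outlets(outlets=None) -> float:
    """Total resistance of the outlet bank in parallel (Pa*s/mm^3)."""
    outlets = outlets or DEFAULT_OUTLETS
    return 1.0 / sum(1.0 / (rp + rd) for rp, _, rd in outlets.values())


def calibrated_mean_inflow(target_pressure_mmHg: float = 90.0,
                           outlets=None) -> float:
    """Mean inflow that loads the parallel outlet bank to the target pressure.

    This back-computes the calibration quantity (the study's waveform is
    tuned for ~90 mmHg mean aortic pressure); it is a calibration, not a
    measured flow.
    """
    return target_pressure_mmHg * MMHG_TO_PA / parallel_outlets(outlets)


# ---------------------------------------------------------------------------
# Viscosity and wall stresses

@dataclass
class ViscosityModel:
    """Carreau-Yasuda shear-thinning viscosity (Pa*s).

    Defaults are standard literature values for whole blood.
    """

    mu0: float = 0.056
    mu_inf: float = 0.00345
    lambda_cy: float = 1.902
    a: float = 1.25
    n: float = 0.22

    def __post_init__(self):
        if not self.mu0 >= self.mu_inf > 0:
            raise ValueError("require mu0 >= mu_inf > 0")

    def __call__(self, shear_rate):
        g = np.asarray(shear_rate, dtype=float)
        if np.any(g < 0):
            raise ValueError("shear rate must be non-negative")
        return self.mu_inf + (self.mu0 - self.mu_inf) * (
            1.0 + (self.lambda_cy * g) ** self.a
        ) ** ((self.n - 1.0) / self.a)


def carreau_yasuda_viscosity(shear_rate, model: ViscosityModel | None = None):
    model = model or ViscosityModel()
    return model(shear_rate)


@dataclass
class StressField:
    """Per-ring time-averaged wall stresses (Pa)."""

    sigma_theta: np.ndarray
    sigma_ss: np.ndarray
    tau_w: np.ndarray

    def __post_init__(self):
        for arr in (self.sigma_theta, self.sigma_ss, self.tau_w):
            if not np.all(np.isfinite(arr)):
                raise ValueError("stresses must be finite")
        if np.any(self.tau_w < 0):
            raise ValueError("wall shear stress must be non-negative")

    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame(
            {
                "ring_index": np.arange(len(self.sigma_theta)),
                "sigma_theta_Pa": self.sigma_theta,
                "sigma_ss_Pa": self.sigma_ss,
                "tau_w_Pa": self.tau_w,
            }
        ).to_csv(path, index=False)


def thin_wall_stresses(radii, thickness: float, pressure_mean: float,
                       flow_mean: float,
                       viscosity: ViscosityModel | None = None) -> StressField:
    """Laplace-law wall stresses and Poiseuille wall shear per ring.

    sigma_theta = p r / h, sigma_ss = p r / (2 h), tau_w = mu(g) g with
    g = 4 Q / (pi r^3) the Newtonian-profile wall shear rate (independent
    of viscosity, so the effective viscosity is a direct evaluation).
    """
    r = np.asarray(radii, dtype=float)
    if np.any(r <= 0) or thickness <= 0 or pressure_mean <= 0:
        raise ValueError("radii, thickness and pressure must be positive")
    viscosity = viscosity or ViscosityModel()
    sigma_theta = pressure_mean * r / thickness
    sigma_ss = sigma_theta / 2.0
    gamma_w = 4.0 * flow_mean / (np.pi * r ** 3)
    tau_w = viscosity(gamma_w) * gamma_w
    return StressField(sigma_theta=sigma_theta, sigma_ss=sigma_ss, tau_w=tau_w)


# ---------------------------------------------------------------------------
# Membrane inflation

def membrane_inflation(unloaded_radius: float, thickness: float,
                       mu_kpa: float, pressure_pa: float):
    """Elastic circumferential stretch of a pressurized incompressible membrane.

    Solves mu (lam^2 - 1/lam^2) = p lam^2 R / H for lam >= 1 with the axial
    stretch held at 1 (so the loaded mid-wall radius is lam*R and the wall
    thins as H/lam).  Returns (lam, loaded_radius).  A root exists only
    below the limit-point pressure p < mu H / R.
    """
    R, H = float(unloaded_radius), float(thickness)
    if min(R, H, mu_kpa, pressure_pa) <= 0 and pressure_pa != 0:
        raise ValueError("inputs must be positive")
    if pressure_pa == 0:
        return 1.0, R
    mu = mu_kpa * 1e3  # Pa
    load = pressure_pa * R / H
    if load >= mu:
        p_max = mu * H / R
        raise ValueError(
            f"pressure beyond membrane limit point (p must be < {p_max:.1f} Pa)"
        )

    def resid(lam):
        return mu * (lam ** 2 - lam ** -2) - pressure_pa * lam ** 2 * R / H

    hi = 2.0
    while resid(hi) < 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover
            raise ValueError("no root in bracket")
    lam = brentq(resid, 1.0, hi, xtol=1e-12, rtol=1e-14)
    return float(lam), float(lam * R)


def invert_inflation(loaded_radius: float, thickness: float,
                     mu_kpa: float, pressure_pa: float) -> float:
    """Unloaded radius whose inflated radius equals ``loaded_radius``."""
    r = float(loaded_radius)
    if pressure_pa == 0:
        return r

    def resid(R):
        _, r_loaded = membrane_inflation(R, thickness, mu_kpa, pressure_pa)
        return r_loaded - r

    # the loaded radius exceeds the unloaded one, so R < r; the limit
    # point bounds R above by mu*H/p
    R_max = min(r, 0.999 * mu_kpa * 1e3 * thickness / pressure_pa)
    return float(brentq(resid, 1e-9, R_max, xtol=1e-12, rtol=1e-14))
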