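# vesselgrow

Hemodynamics-driven growth-and-remodeling (G&R) analysis of ascending
aortic aneurysm progression, built for longitudinal vessel geometry: fit a
stress-driven kinematic growth law to two imaging time points, predict the
third, and relate the fitted growth constants to outcome across a cohort
with right-censored lifespans.

The package is aimed at cardiovascular biomechanics work on murine
aneurysm models (e.g. fibulin-4 smooth-muscle knockouts, which develop
ascending aortic aneurysms), where serial scans of the same vessel exist
but raw imaging data are rarely shareable — so every stage can also be
exercised end to end on synthetic longitudinal geometries with known
ground truth.

## The model

Wall stresses come from a desk-scale surrogate of a fluid–solid
interaction simulation: a three-element Windkessel (RCR) bank converts a
periodic inflow into a mean pressure p; Laplace's law for the thin wall
gives σ_θθ = p·r/h and σ_ss = p·r/(2h); Poiseuille flow with
Carreau–Yasuda shear-thinning viscosity gives τ_w = μ(γ̇)·γ̇ with
γ̇ = 4Q/(πr³).

Growth is anisotropic kinematic growth with stress homeostasis
(Alford–Taber form), per ring element:

    dλ_gr/dt = (1/T_r) (σ_θθ/σ̂_θθ − 1) λ_gr
    dλ_gθ/dt = [(1/T_θ)(σ_θθ/σ̂_θθ − 1) + (1/T_τ)(τ_w/τ̂_w − 1)] λ_gθ
    dλ_gs/dt = (1/T_s) (σ_ss/σ̂_ss − 1) λ_gs

with G = diag(λ_gr, λ_gθ, λ_gs) and the deformation split F = F_e·G.
Geometry is summarised by 6 equally spaced rings (mean point-to-centroid
radius per ring, consecutive-centroid segment lengths), located on the
surface through a harmonic (Laplace-equation) tube parameterization:
axial coordinate s with 0/1 on the inlet/outlet loops, circumferential θ
after cutting the tube along an inlet-to-outlet shortest edge path.

Tuning minimises the chi-square misfit of the 2n−1 observables (n radii,
n−1 segment lengths) at the first follow-up over (T_θ, T_s) — or the
per-domain constants over four equal axial domains — with a
Levenberg–Marquardt iteration in log space.  Validation compares the
120-day prediction with the second follow-up via relative differences
Δr = (r_p − r_m)/r_m (interior rings 2–5) and Δl on the full length, and
against a linear projection of the first two time points.  Cohort outcome
analysis uses a Bonferroni-corrected Pearson map and Tobit censored
regression of lifespan (cutoff 25 months) with the McKelvey–Zavoina
pseudo-R².

## Worked example

```python
from vesselgrow.pipeline import run_tuning, run_validation
from vesselgrow.synthetic_cohort import (
    StudyConditions, TubeSpec, generate_longitudinal_geometries)

cond = StudyConditions()          # 90 mmHg, E = 722 kPa, nu = 0.44
tube = TubeSpec()                 # r = 0.6 mm, L = 3 mm vessel segment
meshes, truth = generate_longitudinal_geometries(
    tube, cond, T_theta=150.0, T_s=300.0, noise=0.0, seed=0)

rep = run_tuning(meshes[0], meshes[1], cond)
print(rep.fit.T_theta, rep.fit.T_s)       # 150.000..., 300.000...
val = run_validation(meshes[0], meshes[1], meshes[2], rep, cond)
print(val.metrics.mean_delta_r)           # ~ -1e-14 (perfect-model world)
print(val.baseline_abs_error)             # 0.0297
```

The fitted constants match the generating ones to machine precision on
noiseless input, the 120-day prediction has essentially zero radius error,
and the linear projection of the first two time points is off by ~3 % —
growth is super-linear, so straight-line extrapolation under-predicts.

The same workflow over a noisy 10-subject cohort is scripted under
`analysis/` (run in order):

```sh
python analysis/01_generate_cohort.py --seed 1
python analysis/02_tune_validate.py  --seed 1
python analysis/03_multidomain_comparison.py --seed 1
python analysis/04_correlate_outcomes.py
```

With 0.01 mm surface noise and independent remeshing between time points,
script 02 prints a median recovery error of 1.8 % for T_θ and 0.5 % for
T_s, and a validation radius error of 0.44 ± 0.27 % versus 5.6 ± 3.4 %
for the linear baseline (the model wins in 10/10 subjects).  Script 03
shows the four-domain fit beating uniform growth (nested F-test rejects
in 100 % of noise replicates); script 04 reports positive
lifespan–(T_θ/σ̄_θθ) association from the Tobit fit.

There is also a thin CLI over the same functions:
`vesselgrow synth|tune|validate|correlate|all`.

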