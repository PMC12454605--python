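# Methods

## Scope and overall design

The package analyses longitudinal tubular vessel geometry with a
stress-driven kinematic growth model.  The workflow has three stages:

1. **Tuning** — measure the vessel at a baseline and a first follow-up
   (60 simulated days apart, i.e. 2 months at 30 days/month), run the
   growth model forward from the baseline and fit the circumferential and
   axial growth time constants so the predicted ring observables match
   the follow-up.
2. **Validation** — run the fitted model for 120 days and score the
   prediction against a second follow-up.
3. **Outcome correlation** — across a cohort, relate the fitted constants
   (and the driving ratio T_θ/σ̄_θθ) to lifespan and other covariates
   with a Pearson map and Tobit censored regression.

A full 3-D fluid–solid interaction / finite-element treatment is
deliberately replaced by a 0-D + thin-wall surrogate.  The growth law
consumes only three scalars per element (σ_θθ, σ_ss, τ_w), and for a
vessel whose wall is thin relative to its radius those are well
approximated by lumped hemodynamics plus Laplace's law.  This is the
package's central modelling decision; its consequences are listed under
*Limitations*.

## Hemodynamic surrogate

**Windkessel.** Each outlet is a three-element RCR circuit,
dPc/dt = (Q − Pc/Rd)/C with P = Q·Rp + Pc, integrated by RK4 to periodic
steady state (last-two-period mean drift < 0.1 %).  At steady state the
period-mean pressure is mean(Q)·(Rp+Rd), independent of C; this identity
is used as a solver check.  The default outlet bank (left subclavian,
left common carotid, brachiocephalic trunk, distal aorta) stores
compliance in mm³/Pa — the unit the RCR ordinary differential equation
requires for the printed numeric values.  The inflow waveform is a
parameterized parabolic-systole pulse (period 0.1 s ≈ 600 bpm, systolic
fraction 0.35); its mean is the calibrated quantity, back-computed so the
parallel outlet bank sits at 90 mmHg mean pressure (~114 mm³/s).  That
mean flow is a calibration, not a measured datum.

**Wall stresses.** σ_θθ = p·r/h and σ_ss = p·r/(2h) (capped thin-walled
cylinder).  Wall shear uses the Poiseuille wall shear rate γ̇ = 4Q/(πr³),
which for a parabolic profile does not depend on viscosity, so the
Carreau–Yasuda effective viscosity is a direct evaluation
τ_w = μ(γ̇)·γ̇ (no fixed-point iteration is needed).  Carreau–Yasuda
parameters default to standard whole-blood literature values
(μ0 = 0.056 Pa·s, μ∞ = 0.00345 Pa·s, λ = 1.902 s, a = 1.25, n = 0.22),
fully configurable.

**Elastic wall.** The material is compressible Neo-Hookean
(W = μ/2(I1−3) − μ ln J + λ/2(ln J)², Lamé constants from E and ν with
ν = 0.44).  The energy form is implemented verbatim for evaluation and
testing; the inflation used inside the growth loop is the incompressible
thin-membrane simplification with the axial stretch held at 1:
μ(λ² − 1/λ²) = p λ² R/H, solved by bracketed root finding (the closed
form λ = (μ/(μ − pR/H))^¼ serves as an independent oracle in the tests).
A root exists only below the limit-point pressure p < μH/R; exceeding it
is reported as an error naming the bound.  Note that with this form
σ_θθ = μ(λ² − 1/λ²) = p·r_loaded/h_loaded, so the inflation and the
Laplace-law stress evaluation are mutually consistent.

## Growth model

Growth stretch ratios (λ_gr, λ_gθ, λ_gs) per ring element follow the
stress-homeostasis laws given in the README; the growth tensor is
diagonal in the local (radial, circumferential, axial) frame, and
F = F_e·G.  Homeostasis (all stresses at target) is an exact fixed point.
The wall-shear term is off by default (T_τ = ∞) because its target is
not identifiable from geometry alone; it can be enabled via
configuration.

**Targets.** Homeostatic targets default to the baseline stress state
scaled by a target fraction of 0.9, so the baseline is growth-positive —
the positive-feedback situation of an aneurysmal wall, where rising
radius raises Laplace stress which accelerates growth.  The trajectory's
growth increments are therefore strictly increasing, which the tests
assert.

**Time stepping.** Explicit Euler at dt = 10 days (the loop granularity
of the workflow), with optional substeps; positivity of the stretches is
checked after every step.  Against the closed-form exponential solution
for a frozen stress ratio, Euler at 1-day substeps stays within 0.1 %
over 120 days, with the expected first-order halving of the error as the
step is halved.

**Geometry update.** Instead of a finite-element equilibrium solve with
residual stresses, each step scales the unloaded ring radii by the
circumferential growth increment, each segment length by the pair-mean
axial increment, and the (uniform) thickness by the ring-mean radial
increment, then re-inflates to the loaded configuration for the next
stress evaluation.  Residual stresses between rings are therefore not
represented.  Imposed end-ring displacements (linear in time between the
measured end positions) translate the inlet/outlet rings only.

T_r is fixed (default 500 days), not fitted: thickness changes are not
observable in the geometry data the pipeline consumes.

## Mesh measurement

**Parameterization.** The axial coordinate solves the Laplace equation on
the surface (cotangent-weight finite elements, Dirichlet elimination,
sparse direct solve) with 0/1 on the inlet/outlet boundary loops; the
circumferential coordinate solves the same problem after the tube is cut
open along the shortest edge-graph path from inlet to outlet (a graph
approximation of the geodesic — topologically exact, metrically within
one edge length, which is all seam placement needs).  Cut vertices are
duplicated into two seam banks (0 on one, 1 on the other) and θ is taken
modulo 1.  On the regular reference cylinder both fields reproduce the
analytic coordinates to machine precision, because linear functions on
the isometrically unrolled triangulation are exactly discrete-harmonic.

**Rings.** Ring j collects vertices whose axial coordinate falls in a
half-open band centred at j/(n−1), default n = 6.  The band width is a
fifth of the ring spacing rather than the full spacing: the ring radius
is the mean point-to-centroid distance, so any axial scatter of the
selected points inflates it (a full-width band biases the reference
cylinder's radius by ~4 % and drags end-ring centroids inward; the narrow
band restores both to well under 0.5 %).  Band width is configurable;
an empty band raises an error suggesting a wider band or finer mesh.
Ring points are mesh vertices (no iso-contour resampling); centroids are
unweighted vertex means.

**Cross-time mapping.** Vertices of one time point map to the nearest
(s, θ) vertex of another with periodic θ distance, evaluated exactly in
chunks.  Because both meshes are measured through the same ring bands,
systematic parameterization bias largely cancels in growth ratios.

## Fitting

The observation vector is n ring radii followed by n−1 segment lengths
(2n−1 entries; the ordering is this package's convention).  The cost is
χ² = Σ((obs−pred)/σ)² with σ defaulting to 0.02 mm (imaging-voxel
scale); for uniform σ the optimum location is σ-independent.
Levenberg–Marquardt with forward-difference Jacobian, Marquardt diagonal
scaling, damping ×10 up on rejection / ÷10 down on acceptance, and
stopping on relative χ² change, parameter step, or iteration cap.  Time
constants are optimized in log space (positivity is structural); initial
guesses default to 200 days.  The parameter covariance is the usual
s²(JᵀJ)⁻¹ mapped back through the delta method.

The multi-domain variant assigns separate (T_θᵏ, T_sᵏ) to four equal
axial domains (ring j at coordinate s belongs to domain ⌊4s⌋, clipped);
with 6 rings the domain occupancy is (2,1,1,2) and the 8-parameter model
remains identifiable from the 11 observables.  Model comparison uses the
nested F-test on the two SSEs, with F clipped at 0 when the full model
fails to reduce the error.

Validation metrics: Δr per ring with the mean over interior rings only
(rings 2–5 of 6; the end rings are excluded to avoid boundary bias), Δl
on the full inlet-to-outlet length, and a linear projection
r_t2 = 2·r_t1 − r_t0 as the baseline (equal time spacing).

## Outcome statistics

Pearson correlations are computed on observed values with two-sided
p-values from the t-transform (n−2 dof) and Bonferroni correction over
the number of distinct off-diagonal pairs.  Lifespan is right-censored
at 25 months (animals alive at the cutoff were euthanized), so regression
uses the Tobit model: censored-normal maximum likelihood with σ on the
log scale, analytic gradient, BFGS, standard errors from the inverse
observed information (numeric Hessian).  Goodness of fit is the
McKelvey–Zavoina pseudo-R² = S/(S + Nσ²) with S the deviation sum of the
latent predictions Xβ̂ — the latent-prediction form, which is 0 under the
null and approaches 1 as σ → 0.  The packaged 10-animal reference table
(sex, lifespan, ascending/descending modulus, tortuosity index; 4 records
censored) ships as a checksummed CSV fixture.

## Synthetic data generator

The generator emulates the statistical structure of a longitudinal
murine aneurysm imaging study, since no raw imaging data are available:

- **Geometry**: structured triangulated tubes (default radius 0.6 mm,
  length 3 mm, 64×40 grid), optional centerline curvature and a Gaussian
  aneurysm-like bulge.  Grown time points are rebuilt from the simulated
  ring-radius profile and total length; measurement noise is Gaussian
  along vertex normals (mimicking segmentation error, default 0.01 mm);
  follow-ups can be independently remeshed at different resolutions so
  the cross-time machinery does real work.
- **Study conditions**: 90 mmHg mean pressure, E = 722 kPa, ν = 0.44,
  wall thickness 0.06 mm, target fraction 0.9, scan times 0/60/120 days.
  With these, T_θ around 100–150 days yields 20–35 % radius growth over
  120 days, matching the range reported for aneurysmal mice; the severe
  end (T_θ ≈ 70 d) roughly doubles the radius.
- **Cohort**: true constants are log-normal (T_θ median 120 d, T_s median
  200 d, log-sd 0.25), truncated below at 70 days because the membrane
  surrogate has a finite limit-point pressure and faster growth runs past
  it within the study horizon.  Lifespan follows
  LS = 12 + 12·(T_θ/σ̄_θθ[kPa]) + ε, ε ~ N(0, 2.5²) months, censored at
  25 — coefficients chosen to give roughly 40 % censoring, mirroring a
  4-in-10 design.  The tortuosity covariate is generated with a negative
  dependence on T_s; moduli are log-normal around murine aortic values.
  These linkages are emulation targets, not inferences.
- Identical seeds reproduce cohorts and meshes bit for bit.

Because ring observables average ~64 circumferential vertices, the
effective observation noise is the vertex noise divided by √64
(≈ 0.00125 mm for the 0.01 mm default); that value is used wherever
ring-level observation noise is injected directly.

## What the synthetic tests do and do not show

Passing recovery and validation tests on this generator demonstrate that
the inverse machinery is correct and well-conditioned *when the forward
model is the data-generating process* (plus measurement noise, remeshing
and mild shape heterogeneity).  They do not demonstrate that the growth
law describes real aortic tissue: real vessels have non-uniform and
evolving wall thickness, residual stress, anisotropic and heterogeneous
material response, thrombus, and biochemically mediated remodeling that
no purely stress-driven law captures.  Reported per-animal error
magnitudes from imaging studies are therefore not reproduced here — only
the properties of the method itself.

## Numerical choices and degenerate inputs

- Laplace solves: sparse direct (SuperLU); singular systems (disconnected
  meshes) are reported as errors.  Harmonic fields are clipped to [0,1]
  against round-off at the 1e-15 level.
- Inlet/outlet labelling: the boundary loop with the lower mean
  coordinate along a configurable axis (default z) is the inlet.
- Shortest-path ties resolve to the lowest vertex index (deterministic).
- Two identical rings give a zero segment length (allowed); rings with
  fewer than 3 points, non-manifold surfaces, and closed surfaces are
  errors with messages naming the defect.
- Euler steps that would drive a stretch non-positive raise an error
  advising a smaller step.
- Problem sizes: the default test and acceptance runs use the 64×40
  reference tube, 6 rings, 20 noise replicates for the multi-domain
  comparison and 50 for the Tobit benchmarks — small enough to run on a
  laptop core in seconds while leaving the Monte-Carlo acceptance margins
  comfortable.

## Known limitations

- No residual stress between rings; the equilibrium step is kinematic.
- Uniform wall thickness; thickness growth affects all rings equally.
- The membrane surrogate has a limit-point pressure; very fast growth
  (T_θ below ~60 days under default conditions) reaches it within the
  120-day horizon and is outside the generator's envelope.
- The wall-shear growth term defaults off; enabling it requires choosing
  τ̂_w externally.
- Single tube topology only (no branches); conformal or area-preserving
  parameterizations are out of scope.
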