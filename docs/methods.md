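# Methods

## Problem

A thermal massage bed heats the lumbar back through two contact sources: a
diffuse heating mat at 40 °C covering the posterior surface, and four heated
actuator rollers (operating range 45–65 °C) arranged as the vertices of a
rectangle. The package answers two questions for this configuration:

1. what steady-state temperature is reached at a given tissue depth, and
2. how much does the local blood flow increase as a consequence?

## Tissue model

The computational domain is a synthetic voxelized phantom of the lower back:
a flat slab with tissue layers stacked along depth — skin (1.1 mm),
subcutaneous fat (13 mm), muscle (42 mm) and soft tissue (2.8 mm, continued
as fill to the anterior cut). The layer thicknesses are those measured by
segmentation of a lumbar MRI of a healthy adult; muscle, the presumed
massage target, occupies roughly 1.5–5.5 cm from the surface. An optional
concentric spinal-column insert (vertebra / epidural fat / CSF / cord
cylinder along the superior–inferior axis) is provided for fidelity but
disabled by default: the probe locations sit at ±6 cm laterally, several
thermal penetration lengths away from the column, so it does not affect the
reported profiles.

Voxels are classified by their center, with half-open layer intervals
`[lower, upper)`. Default domain: 300 mm (lateral) × 200 mm
(superior–inferior) × 100 mm (depth) at 1 mm isotropic spacing (the MRI
voxel size); coarser grids are used where speed matters (see *Problem
sizes*).

Per-tissue constants (conductivity k, density ρ, specific heat c, blood
properties ρ_b, c_b, perfusion rate w_b, blood temperature T_b, metabolic
rate Q_m) are literature-survey values carried by `property_table()`; blood
temperatures are converted once from Kelvin to °C (309.7 K → 36.55 °C).
CSF and the intervertebral disc are modeled perfusion-free (w_b = Q_m = 0).

## Steady bio-heat solve

Temperature obeys the steady Pennes equation

    0 = ∇·(k ∇T) + ρ_b c_b w_b (T_b − T) + Q_m .

Perfusion is implemented in the standard sink form, pulling tissue toward
blood temperature. (The source-sign variant ρ_b c_b w_b (T − T_b) renders
the steady operator indefinite at these perfusion rates and domain sizes —
no bounded solution exists — so the sink convention is the only physically
and numerically consistent reading.) The perfusion rate sets the thermal
penetration length λ = √(k/(ρ_b c_b w_b)) ≈ 17.6 mm in muscle, which
controls how fast surface heating decays with depth.

Discretization is a cell-centered 7-point finite-volume stencil; the face
conductivity between unlike tissues is the harmonic mean of their
conductivities, which preserves flux continuity across layer interfaces.
Boundary conditions:

* actuator discs and mat on the posterior surface: Dirichlet patches applied
  through half-cell ghost values (coefficient 2ks). Actuators are
  temperature patches, not meshed solids — at steady state a fixed-
  temperature contact is equivalent for the quantities reported;
* uncovered surface voxels (none under the default full-coverage mat): a
  Robin condition q₀ = h (T_amb − T) with h = 5 W m⁻² K⁻¹, T_amb = 25 °C;
* all domain cuts (lateral faces and the anterior face): Dirichlet at core
  temperature 37 °C; the four lateral faces can be switched to adiabatic,
  which turns a single-voxel column into an exact 1D configuration.

The matrix is symmetric positive definite and solved with Jacobi-
preconditioned conjugate gradients to a relative residual of 1e-8
(deterministic; no randomized components). Fine grids warm-start from a
2×-coarser solve prolonged trilinearly, and sweep settings warm-start from
the previous setting; warm starts change iteration counts only, not the
converged field.

Actuator layout: the device geometry reports a 45 mm roller diameter,
lateral actuator positions at ±6 cm and a 32 mm vertical separation; the
printed two-lobed roller dimensions (65/45/30 mm) are mutually
inconsistent, so each actuator is modeled as a single 45 mm contact disc at
(±60, ±16) mm. With those centers each vertical pair of discs overlaps
(32 mm < 45 mm) and merges into one two-lobed footprint — a deliberate
approximation of the roller, reported as a warning rather than an error
since all discs share one Dirichlet value. Discs clipped by the domain edge
are an error.

### Verification

Two independent oracles validate the solver (tests and
`analysis/04_verify_solver.py`):

* **Perfused-slab closed form.** In 1D the steady Pennes equation has the
  solution T_p + C₁e^{x/λ} + C₂e^{−x/λ} with T_p = T_b + Q_m/(ρ_b c_b w_b).
  A 0.5 mm single-voxel column solved through the full 3D assembly path
  agrees with it to L∞ < 10⁻³ °C (tolerance 0.05 °C).
* **Manufactured solution.** A trigonometric field with its implied source
  on a homogeneous cube converges at observed order 2.0 (threshold 1.8)
  over spacings 4/2/1 mm.

Invariants asserted in the suite: discrete maximum principle on randomized
label grids (Q_m = 0), monotonicity of the field in the actuator setting,
x-mirror symmetry of symmetric scenes, and interpolation convexity of
extracted profiles.

## Circulation transfer model

Blood flow is mapped from the local temperature elevation ΔT by a logistic
transfer function

    F(ΔT) = F_o + (F_max − F_o) / (1 + e^{aΔT + b}),

bounded between a baseline flow F_o and a maximal flow F_max. The model is
calibrated to five simultaneous measurements of deep-muscle temperature and
central femoral artery flow in the leg during passive heat stress
(packaged in `thermassage/data/leg_heat_stress_calibration.csv`):
(34.9, 0.31), (36.2, 0.53), (37.0, 0.86), (37.6, 1.24), (38.3, 1.22)
(°C, L/min). F_o = 0.31 is the minimum measured flow and F_max = 1.22 the
flow at the highest temperature; these are assigned, not refit. The free
parameters are obtained by deterministic least squares over
ΔT = T − 34.9 °C (the lowest measurement is the unheated reference for the
leg data) from a fixed multistart grid; the fit lands at a = −2.68 per °C,
b = 4.88 with SSE = 0.016 (L/min)².

An unbounded exponential variant F_o + (F_max − F_o)e^{−(aΔT + b)} of the
same expression is sometimes written down; it is monotone *increasing
without bound* and cannot be sigmoidal — at (a, b) = (−2.67, 4.88) it
exceeds F_max for ΔT ≥ 2.1 °C and misses the calibration data by three
orders of magnitude in SSE. `form_resolution_oracle()` fits and tabulates
all three candidates (logistic / unbounded / clamped exponential) as
documented evidence for the logistic default; the alternatives remain
selectable in the config.

When predicting back circulation, ΔT is taken relative to the 37 °C core
baseline (a uniform reference field). Flow is evaluated voxelwise; since
the calibration flow is a whole-limb arterial quantity, voxel values are
model outputs indicating the local perfusion state, and the robust summary
is the fold-change F/F_o, which saturates at F_max/F_o ≈ 3.94.

## Profiles and sweep

Profiles sample fields by trilinear interpolation on voxel centers: depth
profiles anteriorly from the surface at a fixed anchor, lateral profiles
across the back at fixed depth. The standard probes are (i) the vertical
line through one actuator centroid (+60, +16) mm — a single centroid rather
than a pair average, for determinism; (ii) the midline (0, 0), the center
of the actuator rectangle; (iii) lateral lines at 20 and 30 mm depth at the
actuator-pair y. The sweep solves 45–65 °C in 5 °C steps, reusing one
assembled matrix.

## Problem sizes

Production runs (and `scripts/acceptance.py`) use the 1 mm grid
(300×200×100 ≈ 6·10⁶ unknowns; a scene solves in ~1–2 minutes on one CPU).
The test suite exercises the same scenes at 2 mm and invariants at 4 mm;
the 2 mm and 1 mm grids agree to ≈0.1 °C at every standard probe, so the
coarser grids are used wherever many solves are needed.

## What the phantom does and does not capture

The phantom reproduces the layered composition, thicknesses and thermal
constants of the imaged anatomy, and the device's source layout and
boundary temperatures. It does not capture the curved, contoured back
surface, the indentation of the 1 cm-tall rollers into soft tissue, or
heterogeneous structures lateral to the probes. Consequences observed with
this package: the circulation model and every solver invariant reproduce
the reference behavior exactly, and the midline probe matches the reported
38.3 °C (2 cm, 65 °C setting) within 0.5 °C; directly under the actuators,
however, the flat-slab phantom heats less than the contoured anatomy
(e.g. 41.7 °C vs 45.5 °C at 2 cm for the 65 °C setting — the flat 45 mm
disc presents a smaller effective contact than an indenting roller, whose
1D full-coverage limit would give ≈48 °C at that depth). Passing tests
therefore demonstrate correct physics and coupling on the surrogate
geometry, not per-probe equivalence with a subject-specific model.

## Numerical choices and degenerate inputs

* Tolerances: CG relative residual 1e-8 (options validated to (0,1));
  fit convergence 1e-10 on parameter change; ties in the multistart broken
  by grid order.
* Voxel classification tie-break: half-open intervals, voxel-center
  membership; extents round up to whole voxels.
* Degenerate calibration data (fewer than 3 points, duplicate temperatures,
  all flows equal) raise before optimization; logistic exponents are
  clipped at ±500 to avoid overflow, far outside any physical ΔT.
* Non-convergent solves raise with the final relative residual; sweeps
  record per-setting failures and continue.

## Known limitations

Steady state only (no transients, no pulsed protocols); no mechanical
deformation or roller motion; no tissue-damage metrics; perfusion w_b is
fixed — predicted flow does not feed back into the heat equation; flat
surface geometry as discussed above.
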