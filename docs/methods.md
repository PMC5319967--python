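# Methods

`fetallv` simulates passive mechanics and strain-driven growth of an
idealised human fetal left ventricle (LV) between mid-gestation (22 weeks)
and term (40 weeks), and uses the calibrated reference model for
patient-specific growth prediction from echocardiographic dimensions and
for scenario experiments (reduced ventricular filling, altered shape).
This note records the model, its numerical treatment, the calibrations,
and the design choices made where the design was genuinely open.

## Geometry and discretisation

The LV is a thick-walled truncated prolate spheroid, axisymmetric about its
long axis. In prolate spheroidal coordinates with focal length `d`,

    x = d cosh(λ) cos(μ),   (y, z) = d sinh(λ) sin(μ) (cos φ, sin φ),

with `μ = 0` at the apex; the endocardial and epicardial surfaces are
surfaces of constant `λ` truncated by a common base plane normal to the
long axis at `μ_base = 120°`. Clinical dimensions map to ellipsoid
parameters in closed form: the inner long semi-axis is
`a = LA / (1 − cos μ_base)`, the focal length `d = sqrt(a² − (SA/2)²)`, and
the epicardial `λ` follows from the equatorial wall thickness.

The mesh is the 30-node / 20-element reference topology (5 longitudinal ×
4 transmural × 1 circumferential element) with cubic-Hermite interpolation
in the longitudinal and transmural directions and linear interpolation
circumferentially. Every nodal scalar carries four degrees of freedom
(value, two first derivatives, mixed derivative) with respect to global
parametric coordinates, which makes the geometry C¹-continuous across
elements by construction. Because the model is axisymmetric and the
diastolic loading with the stated boundary conditions excites no torsion,
the solver's unknowns are the meridian-plane fields `R(ξ₁, ξ₂)` and
`Z(ξ₁, ξ₂)` only; the circumferential sweep is handled analytically (the
energy integrand is φ-independent, so 3-point Gauss quadrature in φ and
the analytic factor 2π coincide). Torsional deformation is therefore not
representable — an acceptable restriction for passive inflation, which is
the only load case simulated. At the apical pole the axis nodes carry the
exact pole conditions `R = 0`, `∂R/∂ξ₂ = 0`, `∂Z/∂ξ₁ = 0`.

Cavity volume is the solid-of-revolution integral `π ∫ R² (−∂Z/∂ξ₁) dξ₁`
along the endocardium (the base plane contributes nothing); wall volume is
the in-plane quadrature of the swept volume element. Both agree with
independent closed-form ellipsoid integrals to better than 0.1% (tested).
The long axis is the inner apex-to-base distance, the short axis the
maximal inner diameter, and the wall thickness is measured at the
equatorial level as the difference of maximal outer and inner radii (the
measurement site is a package choice; the equator is where clinical
short-axis measurements are made).

Myofiber orientation follows the rule-based helix: the in-plane angle
relative to the circumferential direction varies linearly across the wall
from +83° (endocardium) to −37° (epicardium). The local frame (fiber `f`,
cross-fiber-in-wall `c`, radial `r`) is orthonormal and right-handed at
every quadrature point.

## Passive material and incompressibility

The myocardium is incompressible and transversely isotropic with the
exponential (Fung-type) strain energy

    W = C/2 (exp(Q) − 1),
    Q = b_f E_ff² + b_t (E_cc² + E_rr² + 2 E_cr²) + b_fs (2 E_fc² + 2 E_fr²),

in fiber-frame Green–Lagrange strain components. The exponent coefficients
are held at the widely used adult-literature ratios
(b_f = 18.48, b_t = 3.58, b_fs = 1.627); only the stress scale `C` is
calibrated (a single (EDP, EDV) pair identifies a single scale, and the
source for fetal-specific exponents does not exist). Strains with
`Q > 200` raise a nonphysical-strain error.

Incompressibility is enforced weakly by a discontinuous hydrostatic
pressure field per element — constant plus linear terms in the two local
coordinates, with quadratic enrichment in the apical element row where the
pole concentrates the pressure variation — acting as Lagrange multipliers,
augmented by a volumetric penalty `κ/2 (J − 1)²` with `κ = 250 kPa`
(4 × stiffer in the apical row). The augmented-Lagrangian structure keeps
every inner solve a well-behaved minimisation; see below.

Numerical limits: at the calibrated 22-week reference end-diastolic state
the pointwise `|det F − 1|` is below 10⁻³ at all 3×3×3 quadrature points.
At strongly grown late-gestation meshes the apical elements reach ≈ 2×10⁻³:
the bicubic meridian displacement space cannot represent a pointwise
isochoric deformation in the distorted apex, and raising the augmentation
only locks the elements. The weak (projected) constraints are satisfied to
< 0.01 kPa at all ages; pointwise deviations in grown configurations stay
well within the penalty-mode band of 10⁻².

## Equilibrium solves

The total potential is

    Π = ∫ [W(E_e) + κ/2 (J_e − 1)² − p(ξ)(J_e − 1)] dV₀ − p_cav V_cav(u),

where `p(ξ)` is the multiplier field and the cavity pressure, although a
follower load, is conservative for a uniform pressure on the closed
endocardium-plus-base surface, with potential `−p_cav V_cav`. Boundary
conditions: the apex slides along the long axis, the base plane is fixed
longitudinally, and the basal epicardial circumferential constraint is
implied by the no-twist kinematics. An alternative anchoring (apex held,
base free longitudinally) is available as a configuration option.

Each solve nests three layers:

1. **Inner modified Newton** on the displacements at fixed multipliers —
   a minimisation of the augmented potential, safeguarded by an Armijo
   backtracking line search on the energy and an element-inversion guard.
   The Jacobian (forward finite differences of the analytic residual, all
   columns in one batched evaluation) is factorised in the first iteration
   of a load step, reused while contraction is strong, and refreshed when
   the iteration diverges — the modified Newton–Raphson policy.
   Convergence requires both the sum of incremental displacements below
   10⁻³ mm and the sum of residual forces below 10⁻⁵ N.
2. **Augmented-Lagrangian outer updates** project the pointwise penalty
   pressure onto the multiplier basis (a weighted L² projection through
   the basis Gram matrix) and absorb it into the multipliers.
3. **Joint saddle Newton polish** on displacements and multipliers
   together, started once the state is near-converged; the coupling blocks
   of its Jacobian are the constraint gradients (computed in the same
   batched evaluation), and it terminates at a path-independent state with
   multiplier corrections below 10⁻³ kPa.

Loading is incremental (5 steps by default, spaced as `(i/n)^1.5` so that
the soft toe region of the exponential material receives the smallest
increments) with automatic step halving on non-convergence. Warm starts
(previous solution plus a multiplier correction that cancels the warm
state's volumetric misfit) let the weekly growth-loop inflations converge
in a handful of iterations.

The residual is the exact gradient of Π (verified against central finite
differences of the energy to < 10⁻⁵ relative in the tests).

### Unloaded-state estimation

The unloaded configuration of a measured end-diastolic geometry is found by
the backward-displacement fixed point: subtract the computed displacement
field from the target geometry, re-inflate, and repeat until the
end-diastolic mismatch falls below the displacement tolerance (inner
inflations are solved 5 × tighter than the outer tolerance so the fixed
point is not noise-limited).

## Growth law

Growth is kinematic and multiplicative: `F = F_e F_g` with a growth tensor
diagonal in the fiber frame, `F_g = diag(F_ff, F_cc, F_rr)`, and
transversely isotropic (`F_cc = F_rr`). Stimuli derive from end-diastolic
strains (only diastole is simulated, so the cycle-maximal strain is the
end-diastolic strain): the fiber branch (series sarcomere addition,
predominantly circumferential growth) responds to `E_ff`; the transverse
branch (parallel addition — longitudinal and wall-thickness growth) to the
maximal principal strain of the cross-fiber block
`[[E_cc, E_cr], [E_rc, E_rr]]` (using `E_cc` alone is available as an
option). Each branch follows a saturating sigmoid per week:

    ΔF = 1 + Δt · f_max / (1 + exp(−k (s − s₅₀)))   for stimulus s > 0,
    ΔF = 1 otherwise (dead band),

with per-step component limits. Defaults and their provenance:

| parameter | default | rationale |
| --- | --- | --- |
| setpoints `e_set` | 0 strain | any positive end-diastolic strain stimulates growth; sustained loading at constant EDP then drives the continuing growth observed in gestation |
| sigmoid slope `k` | 30 per unit strain | order of magnitude of strain-based growth laws; fixed a priori |
| half-activation `s₅₀` | reference-model mean ED strain per branch (≈ 0.08–0.10) | half-maximal activation at the reference operating point, set during calibration |
| rate scale `f_max` | calibrated (≈ 0.066/week) | adjusted so the terminal EDV matches the normative trajectory — the same quantity the original workflow tuned |
| transverse/fiber ratio | 1 (equal branch maxima) | neutral prior; no independent constraint identifies it (see the shape discussion below) |
| time step | 1 week | gestational sampling of the clinical trajectories |

After each weekly increment the grown (generally incompatible) point-wise
growth field is resolved into a new smooth reference configuration by an
elastic equilibrium solve at zero external load with `F_e = F ΔF_g⁻¹`
(continuation in the growth exponent handles strongly incompatible
increments; a similarity predictor with volumetric multiplier
initialisation starts Newton close). Residual stresses are then discarded
— the grown configuration is treated as the new stress-free reference,
consistent with neglecting residual stress throughout. Incompressibility
of the elastic part makes the wall-volume change equal the volume integral
of `det ΔF_g` (verified to < 1% each step). Reverse-in-time growth inverts
the increment (`ΔF → 1/ΔF`).

### Calibrations

The reference model is constrained by mid-gestation clinical statistics:
median EDP 5.63 mmHg (0.75 kPa — the two are used interchangeably), median
EDV 1.02 mL, end-diastolic dimensions 18 mm × 9 mm, and a filling volume
(EDV − V₀) of 383 µL at the reference preload, which fixes the unloaded
cavity volume at 637 µL. Three nested calibrations:

1. **Unloaded shape.** The unloaded LA:SA ratio is refined (secant, ≤ 6
   steps) so the *end-diastolic* ratio equals the clinical 2.0; the
   closed-form dimension update preserves V₀ = 637 µL exactly. (Inflation
   widens the ventricle, so the unloaded ratio ends slightly above 2.)
   The unloaded wall thickness is held at 3.0 mm, mid-range of fetal
   morphometry at 22 weeks.
2. **Passive stress scale.** `C` is adjusted (secant on log C) until
   inflation to the median EDP reproduces the median EDV within 0.5%.
3. **Growth rate.** The overall rate scale is calibrated (secant on the
   log scale) so the simulated 40-week EDV matches the normative curve
   (exponential through 1.1 mL at 22 weeks and 8.3 mL at 40 weeks).
   Terminal long- and short-axis values are *not* fitted; they emerge
   from the calibrated model. All constants are then frozen for every
   scenario and patient simulation.

### The shape of simulated growth

With the steep sigmoid the growth field concentrates where end-diastolic
strains are largest — the endocardial equator, where both the fiber
direction (near-longitudinal fibers carry little stretch there, but their
cross-fiber partner is circumferential) and the transverse principal
strain point circumferentially. The simulated ventricle therefore
sphericalises over gestation: the terminal aspect ratio falls from ≈ 2 to
≈ 1.1 while the volume trajectory is reproduced. Systematic experiments
(documented in the development history) show no transverse-to-fiber rate
ratio restores proportional growth at fixed terminal volume — raising the
ratio mainly thickens the wall — and a shape-preserving configuration
exists only with a saturated, strain-insensitive law, which would
eliminate the filling-volume sensitivity that is the model's central
result. The published fetal growth constants that evidently balanced the
two behaviours are not available, so this implementation prioritises
strain sensitivity and reports terminal dimensions as a known bias
(long axis under-, short axis over-predicted by roughly a quarter).

## Scenario experiments and patient pipeline

*Filling sensitivity.* The reference unloaded mesh is inflated to the EDP
that yields a filling volume reduced by 10–30% (secant on log pressure),
then grown to term at that constant EDP with frozen constants. Outcomes
are percent changes of 40-week cavity and wall volume relative to the
reference run; linear slopes per 10% filling reduction are
ordinary-least-squares through the origin (the zero-perturbation scenario
is the origin by construction).

*Shape sensitivity.* Wall-thickness variants (±10%, ±30%) move the
epicardial surface only; aspect-ratio variants (±10%, ±20%) rescale LA:SA
at exactly preserved unloaded cavity volume (cavity volume ∝ LA·SA² at
fixed truncation, so the size factor is closed-form). Variants are loaded
either at constant preload (0.75 kPa; the default for reported slopes) or
at constant filling volume (383 µL), grown with frozen constants, and
summarised as slopes of % cavity-volume change per +10% shape change.

*Patient pipeline.* Six-planar echo dimensions (inner/outer widths at base
and mid level, inner/outer lengths) are fitted by least squares over the
truncated-ellipsoid family (inner LA, inner SA, WT free; residuals
reported per measurement). The fitted end-diastolic mesh is unloaded under
the normal material and normal preload — patient-specific pressures are
not identifiable from geometry alone — and grown to the target age with
the frozen reference constants. Severity is reported as predicted EDV
relative to the normal trajectory (percent-of-normal), not as a diagnostic
classification.

## Synthetic data

The generators emulate the two clinical inputs: echo measurement sets are
measured from known ground-truth meshes with multiplicative Gaussian noise
(default 5%, the scale of intra-observer variability in fetal echo), and
candidate-geometry tables sample the seven constraining parameters
uniformly within clinical ranges bracketing the 22-week medians, with
reference means/SDs attached (range midpoints, quarter-span SDs). They
reproduce the *structure* of the clinical inputs, not their covariances:
real echo errors are correlated across dimensions and real candidate sets
were constructed, not sampled. Passing recovery tests on synthetic data
therefore demonstrates the correctness of the fitting machinery, not
clinical measurement robustness. Generation is deterministic per seed.

The packaged per-candidate z-score table carries the printed scores of the
24 idealised geometries so the ranking stage is testable bit-exactly; one
row of the published cumulative column is internally inconsistent with its
own per-parameter scores (candidate 16, Δ = 0.88) and is asserted at the
recomputed value.

## Problem sizes and runtimes

All simulations use the 20-element reference mesh with 3×3×3 Gauss points.
A full 22→40-week growth run is 19 inflation solves plus 18 grown-state
solves (≈ 40 s on one CPU); the complete reference calibration performs
about a dozen such runs, and the two sensitivity experiments add 12 more.
The acceptance script runs the whole set in roughly a quarter of an hour.

## Known limitations

- Axisymmetry and the no-twist kinematics exclude torsion and regional
  wall-motion abnormalities; the right ventricle and septal interaction
  are absent.
- Only passive diastole is modelled: no active tension, no
  pressure–volume cycle, no fetal circulation coupling.
- Growth is hypertrophic strain-driven kinematics only; hyperplasia,
  hormonal regulation, and stress-driven laws are out of scope.
- Residual stresses are discarded after each growth step.
- The pointwise incompressibility of strongly grown apical elements is
  limited by the displacement discretisation (see above).
- Patient predictions inherit the normal-material, normal-preload
  assumptions; neither is patient-identifiable from the available inputs.
- Quantitative sensitivity biases follow from the sigmoid operating range
  (see "The shape of simulated growth"): the terminal-volume response to a
  25% filling reduction computes to ≈ 51% (reported: 65%), and the
  wall-thickness sensitivity of birth cavity volume is ≈ 3× steeper than
  reported, in both loading modes. The wall-volume reduction, the filling
  slope, the aspect-ratio slope and all ordinal relations (thin > thick,
  ShortWide > TallNarrow, monotonicity in filling) are reproduced.
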