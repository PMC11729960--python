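# Methods

## Scope and intent

`porolung` is a deliberately reduced-order realization of organ-scale
poro-hyperelastic lung inflation. The full problem — a contact-resolved 3D
finite-element lung with hundreds of thousands of elements, embedded airway
beams and membrane pleura — is replaced by patchwise spherical compartments
that keep the same constitutive laws, the same pressure–flow coupling
structure, the same measurement model (20 PV pairs + 30 lobe strain
statistics) and the same calibration protocol. Everything the inverse
pipeline sees is therefore faithful in *form*; the geometry is not. All
validation is consequently property- and recovery-based (closed-form
limits, oracle derivatives, ground-truth synthetic experiments), never
field-matching against a meshed organ.

## Constitutive models

**Parenchyma (compressible foam).** One-term hyperfoam energy in principal
stretches with coupled deviatoric/volumetric response,
U = (2μ/α²)[Σλᵢ^α − 3 + (1/β)(J^(−αβ) − 1)], β = ν/(1−2ν). The principal
Cauchy stresses have the closed form σᵢ = (2μ/(αJ))(λᵢ^α − J^(−αβ)), which
is continuous across β = 0. Numerical care:

* the volumetric term is evaluated as `expm1(−αβ ln J)/β`, which is exact
  as β → 0 and avoids catastrophic cancellation for small ν;
* at |β| < 10⁻¹⁰ the analytic limit −α ln J replaces the quotient, so
  ν = 0 — a bound of the calibration box and a physically meaningful
  choice for air-filled parenchyma — never divides by zero;
* ν = 0.5 is rejected at construction (β diverges; the skeleton would be
  incompressible and the pore space could not change volume).

**Airways (Neo-Hookean).** U = C₁₀(Ī₁ − 3) with the compressibility
parameter D interpreted as follows: D = 0 means *analytically
incompressible* — all responses are evaluated on isochoric paths and no
volumetric penalty term is ever formed. In the reduced model the embedded
airway tree is collapsed to a uniaxially loaded volume fraction
(`airway_fraction`, fixed at 0.02); at zero fraction the model degrades
gracefully to parenchyma + pleura.

**Pleura (reduced polynomial membrane).** U = ΣᵢC_{i0}(Ī₁−3)ⁱ, assumed
incompressible, thickness 0.06 mm. The baseline coefficients are the
package's own pooled fit to equibiaxial data: the first coefficient is
pinned by the published baseline initial shear modulus 2C₁₀ = 2.4 kPa
(C₁₀ = 1.2 kPa), and the second, C₂₀ = 6.0 kPa, was chosen once so that
the membrane's tangent stiffness grows steeply beyond ≈ 40 % equibiaxial
strain — the "bilinear", near-inextensible shape reported for pleural
tissue. Per-lung adaptation multiplies every coefficient by one scale
λ_pleura ∈ [10⁻⁶, 3]. The equibiaxial nominal stress is
P(λ) = 2(λ − λ⁻⁵) Σᵢ i·C_{i0}(Ī₁−3)^(i−1) with Ī₁ = 2λ² + λ⁻⁴; it equals
half the derivative of the energy along the equibiaxial path (two in-plane
directions work in parallel), which the tests verify numerically.

**Convexity check.** Membrane stability is assessed numerically: the 2×2
Hessian of the membrane energy with respect to the in-plane
Green–Lagrange components (incompressible kinematics, λ₃ = 1/(λ₁λ₂)) is
evaluated by central differences (step 10⁻⁵) on a default 50×50 grid over
λ ∈ [0.7, 2.0]; the verdict is "convex" iff the smallest eigenvalue is
≥ −10⁻⁹·max|H| at every grid point, and the worst point is reported.

**Biaxial fitting.** The model is linear in the coefficients, so fitting
pools all sample curves and solves one linear least-squares problem
(nominal strain ε → stretch λ = 1 + ε). Pooling coincides with fitting the
averaged curve when every sample contributes the same strain grid, and is
robust to unequal curve lengths — a deliberate divergence from
average-then-fit.

## Forward model

Each lobe ℓ with volume fraction fℓ becomes `n_patches` parallel spherical
compartments of equal initial volume fℓ·V_total/n_patches and equivalent
radius r₀ = (3V₀/4π)^(1/3). A patch at volume V has isotropic stretch
λ = (V/V₀)^(1/3) and recoil pressure

p_rec(λ) = σ_foam(λ) + airway_fraction·2C₁₀(λ − λ⁻²) + 2t₀P_b(λ)/(r₀λ²),

the three terms being the isotropic foam Cauchy stress, the uniaxial
airway surrogate and the Laplace pressure of the pleural membrane. Filling
follows

dV/dt = flow_gain · 4π r₀ λ · k_eff · (p_tr(t) − p_rec(λ)) / p_ref,

where 4πr₀λ is the conductance of a sphere with the pressure gradient
spread over one current radius, k_eff is the lobe permeability times the
patch's lognormal multiplier (median 1, σ = `heterogeneity_sigma` = 0.3,
drawn once per patch from the experiment seed), and p_ref = 1 kPa.

**Unit closure (`flow_gain`).** Permeabilities are carried in their
conventional 10⁻³ mm²·s⁻¹ scaling so all calibrated parameters are
O(0.1–100), but a kPa-normalized Darcy law in these units is not
dimensionally closed: taken literally it would fill a 2.4 L lung by less
than a millilitre per breath. The package closes the units with a single
fixed dimensionless conductance gain, `flow_gain` = 10⁵, chosen once so
that compartment filling time constants are a fraction of the 2 s breath
for mid-range permeabilities — the regime in which a 2.1 kPa ramp produces
organ-scale added volume (≈ 1.7 L at the default truth, the same order as
the ≈ 0.9 L measured on the donor protocol this emulates). The gain is a
model constant, never calibrated, and patch count matters: splitting a
lobe n ways scales total conductance by n^(2/3), so `n_patches` is held at
20 for all study conditions.

**Heterogeneity.** The lognormal patch multipliers stand in for
distributed local pressure application and sub-lobar tissue variability;
they are what gives the per-lobe strain standard deviations their nonzero
targets. σ is a fixed model constant so the calibrated space stays at nine
quantities.

**Integration.** The patch ODEs (independent given the shared ramp) are
integrated jointly with LSODA, relative tolerance 10⁻⁶ and absolute
tolerance 10⁻⁹ mL, on a uniform output grid (≥ 50 steps; 100 in all study
conditions). Corners of the parameter box with near-instant filling are
stiffer than LSODA tolerates; the integrator falls back to BDF before
reporting failure. An auxiliary state accumulates total inflow so that
volume conservation (Σ ΔV_patch = ∫Σq dt) is checkable; it holds to
integrator precision. Within calibration the regenerated simulation uses
rtol 10⁻⁹ (recorded in the experiment's provenance) so forward-difference
Jacobian columns of weakly contributing parameters stay above integrator
noise.

**Outputs.** 20 PV pairs uniform in time over the ramp (added volume
zeroed at t = 0); per-lobe mean and *population* standard deviation of the
major nominal strain λ − 1 over patches at the instants where the applied
pressure first reaches 30 %, 60 % and 100 % of its peak (located by linear
interpolation; the 100 % stage is the ramp endpoint by convention, which
matters when the ramp plateaus).

## Synthetic experiments

The generator emulates the donor study conditions: V_total = 2430 mL,
m = 818 g, ρ = 1.0 g/cm³ (hence V_air0 = 1612 mL, porosity 66 %), peak
pressure 2.1 kPa over a 2 s inflation, 20 PV points, 30 strain statistics.
Measurement noise is Gaussian and independent: 2 % relative on volumes
(transducer-style), 0.005 absolute on strain statistics (DIC-floor-style);
both are order-of-magnitude choices, exposed in `NoiseSpec`, since no
published noise model exists for this apparatus. Noisy strain standard
deviations are clipped at zero and the first PV volume is forced back to
zero. Provenance records the seed, the ground-truth parameter vector and
the exact solver settings, so a record regenerates bit-identically and the
objective at the truth of a noiseless record is exactly zero.

**Default ground truth.** (μ = 3.0 kPa, α = 9.5, ν = 0.3,
k = (3.4, 7.3, 3.5, 10, 5.7)·10⁻³ mm²·s⁻¹, C₁₀ = 0.4 kPa,
λ_pleura = 1.3·10⁻²). The permeability pattern (fast middle-right lobe),
airway stiffness and pleura scale follow the mid-stiffness calibrated
solution of the organ-scale study; the foam exponent is the package's own
choice. A softening foam (α ≪ 3) has recoil bounded by 2μ/(3e) ≈ 0.25·2μ,
so under a 2.1 kPa ramp a spherical compartment either runs away or stays
flow-limited — and a flow-limited V(p) is strictly convex, which
contradicts the defining S-shape of physiological PV curves. With α > 3
the recoil stiffens at large stretch: compliance rises to a maximum near
λ ≈ 1.1 and falls beyond it, giving the lower and upper inflection points.
α = 9.5 with ν = 0.3 places the equilibrium stretch at 2.1 kPa just past
the compliance maximum, so the sampled 20-point curve shows the sign
change in discrete curvature robustly across heterogeneity seeds.

**Default ramp.** Linear from 0 to 2.1 kPa. A smoothstep ramp
(3s² − 2s³) is available but not the default: its rate vanishes at
end-inflation while flux continues, which appends a vertical (convex)
tail to the sampled PV curve and masks the upper inflection at any
affordable conductance.

**What passing tests do not show.** The generator shares its forward model
with the calibrator, so recovery tests demonstrate the inverse machinery
(identifiability, convergence, protocol), not geometric fidelity: there is
no lobe–lobe contact, no gravity, no camera-view masking of the strain
fields, no viscoelasticity or deflation branch, and the patch statistics
correspond to DIC surface statistics only by construction.

## Calibration

The decision vector is (μ, α, ν, k_UL, k_LL, k_UR, k_MR, k_LR, C₁₀,
λ_pleura) — ten components; the evaluation budget follows the conventional
nine-parameter count of the calibrated material quantities (100 × 9 = 900
per start). Bounds: μ, k's, C₁₀ ∈ [0.1, 100]; α ∈ [10⁻⁶, 10]; ν ∈ [0, 0.5];
λ_pleura ∈ [10⁻⁶, 3].

The residual stacks (experiment − model)/δ_block over the 20 volumes, 15
strain means and 15 strain stds, δ_block being the population standard
deviation of the corresponding *experimental* values (the zero-volume
origin included; a degenerate block with zero spread is rejected). The
printed objective form juxtaposes the three sums without an operator; the
residual-stacking least-squares reading is adopted because the protocol
minimizes with a least-squares solver. The error triplet reported for
ranking applies the relative-error formula with absolute values,
excluding exactly-zero experimental components (the t = 0 volume) from
block means.

The engine is scipy's trust-region-reflective `least_squares` with its
native tolerances disabled; an outer wrapper owns termination, checking
after every accepted iteration, in fixed order: (1) |φᵢ − φᵢ₊₁| <
10⁻⁶(1 + |φᵢ|); (2) evaluation budget; (3) 400 iterations; (4)
max|vᵢgᵢ| < 10⁻⁶ with vᵢ = xᵢ − bᵢ toward the bound the negative gradient
points at, else 1; (5) ‖xᵢ − xᵢ₊₁‖∞ < 5·10⁻⁴. Infinity norms are used
where the printed forms leave the norm implicit, and the optimality
gradient is that of φ (2JᵀR). Jacobians are forward differences with
absolute step 10⁻⁶ × (bound width) per parameter, reflected to backward
steps at the upper bound; differencing evaluations count toward the
budget, and the budget is enforced as a hard cap (never exceeded). Failed
forward evaluations return a penalty of 10⁶·(1 + worst successful φ)
spread over the 50 components, keeping the optimizer inside the feasible
box instead of aborting.

MultiStart runs the local solver from three standard starting points
independently (order-insensitive); the best solution is the lowest φ, and
`rank_minima` orders candidates by the mean of the three block errors.
One-at-a-time sensitivity sweeps (±5 % default) report Δφ and the error-
block changes per parameter, skipping and flagging directions that leave
the box.

**Identifiability.** At the default truth the airway term is ≈ 0.2 % of
total recoil and the membrane term ≈ 0.02 %, so C₁₀ and λ_pleura are
resolved only to tens of percent before the function tolerance fires —
an honest property of this measurement set, mirrored in the organ-scale
study where the three local minima disagree on exactly these parameters
by orders of magnitude. Recovery studies therefore use an interior truth
with C₁₀ = 5 kPa and λ_pleura = 0.4 (several percent of recoil each),
where a ±20 % start recovers μ, C₁₀ and λ_pleura within 5 % and every
permeability within a fraction of a percent; with 2 % volume / 0.005
strain noise the solution φ lands at or below twice the noise-floor φ.

## Problem sizes and determinism

Study conditions throughout: 5 lobes × 20 patches, 100 output steps over
the 2 s ramp (a forward run is ~50 ms; a single calibration start
converges in ~50–200 evaluations). Limit checks use 2–3 patches per lobe
where patch count is immaterial. All randomness flows from explicit
integer seeds (patch multipliers, noise streams, oracle sampling states);
identical inputs give bit-identical outputs on one platform, and every
CLI run logs its seed, config hash and package version.

## Known limitations

* The compartment geometry cannot reproduce spatial strain contours, lobar
  sliding or contact; only lobe-aggregated statistics are meaningful.
* Permeability is constant per lobe (no void-ratio dependence); the
  Forchheimer drag coefficient defaults to the Darcy limit, and its
  nonzero form applies the drag to the Darcy flux explicitly,
  q = q₀/(1 + β_F|q₀|).
* `flow_gain` is a phenomenological closure of a unit mismatch, not a
  measured conductance; absolute permeability values are meaningful only
  relative to it.
* The strain noise floor and the lobe volume fractions
  (0.20/0.25/0.20/0.10/0.25) are plumbing defaults, not measurements.
* Deflation, hysteresis, viscoelasticity, anisotropy and gravity are out
  of scope.
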