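# Methods

## Mixture bookkeeping

Each wall layer carries an ordered set of constituents with initial volume
fractions φζ(0) that close to 1 per layer. Turnover changes only the
normalized masses m̂ζ; the deposition rule decides what that does to volume:
CCD keeps the constituent's true density fixed (v̂ζ = m̂ζ), CCV keeps its
volume fixed (v̂ζ = 1). The tissue volume change is the fraction-weighted
sum of constituent volume changes, and normalized partial densities
ρ̂ζ = m̂ζ/v̂ are always derived on demand, never stored, so the composition
state cannot drift. The baseline composition (media: elastin 0.12, ground
0.73, two collagen families at 0.075 each) closes exactly; the adventitial
ground fraction is set to 0.85 — the residual-constituent rule, since ground
matrix is by construction "everything else" — so that layer closes with two
0.075 collagen families as well.

## Growth kinematics

Growth tensors are the transversely anisotropic family Fg = αI + βn⊗n with
det Fg = v̂ and n the wall normal (radial direction in the cylinder, the
normal of the collagen tangent plane n = a₀₁×a₀₂ in general; parallel fiber
directions are rejected). The four kinds differ only in how α, β are tied to
v̂; these growth coefficients are internal to the growth-tensor construction
and deliberately share no namespace with the remodeling rates α, β — two
unrelated parameter pairs that happen to reuse letters. Tensors are stored
in a fixed orthonormal local frame (fiber-plane frame for the patch,
cylindrical {r,θ,z} for the vessel) so growth tensors are diagonal there;
the API itself is frame-agnostic and the frame-consistency property
(conjugation under rotation of n) is tested.

NVG is a configuration-level constraint, not a tensor formula: it requires
an all-CCV deposition assignment so that v̂ ≡ 1 identically; configurations
combining NVG with any CCD constituent are rejected at validation time.

## Constitutive model

Quasi-incompressible layered hyperelasticity with the volumetric/isochoric
split. Penalty energy U = κ/2(Je−1)², neo-Hookean isotropic terms weighted
by ρ̂e, ρ̂g (adventitia has ρ̂e = 0), exponential collagen energy per family
relative to the recruitment configuration. The collagen stress factor is the
derivative with respect to Ī₄, so the chain rule through Ī₄c = Ī₄/Ī₄r
contributes the 1/Ī₄r factor; below recruitment (Ī₄ < Ī₄r) fibers carry
exactly zero stress and energy. Second Piola–Kirchhoff stress (on the grown
intermediate configuration) and Cauchy stress are implemented independently
and tested to agree under push-forward; stress–energy consistency is checked
against central finite differences of the energy, and objectivity under
random rotations. All operations broadcast over leading array axes so the
vessel solver can evaluate entire walls (stations × radial cells) in one
call.

Two pressure treatments: *exact incompressibility* (det Fe = 1, Lagrange
pressure eliminated by the equilibrium ODE — the default everywhere) and a
*penalty-compressible* mode using κ from the material block. The exponent of
the fiber energy is clipped at 700 so that runaway remodeling states produce
saturated (≈1e304) finite stresses rather than overflow; the equilibrium
root-finder then simply rejects those states.

## Remodeling

The stimulus is ξ = (Ī₄c − Ī₄a)/(Ī₄a − 1). A flattened-notation alternative
ξ = Ī₄c/Ī₄a − 1 is retained as a config switch (`stimulus_form: ratio`) for
sensitivity checks; the difference form is the default because it maps a
fully slack fiber (Ī₄c = 1) to exactly −1, giving the atrophy rate a clean
normalization. ξ is computed from the *clamped* fiber stretch, so a slack
fiber atrophies at the maximal rate −1 rather than an unbounded one.

Time integration is explicit forward Euler on τ with dτ = 0.01 year by
default: the rates are O(1)/year, trajectories are smooth, and first-order
convergence (observed order ≥ 0.9 on coupled 10-year trajectories) is
verified by test rather than assumed. The recruitment stretch is floored at
1.0 with a warning count — λ̄r < 1 has no physical reading in the
recruitment picture — and the elastin law m̂e(z,τ) keeps decaying as
c_min^{τ/T} for τ > T, matching simulations that run past the nominal
degradation time.

## Equi-biaxial patch

A single-constituent neo-Hookean patch under equi-biaxial stretch admits
closed-form first Piola–Kirchhoff stresses per kinematics; collagen is
deliberately excluded here. The module is the analytic oracle for the
generic pipeline: on random (λ, v̂, ρ̂) states the closed forms agree with
the growth-tensor → Cauchy-stress → traction-balance route to better than
1e−8 relative. ρ̂ and v̂ enter the patch independently; the CCD/CCV link
between them applies only when states are built through the mixture module.

## Vessel model

**Discretization.** Each layer is split into equal-width radial cells with
one-point Gauss–Legendre (midpoint) quadrature — weights sum exactly to the
layer thickness, and, with v̂ piecewise-constant per cell, the cumulative
integral in the incompressible radial map r(R)² = ri² + (2/λz)∫v̂ρdρ is
evaluated exactly cell-by-cell with the same partition used by the
equilibrium integral. Four cells per layer by default; doubling changes the
solved homeostatic inner radius by ~1e−3 mm (second-order convergence,
tested).

**Equilibrium.** With exact incompressibility, radial equilibrium
dσrr/dr = (σθθ−σrr)/r with σrr(ri) = −p_i reduces to scalar root-finding on
ri for the outer traction condition; a secant iteration warm-started from
the previous step is used (with a bracketed fallback), vectorized across
axial stations during growth. The re-evaluated integral residual is below
1e−6·p_i. In penalty mode the radial stretch at every cell plus ri are
solved by collocation (scipy hybr/lm with smooth repulsion for inadmissible
iterates); as κ → ∞ the penalty solution approaches the exact one
monotonically (tested over three decades of κ).

**Phase 1 (homeostasis).** Masses fixed at m̂ = 1 (so v̂ = 1 and the phase
is independent of the kinematics kind); the recruitment field is driven to
the state where the fiber stretch equals the attachment stretch everywhere
by directly assigning the fixed point of the recruitment rate equation
(λ̄r ← λ̄fiber/λ̄a) between re-equilibrations. This converges to the same
stationary state as time-stepping the rate equation — the fixed point is
ξ = 0 in both cases — without integrating the transient; convergence is to
|λ̄c − λ̄a| < 1e−10, and one further sweep moves the field by < 1e−9.

**Fiber angle.** The baseline parameter set does not pin down the collagen
fiber angle γ (two families at ±γ from the circumferential direction), yet
the homeostatic caliber depends on it. A calibration utility tunes γ by
bisection so the loaded homeostatic inner diameter equals a target (23 mm
for the baseline aorta, giving γ ≈ 49.2°); the homeostatic diameter is
monotone in γ over the search bracket because steeper fibers shift collagen
load-bearing out of the hoop direction.

**Penalty-mode homeostasis.** With the baseline κ = 100 kPa — the same
order as the shear moduli — the wall is far from incompressible under load:
the mean stress of the pressurized wall is ≈ +100 kPa, so Je ≈ 1.7–2.0
(swelling). In this regime the homeostasis iteration has *no fixed point*:
relaxing collagen recruitment lets the soft wall dilate indefinitely
(verified with plain and under-relaxed iterations; the fiber-stretch error
grows monotonically while ri diverges). The penalty-mode thickness is
therefore reported for the exact-incompressible homeostatic state re-solved
once with the penalty active (1.38 mm at baseline, vs 1.13 mm exact). This
is a genuine property of the soft-κ formulation, not a solver failure:
under tension the penalty can only swell the wall, never compact it.

**Phase 2 (growth).** Axial stations z ∈ [L/2, L] (distal–proximal symmetry;
30 stations by default, the mid-length station is the tracked "point A")
evolve independently under the local elastin mass m̂e(z,τ): per step —
prescribe m̂e, evaluate ξ per cell and family, Euler-step λ̄r and m̂c,
recompute v̂ and the growth tensor, re-equilibrate all stations, record.
On an equilibrium failure the step is retried with up to four local
halvings of dτ before the run truncates with an explicit status. Runs also
terminate once the sac reaches fourfold diameter expansion
(`stop_dhat: 4.0`): the quasi-1D rings never fail mechanically, so without
this cap fast-growing runs would continue into expansion regimes in which
the full 3-D problem loses validity (wall folding and distortion), and
"maximum over the run" summaries would be dominated by those states.

**Measurements.** Diameter growth rate is a centered finite difference of
di over a 1-year window; threshold crossings (twofold expansion, the 55 mm
and 10 mm/year repair indications) are linearly interpolated within the
crossing step. Total vessel volume change is the reference-volume-weighted
integral of v̂ over all stations and cells (trapezoidal in z), normalized by
the homeostatic total; for an all-CCV (NVG) run it is identically 1 to
1e−8, a conservation check under test.

## What the quasi-1D reduction does and does not capture

Retained: every constitutive and growth mechanism — CCD/CCV bookkeeping,
all four kinematics, recruitment/mass turnover, elastin degradation
profile, two-layer wall structure, transmural gradients. Reproduced at this
scale: the β-sensitivity sign flip (more collagen production slows TVG/NVG
expansion but accelerates IVG/PVG), the near-identity of TVG and NVG
predictions, the transmural orderings of collagen stretch (PVG > IVG >
TVG ≈ NVG) and volume change (inverted, TVG largest) at twofold expansion,
and the bounded total (≲15%) versus large local (≲190%) volume growth.

Not representable: axial coupling between stations — the bulging sac of the
full axisymmetric problem stretches wall material axially far beyond the
fixed pre-stretch λz = 1.2, and the folding/buckling of the adjacent
non-aneurysmal segment. The main quantitative consequence is wall thinning
at the apex: with λz fixed and NVG volume conservation, the thickness at
twofold expansion is kinematically pinned at ≈0.59 mm (conserved
cross-section area spread over the doubled circumference), roughly twice
the value the axially-stretching 3-D sac reaches. Absolute apex-thinning
numbers from this model should therefore be read as upper bounds; the
*relative* kinematics comparisons (TVG vs NVG vs IVG/PVG) are the reliable
output. Passing tests consequently certify mechanism-level fidelity and
scaled trends, not patient-scale wall-thickness prediction.

## Numerical parameters (defaults)

| parameter | value | units | role |
|---|---|---|---|
| dτ | 0.01 | year | Euler step of the turnover ODEs |
| tau_end | 15 | year | growth-phase horizon |
| stop_dhat | 4.0 | – | termination cap on di/d0 |
| n_radial | 4 | cells/layer | radial quadrature resolution |
| n_axial | 30 | stations | axial stations on [L/2, L] |
| homeostasis tol | 1e−10 | – | max |λ̄c − λ̄a| at convergence |
| equilibrium ftol | 1e−10 | kPa | outer-traction residual |
| λ̄r floor | 1.0 | – | recruitment-stretch lower bound |
| exp clip | 700 | – | fiber-energy exponent guard |

All physical parameters (geometry in mm, pressures and moduli in kPa, rates
in 1/year) live in the baseline config block and are documented in the
README; every run's manifest records the full resolved configuration.
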