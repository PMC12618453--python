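# Methods

`dispercann` discovers sparse, interpretable hyperelastic material models
for myocardium-like tissue from triaxial-shear and biaxial-extension stress
data, with the fiber, sheet, and normal directions allowed to be dispersed
rather than perfectly aligned.

## Continuum model

The tissue is a perfectly incompressible orthotropic solid.  Every test
state is a homogeneous deformation gradient **F** with det **F** = 1, and
the mechanics is expressed through invariants of **C** = **F**ᵀ**F**: the
isotropic I1 = tr **C** and I2 = ½(I1² − **C**:**C**); the squared
stretches I4i = **C** : i₀⊗i₀ along the structural directions i ∈ {f, s, n};
and the coupling invariants I8ij = **C** : sym(i₀⊗j₀).

Dispersion enters through generalized structure tensors.  Each direction
family follows a π-periodic von Mises orientation density on the sphere,

ρ(Θ) = 4 √(b/2π) · exp(b[cos 2Θ + 1]) / erfi(√(2b)),

whose second moment is H = κ I + (1 − 3κ) i₀⊗i₀ with the scalar dispersion
parameter

κ(b) = ¼ ∫₀^π ρ(Θ) sin³Θ dΘ ∈ [0, ⅓].

κ = 0 is perfect alignment, κ = ⅓ an isotropic cloud; κ(b) is strictly
decreasing (κ(1) ≈ 0.2344).  The `+1` in the density exponent is required
by the sphere normalization (1/4π)∫ρ dω = 1; a variant without it
integrates to e^(−b).  The dispersed invariants used as model inputs are
the contractions I4i\* = **C** : Hᵢ = κᵢ I1 + (1 − 3κᵢ) I4i.  Dispersion is
applied to the fourth invariants only; the coupling invariants are used
raw.  The density is evaluated through the Dawson function
(erfi(x)·e^(−x²) = 2D(x)/√π), which is stable for concentrations up to at
least 10³; κ(b) uses adaptive Gauss–Kronrod quadrature at absolute
tolerance 1e−10, because κ enters the stress linearly and quadrature error
propagates directly.

## Energy library and tension switch

The energy is a fixed library of 32 terms: for each of the eight inputs
(I1−3, I2−3, I4f\*−1, I4s\*−1, I4n\*−1, I8fs, I8fn, I8sn), the first and
second powers, each through the identity or through w₂[exp(w₁·base) − 1].
Identity-node layer weights only appear as a product and are collapsed into
one effective weight (48 trainable parameters total, all ≥ 0; inner weights
unitless, outer weights kPa).  The corrections by 3 and 1 make ψ(**F**=**I**) = 0
exactly.

A tension–compression switch deactivates an entire I4i\* row (energy and
derivatives) whenever the *undispersed* I4i < 1, preventing compressive
stiffening.  Two consequences worth knowing:

- With κᵢ > 0 the energy is genuinely discontinuous across the switch
  boundary I4i = 1 away from the rest state, because the dispersed base
  κᵢ(I1 − 3) is nonzero there.  The protocol deformations never sit in the
  interior of that discontinuity (biaxial states have I4f, I4n > 1 and
  I4s < 1; at rest every base vanishes), but finite-difference probes of
  ψ(**F**) must avoid states exactly on the boundary.
- First-order anisotropic terms (the linear and exp-linear nodes of the
  I4\*/I8 rows) have nonzero energy derivatives at **F** = **I** that no single
  hydrostatic pressure can cancel, so a model containing them has a small
  residual stress in the reference configuration.  The L1 penalty drives
  such weights toward zero in discovery; the stress-free-reference property
  is exact for models built from the quadratic and exp-quadratic
  anisotropic nodes.

Exponential inner arguments are capped at 50 with a hard error rather than
silent clipping, which would corrupt training gradients.

## Stress

The Cauchy stress is σ = Σₖ (∂ψ/∂Iₖ)(∂Iₖ/∂**F**)·**F**ᵀ − p**I**, with the
dispersed push-forwards 2**F**Hᵢ**F**ᵀ.  Closed forms are derived from this
general formula (and verified against a finite-difference oracle, which is
the arbiter wherever alternative printed forms circulate):

- Simple shear, mode ij (**F** = **I** + γ eⱼ⊗eᵢ, stretching direction i):
  σᵢⱼ = 2γ[∂₁ψ + ∂₂ψ + (1−2κᵢ)∂₄ᵢψ + κⱼ∂₄ⱼψ + κₖ∂₄ₖψ] + ∂₈ᵢⱼψ,
  where k is the out-of-plane direction.  Note the coupling derivative
  enters with coefficient 1, not γ, and the third direction contributes
  whenever κₖ > 0.  A commonly printed truncation (γ·∂₈ᵢⱼψ, no κₖ term) is
  available as `form="printed"` for comparison studies.
- Biaxial extension with plane stress through the sheet thickness: p is
  solved exactly from σss = 0 of the general formula, including the
  anisotropic terms, giving
  σff = 2(λf²−λs²)∂₁ψ + 2(λf²−λs²)λn²∂₂ψ + 2[λf²(1−2κf) − λs²κf]∂₄fψ
        + 2[λf²κs − λs²(1−2κs)]∂₄sψ + 2κn(λf²−λs²)∂₄nψ,
  and symmetrically for σnn.  The truncated printed variant (isotropic-only
  pressure) is again behind `form="printed"`.

Every protocol stress is a linear functional of the eight energy
derivatives with coefficients affine in (κf, κs, κn); the trainer exploits
this for closed-form gradients.

## Protocols and synthetic data

The standard campaign has eleven protocols: six shear modes (fs, fn, sf,
sn, nf, ns; channel σᵢⱼ) and five biaxial stretch-increment ratios 1:1,
1:0.5, 1:0.75, 0.5:1, 0.75:1 (channels σff and σnn) — 16 stress channels.
Ratios scale the increments λ−1, so protocol stretches never dip below 1.
Default grids are γ ∈ [0, 0.5] and λ ∈ [1, 1.1] with 17 points per curve,
matching the strain ranges of the published experimental figures; exact
experimental grids are not printed anywhere, so these are configuration.

The generator emulates the real laboratory campaign in its protocol set,
strain ranges, stress magnitudes (peak ≈ 6 kPa with the published
four-term model) and noise structure.  It does not emulate specimen
heterogeneity, preconditioning/hysteresis, inter-sample variability, or
actual measured grids — so passing the synthetic suites demonstrates
correctness and robustness of the discovery machinery, not experimental
fidelity.

Measurement noise is additive Gaussian per sample, k·N(0, std_channel),
with std_channel the standard deviation of that channel's stresses and
k ∈ {0.03, 0.05, 0.07, 0.1} the studied levels; it is applied once per
dataset, not per epoch.

## Discovery

The loss is the squared stress misfit summed over all samples plus
α·Σ|w| with α = 0.01.  Three data-term normalizations are available; the
default is the raw sum.  The trade-off matters: with the misfit *averaged*
over all samples, α = 0.01 is strong enough that the loss optimum prefers a
visibly shrunken model (mean R² ≈ 0.94 on exactly representable data) —
under that objective the published discovered models are demonstrably not
optimal, while under the raw-sum objective they are reproduced.  Since Adam
is invariant to the overall loss scale, the choice is exactly a choice of
effective regularization weight.

Training: Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e−7), batch size 32, up to
30 000 epochs, non-negativity re-projected (clip at 0) after every step,
early stopping when the full training loss has not improved by more than
1e−8 for 1 000 consecutive epochs, best-loss snapshot returned.
Initialization follows the standard recipe: Glorot-normal clamped at zero
for collapsed identity weights, uniform [0, 0.1] for exponential pairs.
Multiple restarts (default 3) guard against poor local minima; tests and
the acceptance script use single restarts with the default grids, which
reproduce the multi-restart optima on these problems to ±1e−5 in mean R².
The learning rate is not fixed by any published account; 0.001 is the
standard Adam default at this parameter count and is validated by the
self-consistency suite.

A term is reported *active* when its peak stress contribution across the
protocols exceeds 0.5% of the peak total stress; published tables omit
near-zero weights without stating a cutoff, and this threshold reproduces
their sparsity.

R² is computed per stress channel (1 − SSres/SStot about the channel mean)
and summarized as the unweighted mean over the 16 channels; zero-variance
channels are excluded with a warning.

## Dispersion-parameter identifiability

Trainable κs are parameterized by a scaled logistic onto [0, ⅓] (boundary
reachable within 1e−3) and optimized jointly with the weights.  On
synthetic data that the term library can represent exactly, this joint
problem is *practically non-identifiable* in κs and κn: the retrainable
weights absorb the effect of dispersion almost exactly (R² ≈ 0.9998 at
κ ≈ 0 on data generated with κn = 0.3), and the absorbed solutions have
*lower* total loss than training at the true κ, so no optimizer can recover
the sheet/normal dispersion from stress data alone.  Only the fiber κ is
meaningfully constrained, through the fit-quality trend.  This mirrors the
empirical finding that arbitrary sheet/normal dispersion improves fits to
the real data while fiber dispersion must stay small.  For applications
that need κ estimates, the package provides a well-posed alternative:
`fit_kappa_fixed_weights` holds the energy weights fixed and solves a
bounded least-squares problem (L-BFGS-B on [0, ⅓]³), which recovers known
κ triples to ≈1e−4 on noise-free data.

## Numerical and design notes

- Shear convention: **F** = **I** + γ eⱼ⊗eᵢ for mode ij; this is the unique
  convention under which the closed-form shear coefficients (1−2κᵢ) on the
  stretched direction and κⱼ on the sheared direction agree with the
  general stress formula.
- Switch semantics at I4 = 1 are inclusive (≥); the contribution is zero at
  the boundary itself.
- The switch is evaluated on the undispersed I4 even though the energy uses
  I4\*; this is a deliberate reading of the tension criterion as a statement
  about the mean-direction stretch.
- I8 terms use signed invariants; for all eleven protocols the relevant
  signs are non-negative.
- Model JSON round-trips weights bit-exactly (Python float repr).
- Degenerate inputs: non-orthonormal frames, non-positive stretches,
  out-of-range κ, and malformed dataset files raise with specific messages;
  a diverging restart (NaN loss) is abandoned with diagnostics and the
  remaining restarts proceed.

## Problem sizes

Tests and the acceptance script run the full pipeline at the default
11-protocol, 17-points-per-curve campaign (272 stress samples), with full
30 000-epoch schedules for the self-consistency and recovery experiments
and shorter schedules (≤ 8 000 epochs, reduced grids) for directional
property checks such as sparsity-versus-α, which probe trends rather than
converged optima.

## Known limitations

- Incompressibility is exact; no volumetric/compressible energy.
- Passive response only: no active stress, viscoelasticity, or growth.
- Dispersion affects the fourth invariants only, not the couplings.
- Homogeneous deformations only; no boundary-value problems.
- The misspecification refits sit within ≈1e−3 in mean R² of the published
  values; residual differences trace to unprinted details of the original
  data grids and training implementation.
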