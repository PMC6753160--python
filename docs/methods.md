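# Methods

## Dipolar model and conventions

A residual dipolar coupling is modelled as `D = D_max · bᵀ S b`, with **b**
the unit N→H internuclear vector in the PDB frame and **S** the traceless
symmetric Saupe order tensor. `D_max` defaults to 21.7 kHz, the magnitude of
the static dipolar interaction constant for an amide pair at an effective
bond length of 1.04 Å (the librationally corrected value commonly used for
proteins). Every statistic the package reports for scientific interpretation
— Q factors, Euler angles, 5D angles, generalized magnitudes entering
*ratios*, and the interdomain order parameter — is invariant to this
constant; it only fixes the unitless scale of **S**.

Principal-frame parameters follow the standard ordering
|A_zz| ≥ |A_yy| ≥ |A_xx|, giving `Da = D_max·A_zz/2` and
`R = (2/3)(A_xx − A_yy)/A_zz ∈ [0, 2/3]`. Orientations are intrinsic zyz
Euler angles of the rotation taking PDB-frame coordinates into the
principal frame. Because a symmetric tensor cannot distinguish a frame from
the same frame with two axes negated, four proper rotations are equivalent;
`equivalent_euler_frames` enumerates them and the canonical representative
has β ∈ [0°, 90°] with the lexicographically smallest (β, α, γ). The
generalized degree of order is `GDO = √(2/3 · Σ S_kl²)`; any fixed
convention would do, since all conclusions drawn from magnitudes are
ratios.

The Q factor uses the plain convention `rms(D_calc − D_obs)/rms(D_obs)`;
normalisation by `√(2Da²(4+3R²)/5)` is available as an option. The fit is
unweighted by default so Q values are comparable across datasets; 1/σ²
weighting is available.

## Measurement chain

Couplings are differences between anisotropic and isotropic ¹⁵N splittings.
For the HSQC/TROSY pair the decoupled HSQC position is the multiplet centre
and the TROSY line is displaced by `sign·(J+D)/2`; the splitting is twice
the displacement, and the displacement sign is a single configurable
constant (`FixtureSpec.trosy_sign`) so either TROSY-component convention
can be represented. For IPAP the splitting is the signed separation of the
doublet components. ¹J_NH defaults to −93 Hz; only differences matter.

Peak-position uncertainty is σ_v = LW/(2·SN). It propagates with the same
arithmetic as the positions: each HSQC/TROSY splitting carries
σ = 2·√(σ_v² + σ_v²), each IPAP splitting σ = √(σ_v² + σ_v²), and the
coupling combines the isotropic and anisotropic splitting uncertainties in
quadrature. For constant SN and LW the HSQC/TROSY chain therefore yields
σ_D = 4·σ_v (a direct consequence of composing the three stated formulas).

Quality filters exclude records, with the first matching reason in the
priority order flexible > exchange > overlap > sigma, when the residue's
local order parameter S² < 0.85, it undergoes conformational exchange, its
resonances overlap (an input flag — peak picking is out of scope), or
σ_D > 5 Hz. Both thresholds are strict inequalities, so records exactly at
the boundary survive. Filtering is idempotent and recomputes the dataset's
RMS uncertainty over survivors.

## SVD fit

With rows `[x²−z², y²−z², 2xy, 2xz, 2yz]` the model is linear in the five
free components (S_xx, S_yy, S_xy, S_xz, S_yz); the least-squares solution
is computed from the singular-value decomposition of the design matrix. A
condition number above 10⁸ (or fewer than five usable records) raises an
error naming the degenerate geometry: vector sets that are parallel or
coplanar cannot determine all five components. The reported condition
number is a useful diagnostic well before that threshold — ideal helices
carry N–H vectors in a ~12°-half-angle cone about the helix axis, so a
single helix conditions the fit poorly and the synthetic two-helix fixture
places its second helix in a generic orientation to span all five degrees
of freedom (condition number ≈ 18).

## Monte-Carlo uncertainty

Each iteration adds independent Gaussian noise of each record's own σ_D to
the couplings (scaled by `rdc_noise_scale`) and rotates every bond vector
about a uniformly random perpendicular axis by an angle drawn from
|N(0, σ_angle)| — a cone-style model of residual structural noise. The
structural-noise magnitude is an explicit assumption, default 5° s.d.,
configurable and echoed in every result. The two channels are independent
and residue-to-residue noise is uncorrelated (no evidence for a correlation
structure is assumed). Draws are deterministic given (seed, iteration), so
summaries are bitwise reproducible.

One wrinkle deserves emphasis. At realistic noise the sampled rhombicity
can cross its upper bound 2/3, where the |eigenvalue| ordering swaps the
y/z principal axes and flips the sign of Da; naively summarised, a unimodal
parameter distribution looks bimodal (we observed ~20% sign flips at
σ_D = 1.8 Hz on 28 couplings). Monte-Carlo samples are therefore
re-parameterised by matching each sample's principal axes to those of the
unperturbed point estimate (maximum total |cosine| overlap) before Da, R
and the Euler angles are read off; individual samples may then carry
R > 2/3, which is the honest picture near the boundary. Euler α and γ are
summarised with circular mean/s.d. on [0°, 360°); β, bounded in [0°, 180°],
and the 5D angle use ordinary statistics. Fit failures on perturbed draws
are counted, and more than 10% failing aborts the analysis.

The Monte-Carlo machinery is validated against the analytic (delta-method)
covariance `P diag(σ_i²) Pᵀ` with `P` the scaled pseudoinverse of the
design matrix: with coupling noise only, the empirical s.d. of every Saupe
component agrees with the analytic value within a few percent at 1000
iterations, and 68% intervals for Da show nominal coverage over replicate
simulated experiments.

## Tensor comparison

The irreducible 5-vector is
`(√(3/2)·s_zz, (s_xx−s_yy)/√2, √2·s_xy, √2·s_xz, √2·s_yz)`, scaled so the
Euclidean inner product of 5-vectors equals the Frobenius inner product of
the matrices. The 5D angle is then identical to the matrix-level definition
`cos θ = ⟨S₁,S₂⟩_F/(‖S₁‖_F‖S₂‖_F)`, which removes any component-convention
ambiguity, and normalisation makes it independent of magnitude differences.
Principal axes are unsigned directions; each is reduced to the hemisphere
representative with z ≥ 0 (ties: y, then x) and drawn in the equal-area
sinusoidal projection x = λ·cosφ, y = φ. Axially symmetric tensors are
flagged: their transverse axes are an arbitrary basis of the degenerate
plane.

## Rigid-body refinement

Degrees of freedom are one rigid rotation per declared secondary-structure
element, about the element's Cα centroid, plus a global rotation of the
tensor frame; Da and R stay fixed (initially at the template best-fit
values). Translations are excluded — RDCs are orientation-only observables.
The objective is the soft square-well energy
`E = k·Σ max(0, |D_calc − D_obs| − σ_D)²`, zero inside each coupling's
uncertainty and harmonic in the excess, with continuous first derivative at
the well edge.

Optimisation is Metropolis simulated annealing (geometric cooling, default
0.95 over 50 temperatures × 200 moves; the starting temperature is
auto-calibrated to ≈50% initial acceptance) with three safeguards the raw
scheme needs:

1. **Bounded rotations.** Per-element total rotations beyond 30° incur a
   steep penalty. Refinement presumes a template close to the truth; beyond
   small reorientations the well-known RDC orientational degeneracy (180°
   flips about the tensor's principal axes reproduce every coupling) makes
   large excursions meaningless, and unbounded annealing does wander into
   those flip-equivalent basins.
2. **Tensor re-derivation cycles.** Da and R taken from the *template* fit
   are biased exactly when the template needs refining. Outer cycles
   (default 2) re-derive Da, R and the base orientation from the improved
   geometry by SVD; each update is adopted only if it lowers the current
   energy, so the best-so-far trace is non-increasing by construction.
3. **Variable-projection polish.** The flat well bottoms make the exact
   solution a whole region. A final Levenberg–Marquardt pass minimises the
   plain (un-welled) misfit over the rotations with the tensor profiled out
   by linear least squares at every step, selecting the central solution;
   it too is adopted only if the soft-well energy does not increase.

Loops and linkers keep their template coordinates; no covalent-geometry
bookkeeping is done at element junctions, and the largest junction Cα
displacement is reported as a diagnostic rather than repaired. Because any
common rotation of all elements together with the floating tensor frame
leaves the energy invariant, the per-element absolute rotation is defined
only up to that gauge; the recoverable quantity is the *relative* rotation
between elements (`RefineResult.relative_rotation_deg`), which is what the
recovery tests assert. On the synthetic two-helix fixture a 10° rotation of
one helix is recovered to machine precision from noiseless data.

Cα RMSDs to the template are computed without superposition by default
(both structures share the template frame); an optional Kabsch
superposition is provided.

## Alignment propagation and the linker order parameter

The effective tensor seen by an indirectly aligned domain is the weighted
conjugation average `Σ_c w_c · R_cᵀ S R_c` over the linker conformer
ensemble, and the order parameter is the magnitude ratio
`S² = |S_indirect|/|S_direct|` — a plain ratio, not squared, matching the
arithmetic of the experimental worked example (3.5×10⁻⁴ / 2.5×10⁻³ = 0.14
with first-order uncertainty 0.05). Its experimental uncertainty uses
first-order propagation of the two magnitude s.d.s.

Two ensemble families are provided: uniform (Haar) rotations for a fully
flexible linker, and a one-parameter "concentrated" family with rotation
angles distributed ∝ exp(κ·cosω) on [0, π] about uniform random axes — a
declared surrogate for optimised ensembles from other experiments, whose κ
interpolates from broad sampling to the rigid limit. Note that κ = 0 is
*not* the Haar ensemble (the uniform-angle density lacks the 1−cosω Haar
weight), and for isotropically distributed axes the predicted order
parameter has a closed form: the conjugation average is χ₂(ω)/5 times the
input tensor for fixed angle ω, with χ₂(ω) = 1 + 2cosω + 2cos2ω, so
κ = 0 gives S² = 1/5 while the Haar ensemble gives 0. The forward pipeline
closes exactly: fitting noiseless simulated couplings for a direct and a
propagated tensor and taking the fitted-magnitude ratio reproduces the
ensemble prediction to 10⁻⁶. Composition of two independent ensembles
(propagation through two linkers in series) is provided as a conformer-wise
product.

## Synthetic data

The generator emulates the measurement regime of RDCs on a flexible domain
of a very large complex: couplings spanning roughly ±30 Hz, RDC
uncertainties near 1.8 Hz RMS, ¹⁵N linewidths of 11 ± 2 Hz (truncated at
zero), and ¹J_NH = −93 Hz. Structures are ideal backbones built by
natural-extension from standard bond geometry (helix φ/ψ = −57°/−47°,
strand −120°/130°, ω = 180°), with the amide H placed in-plane opposite
the bisector of the two nitrogen bonds; the first residue has no amide
proton. The default tensor (Da = −15 Hz, R = 0.3, a generic orientation)
was chosen once so the two-helix fixture's couplings span that realistic
range. Peak lists are exact at zero noise — the measurement chain then
returns the generating couplings to rounding error — and with noise on,
each position receives Gaussian error of its own σ_v.

What the generator does **not** emulate: real chemical-shift dispersion
(peak centres are uniform random), overlap arising from crowding (overlap
is an input flag), lineshape distortions, anisotropic structural noise, or
the actual linker topology of a dimeric two-domain protein (one effective
rotation per conformer). Passing tests therefore demonstrate correctness of
the estimators and their calibration under the declared noise model, not
robustness to pathologies of real spectra.

## Problem sizes and numerics

Default validation problem sizes: two 15-residue helices (28 couplings),
1000 Monte-Carlo iterations, 10⁴–10⁵ conformers for ensemble averages —
sizes at which every distributional check is comfortably converged.
Degenerate inputs are handled explicitly: zero tensors are flagged rather
than decomposed, axially symmetric tensors flag their transverse axes, the
5D angle refuses zero tensors, rank-deficient fits raise errors naming the
geometry, and inverse-CDF sampling of the concentrated ensemble uses a
20001-point grid (adequate for κ up to 10⁴, where the angular s.d. is
~0.6° against a grid step of ~0.009°). Euler extraction at gimbal lock
(β = 0° or 180°, i.e. axial tensors) folds the spare angle into α, as is
conventional.

## Known limitations

- Single alignment medium, single coupling type; no simultaneous
  multi-medium fitting and no alignment prediction from molecular shape or
  charge.
- Refinement does not maintain covalent continuity between elements;
  resulting junction distortions are reported, not repaired. Coordinates of
  loops are never refined.
- The concentrated-rotation ensemble is a surrogate family, not a physical
  linker model; it is validated only against its own analytic and
  simulation oracles.
- Insertion codes and mmCIF input are not supported; amide protons must be
  present in the input coordinates (no hydrogen building).
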