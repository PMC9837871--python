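# Methods

## Forward model

The domain is a 2D disk of diameter d = 100 mm with L = 16 electrodes evenly
spaced on the circumference. The quasi-static conduction equation
∇·(σ∇φ) = 0 is discretized with piecewise-linear (P1) triangles; current
±I is applied as a uniform density over the electrode arcs (gap model: no
contact impedance, no electrode metal in the mesh) and the boundary is
insulating elsewhere. The Neumann problem determines φ up to a constant;
we ground one node for the solve and then shift to the zero-mean gauge.
All observables are potential differences, so the gauge choice is
unobservable (tested). One sparse LU factorization per conductivity field
is reused across all stimulation pairs.

Electrode voltages are read as the boundary-length-weighted mean potential
over the arc nodes. These weights are exactly the consistent P1 load of a
uniform current density on the arc, which makes the discrete Green identity

    S(σ) · σ = U(σ)

hold to machine precision, where S[m,e] = (1/I) ∫ₑ ∇φ_mc·∇φ_mv dΩ with
φ_mc the field of combination m's stimulation pair and φ_mv the field of
its measurement pair driven at the same amplitude (reciprocal excitation).
This identity is the foundation of the OO-SME decomposition
ΔU = S_bΔσ + ΔSσ_b + ΔSΔσ, which is exact whenever ΔS = S_o − S_b is
computed from the true object field.

**Units.** Lengths are mm at the interface (m internally), conductivity
S/m, current mA, potentials and voltages mV, with unit thickness in the
third dimension. The mV/mA system (transfer impedances in Ω) is the
instrument-natural scale and it is the scale at which the pieces of the
inverse problem are mutually balanced: sensitivity entries are O(1), so the
Noser weights (squared sensitivities) are commensurate with the unit-free
graph Laplacian in the hybrid prior, and the second-order surrogate
S† = S² (elementwise) is a non-negligible perturbation of S. In SI volts
the same formulas are dimensionally unbalanced — the Laplacian term is six
orders of magnitude too strong and S† six orders too weak; this is a known
incoherence of the formulation, resolved here by fixing the working units
once.

## Mesh and protocol

The triangulation uses structured concentric rings (point count growing
linearly with radius, outer ring a multiple of L) passed through Delaunay;
interior points receive a small seeded jitter (10% of local spacing) so
meshes are reproducible yet free of degenerate co-circular configurations.
At the default target of 3767 elements the realized mesh has ~1.9k nodes
and ~3.6k elements with minimum angles above 30°. Electrode arcs cover
half the inter-electrode pitch by default (configurable); electrode 1 is
centred on the positive x-axis, numbering counter-clockwise, 1-based.

The quasi-adjacent protocol pairs electrodes two pitches apart for both
stimulation and measurement: one loop per stimulation position, all
measurement pairs not touching a stimulation electrode, ascending — 16
loops × 13 = 208 combinations. Spans are configurable (span 1 gives the
adjacent pattern, also 208 combinations at L = 16). Every combination has
its reciprocal partner in the protocol (104 pairs), which the SNR
estimator exploits.

## Reconstruction

Both steps minimize ‖ΔU − u(Δσ)‖² + μ²‖R(Δσ)‖² with the hybrid prior
‖R(x)‖² = 0.5 Σₑ ωₑxₑ² + 0.5 xᵀLx, where ωₑ is the column energy of S_b
(Noser weighting) and L the graph Laplacian of the element edge-adjacency.
The normal equations are solved matrix-free by conjugate gradients from a
zero start (relative-residual tolerance 1e-8, at most 500 iterations; the
quadratic functional decreases monotonically, the residual norm may not —
CG minimizes the energy norm). ω and μ are computed once from S_b and held
fixed across steps and models, so model differences are attributable to the
voltage approximation alone.

μ defaults to the noise-balance value μ = √(σ₁·10^(−SNR/20)) with σ₁ the
largest singular value of S_b — the smallest damping for which a
truncated-SVD argument bounds the noise term of the reconstruction by the
data term. The SNR used for this choice and for noise injection defaults
to 40 dB, a typical figure for a benchtop impedance-analyzer front end at
100 Hz.

**First-order sign.** The physical first-order response of boundary
voltages to a conductivity increase is a voltage *decrease*: the Jacobian
is ∂U/∂σₑ = −S[:,e] exactly (verified against finite differences in the
tests). The Taylor-based models — the one-step linear model, the
sensitivity-updating model (S_b* recomputed at σ_b + Δσ_init) and the
second-order model (S_b + S†) — therefore reconstruct with the
Jacobian-signed operator −A. Solving them with +A produces sign-flipped
images (correlation ≈ −0.87 with the truth on the reference phantom) and
breaks the two-step flow.

**OO-SME step 2.** When ΔS* is re-estimated from the current iterate
σ_o* = σ_b + Δσ, the OO-SME voltage change
u*(Δσ) = S_bΔσ + ΔS*σ_b + ΔS*Δσ equals the exact FEM change
U(σ_b+Δσ) − U(σ_b) — apply the Green identity at both fields. Matching it
to ΔU is thus the full nonlinear inverse problem, and the step-2 update
implemented here is its Gauss–Newton subproblem about the current iterate:
operator S_o*, right-hand side S_o*(Δσₖ + σ_o*) − U_b − ΔU, prior on the
total Δσ. A naive one-shot solve that freezes ΔS*σ_b as explained data
deflates the data term by an order of magnitude and collapses to a
near-zero image for every μ; the self-consistent form keeps the full data
misfit in play and strictly improves on step 1. One update is performed by
default (`step2_iterations`); more updates sharpen the updating model's
images but the fixed-point iteration is not contractive and is not run to
convergence by default.

Updated backgrounds are floored at 1e-4 S/m before recomputing
sensitivities, since first-pass estimates can undershoot the positivity
constraint.

## Synthetic data

The phantom generator emulates a fat tank (0.021 S/m) with lean-meat
inclusions (0.267 S/m at 100 Hz; Δσ = 0.246 S/m). Four presets provide
circular inclusions with diameters 0.32 d, 0.27 d, 0.34 d and (0.18 d +
0.27 d, two objects); positions are package choices placed well inside the
boundary. Two noise sources model real measurements: (i) tissue
inhomogeneity — additive uniform conductivity noise up to 20% of Δσ on a
random 40% of elements of the object field, floored to keep σ positive;
(ii) measurement noise — Gaussian white noise on ΔU rescaled so its
*maximum* equals 10^(−SNR/20)·max|U_b|. The reciprocity-based estimator
reads noise as half the difference of each reciprocal pair and reports the
average log ratio; for Gaussian noise this average-log convention sits
about 8 dB above the max-amplitude injection figure at 208 samples (the
two conventions coexist deliberately and the gap is documented in the
tests). What the generator does **not** emulate: electrode contact
impedance and drift, 3D current spreading, frequency dependence, hardware
crosstalk — so green tests here do not certify performance on bench data.

All randomness flows through named integer seeds; experiment-level runs
derive mesh and per-phantom seeds from a single seed via `SeedSequence`.

## Evaluation

RA (relative accuracy) is 100·max(0, 1 − mean over object elements of
|Δσ*ᵢ − Δσᵢ|/|Δσᵢ|), the complement of the mean relative error, clamped to
[0, 100]. The truth Δσ is the ideal (pre-noise) 0.246 S/m step.
Approximation-error ratios are L2-norm ratios 100·‖ΔU* − u‖/‖ΔU*‖ with u
evaluated at the true Δσ (an elementwise-mean variant is available).
Component ratios are projection coefficients rₖ = ⟨cₖ, ΔU⟩/⟨ΔU, ΔU⟩, which
sum to exactly 1 for the true ΔS; deviation from 1 with an estimated ΔS*
measures estimation quality.

Problem sizes: the test suite exercises most properties on ~800-element
meshes; the end-to-end study runs at the full ~3.6k elements, with the
ten-seed ordering statistics taken at ~1.2k elements.

## Known limitations

At the 12.7× conductivity contrast of the fat/lean phantoms the forward map
saturates: halving the object's Δσ amplitude changes the boundary data by
only ~12%, and a slightly larger object at lower contrast is nearly
indistinguishable from the true one (size/amplitude degeneracy). Any
quadratically regularized solve — including the converged self-consistent
OO-SME update — therefore recovers the object's location and shape much
better than its amplitude; on these phantoms step 2 roughly doubles the RA
of the linear first pass but quantitative amplitude recovery would require
stronger priors (e.g. binary or level-set constraints) that are outside
this package's scope. The second-order surrogate S† = S² is
scale-dependent by construction (squared units); its effect is reported at
the package's working scale. The Laplace penalty treats all element
adjacencies equally (no edge-length weighting), and the complete electrode
model (contact impedance) is not implemented.
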