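# Methods

## Problem

Optical tomography reconstructs the scattering coefficient σ(x) of a
tissue from light measurements on its boundary.  `detomo` implements the
two standard forward models and a Bayesian inversion pipeline built
around a delayed-acceptance (two-level) Metropolis–Hastings sampler that
uses the cheap diffusion model to screen proposals for the expensive
transport model.

## Forward models

**Radiative transfer (RTE).**  The photon phase-space density f(x, v)
satisfies the scaled equation

    v·∇f = (σ/ε) L f,      L f = ⟨f⟩_v − f,

on Ω × S¹ with inflow data φ on Γ− = {(x, v) : x ∈ ∂Ω, v·n < 0}.  The
angular measure is normalized (⟨1⟩_v = 1) and ε is the Knudsen number,
the ratio of photon mean free path to domain size.  Discretization:
discrete ordinates with N_v cell-centered directions θ_m = (m + ½)·2π/N_v
and equal weights (cell-centering keeps cos θ and sin θ away from zero,
which node-centered sets with N_v = 16 would violate at θ = π/2), and
first-order upwind differences in space on a tensor grid x_i = i·dx.
Inflow rows are enforced as identity equations on the discrete incoming
set (any direction whose upwind stencil exits the domain).  The sparse
system is solved by LU factorization (one factorization per medium,
reused across all source vectors); a GMRES+ILU backend is available.
In "pseudo-2D" slab mode the spatial domain is [0, 1] with the full
circle of directions and transport term cos θ·∂x only.

**Diffusion (DE).**  As ε → 0 the fluence ρ = ⟨f⟩_v satisfies
∇·(1/σ)∇ρ = 0 with Dirichlet data ξ inherited from φ.  (The dimensional
constant C_d = 1/d multiplying the operator is dropped — the equation is
homogeneous — and retained only where transport and diffusion data are
compared.)  Discretization: conservation-form finite differences on the
same tensor grid, with the face coefficient the harmonic mean
2/(σ_i + σ_{i+1}); this is the flux-continuous choice for the
piecewise-constant media used throughout, and coincides with lowest-order
FEM with mass lumping on this grid.  Keeping both models on one grid
makes the measurement operators align node for node.

**Boundary data extraction.**  The transport datum is the net boundary
current h_RTE = (1/(C_d ε)) Σ_m w_m (v_m·n) f(x_b, θ_m) over the full
direction set; the half-range (outgoing-only) variant retains an O(1/ε)
fluence term and does not converge to the diffusion datum, so it is
exposed only behind a flag.  The diffusion datum is extracted from the
conservation form: h_DE = −a_face·(ρ_inward − ρ_boundary)/dx with the
harmonic face coefficient.  This is the flux the interior balance
conserves; it is nodally exact for piecewise-constant media and makes the
net flux through the closed boundary vanish to round-off for continuous
Dirichlet data.  A polynomial one-sided stencil was rejected because the
benchmark media place σ-jumps within two cells of the boundary, where
such a stencil reads across the discontinuity and returns O(1)-wrong
fluxes.

**Sign orientation.**  Fick's law gives the small-ε limit of the
transport current as the *outward photon flux* −(1/σ)∂ρ/∂n.  `dtn_flux`
therefore defaults to that orientation (`convention="flux"`), so the two
forward maps converge; the bare normal-derivative datum +(1/σ)∂ρ/∂n is
available as `convention="gradient"`.

**Asymptotics of the discretization.**  First-order upwinding carries
numerical diffusion whose contribution to the normalized current scales
like σ·dx/ε relative to the physical flux.  At dx = 0.05 and σ up to 30
this dominates below ε ≈ 2⁻⁴: the *density* ρ still approaches the
diffusion solution monotonically along the ε-ladder, but the normalized
current h_RTE stops converging to h_DE at fixed dx (it does converge
under mesh refinement at fixed ε, which is how the property is tested).
The physical currents C_d·ε·h used as measurements shrink with ε and are
unaffected.

## Measurements and synthetic data

A design excites K = 20 unit Kronecker-delta sources at left-edge nodes
(isotropic over incoming directions for the RTE; the same nodal values as
Dirichlet data for the DE) and reads J = 80 detectors at all boundary
nodes, corners counted once.  The dx = 0.05 grid has 21 left-edge nodes;
the bottom 20 are excited (the stated 20 experiments cannot use "all 21
nodes", and excluding both corners would leave 19 — the top corner is
dropped).  The measured quantity is the physical outgoing current
C_d·ε·h.  Synthetic data adds i.i.d. N(0, γ²) noise, γ² = 1e-4, from a
seeded generator; the same vector feeds both posteriors, mirroring one
physical experiment.  Data are generated by the transport model on the
same grid used for inversion (the "inverse crime" is accepted: the goal
is method verification, not discretization-robustness).

## Posteriors and samplers

The unnormalized log posterior is log μ0(θ) − m(θ)/(2γ²) with misfit
m(θ) = mean over the J·K channels of (b − G(θ))².  The *channel-averaged*
misfit (rather than the plain sum) is the package default: with 1600
channels the summed form concentrates the posteriors so sharply that the
surrogate's O(ε) model error exceeds the posterior width at moderate ε
and the second-level screen rejects every proposal, while the averaged
form keeps both posteriors diffuse and the delayed-acceptance scheme
productive across the whole ε-ladder — the regime all reference results
live in.  The summed form remains available
(`misfit_normalization="sum"`).

One-level sampling is symmetric random-walk Metropolis.  The two-level
sampler pre-accepts with the DE posterior (rate α), then corrects with

    β = min{1, [μ_DE(x|b) μ_RTE(y|b)] / [μ_DE(y|b) μ_RTE(x|b)]},

the closed form in which the integral-form second-level proposal density
cancels.  The RTE forward map is evaluated only for pre-accepted
proposals (verified: target-solve count = n_preaccept + 1).  All
acceptance arithmetic is in log space; per-state forward maps are cached
so each state is solved exactly once.  Out-of-support proposals are
rejected at level 1; no reflection at the box boundary.  Exact
finite-state versions of both kernels (`discrete_mh_matrix`,
`discrete_two_level_matrix`) serve as oracles for detailed balance and
stationarity.

**Priors and initialization.**  Example 1 (single disk at (0.5, 0.5),
parameters (r, h), truth (0.4, 10)): uniform r ∈ [0, 0.5], h ∈ [8, 12];
chain starts at the prior midpoint.  Example 2 (five disks, parameters
(h1..h5, r1..r5)): the reference prior is stated only as "uniform"; the
package uses heights ∈ [0, 15] and radii ∈ [0, 0.25] — wide enough to
contain every true inclusion (max height 10, max radius 0.19) while
keeping all disks inside the unit square for the fixed centers.  The
chain starts at (0.6 + 0.4·u)·truth componentwise (an initial guess up to
40 % low).  Proposal: componentwise Gaussian random walk, widths 0.02 for
radii and 0.2 for heights (≈ 4–5 % of the prior ranges).  No burn-in is
discarded by default.  A single run seed drives everything: data seed =
seed, chain/initialization seed = seed + 1.

## Distances and cost model

Chains are smoothed with a Gaussian product-kernel KDE (Silverman's rule
by default) on the prior box with 100 cells per dimension, renormalized
over the box; Hellinger and KL distances are computed cell-wise, with
densities floored at 1e-30 under the KL logarithm.  The cost model for k
accepted samples is Cost1 = (k/r1)·C_R and
Cost2 = (k/(αβ))·C_D + (k/β)·C_R, with ratio → r1/β as C_D → 0; C_D and
C_R can be measured as median wall times over repeated solves (`detomo
cost --measure`).

## Problem sizes and defaults

Benchmark grids: slab 21 × 16 = 336 unknowns; unit square
21 × 21 × 16 = 7056 unknowns (sparse LU ≈ 0.25 s, so a full 10³-step
two-level run costs a few minutes).  The test-suite reruns the
reconstruction benchmarks at 300 sampling steps, which leaves the
acceptance-rate estimates within a few points of their full-scale values;
the reproduction script uses the full 10³ steps.

## What the synthetic benchmark does and does not show

The generator reproduces the benchmark studies exactly as specified:
parametric disk/bump media, delta sources, full boundary detector
coverage, additive homoscedastic Gaussian noise, and data simulated by
the same discretization used for inversion.  It does not emulate real
detector physics (numerical aperture, shot noise), model error between
the RTE and tissue, absorption or anisotropic (Henyey–Greenstein)
scattering, or out-of-model media — so passing tests demonstrate the
correctness and internal consistency of the solvers and samplers, not
field performance on clinical data.

## Known limitations

* Monte-Carlo error of 10³-step chain means is comparable to a third of
  the posterior spread (≈ 0.05 for radii of spread ≈ 0.07); marginal-mean
  reproduction at that chain length is accordingly seed-dependent.
* The upwind transport scheme is not asymptotic-preserving (see above).
* Characteristic-function media are not W^{1,∞}; the admissibility check
  is a discrete-grid verification aid, not a gate.
* The slab convergence study's inflow data (unit isotropic on the left,
  vacuum on the right, with matching Dirichlet data for the diffusion
  reference) is an assumption; the reference study does not print its
  boundary data, and the printed error magnitudes could not be reproduced
  under any of several plausible boundary-data and discretization
  variants (the monotone decay and the saturation order of magnitude
  could).
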