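# Methods

`petalign` estimates the rigid misalignment of PET detector blocks — a
translation `T_d` (mm) and a rotation `R_d` (degrees, about the block's own
designed axes) per block `d` — directly from TOF-binned list-mode
coincidence data, given a known tracer distribution. This note records the
model, the estimation procedure, the synthetic data generator used to
validate it, and the numerical choices that shape the implementation.

## Alignment model

A scanner blueprint consists of block centre positions `P ∈ R^{Ndet×3}` and
orthonormal local frames `(X_d, Y_d, Z_d)` (for cylindrical scanners:
tangential, radially-outward DOI, axial). The realized geometry is modelled
as

    P̂_d = P_d + T_d,        (X̂,Ŷ,Ẑ)_d = R(R_d) (X,Y,Z)_d

where `R(R_d)` rotates about the *blueprint* axes of block `d`, intrinsic
x → y → z order. Because all three rotation axes are the (fixed) blueprint
axes, the conjugation identity reduces the update to a right-multiplication
of the basis by a standard Euler matrix, which keeps both the forward map
and its derivatives cheap. The deviations of interest are small (a few mm /
degrees), so the composition-order ambiguity is second-order; the order is
nevertheless fixed and tested.

Crystal voxels — the discretization cells of a block's interaction space —
are described by a lookup table of local centres and half-extents; crystal
`(d, cr)` maps to global coordinates through the block frame. Regular
binnings of the block volume (e.g. 1×1×1 mm³ cells of a 48×48×10 mm³
block) are provided as a parametric constructor; irregular tables are
supported by the same container.

## Forward model

The expected rate of a coincidence bin `(λ1, λ2, t)` is

    L = s · E_λ1 E_λ2 · exp(−∫ A dl) · ∫ K_TOF(x, t) F(x) dl

with the integrals along the line between points drawn uniformly inside the
two crystal voxels (averaged over `n_crystal_samples` draws, antithetic in
pairs), `F` the known activity, `A` an optional attenuation map, `E`
per-crystal efficiencies, and `K_TOF` a Gaussian of FWHM `c·CTR/2` centred
on the position encoded by TOF bin `t` (bin width defaults to FWHM/3;
midpoint rule over the bin, with an exact-erf option). The global scale `s`
absorbs acquisition duration and the arbitrary normalization of raw-count
efficiencies. Solid-angle and incidence-angle factors are deliberately not
modelled; on the scanner scales used here they vary by a few percent across
accepted pairs and are largely absorbed by per-crystal efficiencies.

Line integrals are midpoint sums over a subdivision of the chord whose
count is fixed per problem (from the scanner diameter and the grid
spacing), evaluating only samples inside the activity bounding box and a
±3.75σ TOF window. Fixing the subdivision — rather than the sample spacing —
keeps the quadrature smooth under endpoint perturbations, which the
analytic gradients rely on. A classical Joseph-method projector
(principal-axis plane stepping, bilinear transverse interpolation, refined
along-axis quadrature) is provided for plain line integrals and serves as a
cross-check; grids are trilinear between voxel centres and exactly zero
outside their box. The analytic likelihood gradient assumes the activity
vanishes at its grid boundary; every rasterized phantom is padded so this
holds.

Gradients of `L` with respect to all `6·Ndet` parameters are computed
analytically: the chain rule through the crystal endpoints combines the
spatial gradient of the trilinear field, the derivative of the TOF kernel
argument, and the derivative of the chord length; rotations enter through
the derivative of the Euler matrix times the local crystal offset. A
central-finite-difference test pins the implementation to 1e-3 relative.

## Likelihood and estimation

The estimate minimizes the Poisson negative log-likelihood

    NLL(T, R) = Σ_bins [ s·L − C·log(s·L) ]

over all valid bins. The sum is estimated per iteration by a weighted
batch:

* all (or a uniform subsample of) histogram-support bins contribute both
  terms, `w·(s·L − C·log(s·L + δ))`;
* the rate mass of the astronomically many empty bins is estimated by
  TOF-*marginalized* crystal-pair draws stratified over detector pairs
  (`Σ_t L` is a plain line integral), with weights `Ncr²/n_per_pair`.

Four details proved load-bearing at small batch sizes and are worth
recording:

1. **Counted bins always carry their own rate term.** Estimating the
   support's rate mass by sparse uniform draws lets an optimizer inflate
   rates on counted bins invisibly to the estimator (the batch loss then
   falls without bound). With the support's `+s·L` counted exactly, there
   is no incentive to place rate mass anywhere unsampled.
2. **The scale is never profiled against the same batch that is being
   minimized.** Per-batch profiling places a noisy estimate inside a
   logarithm; by Jensen's inequality, configurations that *inflate the
   estimator's variance* are rewarded. The scale is instead tracked by a
   strongly damped EMA across iterations (and frozen per deterministic
   stage), so it is constant with respect to any single batch. Profiling
   remains available (and exact, via the envelope theorem) for analyses at
   fixed parameters.
3. **The empty-bin strata integrate a blurred, coarsened activity**
   (1.5 mm default). The total-rate functional is smooth, so this changes
   it only at second order in the blur width — but it makes each stratum
   cheap (coarser quadrature) and, more importantly, un-evadable: against
   sharp sub-millimetre sources a deterministic optimizer can tune the
   geometry so that the specific sampled chords miss the activity
   (observed as a frozen-batch loss far below the truth's that does not
   generalize to fresh batches); against millimetres-wide blobs sampled
   from hundreds of pair directions, millimetre-scale moves cannot hide
   rate mass.
4. **The log guard is relative and robust.** `δ = 10⁻³ ×` (weighted mean
   of counted-bin scaled rates, each capped at 10× its own count). An
   absolute floor silently swallows the log-term gradients whenever the
   model mass spreads over many bins — exactly the coarse-blur regime
   below; an uncapped mean can be raised by inflating a handful of bins
   (subsidizing `log δ` for abandoned ones); a median collapses when
   sparse in-voxel sampling zeroes over half the individual rates (coarse
   crystals, point-like sources).

### Optimization protocol

The reference protocol (Adam, 200 iterations, 5·10⁶-bin batches, learning
rates 1 mm / 0.1°) presumes batch gradients with per-coordinate
signal-to-noise well above one. At desk-scale batches (10³–10⁵ bins) this
does not hold — the same Adam loop is a random walk of step ≈ lr — so the
package layers three small-batch adaptations on top, all recorded here as
its own design choices:

* **Coarse-to-fine activity blurring** (`blur_stages`): early iterations
  evaluate the likelihood against `F` convolved with an isotropic Gaussian
  (σ descending, e.g. 2 → 1 → 0.5 → 0 mm). Sub-millimetre calibration
  phantoms give zero gradient to blocks more than a crystal pitch away;
  blurring widens the attraction basin to the initial-misalignment scale.
* **Cosine learning-rate decay** for the stochastic phase.
* **A deterministic polish** (`polish_iterations`): one large frozen batch
  (full support where affordable) with frozen in-voxel offsets defines a
  smooth deterministic objective; L-BFGS-B minimizes it through a blur
  ladder. Rotations stay frozen during coarse stages — at blur widths far
  above the rotation lever arm (≈0.3 mm per degree for 48 mm blocks) they
  are nearly unidentified and drift along flat directions — and are
  released when the blur reaches the crystal pitch; they are expressed in
  mm-equivalent units (3° per unit) so the Hessian approximation is not
  dominated by the translation/rotation curvature gap. Parameters are
  box-bounded at ±8 mm / ±8°. The last ladder rung is repeated on
  independent frozen batches and the solutions averaged (loss outliers
  rejected): each repetition's error is dominated by its batch's
  subsample noise, which independent averaging beats as 1/√reps. A full
  Gauss-Newton Hessian over all blocks (per-bin outer products, including
  the cross-block coupling of each bin) is available as an alternative
  final-stage optimizer (`polish_newton`).

The benchmark preset (`desk_optimizer`) uses a 24-iteration Adam phase at
σ = 2 mm blur with 8·10³-bin batches, then a frozen-batch ladder of
1.4·10⁵ bins (data subsample plus strata) through σ = 0.5 (translations
only) → 0.5 → 0.25 → 0 mm with 24 L-BFGS iterations per stage and two
averaged final repetitions; the lighter variant drops the 0.25 mm rung and
uses 1.2·10⁵-bin batches. One benchmark calibration takes several minutes
on one CPU core, and repeated runs that differ only in their batch draws
scatter the final mean translation error by roughly ±30% — the estimate
remains optimizer-noise dominated at this compute scale.

The likelihood is invariant under a common rigid motion of all blocks plus
the phantom, so accuracy is always reported after a closed-form rigid
Procrustes registration (positions fitted, rotation applied to axes;
no scaling, no reflection).

## Synthetic data generator

The generator replaces a Monte-Carlo particle-transport study at desk
scale. Annihilation points are drawn analytically from the phantom (uniform
in spheres; across the cross-section of a clamped cubic B-spline tube,
uniform in arc length; shell and hot-rod volumes), or exactly from the
trilinear density of a voxel grid. Back-to-back photon pairs are cast as
opposite rays; each side finds the nearest block (slab test in block-local
frames) and interacts at an exponential depth along its chord through the
block (μ = 0.083 mm⁻¹, LYSO-like at 511 keV; photons whose depth exceeds
the chord escape). The event is assigned the crystal voxel *containing the
interaction point* — matching the forward model's uniform-in-voxel
assumption; assignment at the entry face instead produces an
obliquity-correlated DOI bias that measurably distorts rotation estimates.
Accepted pairs are thinned with probability ∝ `E_λ1 E_λ2 exp(−∫A)`; the
TOF value is the true signed midpoint offset of the interaction points plus
Gaussian timing blur, then binned.

Not emulated: energy deposition and windows (every accepted event is
implicitly in-window), scatter, randoms, positron range, non-collinearity,
inter-block penetration (a photon traversing its first block escapes rather
than reaching the next), dead time and pile-up. Passing recovery tests
therefore demonstrates correctness of the estimator under its own physics
assumptions — the classical Monte-Carlo ingredients it omits act, on real
data, as additional efficiency-like and resolution-like mismatches of the
kind the reference study showed the method tolerates.

Phantom rasterization preserves first moments: point sources are splatted
trilinearly (sub-voxel centroid errors of a nearest-voxel scheme, ~0.1 mm,
otherwise propagate one-for-one into block-position bias), tubes by
sub-voxel coverage fractions of the region within one radius of the spline.

Per-crystal efficiencies are estimated by the fan-sum method: each
crystal's efficiency is its raw coincidence count with partners in a fan of
opposing blocks (optionally including axial neighbours), with no geometric
correction — matching the in-system protocol whose raw counts also absorb
solid-angle and depth-acceptance patterns.

## Reconstruction

TOF list-mode OSEM with fixed iteration count: events are sorted by the
transaxial azimuth of their LOR (folded to [0, π)) and dealt round-robin
into subsets of equal size; the update forward-projects along
`lors_per_event` lines sampled inside the two crystal voxels, backprojects
the event ratios with the same TOF weighting, and divides by a sensitivity
map (Monte-Carlo sum of efficiency × attenuation backprojections over
crystal pairs, stratified per detector pair). Nonnegativity is preserved by
construction and voxels without sensitivity stay zero. The reconstruction
deliberately reuses the forward-model projectors (single source of truth).

## Evaluation metrics

Per-axis errors: `ΔT_i` is the mean over blocks of `|P*_{d,i} − P̂_{d,i}|`
(after Procrustes); `ΔR_i` the mean angle between corresponding local axis
vectors, in degrees. The axis-angle definition cannot see a rotation about
the axis itself; it is kept as the field-standard report, with per-block
residuals available for finer analysis. Image scores on sum-normalized
images: PSNR (`10·log10(max²/MSE)`), a global (single-window) SSIM with
`C1=(0.01L)², C2=(0.03L)²`, COV (100·σ/μ in a uniform-region mask), and
per-diameter peak-to-valley ratios sampled at the known synthetic rod
layout (rod centres vs. inter-rod midpoints).

## Problem sizes

The bundled experiment presets use a 24-block, 3-ring scanner (75 mm inner
radius, 48×48×10 mm³ blocks), ten point sources (radius 0.125 mm) in a
20 mm-radius, ±30 mm FOV cylinder — or a 250 µm tube through the same ten
points — misaligned with σ_T = 2 mm, σ_R = 2°, CTR 250 ps, and 2–3 million
coincidences; activity grids use 0.3 mm voxels. Test fixtures use smaller
rings and coarser crystals. These sizes are the package's desk-scale
choices; every count, size and learning rate is a config field, and the
reference GPU-scale protocol is reproduced by the `OptimizerConfig`
defaults.

## Known limitations

* Rotations are weakly identified relative to translations (lever arm
  ≈ 0.3 mm/° for 48 mm blocks); their errors are correspondingly more
  sensitive to event count and batch size, mirroring the reference study's
  pattern across crystal binnings.
* The estimator has a per-block no-op stability floor of roughly
  0.1 mm / 0.2° (∞-norm): even from an exact initialization with the full
  support and estimated efficiencies, the ML fit absorbs the
  non-separable geometric factors the rate model omits (solid angle,
  within-voxel obliquity–depth correlation) into small geometry moves.
  Per-axis *means* over many blocks land well below this floor.
* The axis-angle `ΔR` metric is blind to rotation about the compared axis.
* The rate model omits solid-angle factors; with uniform efficiencies this
  leaves a percent-level per-bin mismatch (absorbed in practice by fan-sum
  efficiencies).
* The simulator's exponential-depth interaction model is a single-interaction
  approximation without inter-crystal scatter or block cross-talk.
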