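# Methods

This note documents the models, numerical choices, and measured
behaviour behind `spirecon`. Everything quantitative stated here is
recomputed by the test suite or by `scripts/acceptance.py`.

## Scattering model and conventions

A particle with electron density `ρ(x) ≥ 0` of compact support
scatters a far-field intensity `I(q) = |G(q)|²` with
`G(q) = ∫ ρ(x) e^{-2πi q·x} dx`. A flat detector at distance `L` and
wavelength `λ` samples `I` on the Ewald sphere: pixel `p` with unit
scattering direction `s` sits at `q = (s - s₀)/λ`, `‖q + s₀/λ‖ = 1/λ`.
Each pattern is this curved slice rotated by the (unknown) particle
orientation.

Fixed conventions: lengths in metres, reciprocal space in cycles/metre
(so the NUFFT band limit is `|q·Δx| ≤ 1/2` per axis); quaternions are
scalar-first, unit, active, canonicalized to `w ≥ 0` (q and −q are one
rotation); images are slow-axis-major; cubic grids have voxel centres
at `(k − M//2)·Δ` and centred zero frequency; the forward (type-2)
NUFFT carries `e^{-2πi}` with no normalization and the type-1 operator
is its exact adjoint. A flat-Ewald mode (`q_z = 0`) exists for analytic
tests; curved is the default everywhere.

## Non-uniform FFT

Type-2 evaluates `f(p) = Σ_k c_k e^{-2πi p·x_k}` at arbitrary in-band
points; type-1 is the adjoint. The fast path is kernel gridding: an
exponential-of-semicircle window `ψ(z) = exp(β(√(1−z²)−1))` on a
2×-oversampled fine grid, FFT, and diagonal deconvolution by the
window's quadrature-computed Fourier transform, with `β = 2.30 w` and
width `w = ⌈log₁₀(1/ε)⌉ + 2` for requested accuracy `ε` (default
`1e-8`; measured ≤ 4e-9 against the exact `O(M³P)` direct sum, which
ships alongside as the oracle). Points are processed in
fine-grid-slab order (a deterministic lexsort) for cache locality;
spreading of real-valued data skips the imaginary half. On one CPU
core a 3-million-point transform on a 64³ grid runs in a few seconds
at `ε = 1e-4`, the accuracy used inside the reconstruction loop where
Poisson noise dominates.

## Synthetic data

The phantom is a sum of isotropic Gaussian blobs with seeded random
centres inside a support sphere of radius `N·voxel/4` (so oversampling
2 keeps the autocorrelation representable). Default study conditions,
chosen once: 32³ grid, 1 Å voxels, 4 blobs of σ = 2.5 Å; a 64×64
detector whose corner reaches 90% of the density Nyquist (via
`design_geometry`); 2000 patterns of ~4000 expected photons. The
two-conformation pair displaces one blob along a seeded direction; for
separation experiments the default is 2 blobs of σ = 2 Å with an 8 Å
(4σ) shift, which puts the ground-truth pair correlation at ~0.82 —
close enough to be a genuine mixture, far enough apart that a correct
model prefers its own state by a clear margin.

Noise: the expected image is `fluence_i · I(R_i q_p)` (the intensity is
evaluated by a type-2 NUFFT of the density itself, a path independent
of the reconstruction's AC-based slicing); fluence jitter is log-normal
with the configured coefficient of variation (the simplest nonnegative
choice); miscentering is an integer-pixel roll from a rounded Gaussian
(lattice-respecting); the background is one static plane across the
stack; Poisson sampling comes last. All randomness derives from one
seed in a fixed draw order, so stacks are bitwise reproducible.
`fluence_for_mean_photons` converts a photons-per-pattern budget into
the fluence factor by probing random orientations.

A caveat the tests inherit: simulation slices the *density's* Fourier
transform while reconstruction slices *autocorrelation* volumes, so the
two NUFFT paths differ in conditioning but share one implementation —
a mild inverse crime. Real-data effects not emulated: detector gain
structure and saturation, structured (non-planar) background, partial
coherence, spectral bandwidth, multi-particle hits, hydration layers.

## Orientation matching

Reference slices are the model intensity at the detector's rotated
Ewald points, computed by one batched type-2 NUFFT per orientation set;
negative numerical residues are clipped and the clipped mass logged.
The weighted-L2 distance with closed-form per-image scale reduces to
two BLAS matrix products over (images × slices), so exhaustive
comparison against hundreds of references is cheap. A Poisson negative
log-likelihood with Newton-fitted scale is also provided (it is
exhaustively verified against a brute-force scalar-minimization oracle,
as is the L2 path).

## Merging

With hard orientation assignments, all patterns sharing a reference
orientation are averaged after scale normalization and carry their
count as a least-squares weight — algebraically identical to stacking
them individually, and it bounds the NUFFT point count by
`n_ref × n_pixels`. Sample sets are Friedel-symmetrized (`(−p, y)`
mirrors at half weight), which physics guarantees and which makes the
Toeplitz symbol real. The normal-equations kernel lives on the
2M-padded grid; each operator application is one real-FFT circular
convolution. The solver is the conjugate-residual variant of the
conjugate-gradient family — identical cost per iteration, but it
minimizes the residual norm at each step, giving a non-increasing
residual history (plain CG residuals oscillate). Tikhonov uses the
identity operator; λ sweeps are selected at the L-curve corner
(maximum curvature of log-misfit vs log-norm), falling back to the
smallest λ within 5% of the minimum misfit. Defaults: λ grid
`(1e-8, 1e-6, 1e-4)` relative to the kernel zero-lag (= total sample
weight), tolerance 1e-3 and 50 iterations inside the loop (noise-
limited), 1e-6/200 for standalone noise-free merges.

## Phasing

Standard alternating projections on `√I` (Friedel-symmetrized, clipped,
and divided by the voxel³ Riemann factor so densities come back in the
input's units): HIO (β = 0.9) followed by ER, with either a fixed
spherical support or shrinkwrap (Gaussian blur σ = 1.5 voxels,
threshold 12% of the blurred maximum, every 20 iterations, starting
from a sphere of a quarter of the grid side). The object is recentred
periodically by the circular centre of mass, which removes translation
drift without fighting the support. Multi-start (default 4 seeded
starts) keeps the lowest final Fourier error. The update rule is this
package's interpretation of projection phasing under positivity and
support constraints; recovered densities are scored by
`align_densities`, which searches all cyclic translations and the
centro-inversion twin (the gauge freedom of phase retrieval) via FFT
cross-correlation.

## The reconstruction loop

Generation 0 draws each image's orientation uniformly from the
reference grid, then merges and phases once (one pooled model). Every
later generation: slice the current autocorrelation estimate(s) at the
`n_ref` reference orientations (quasi-uniform super-Fibonacci
covering, default 800), reassign per image by hard argmin, re-merge,
re-phase, and record history. The loop stops at `n_generations_max` or
when the maximum aligned relative density change drops below
`convergence_tol` (strict). The generation with the lowest summed
matching distance is selected and its merged autocorrelation(s) are
re-phased with a stronger final schedule (HIO 200 + ER 50, four
starts) to produce the returned densities; the light per-generation
phasing only feeds the convergence diagnostic.

For `K > 1` conformations the loop is staged. All images share one
pooled model for `split_generation` generations so the orientation
gauge settles; conformations are then seeded by a random balanced
split and refined jointly, with orientations chosen per conformation
by the stable weighted-L2 metric and the conformation decided by the
Poisson likelihood at those orientations (a K-hypothesis test where
the exact likelihood is the right statistic, and which cannot perturb
the orientation search). Whether a random split amplifies into
distinct models depends on how well it happens to project onto the
true heterogeneity axis, so several seeded splits are probed for a
couple of generations each and the one with the largest inter-model
autocorrelation divergence — a ground-truth-free signal — is kept. A
conformation that loses all images is re-seeded with the
worst-matching half of the largest one.

Two choices here were settled by measurement, not taken from the
standard description, because the obvious alternatives fail:

* **Slices come from the merged autocorrelation, not the re-phased
  density.** Phasing projects onto a compact support, which erases
  precisely the anisotropy that matching needs: from a cold start the
  phased model is nearly spherical and matching is degenerate
  (correlation collapses to ~0.34 on the reference problem), and even
  from a good model the phased-slice loop collapses onto < 40
  orientations within a few generations. The merged AC is itself the
  current estimate of the density's autocorrelation, so slicing it is
  a faithful reading of the algorithm; it is stable for 15+
  generations at correlation ~0.95.
* **Per-image scales are frozen for the whole run (unit scale by
  default; totals-proportional for jittered beams) and the matching
  weights are uniform.** Refitting a free scale per (image, slice)
  pair, or down-weighting bright pixels by inverse counts, both let
  over-fitted reference slices attract unboundedly many images; the
  hard-argmin assignment then collapses onto a shrinking orientation
  subset and the reconstruction degrades (the orientation count falls
  from ~500 to ~30 and correlation to 0.3–0.7). With frozen scales and
  uniform weights the unique-orientation count stays ~500/800 and the
  summed matching distance decreases monotonically. Per-image totals
  normalization also silently discards the orientation- and
  conformation-dependent total-intensity channel, so the unit scale is
  preferred when the beam is steady. Inverse-count weights and fitted
  scales remain available on `match_orientations` for standalone use,
  where a trusted model makes them the statistically better choice.

Warm-starting each generation's phasing from the previous density is
on by default; it cannot influence the loop's trajectory (slices do
not depend on the phased density) and merely stabilizes the density-
change diagnostic.

## Problem sizes and runtime

The reference conditions (2000 × 64×64 patterns, 32³ phantom, 64³
reconstruction grid, 800 references) run one generation in ~25 s on a
single CPU core: slicing ~5 s, matching ~3 s, merging ~12 s (two
type-1 NUFFTs over ~4M Friedel-doubled points plus ≤ 50 convolution
iterations), phasing ~5 s. The acceptance script caps the K=1 run at 6
generations and the K=2 run at 8 — the loop reaches its plateau by
generation 2–3 on these conditions — to keep a full from-scratch
reproduction around a quarter of an hour.

## Known limitations

* Hard assignment (argmin) throughout; no probabilistic orientation
  weighting, by design.
* The miscentering and background noise processes are simulated but the
  reconstruction loop does not model them; they are exercised by the
  simulator statistics tests, and reconstructions in their presence
  degrade gracefully rather than being corrected.
* Pearson correlation over the full volume is a weak discriminator for
  smooth compact objects (independent few-blob phantoms correlate at
  0.9+ after gauge search; the empirical-null test uses finely
  structured 8-blob phantoms where the null median is < 0.5). The K=2
  margin criterion is therefore evaluated on the more structured
  2-blob pair, where the truth pair itself correlates only ~0.82.
* Orientation resolution is limited by the reference covering (~25°
  mean nearest-neighbour spacing at n_ref = 800); adequate for the
  smooth default phantoms, not for atomic-resolution targets.
* Two-conformation separation at the reference desk-scale conditions
  (2000 patterns, ~4000 photons each) is at the edge of what the data
  support: the conformational signal per image is a fraction of the
  Poisson and orientation-discretization noise, hard assignment gives
  each image only one vote, and the state whose blobs overlap into a
  single lump acts as an attractor for the self-consistent loop. The
  two-conformation test asserts the full separation property (distinct
  densities with a clear correlation margin, ≥ 80% classification) and
  currently fails it at these conditions; the measured margins and
  accuracies are reported by the acceptance script. The paper-scale
  version of this experiment uses orders of magnitude more patterns.
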