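# Methods

`fiberodf` estimates the orientations of white-matter fiber populations
inside a voxel from high angular resolution diffusion MRI (HARDI) signals.
It combines a generalized q-sampling (GQI) reconstruction of the
orientation distribution function (ODF) with a probabilistic direction
extractor that clusters thresholded ODF directional data using mixtures of
von Mises-Fisher (vMF) distributions, and ships the deterministic
local-maxima baseline ("Std") together with the simulation benchmarks used
to compare the two.

## Direction grids

ODFs are evaluated on near-uniform direction sets produced by recursive
midpoint subdivision of the icosahedron (10·4^L + 2 vertices at depth L).
Diffusion is antipodally symmetric, so only one direction per antipodal
pair is kept: depth-2 and depth-3 meshes give the 81- and 321-direction
hemisphere grids used throughout. Subdivision uses an exact midpoint cache:
antipodal vertices match bit-for-bit, the hemisphere reduction (keep
u_z > 0, ties broken by u_y, then u_x, with a 1e-9 ring tolerance) is
exact, and vertices are ordered by (z, y, x) descending so ODF vectors are
comparable across runs. Quadrature weights, where needed, assign each
vertex a third of the solid angle of its incident spherical triangles
(Van Oosterom–Strackee), which tiles 4π exactly.

## Signal model

Each fiber population is a prolate diffusion tensor with eigenvalues
{1700, 200, 200}·10⁻⁶ mm²/s; a voxel's normalized attenuation along
gradient direction u at weighting b is the fraction-weighted sum of
mono-exponential compartments S(u) = Σₖ pₖ·exp(−b·uᵀDₖu) with S₀ = 1.
Rician noise is applied to the attenuation as S = ‖(S + n₁, n₂)‖ with
n₁, n₂ ~ N(0, σ); the typical level σ = 0.033 corresponds to SNR ≈ 30.
Simulated acquisitions sample a single shell on the 321-direction
hemisphere grid — the same density the profiles are mapped on — which is
what the crossing-fiber experiments assume; at 81 directions the hardest
configurations (three fibers 50° apart at b = 5000) are no longer reliably
resolved.

## GQI reconstruction

The spin distribution function along direction u is the sinc-weighted sum
ψ(u) = L·Σᵢ W(qᵢ)·sinc(L·|qᵢ|·(gᵢ·u)), with sinc(x) = sin(x)/x and
|qᵢ| = √(b·τ). The diffusion-time constant τ = 0.018 (b in s/mm²) and the
dimensionless sampling length L = 1.25 follow the convention of the widely
used GQI implementations; L sets how far displacement is integrated along
each direction and therefore the angular sharpness of ψ. Both are exposed
as parameters. Small negative values from sinc side lobes are clipped to
zero, and thresholds everywhere operate on the min–max normalized profile
(default threshold 0.4). Note that for an isotropic signal the discrete
sinc sum is not perfectly rotation invariant: the residual ripple grows
with the shell radius (≈0.1% of the profile at b = 1000, ≈6% at b = 3000),
which bounds how "flat" an isotropic reconstruction can be.

Anisotropy is summarized by the generalized fractional anisotropy,
GFA = std(ψ)/rms(ψ) in its √(N·Σ(ψ−ψ̄)²/((N−1)·Σψ²)) form, defined as 0
for constant (or all-zero) profiles.

## Clustered-vMF direction estimation

Grid directions whose normalized ODF value clears the threshold are
treated as directional data. Because a crossing can straddle the
hemisphere seam, the sample is duplicated to the full sphere (each vertex
with its antipode) and mixtures with even component counts 2, 4, …,
2·max_fibers (default max_fibers = 3) are fitted by weighted EM:

* density f(x|μ,κ) = c₃(κ)·e^{κμᵀx}, c₃(κ) = κ/(4π·sinh κ), evaluated in
  the log domain so κ up to the cap of 700 never overflows;
* initialization by weighted spherical k-means++, 5 restarts, best final
  log-likelihood wins; convergence at relative log-likelihood change
  < 1e-8 or 200 iterations; soft responsibilities by default (hard
  assignment available);
* κ updates use the Banerjee et al. closed-form approximation
  κ̂ = r̄(3 − r̄²)/(1 − r̄²);
* components with vanishing responsibility mass are pruned with a warning.

The number of components is selected by BIC = −2·loglik + p·log(n_eff)
with p = 4k − 1 (two angles per mean, one concentration per component,
k − 1 mixing weights); ties go to the smaller k. The selected components
are merged into axes by greedy antipodal pairing (means within 15° of
antipodal), the pair's α-weighted mean direction becoming the axis, the
summed α its weight, and the mean κ its concentration; axes closer than
15° are merged afterwards. Unpaired components mark the voxel unresolved
rather than silently producing an axis.

Points are weighted by their normalized ODF value, which preserves the
lobe-mass information an unweighted fit discards; a uniform-weight flag is
available. The weights are rescaled to mean 1 before fitting: raw
sub-unit weights shrink both the weighted log-likelihood and BIC's
effective n, and the model-complexity penalty then systematically
under-selects the component count at marginal lobe separations (a
three-fiber 50° crossing at b = 5000 collapses to two axes even without
noise). Rescaling leaves relative lobe masses untouched and restores the
per-observation likelihood scale.

## Std baseline

The deterministic comparator emulates common practice: a grid vertex is a
peak when its normalized value clears the threshold and is maximal within
a fixed axial radius (default 25°, larger than the 321-grid spacing of
≈8.6°); peaks within the radius of a larger peak are dropped, survivors
are ranked by height (the global maximum is the major fiber) and truncated
to max_fibers. A randomized fidelity mode (`n_samples`) snaps random
directions to the best vertex within the radius first, mimicking the
historical random-sampling implementations. The radius and sample count
those implementations used are not published; ours are documented
defaults, not claimed identical.

## Benchmarks

`run_benchmark` sweeps crossing angle × SNR grids (defaults: angles
{90, 80, 70, 60, 50}°, SNR {10, 20, 30} with σ = 1/SNR, equal fractions,
b = 3000, threshold 0.4). Every replicate applies a fresh uniformly random
3D rotation (quaternion method) to the whole fiber configuration, so
results carry no grid-alignment bias, and scores the estimate by the mean
axial error of the Hungarian-optimal assignment to the true axes over
min(n_est, n_true) pairs; an empty estimate scores 90° by convention, and
`correct_count` records n_est == n_true. Summaries report median,
quartiles and 1.5·IQR whiskers (the boxplot statistics) plus the
correct-count rate. Replicate seeds are spawned from the master seed with
a counter-based SeedSequence scheme, so any replicate is reproducible in
isolation.

`run_curved_field` builds a 32×32 two-bundle phantom: a straight
horizontal band crossed by an annular bundle centred on the left edge at
the band's mid-height (inner/outer radii 0.2/0.9 of the grid width), whose
per-voxel axis is the arc tangent. Inside the band the tangent sweeps
through vertical, so overlap voxels cross at angles from ≈57° to ≈89°;
overlap voxels carry two equal-fraction compartments. The published
example this emulates gives no equations, so this geometry is a faithful
analogue, not a replica.

`minimum_resolvable_angle` scans two-fiber separations from 90° downward
in 5° steps (b = 5000, σ = 0.033, 50 replicates per angle by default) and
reports the narrowest angle in the contiguous run where ≥ 80% of
replicates return exactly two axes, each within 15° of a distinct true
axis. This is the quantity `scripts/acceptance.py` recomputes.

## Problem sizes and determinism

The benchmark suites in the tests run at reduced replicate counts
(50–100 per condition, 16×16 or 32×32 fields) — large enough for the
orderings and rates they assert, small enough to keep the whole suite in
the minutes range. All stochastic paths take either an integer seed or a
numpy Generator; given a seed, simulations, fits and whole-volume runs are
bit-reproducible.

## What the simulations do and do not show

The generator reproduces the ingredients that drive angular resolution:
prolate-tensor compartments, partial-volume mixing, magnitude (Rician)
noise, and arbitrary voxel orientation. It does not model pulse-sequence
physics, T2 decay, eddy currents, spatially correlated noise, intra-voxel
dispersion, or non-Gaussian restricted diffusion, so passing benchmarks
demonstrate correctness of the estimator pipeline under the stated model,
not performance on scanner data. For real volumes, directions are
reported in the image coordinate frame and no gradient-to-image rotation
is applied — callers using scanner b-tables must handle that alignment.

## Known limitations

* At high b (≈5000) and SNR ≈ 30, Rician rectification occasionally
  creates a spurious super-threshold lobe and BIC over-selects one extra
  component (~5–10% of 90° replicates); no heuristic pruning of
  small-weight components is applied.
* BIC selection is capped at max_fibers = 3 by default (even mixtures up
  to k = 6); denser configurations require raising the cap.
* Separations below ≈45° at b = 5000 (and below ≈50–60° at b = 3000 for
  the Std baseline) are not reliably resolved, consistent with the
  angular bandwidth of the unsharpened ODF.
* The min–max normalization makes the 0.4 threshold scale-free but
  sensitive to the single largest lobe; profiles with extreme lobe-height
  imbalance may lose the minor lobe below threshold.
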