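# Methods

This note records the models implemented, the defaults chosen where a
design decision was genuinely open, the numerical choices, and the
limits of what the synthetic evaluation shows.  Axis convention
throughout: arrays are (Z, X, Y) = (axial, fast, slow), 0-based,
half-open ranges; the axial voxel size defaults to 5 µm and the lateral
ones to 10 µm.

## Synthetic phantoms

The package is exercised entirely on seeded synthetic volumes with
exact ground truth.

**Layered structural phantom.** Three classes (background, epidermis,
dermis) separated by smooth height fields AB1 < AB2 < AB3, generated as
sums of low-frequency sinusoids (default amplitude 3 voxels, 3
components) around mean depths 14/28/52 voxels in a 64-deep volume, or
supplied explicitly.  Reflectivity means are 0.05/0.55/0.35
(background/epidermis/dermis): the epidermis is the brightest band in
skin OCT, the dermis intermediate.  Speckle is modelled as a
multiplicative unit-mean Gamma field (shape 4), the standard surrogate
for fully developed coherent-imaging speckle; additive Gaussian noise
(σ = 0.02) models detection noise.  Labels are rasterized before noise,
so they are exact.

**Vessel phantom.** Tubes are rasterized by distance-to-polyline
(radius ≥ 1 voxel); ground-truth mask and centerline voxels are
recorded before any artifact.  Artifact families and defaults:
additive Gaussian noise (σ = 0.05); salt-and-pepper noise (fraction of
voxels forced to 0 or the tube peak); stripe artifacts as full-extent
lines along the fast axis at seeded random (z, y) positions, adding a
fixed intensity (amplitude is specified as an absolute intensity rather
than a noise-std multiple — more controllable in tests and equivalent
up to a constant); axial tail artifacts extending *above* each tube
(toward the probe, the direction where decorrelation tails appear
behind large vessels), scaled by a factor strictly below 1 of the local
tube intensity and decaying exponentially (default length 5 voxels) —
tails are always dimmer than the vessel they shadow.  The tail
direction is configurable since physical tails can extend downward for
some geometries.

The phantoms reproduce the *artifact families* of decorrelation
angiography, not its physics: there is no interferometric forward
model, no real speckle correlation structure, no motion beyond stripe
lines, and tube cross-sections are circular.  Passing tests therefore
establish that each algorithm does what it claims on signals with known
truth — not that the defaults are tuned for any particular instrument.

## Curvelet transform and denoising

The 3D transform is a frequency-domain tight frame: smooth radial
windows on dyadic shells (Meyer-type smoothstep transitions, low-pass
below 2^(−n_scales) of the corner frequency, finest band extending to
the frequency-cube corner) multiplied by angular wedge windows obtained
by tiling the faces of the frequency cube (gnomonic coordinates
u = ξ_b/ξ_a, v = ξ_c/ξ_a on the dominant-axis face, smooth half-cell
overlap).  Windows are symmetrized under ξ → −ξ (required at Nyquist
planes of even-sized axes) and **pointwise normalized so that
Σ W² = 1 exactly**.  This makes Parseval and perfect reconstruction
hold by construction — measured round-trip error ≈ 3×10⁻⁸ relative,
limited only by the float32 window storage (forward and inverse share
the same windows, so the cast does not break tightness).  Defaults:
n_scales = ⌈log₂ min(shape)⌉ − 3; wedges per face 8 at the coarsest
directional scale, doubling every other scale (97 bands at 64³).
Coefficient blocks are full-size real arrays (no frequency wrapping or
subsampling): simpler, exactly invertible, and cheap at desk scale.

**Noise estimate.** Finest-scale coefficients are divided by their
band noise gain g_b = sqrt(mean W_b²) (the std a unit-variance white
field acquires in that band), pooled, and σ is the median absolute
deviation / 0.6745 — a robust estimate of the volume-domain noise std.

**Hard thresholding.** A coefficient at scale s survives iff
|C| ≥ C(s)·σ·g_b; C(s) = 3 for all scales, 4 at the finest.  The rule
is exact hard thresholding and is exactly idempotent in the coefficient
domain.  Re-running the full volume-domain pipeline is *not* exactly
idempotent — re-analysis of the reconstruction redistributes energy
through the redundant frame — so stability across passes is asserted on
recovered PSNR rather than on coefficients.

**Stripe filter.** A stripe elongated along axis e concentrates its
spectrum in the plane perpendicular to e; the stripe band set is all
directional bands whose central direction lies within 15° of that
plane.  Within each selected band, coefficients whose magnitude is at
or above the band's mean magnitude are zeroed; the rest are untouched
("mean" is the mean of coefficient magnitudes; the equality case is
zeroed).  The low-pass block carries bulk anatomy and is exempt from
both filters.

## Optimally oriented flux

By the divergence theorem, the oriented-flux matrix
Q_ij(x; r) = ∮_{|h|=r} ∂_i(G_σ*f)(x+h) n_j dA equals the smoothed
Hessian convolved with the solid-ball indicator, so Q is computed in
the Fourier domain with the analytic ball transform
B_r(ξ) = 4πr³(sin u − u cos u)/u³, u = 2πr|ξ|.  Pre-smoothing is
Gaussian with σ = 1 voxel (needed for a well-posed gradient of
near-binary input); the volume is mirror-padded by r + 2 voxels so the
circular convolution cannot wrap responses across borders.  This
FFT-based Q agrees with a direct numerical surface integral over a
discretized sphere within 5 % on tube phantoms.

Eigenvalues are obtained by standard symmetric eigendecomposition
(ascending, λ1 ≤ λ2 ≤ λ3; trace is conserved to 10⁻⁸).  The response is
R(x) = max over the integer radius grid {2..6} voxels of
max(−λ̄/r², 0).  The eigenvalue combination λ̄ = (λ1+λ2)/2 is the
default — the mean cross-sectional curvature, appropriate for tubes
with elliptical cross-sections — with λ1 alone available by
configuration.  The 1/r² factor is the sphere-surface normalization
that makes responses comparable across radii; with it, the per-radius
response at a tube center peaks at the true radius (±1 voxel on
phantoms).  Sub-voxel radii and anisotropic-voxel correction are out of
scope.

## Layer segmentation

B-scans are enhanced with CLAHE (8×8 tiles, clip limit 2.0 expressed as
a multiple of the uniform histogram level, 256 bins) and fed to a
U-Net: per level two 3×3 convolutions + ReLU, 2×2 max-pooling down,
2×2 transposed-convolution up with skip concatenation, 1×1 output
convolution.  The network is written in numpy with analytic backprop
(verified against finite differences) and Adam; float32 by default.
The loss is weighted cross-entropy plus soft Dice with equal weights —
the class-frequency imbalance between background and tissue makes plain
pixel losses insensitive, and inverse-frequency class weights plus the
Dice term counter it.  Desk-scale defaults: depth 2–3, 8–16 base
channels, 64×64 B-scans, 12–15 epochs, batch 8, learning rate 10⁻³;
training 70 such B-scans takes ~20 s on one CPU.  K-fold
cross-validation uses disjoint seeded partitions covering every sample
once and reports per-epoch loss/accuracy per fold; the returned model
is refit on all samples.  Training pools B-scans from several phantom
geometries (including noise-free ones); a single geometry generalizes
poorly to unseen boundary shapes.

Boundary extraction per A-line: AB1 = first epidermis voxel, AB2 =
first dermis voxel, AB3 = one past the last dermis voxel.  An A-line
with several runs of a class keeps the longest run (robust to stray
speckle misclassification) and is QC-flagged; an A-line missing a class
is NaN and never interpolated; ordering AB1 ≤ AB2 ≤ AB3 is enforced by
clipping after extraction.  Boundary error is the mean absolute axial
deviation over columns defined in both surfaces.  Thickness maps are
boundary differences × the axial voxel size; summaries (mean, variance)
exclude undefined columns.  Segmentation quality is judged on boundary
error, which stays meaningful under heavy class imbalance; no numeric
boundary-error reference exists for real data, so acceptance is phantom
recovery (≤ 2 voxels mean absolute error on held-out B-scans).

## Vesselization

Smoothing uses an explicit 5×5×5 Gaussian kernel; the fixed support
needs a width, chosen as σ = 1 voxel, truncated and renormalized to
unit sum.  The global threshold defaults to Otsu on the
smoothed volume (fixed-value and percentile variants exist for
reproducibility across timepoints); thresholding applies to the OOF
response by default, with a configuration switch for the denoised
intensity.  Components are 26-connected; the minimum component volume
defaults to 27 voxels (a 3³ speckle blob).  Skeletonization is 3D
medial-axis thinning; the input is edge-padded first so border-touching
vessels are not eroded from their ends, and any input component that
the thinning backend deletes outright (a known failure mode for small
even-width objects) gets back its deepest voxel (distance-transform
argmax), preserving the component count exactly.

## Metrics and the longitudinal statistic

VA/VS are voxel (pixel) counts — VS is deliberately an unscaled count,
matching the indicator-sum definition, with physical scaling left to
the caller.  Densities divide by the dermis-mask size.  2D metrics are
computed on the axial maximum projection, with the 2D skeleton
*recomputed* by 2D thinning of the projection (not by projecting the 3D
skeleton), matching how en-face angiograms are quantified; the dermis
denominator is the projected mask.

The per-day summary is the mean absolute relative change over
consecutive timepoints, rate = (1/(n−1)) Σ |v_{i+1}−v_i| / v_i,
reported at 3 decimals with half-away-from-zero rounding.  Applied to
the packaged published series it reproduces the published column for 7
of 8 rows; the published 2D VAD value 0.169 recomputes to 0.168 from
the printed per-day values, presumably because the published rate was
derived from unrounded underlying data.  The packaged CSV preserves the
published row labels verbatim, including the apparent swap of the 2D
VS/VSD rows (the printed 2D "VSD" row holds skeleton counts and the 2D
"VS" row holds densities); the reproduction test treats labels as
opaque row identifiers.

## Pipeline

Stage order per timepoint: segment → boundaries/thickness → denoise →
OOF → vesselize → metrics (3D + 2D), with vessel metrics restricted to
the dermis mask.  The full angiographic volume is denoised and masks
are applied only at metrics time — masking before denoising would
create artificial edges inside the transform.  Per-timepoint parameter
overrides are explicit configuration (no auto-tuning).  Every output
carries a SHA-256 hash of the configuration; identical configuration +
seed yields byte-identical metrics CSV.  Volumes travel as multi-page
float32 TIFF or NIfTI with a JSON sidecar (axis labels, voxel size);
readers refuse files whose sidecar axis order disagrees rather than
silently permuting axes.

## Problem sizes

Tests and the acceptance script run at 24³–64³ volumes, 70 training
B-scans of 64×64, and 1–3 pipeline timepoints at 32×32×24 — sizes
chosen so the whole suite runs in a few minutes on one CPU while every
claim (tight frame, oracle equivalence, radius selection, boundary
recovery, determinism) is still exercised at full fidelity.

## Known limitations

- The curvelet frame stores full-size coefficient blocks; memory grows
  as (number of bands) × volume size, which is fine at desk scale but
  would need frequency wrapping for 800³ clinical volumes.
- The U-Net is a CPU implementation sized for phantoms; real B-scan
  segmentation at clinical resolution would need a GPU framework and
  real annotations.
- Stripe selection assumes a single known stripe axis; oblique motion
  artifacts are untouched.
- No vessel tortuosity, branching, or diameter statistics; no
  statistical testing across animals.
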