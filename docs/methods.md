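# Methods

## Model and procedure

The package scores false-lumen (FL) thrombosis per aortic cross-section and
per subject, fully unsupervised. The pipeline is: synthetic phantom
generation (or user-supplied NIfTI volumes + centerline text), perpendicular
reslicing into centered 64×64 images, convolutional VAE training with a 2D
latent space, latent-space partitioning, and thrombus scoring.

### Variational autoencoder

Encoder: Conv2D(1→c₁, k=3, stride 2) → ReLU → Conv2D(c₁→c₂, k=3, stride 2)
→ ReLU → flatten → Dense(16) → ReLU → two linear heads for μ and log σ²
(each ℝ²). Decoder mirrors it with transposed convolutions and emits pixel
logits mapped through a sigmoid. Default channels are c₁=16, c₂=32: the
smallest width at which phantom anatomy reconstructs cleanly, chosen so a
full six-subject study (≈1200 images, 100 epochs) trains in a few minutes
on a single CPU core; widths are configurable. The implementation is plain
numpy with hand-derived backpropagation; the transposed convolution is the
exact adjoint of the strided convolution (verified by an inner-product
identity test), and all gradients are covered by finite-difference checks.

Loss: per-image reconstruction term plus the closed-form KL divergence of
the diagonal Gaussian posterior from the standard-normal prior, summed per
image and averaged over the batch. Reconstruction is Bernoulli pixel
cross-entropy by default (canonical for [0, 1]-normalized images; computed
from logits for numerical stability) with summed squared error available by
config. Optimizer: Adam, learning rate 1e-3, batch size 32, 100 epochs —
the canonical protocol; all defaults configurable. Training is bit-for-bit
reproducible from the config seed on a fixed platform (float32 arithmetic;
the inference API runs in float64).

Scoring uses the posterior mean μ, never a sampled z, so scores are
deterministic given a trained model.

### Latent partition and thrombus score

The latent plane is split by a straight line at x₀ on one axis; slices on
the thrombus side score ts = (x − x₀)/(x_min − x₀), clamped to [0, 1]
(clamping only affects out-of-cohort points beyond x_min), and ts = 0
elsewhere; degenerate partitions (no reference point on the thrombus side)
score everything 0 rather than erroring. The subject score is the
arithmetic mean of its slice scores; slice values are sorted before summing
so the mean is exactly permutation-invariant.

Latent axes of a VAE are a per-training-run artifact, so the partition is
always fit to the model at hand:

- **fixed** mode places x₀ at a user constant (default −0.8, thrombus
  below) — the convention of inspecting one trained model.
- **auto** mode runs a deterministic 1D 2-means on the chosen axis
  (extreme-point initialization, ties toward the lower center) and puts x₀
  at the midpoint of the two centers. The thrombus side is the cluster
  whose members have the larger segmented foreground area — dissected
  aortas are larger — with a manual orientation override available.
- the axis defaults to the first latent component; the pipeline's
  `axis: auto` selects the axis whose 2-means split has the largest
  center separation relative to pooled within-cluster spread, since
  bimodality can land on either axis depending on the training run.

x_min is stored from the fitting cohort, not taken from the −3..3
visualization range of the decoder grid.

### Reslicing geometry

Conventions fixed throughout: 0-based pixel-center indexing with the grid
center of an n×n image at ((n−1)/2, (n−1)/2); world coordinates in mm with
voxel centers at index × spacing; out-of-volume samples fill with 0 (the
masked-background value).

Centerlines are resampled at uniform arc length (endpoints preserved; the
final segment may be shorter). Resampling an existing `Centerline` object
reuses its stored arc-length table, which makes same-step resampling an
exact fixed point. Tangents come from central differences (one-sided at the
ends); frames are transported by the double-reflection rotation-minimizing
scheme — Frenet frames were rejected because their normals flip at
inflection points. Cross-sections are sampled by trilinear interpolation;
mask volumes by nearest neighbor. Auto-centering translates by whole pixels
only (no resampling blur), leaving the mask centroid within half a pixel of
the grid center; masking and centering are one operation, and the in-plane
field of view (default 64 mm) is a config parameter because the source
protocol's value is not published.

## Phantom generator

The generator emulates windowed CT angiography of a dissected aorta. Each
cross-section is built from two half-disks of independent radii joined
along a straight septum stripe (2 mm by default): the true lumen (TL) on
one side, the false lumen (FL) on the other. Thrombus fills an angular
fraction f of the FL half-disk, so the thrombosed area fraction equals f in
closed form. Intensities (window-normalized): patent lumen U(0.75, 0.95),
thrombus U(0.40, 0.55), background U(0.20, 0.35) — bright lumen, thrombus
isointense with soft tissue — then additive Gaussian pixel noise
(σ = 0.03) and clamping to [0, 1]. Radii: TL U(8, 12) mm, FL U(10, 16) mm,
with dissected slices drawn from the upper halves of both ranges to
reproduce the larger diameters of dissected aortas; vessel centers are
jittered ±3 px so auto-centering is exercised. Per class: THROMBOSED_FL
draws f from the configured range (default 0.9–1.0), PARTIAL_FL from the
central 20–80 % of that range's upper bound so its FL is neither empty nor
fully thrombosed, PATENT_FL has f = 0, NO_FL is a single disk with no
septum. Cohorts default to ~200 slices per subject, matching the few
hundred slices a clinical CTA stack yields.

Volumes stack axial cross-sections along z with an optional single-axis
sinusoidal bend (amplitude 8 mm by default) whose closed-form tangents
support the frame tests; geometry and intensities are drawn once per volume
so the tube is longitudinally coherent, and the ground-truth centerline
runs through the patent TL. Because the tube is rasterized in axial planes,
truly perpendicular cuts through a strongly bent tube are elliptical by the
local tilt cosine; the analytic disk-area oracle therefore applies to
straight or mildly bent tubes.

What the phantoms do **not** model: CT physics (beam hardening, contrast
kinetics, partial-volume blur), branch vessels, stent-graft artifacts,
motion, anatomical shape variability beyond the two-half-disk family.
Passing tests therefore demonstrate that the algorithmic chain is correct
and self-consistent on controlled anatomy — not clinical performance on
patient CTA.

## Numerical choices and degenerate inputs

- KL is clamped at 0 when float cancellation near the prior produces
  residues above −1e-9; genuine negatives would still surface.
- 2-means ties assign to the lower center; a single-valued axis yields one
  cluster and a degenerate or thrombus-below fallback.
- Empty masks, empty cohorts, degenerate centerlines (< 2 distinct
  points), mixed-subject score lists, and non-finite latent coordinates
  raise named errors; out-of-bounds tubes name the offending slice.
- The pipeline derives per-stage seeds by hashing the stage name into the
  run seed, so adding or reordering stages never shifts another stage's
  random draws.

## Prior centering (measured)

With the canonical ELBO the KL term anchors the pooled posterior-mean
cloud to the prior's support but does not pin its mean to the origin: with
default settings we measure per-axis pooled means of magnitude ≈ 0.7–2.2
across seeds and cohort sizes (moving toward 0 with longer training), with
per-axis spreads ≈ 0.8–1.7. The property test therefore asserts the cloud
stays within the prior's 3σ support (|mean| < 3, std < 3 per axis) rather
than a tighter band. The bipolar cluster structure that the scoring relies
on is unaffected.

## Known limitations

- The two-half-disk anatomy cannot produce crescent FLs that wrap around
  the TL; scores on such anatomy are untested.
- The latent partition is a single straight line; anatomy with more than
  two latent clusters (e.g., mixed pathologies) would need a richer
  classifier.
- Training on very small cohorts (tens of images) with the smallest test
  architectures underfits and leaves the latent cloud off-center; study
  conditions use ≥ a few hundred images.
- Pipeline determinism is per-platform (BLAS summation order may differ
  across builds).
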