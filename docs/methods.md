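# Methods

## Problem

Respiratory-gated PET splits the acquisition into g (typically 8) phase
bins, so each gate carries roughly sqrt(g) times the noise of the ungated
image. Plain Gaussian post-filtering buys noise reduction at the price of
resolution loss and partial-volume aggravation in small lesions. The
bilateral filter avoids this trade-off by weighting neighbors in both the
spatial and the intensity domain, but its two parameters must be re-tuned
per study, which blocks routine use. This package implements the full
remedy pipeline: (1) an automated, ROI-driven grid search that picks the
bilateral parameters jointly for all gates of a study, and (2) a residual
3D U-Net trained to reproduce the optimized filter output directly, so
that inference needs no parameters at all. A synthetic gated-PET phantom
generator makes every stage testable without patient data.

## Bilateral filter

The kernel is the product of a spatial and an intensity Gaussian,

    W(m, n) = exp[-(P_m - P_n)^2 / (2 sigma_S^2)] * exp[-(I_m - I_n)^2 / (2 sigma_I^2)],

with the spatial part anisotropic: sigma_z = 0.76 * sigma_xy, accounting
for the higher axial resolution of the reconstructions this method
targets. The quoted spatial parameter sigma_S is always the arithmetic
mean (2 sigma_xy + sigma_z)/3, so sigma_xy = 3 sigma_S / (2 + 0.76).
Filtering operates in SUV units; sigma_I is in g/mL.

Numerical choices the filter definition leaves open:

* **Kernel support.** Truncated at 3 spatial sigmas per axis
  (radius_axis = ceil(3 sigma_axis / spacing_axis)); beyond 3 sigma the
  spatial weight is < 0.012. The cutoff is configurable (`KernelSpec`).
* **Intensity domain.** Never truncated; the spatial cutoff already
  bounds the neighborhood.
* **Borders.** Renormalization over the in-bounds neighborhood — no
  padding, so every output voxel stays a convex combination of observed
  intensities and global min/max are never exceeded.
* **Precision.** 64-bit accumulation throughout, so the production
  (shifted-array, symmetry-halved) implementation agrees with the naive
  per-voxel reference to ~1e-15 relative; the reference implementation is
  kept as the permanent correctness oracle.

## Parameter optimization

For a study with g gates and l lesion ROIs, the grid search minimizes

    S(sigma_S, sigma_I) = sum_{i<=g} sum_{j<=l} [dSUVmax_ij]^2 + sum_{i<=g} [dNoise_i]^2,

where both terms are symmetric fractional differences in percent: dSUVmax
compares the filtered gate with the *unfiltered same gate* in each lesion
ROI, and dNoise compares the filtered gate's liver coefficient of
variation with that of the *ungated* image. The objective therefore pulls
every gate's noise down to the ungated level while penalizing focal
signal loss. Optimization is joint over all gates (one parameter pair per
study): gates of one study share noise, resolution and contrast, and the
joint sum stabilizes the argmin.

The default grid is 11 sigma_S values on [3.1, 5.9] mm (linear) by 15
sigma_I values on [0.1, 10.0] SUV — 165 combinations. The sigma_I axis is
spaced geometrically: it spans two decades and clinically fitted values
cluster near the bottom of the range, so linear spacing would waste most
points. Ties (within 1e-12 relative in S) resolve to the smallest
sigma_I, then smallest sigma_S — the least smoothing consistent with the
optimum, guarding against over-smoothed flat-surface argmins. Grid points
at which a metric is undefined (e.g. zero liver mean) are recorded as
invalid and excluded rather than aborting the scan. A user-supplied
parameter pair can bypass the search (recorded as "manual" provenance),
mirroring the visual-override step of the clinical workflow.

## Neural network

A residual 3D U-Net maps a normalized unfiltered patch to its filtered
counterpart. The global residual bypass is the key design element: the
input x (in [0, 1]) is clamped to [eps, 1-eps] (eps = 1e-4), passed
through the logit, added to the U-Net body's output, and squashed by a
final sigmoid:

    y = sigmoid( logit(clamp(x)) + body(x) ).

A zero body output reproduces the input exactly; outputs are confined to
(0, 1); and because the logit has large slope near 0 and 1, the network
finds it hard to move extreme intensities — exactly where quantitative
SUV information is most precious. The network head is zero-initialized so
an untrained model *is* the identity, which also makes "training improves
over initialization" a meaningful baseline.

The body is an encoder–decoder with residual conv blocks
(conv–act–conv + identity/1x1-projected skip, leaky-ReLU activations),
2x average pooling, nearest-neighbor upsampling and channel-concatenation
skip connections at every resolution level. Depth and widths are
configurable (`UNetSpec`); the default (depth 3, 16 base channels, growth
2) and the desk-scale test configuration (depth 2, 8 base channels) are
both small by deep-learning standards — the mapping being learned is a
smoothly varying local filter, which does not demand large capacity.

Layers are implemented directly on numpy (channels-last tensors, one
BLAS matmul per kernel offset) with hand-written backward passes, all of
which are verified against finite-difference gradients in the test suite.

### Training protocol

Mean-absolute-error loss, Adadelta optimizer (rho 0.95, eps 1e-6), batch
128, at most 400 epochs, early stopping when the validation MSE has not
improved for 50 epochs, and selection of the best-validation-MSE epoch
(the untrained state is also a selection candidate; the patience counter
baselines at the first trained epoch). Desk-scale runs shrink the sizes
(epochs, batch, data volume) but keep the protocol; the optimizer is
pluggable (Adam converges much faster at tiny scale and is used in the
desk-scale tests — the contract there is improvement over initialization,
not weight equality with any particular run).

Patients are assigned to 5 cross-validation folds at the patient level:
fold f tests on fold f; the remaining patients split 4:1 into training
and validation (64/16/20 of the cohort), with validation drawn from fold
(f+1) mod k so the rotation is deterministic. No patient's gate volumes
ever cross a partition.

### Preprocessing and augmentation

Each (unfiltered, filtered) volume pair is normalized to [0, 1] with a
*single shared* affine map from the pair's joint min/max — per-volume
scaling would distort the residual target. 32^3 patches are cut on a
regular lattice of stride 24 (25% overlap), with the last patch snapped
to the boundary so every voxel is covered. Run-time augmentation applies
independent 50% flips per axis and a shared gamma correction
v -> v^gamma with gamma = (1 + |G|)^sign(G), G ~ N(0, 0.5^2) — log-gamma
symmetric about zero, with 0 and 1 as fixed points; input and target of a
pair are always transformed identically, redrawn per sample per epoch.

### Inference

Whole volumes are normalized by their own range, processed in
overlapping tiles (default 64^3, 16-voxel overlap; tile edges must be
divisible by the network's downsampling factor) blended by uniform
averaging, and mapped back to SUV. Axes shorter than a tile are
reflect-padded and cropped afterwards. The zero-body identity survives
tiling seam-free, which the suite checks explicitly.

## Phantom generator

The phantom emulates the statistical structure the optimizer and
denoiser rely on, not anatomy:

| parameter | default | rationale |
| --- | --- | --- |
| spacing | 3.3 x 3.3 x 2.0 mm | clinical reconstruction geometry |
| matrix | 64 x 64 x 48 | liver field of view rather than whole body |
| gates | 8 | phase-based gating standard |
| liver uptake | 2.0 SUV over 0.5 background | typical hepatic tracer pool |
| lesion peaks | 3 / 6 / 12 SUV, 9 mm radius | contrast ladder, successive ratios >= 1.5, spanning liver-comparable to high focal uptake |
| motion | 12 mm peak-to-peak, axial, rigid | typical respiratory liver excursion |
| PSF | 6 mm FWHM isotropic Gaussian | reconstructed resolution |
| noise | 20% liver CV per gate, multiplicative, 1-voxel correlation blur | single-gate noise level; 8-gate mean lands near 7% |

Per gate i, structures are painted analytically with their centers
shifted by (A/2) cos(2 pi i / g) — no resampling, so noiseless gates are
exact — then blurred with the PSF and degraded with multiplicative
Gaussian noise. The noise field is white noise blurred with a small
Gaussian (periodic boundary mode, so the analytic sum-of-squared-taps
normalization is exact) and scaled so the liver-ROI CV equals the target.
The ungated image is the voxel-wise *mean* of the gates: for
SUV-normalized images the mean is the quantity whose noise falls by
sqrt(g) while preserving the SUV scale (a raw count sum would rescale
intensities).

ROIs come from the generating geometry: the liver mask is the liver
ellipsoid eroded by 1.5 x PSF-FWHM laterally (plus half the motion
amplitude axially) and excludes dilated lesion neighborhoods — matching
the clinical prescription of a *visually homogeneous* liver area (the
noiseless ROI content has CV < 1%). Lesion masks are capsules: all
voxels within the lesion radius of the lesion center's axial motion
path. A static sphere at one reference phase would lose the lesion peak
in half the gates; the capsule keeps the peak inside the mask at every
phase, as a clinician drawing on a gated series would.

What the phantom does **not** model: deformable anatomy, attenuation and
scatter, sinogram-level Poisson statistics, spatially varying noise
texture, heterogeneous liver uptake, and lesion shapes other than
spheres. Consequences: passing tests demonstrate that the optimizer and
the network do what they claim under idealized but statistically
representative conditions; they do not certify performance on clinical
reconstructions.

## Desk-scale study conditions

The test suite and the acceptance script run the pipeline end to end at
sizes chosen for a single CPU core: phantoms at 48 x 48 x 32 with 8
gates, a reduced 5 x 7 parameter grid, a depth-2/8-channel network
trained for 24 epochs (batch 8, Adam 3e-3) on <= 200 patch pairs from
three studies, evaluated on a fourth, held-out study. Under these
conditions (as the suite and `scripts/acceptance.py` measure) the
optimizer drives single-gate liver noise from ~20% to near the ungated
~7% (fractional noise difference around -80 to -85%), preserves SUVmax
of lesions with focal-to-liver ratio >= 2 to within 10%, and sacrifices
25-30% of SUVmax in the liver-contrast lesion — the known failure mode
of globally parameterized bilateral filtering for targets whose uptake
approaches the noise level. The trained network tracks its bilateral
target within ~10-20% relative in noise and within a few percent in
SUVmax, and under-smooths the low-contrast lesion relative to the
bilateral filter.

## Known limitations

* The numpy network trains at desk scale only; a production-scale
  training run (hundreds of epochs on ~3 x 10^5 pairs) is a matter of
  compute, not code, and would want a GPU framework behind the same
  interfaces.
* The noise metric inherits the liver-ROI assumption; without a
  sufficiently large homogeneous liver region a CV-based noise estimate
  becomes unreliable, and the package raises rather than guessing.
* Rigid axial motion cannot probe deformation-sensitive behavior.
* NIfTI-1 with axis-aligned orientation is the only supported on-disk
  format; oblique affines are rejected rather than resampled.
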