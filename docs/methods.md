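# Methods

`voxsr` implements a complete, desk-scale pipeline for studying 3D
single-image super-resolution (SISR) of volumetric MRI: degradation
simulation, five convolutional architectures, the loss/metric suite,
patch-based training with grid-aggregated inference, and a training-free
grey-box uncertainty-mapping procedure.  This note records the models,
their assumptions, the parameters that matter, and the numerical choices
made where the design was genuinely open.

## Problem setting

A high-resolution volume `X` is degraded by a known band-limiting
operator `f` into a low-resolution volume `Y = f(X)`; a network `g` with
parameters θ is trained so that `g(Y) ≈ X`.  Degradation is simulated by
sinc resampling with per-axis scale factors drawn from
{2, 2.5, 3, 3.5, 4}; the product of the per-axis factors is the
theoretical acceleration (8, 15.625, 27, 42.875, 64).  The
low-resolution volume is re-interpolated onto the reference grid *before*
training ("lazy" pre-interpolation), so every network maps a volume to a
volume of identical dims and the low-/high-resolution patch pairs can be
cut at identical corners.

## Sinc degradation

`sinc_resample` realises band-limited resampling exactly in the Fourier
domain: forward FFT, symmetric crop (downsampling) or zero-pad
(upsampling) of the centred spectrum, inverse FFT, real part, with the
mean (DC) preserved.  The index convention keeps DC centred; the lone
−b/2 Nyquist bin of an even-length band has no +b/2 partner, breaks
Hermitian symmetry, and is therefore dropped whenever an axis is
resampled.  With that convention the down-then-up round trip is exactly
a projection (applying it twice equals applying it once, to float
precision), which the test suite asserts.  Low-resolution grids are
`floor(dims / factor)` per axis; re-interpolated volumes are clipped to
[0, 1] because ringing overshoots the range.  Baseline interpolators
(nearest-index replication and cubic spline in index space) share the
centre-aligned grid convention.

## Volumes and intensities

All computation happens in voxel index space; the NIfTI affine is
carried through untouched and no reorientation is performed.  Every
volume is linearly rescaled to [0, 1] per volume before use; a constant
volume maps to zeros (degenerate-range rule).  Internal precision is
float32 inside the networks and float64 in the metrics.

## Synthetic phantoms

The generator emulates single-channel brain-like volumes so that the
whole pipeline is testable without a download.  A phantom (default 96³
voxels at 0.9 × 0.9 × 1.2 mm) is a randomised head ellipsoid with:

* nested tissue bands (default 3) of piecewise-constant intensity with a
  smooth ±8% multiplicative modulation (bias-field-like);
* thin (~1–2 voxel) interfaces at the band boundaries;
* 12 random curvilinear filaments, 1–2 voxels thick (vessel-like);
* additive Gaussian noise, default σ = 0.01 (high-SNR structural MRI);
* contrast profiles: a T1-like profile is bright outside/dark inside
  with bright fine structures; T2-like inverts the tissue ordering and
  renders structures dark (flow-void-like), so phantoms sharing a
  geometry seed have identical support masks and anti-correlated
  interiors; PD sits in a narrow mid-grey band.

Interfaces and filaments carry energy above the Nyquist limit of a
2×-downsampled grid, so degradation measurably destroys detail (the
factor-2 sinc round trip loses ≥ 1e−3 of SSIM) and super-resolution is
non-trivial.  What the phantoms do **not** emulate: anatomy, MR physics
(relaxation, B0/B1 inhomogeneity beyond a smooth modulation), partial
volume statistics of real tissue, scanner noise correlations.  Passing
the desk-scale experiments therefore shows the pipeline and optimisation
behave correctly on structured volumetric data, not that any particular
SSIM level transfers to clinical images.

## Architectures

Every network maps a 1-channel volume to a 1-channel volume of the same
dims.  Hyperparameters printed in the literature are kept; widths the
descriptions leave open were calibrated once against the published
trainable-parameter counts and frozen (see `voxsr.models`):

| architecture | parameters | depth/width defaults |
|---|---|---|
| RRDB | 246,865 | 3 dense blocks × 6 layers, growth 12, 4 shallow features; LFF 1×1×1 → 12; fusion 36 → 72 (1×1×1) → 22 (3×3×3) → 1 |
| SPSR | 493,754 | two RRDB trunks (image + Sobel-magnitude branch), gradient head 22 → 1, fusion 44 → 1 → 1 |
| UNet / UNetMSS | 5,418,563 | depth 2, base width 64 (64‑128‑256), transposed-conv k2 upsampling, MSS heads 256 → 1 and 128 → 1 |
| ShuffleUNet | 106,957,377 | widths 64/128/256/512, c/4 decomposition streams, latent 1024; double-conv hidden widths 67/128/266/546 |

Notes on the open choices:

* **RRDB.**  The three dense blocks read the shallow features in
  parallel; dense connectivity inside a block cascades the block input
  through every layer, and a global input→output residual makes the
  identity easy to represent (standard for residual SR networks).  ReLU
  activations throughout; the 1×1×1 local feature fusion is linear.
* **SPSR.**  The gradient branch receives the Sobel gradient magnitude
  of the input and is supervised with an L1 loss between its 1×1×1 head
  output and the Sobel magnitude of the ground truth (weight 1.0 by
  default); fusion is a single concatenation + 1×1×1 convolution
  followed by a 1×1×1 output refinement.
* **UNet/UNetMSS.**  One class family with a shared trunk.  The
  depth-2/width-64 configuration reproduces the published parameter
  count exactly once the two multi-scale-supervision heads are included
  as 1×1×1 convolutions (5,418,177 + 257 + 129), which is why UNet and
  UNetMSS share one count: plain UNet simply never routes loss through
  the heads.  Depth 2 also yields exactly five internal perturbation
  sites (two contraction blocks, bottleneck, two expansion blocks).
  The multi-scale loss upsamples the bottleneck-scale and mid-scale
  outputs to ground-truth dims by nearest neighbour and combines the
  per-scale losses as an α-weighted mean (default equal weights, s = 3);
  the combination is invariant to rescaling all α by a common factor.
* **ShuffleUNet.**  "Convolutional decomposition" is four parallel
  3×3×3 convolutions producing four c/4-channel streams; pixel unshuffle
  (r = 2, channels ×8, spatial ÷2) is applied to one stream and the
  other three are forwarded as skips, which makes all channel
  bookkeeping self-consistent (the shuffled stream re-emerges in the
  expansion path at exactly the skip width).  The natural width plan
  lands within 1% of the published count; the three double-conv hidden
  widths (blocks 1/3/4: 67, 266, 546) are the calibrated remainder.

Initialisation is Xavier–Glorot uniform, `U(−1/√n, 1/√n)` with `n` the
layer fan-in, biases zero, deterministic given a seed.  The bound is
implemented with the `1/√n` reading (maintaining activation variance);
the printed form of the rule is typographically ambiguous between `1/n`
and `1/√n`.

## Numerical engine

No GPU framework is assumed: the package ships a small reverse-mode
autodiff tape over float32 numpy arrays (`voxsr.nn`), with 3D
convolutions evaluated as im2col + BLAS matmul (chunked along depth to
bound the buffer at 64 MB), kernel-2/stride-2 transposed convolutions as
einsum block scatter, 2×2×2 max pooling, pixel shuffle/unshuffle as pure
rearrangements, and fixed-kernel separable correlations for the Gaussian
and Sobel filters.  Gradients of every operation — including the full
windowed SSIM training loss — are checked against finite differences in
the test suite.

## Losses and metrics

* **SSIM** follows the windowed formulation with Gaussian weights
  (window 11, σ = 1.5, k1 = 0.01, k2 = 0.03, dynamic range 1,
  population covariances).  The reported metric crops the filter-support
  border and matches `skimage.metrics.structural_similarity` (the
  independent oracle in the tests) to float precision; the
  differentiable training variant keeps the border windows (zero
  padding), a difference of a few 1e−3 on realistic patches.
  `ssim_loss = 1 − mean SSIM` is the default training loss.
* **L1 / MSE** are per-voxel means (not raw sums), so values are
  comparable across patch and volume sizes.
* **Sobel gradients** use the separable [−1,0,1] ⊗ [1,2,1] ⊗ [1,2,1]
  kernels with reflected borders (a constant volume then has exactly
  zero gradient; zero padding would manufacture edges at the boundary).
  The training-side differentiable Sobel keeps zero padding, with an
  ε = 1e−12 regulariser inside the magnitude square root.
* **Mixed gradient loss** is MSE + λG · mean squared difference of the
  Sobel magnitudes, λG = 1.0 by default (configurable; no canonical
  value exists).
* **PSNR** is 10·log10(L²/MSE), +∞ for identical volumes; **NRMSE**
  divides RMSE by the ground-truth intensity range (= 1 after
  rescaling).  Range normalisation is a documented choice; mean- or
  max-normalised variants would scale the values but not the ordering.

## Training and evaluation

Per epoch: the subject order is shuffled; in the scale-generic regime a
per-(volume, epoch) factor is drawn uniformly from the scale set and the
degradation applied on the fly; a fixed number of patches per volume
(full-scale default 60 of 64³) is sampled uniformly with aligned
low-/high-resolution corners; the patch list is mixed across subjects;
gradients of (loss / batch) are accumulated over each effective batch
(default 22) before one Adam step (learning rate 1e−4), which the test
suite verifies equals the gradient of the mean batch loss regardless of
chunking.  Validation runs every epoch on seeded patches; the learning
rate is multiplied by 0.1 after 3 epochs without improvement (the
patience is stated in the recipe, the factor is this package's default);
no early stopping — all epochs run and the best-validation weights are
kept and restored.  Checkpoints are single npz archives carrying
weights + architecture spec + training config + seed.

Evaluation is always on full volumes: the input is tiled by a grid of
patches (default 64³ with 8-voxel overlap — overlap is part of the
recipe, its size is this package's default), each patch is inferred, and
overlapping predictions are averaged with equal weights.  Volumes
smaller than the patch are zero-padded symmetrically and cropped after
aggregation.  Metrics are computed on the aggregated volume, never on
patches.

## Grey-box uncertainty mapping

For a trained RRDB (3 sites, one at the end of each dense block) or
UNet/UNetMSS (5 sites), inference-time perturbations are armed at every
site simultaneously: voxel-wise dropout at a rate, or additive Gaussian
noise with a sigma, the same parameter at all sites.  One grid-aggregated
prediction is generated per parameter in {0.01, 0.02, 0.05, 0.1, 0.2,
0.5} (one sample per parameter by default; `samples_per_param` exposes a
Monte-Carlo extension), each with an independently derived seed.  The
uncertainty map is the voxel-wise population variance over the
prediction stack; it is permutation-invariant, non-negative, and zero
iff all predictions agree.  The map is compared against the per-voxel
absolute error of the unperturbed prediction by Pearson correlation
(per image); a constant map makes the correlation undefined and returns
NaN with a warning.  Perturbations act inside patch inference, so maps
are grid-aggregated exactly like predictions.

## Desk-scale reference experiments

`voxsr.experiments` freezes two reference analyses sized for a single
CPU (problem sizes are the package's own desk-scale choices):

1. **Super-resolution vs interpolation.**  20 phantoms (96³) at factor
   2 per axis; a reduced-width UNet (depth 2, base width 8) trained for
   10 epochs with the SSIM loss, learning rate 1e−3, effective batch 4,
   16 random 32³ patches per volume per epoch; 70/18/12 subject split
   (14 train / 3 validation via the plateau schedule / 3 held out);
   evaluated on whole volumes against the sinc / nearest / bicubic
   baselines over all 20 phantoms.  The higher learning rate and small
   batch are the appropriate optimisation scale for a ~90k-parameter
   network on hundreds of patches; the full-scale defaults (1e−4,
   batch 22, 50 epochs) remain the package defaults.
2. **Uncertainty sanity.**  On the model trained in (1): five seeded
   repetitions of 2-sample variance maps at dropout rates 0.01 and 0.5
   (mean map variance must not decrease with the rate), plus the
   correlation of a full 6-parameter dropout variance map with the L1
   error map.

## Known limitations

* The convolution engine is single-threaded BLAS; full-scale training
  (hundreds of volumes, 50 epochs) is out of desk-scale reach by design.
* Phantoms are geometric, not anatomical; absolute metric values do not
  transfer to clinical MRI.
* The ShuffleUNet is instantiable and count-exact but too large to train
  at desk scale; its training path is exercised only at reduced widths.
* SPSR's fusion point and the ShuffleUNet hidden widths are calibrated
  reconstructions of under-specified designs; alternative placements
  with the same counts exist.
* `infer-transformation` (flip/rotation) uncertainty is deliberately not
  implemented: with anisotropic voxels those transforms alter structure.
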