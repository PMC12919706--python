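# Methods

## Problem and parameterization

`gridreg` performs deformable 3D registration by predicting a displacement
vector at each node of a sparse, corner-aligned control grid of size
(gw, gh, gd), then interpolating those vectors to every voxel. The dense
field `T` acts by backward warping, `output(x) = moving(x + T(x))`, the
standard spatial-transformer convention: the loss compares the warped moving
image against the fixed image, and the gather direction is what that loss
differentiates through. Displacements are stored in voxel units of the fixed
lattice; millimetres appear only inside evaluation metrics that multiply by
the voxel spacing.

Restricting the transformation to a coarse grid is an explicit capacity
control: homogeneous or noisy regions carry no reliable local
correspondence, and a voxel-wise field can fit that noise with folded,
implausible warps. A coarse grid with smooth interpolation cannot represent
such high-frequency warps at all, which is why the Jacobian-determinant
statistics of its fields stay clean (the property the acceptance experiment
measures).

## Field interpolation

The dense field is a separable basis expansion
`T(x,y,z) = Σ_ijk T(i,j,k) Bx(x;i) By(y;j) Bz(z;k)` with three
interchangeable 1D bases:

* **trilinear** — hat functions `max(0, 1 − |x − xi|/Δ)` with Δ the control
  spacing. Interpolating; reproduces constants and linear ramps exactly.
* **bspline** — cubic B-splines via the Cox–de Boor recursion on a clamped
  uniform knot vector over the normalized axis [0, 1]. Approximating but
  C², a partition of unity; the half-open degree-0 indicator means the
  right axis endpoint is evaluated as a left limit.
* **gauss_deconv** — a truncated Gaussian stencil applied as a transposed
  convolution. σ defaults to 0.45 control spacings with support truncated
  at 3σ, a width chosen to approximate the cubic B-spline kernel. A raw
  Gaussian does not sum to one on a discrete lattice, which would bias
  every displacement, so the per-axis weights are renormalized to preserve
  constants; with per-axis normalization the full 3D weight of each voxel
  also sums to one.

Because the expansion is a tensor product, `upsample` applies three 1D
stencil matrices (exact, O(N·g) instead of O(N·G)); the literal triple-sum
evaluator `upsample_oracle` is kept for verification and used throughout
the tests.

## Losses

All spatial sums are means over the voxel domain so the loss weights are
comparable across image sizes.

* **Uncertainty-weighted similarity.** The model's Bayesian head predicts a
  mean and a raw variance per control point; σ² = softplus(η) keeps the
  variance positive. Training draws S Monte Carlo displacement samples
  (reparameterization: T = μ + σ⊙ε), upsamples and warps with each, and
  minimizes mean(r²/(2σ²(x))) + λ0·mean(log σ²(x)). The per-voxel variance
  σ²(x) is the control-grid variance upsampled with the same basis as the
  displacement, averaged over the three vector components to a scalar, and
  clamped below at 1e-6 — the variance is predicted per control point but
  indexed per voxel, and interpolation is the only consistent reading.
  Defaults: λ0 = 0.5, S = 4. λ0 = 1/2 is the exact coefficient of the
  heteroscedastic Gaussian negative log-likelihood; a much smaller λ0 lets
  the variance head absorb residuals (the stationary point is
  σ² = r²/(2λ0)), which decouples the similarity gradient and stalls
  deformation learning. With the Bayesian head disabled the term
  reduces to half the mean squared error of the mean-field warp.
* **Soft Dice.** 1 − 2|A·B|/(|A| + |B| + ε) on the fixed mask versus the
  trilinearly warped (soft) moving mask; included only when masks exist.
* **Bending energy.** Mean squared second derivative of the dense field:
  central second differences on interior voxels, three pure plus twice
  three mixed terms per component, summed and divided by the total voxel
  count. Zero on affine fields by construction.

Total: L = λ1·L_uncert + λ2·L_dice + λ3·L_bend with λ1 = λ2 = 1.

**Bending weight.** The literature value for this penalty is quoted on a
raw-sum convention without stating the normalization, so it does not
transfer directly. We calibrated λ3 by the same protocol as the original
bending-weight sweep: optimizing a control grid directly (`fit_gdf`) on
synthetic pairs with known ground truth across a λ3 grid and keeping the
value with the best control-point recovery. The default is λ3 = 0.01 under
the mean normalization; the sweep is reproducible with
`fit_gdf(..., weights=LossWeights(lambda3=...))`.

## Network

A 2-channel (fixed, moving) input passes through `num_layers = 5` blocks of
stride-2 3D convolution + ReLU, starting at 16 channels and doubling per
level. Weights use He fan-in uniform initialization with zero biases — the
standard choice for ReLU networks without normalization layers; a more
conservative bound makes deep-level activations collapse and the output
insensitive to its input at small step counts.

Each pyramid level is adaptively average-pooled to `proj_spatial = (8,8,8)`,
mapped to `proj_channels = 32` by a per-token linear (1×1×1 conv), and
flattened to Np = 512 tokens; a fixed sinusoidal encoding of the token
centers is added so tokens keep spatial identity. Pooling to a fixed token
count makes the per-level token sequences concatenable, which the decoder
needs.

The decoder treats control points as queries. Their positional encodings
(Cpe = 66 channels: 11 frequency bands × sin/cos × 3 axes; cached per grid
size) seed a per-query feature stream. Levels are processed bottom-to-top;
at each level the projected tokens are concatenated with a per-token
decoder stream (a learned linear + ReLU of the previous level's tokens,
`decoder_channels = 32`), multi-head cross-attention (H = 4 heads of
d = 16) reads them with the query stream as queries, and its output is
added residually to the query stream (intermediate output width equals Cpe
so the residual is well-typed). A final linear + ReLU gives 64 features per
control point, from which two linear heads produce μ and η. The per-level
channel schedule is not fixed by any external constraint; this residual
two-stream design was chosen because it keeps every projection matrix sized
by channel counts only.

That sizing is the grid-adaptive property: changing (gw, gh, gd) changes
only the number of query rows, never a weight shape, so one trained model
serves any grid. Training samples the grid uniformly per step from
{5³, 8³, 10³, 15³}; validation picks one grid afterwards (ties broken
toward the coarsest grid, the stronger regularizer).

Positional-encoding width must be divisible by 6 (three axes × two phases);
the default is 66, the closest multiple of 6 to a 64-channel budget.
Attention is global over tokens by default; an optional locality mask
(Euclidean radius in normalized coordinates) restricts each query to nearby
tokens, and a query with no token in range is an error rather than a NaN.
An ablation switch removes the projector entirely, attending over flattened
bottleneck features instead.

The package computes gradients with an internal reverse-mode autodiff
engine on numpy arrays (`gridreg._tensor`): a tape of operations with
hand-written adjoints, including the strided 3D convolution, the separable
resampling stencils, trilinear warping, and a fused scaled-dot softmax.
Every adjoint is tested against central finite differences. Optimization is
Adam (lr 1e-4, batch 4 by default).

## Synthetic study conditions

The phantom generator emulates the image structure the method targets: a
central quasi-ellipsoidal organ (radius ≈ 0.30 of the volume) with a
homogeneous interior and contrasted boundary, 6 smooth Gaussian intensity
blobs as distinctive features, additive Gaussian intensity noise
(σ = 0.02), and intensities normalized to [0, 1]. Landmarks sit at blob
centers. The ground-truth deformation is smoothed white noise on a 5³
control grid scaled to a maximum displacement of 2.5 voxels — strictly
below half the control spacing, which for these smooth fields guarantees a
fold-free truth (independent uniform draws at the same amplitude can fold
through cross-axis gradient terms; smoothness is part of the guarantee).
The moving image is the phantom; the fixed image is the phantom warped by
the truth plus fresh noise; masks and landmarks are transported with the
same field. All randomness flows through numpy's PCG64 generator from a
single seed.

What the generator does **not** emulate: multi-modal appearance differences,
bias fields, acquisition artifacts, topology changes, or inter-subject
anatomical variability. Passing tests therefore demonstrate correctness of
the machinery and the regularity properties of the sparse parameterization,
not clinical-grade accuracy.

Experiments run at desk scale — 32³ voxels, 50 pairs (40 train / 10 held
out), 10 epochs — sizes chosen so the full study runs on a single CPU in
minutes. The clinical-scale configuration (128³ images, hundreds of
epochs) is the same code path.

## Numerical choices

* Out-of-bounds samples clamp to the border (no dark halo at edges).
* Nearest-neighbor warping for binary masks at evaluation; soft trilinear
  warping inside the Dice loss.
* Landmark transport inverts the gather field by fixed-point iteration
  (5 iterations; exact for constant fields, convergent while displacement
  gradients stay below one).
* Jacobians use `numpy.gradient` (central interior, one-sided borders);
  log-determinant summaries are the mean and SD of |log det J| over voxels
  with positive determinant, with the convention recorded in the output.
* Dice of two empty masks is 1; one empty mask gives 0.
* Softplus variances are clamped at 1e-12 during training to guard float32
  underflow for very negative η.
* The network runs in float32 by default; tests that compare against
  finite differences use float64.

## Known limitations

* The decoder's per-level channel schedule and the projector geometry are
  package choices; total parameter count is not matched to any external
  architecture description.
* The grid-level similarity term is not implemented (no formula exists for
  it); image-level similarity is MSE only — no mutual information or
  cross-correlation.
* No diffeomorphic integration (scaling-and-squaring) and no
  world-coordinate/affine pre-alignment; inputs are assumed resampled to a
  shared lattice.
* The scaled-down training run demonstrates optimization behavior and
  regularity, not converged registration accuracy; converged accuracy
  requires clinical-scale data and training budgets.
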