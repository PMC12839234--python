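# Methods

This note documents the models, algorithms and design choices behind the
package, in the spirit of a methods appendix: what is computed, under what
assumptions, with which defaults, and what the synthetic validation does
and does not demonstrate.

## Forward noise model

Observations follow the mixed Poisson–Gaussian model standard for
photon-limited microscopy:

    y_p = (1/α) · Poisson(α · f(x)_p) + ε_p,   ε_p ~ N(0, σ²)

- **α (photon-to-digital gain, dimensionless, default 80).**  Larger α
  means more photons per intensity unit, hence lower relative shot noise.
- **σ (readout std on the [0, 1] scale, default 0.02).**  Additive,
  signal-independent sensor noise.
- **f(x) = h ∗ x** with a normalized, odd-sized, non-negative PSF kernel
  and zero boundary padding; the identity when no PSF is given (the usual
  assumption when the optics are pre-calibrated).

The un-clipped observation has closed-form moments E[y] = f(x),
Var[y] = f(x)/α + σ², which the tests use as analytic oracles.  Observations
handed to the pipeline are clipped to [0, 1] because the data model declares
images on that range; moment tests therefore run pre-clipping (clipping
biases both moments).

**Noise levels.**  A level-L observation is the pixel-wise mean of L
independent captures (sub-seed = seed + frame index), so variance shrinks
by 1/L and *higher level = cleaner image*.  This is the frame-averaging
convention of paired-acquisition benchmarks, where the ground truth itself
is an average of ~50 captures.  The defaults α = 80, σ = 0.02 put a
level-1 64×64 phantom near 25 dB PSNR, the input regime such benchmarks
typically occupy.

## Phantoms

The generator emulates the features of fluorescently labelled cell images
that matter to a gradient-aware loss: a low uniform background (0.08),
elliptical cell bodies with a smooth quadratic interior profile (peak
0.35–0.65), and a thin (~1.5 px) bright membrane rim whose brightness is
the `membrane_contrast` parameter.  Cell count, sizes, orientations and
placements are drawn from a seeded generator, so datasets are fully
reproducible.  What the phantoms do **not** emulate: optical blur,
out-of-focus light, autofluorescence gradients, structured backgrounds, or
the texture statistics of real tissue.  Synthetic results therefore
validate the *machinery* (model, loss, optimisation, metrics) and the
relative behaviour of its variants — not absolute performance on real
micrographs.

## Network

Encoder–bottleneck–decoder, fully convolutional, single channel:

| stage | operation | output (512×512 input) |
|---|---|---|
| enc1 | Conv3×3 s2 + BN + ReLU | 256×256×32 |
| enc2 | Conv3×3 s2 + BN + ReLU | 128×128×64 |
| enc3 | Conv3×3 s1 + BN + ReLU | 128×128×128 |
| enc4 | Conv3×3 s1 + BN + ReLU | 128×128×256 |
| CBAM | channel then spatial attention | 128×128×256 |
| conv5 | Conv3×3 s1 + BN + ReLU (+ skip3) | 128×128×128 |
| tconv1 | TransConv3×3 s2 + BN + ReLU (+ skip2) | 256×256×64 |
| tconv2 | TransConv3×3 s2 + BN + ReLU | 512×512×32 |
| conv6 | Conv3×3 s1, linear (+ skip1) | 512×512×1 |

Skips: skip1 = three linear 3×3 convs (1→1) on the raw input, added to the
final conv; skip2 = 1×1 conv 32→64 from enc1, added after tconv1; skip3 =
1×1 conv 64→128 from enc2, added after conv5.  These attachment points are
the unique shape-consistent choices given the stage table.

CBAM: channel attention pools the bottleneck map globally (average and
max), passes both vectors through a shared bias-free MLP 256→16→256 (r =
16), and gates channels with sigmoid(MLP(avg) + MLP(max)); spatial
attention concatenates the channel-wise mean and max maps and gates pixels
through a 7×7 convolution (with bias) and a sigmoid.  The `attention`
option ("none" / "channel" / "spatial" / "full") builds the ablation
variants; their parameter counts differ from the baseline by exactly
2·256·16 = 8192 (MLP) and 7·7·2+1 = 99 (spatial conv).

**Resolved ambiguities.**  Where the architecture description admits two
readings we fixed: the final convolution is 3×3 (1×1 available via
`final_kernel`); conv5 takes the CBAM's 256 channels; the decoder uses
BatchNorm + ReLU symmetrically with the encoder, with the final conv linear
so clamping is the only output nonlinearity.  The serialized float-32 state
(parameters plus BatchNorm running statistics) is 796,994 entries =
3.040 MB; the two under-specified sublayers above bound how exactly the
count can be pinned down.

**Initialization.**  Convolutions are Kaiming-uniform and BatchNorm is
ones/zeros, all seeded — with two deliberate exceptions: the skip1 chain is
initialized as delta (identity) kernels and conv6 as zeros, so a freshly
built network is exactly the identity map.  A denoiser is a perturbation of
the identity; starting there means short training budgets are spent
learning the *correction* rather than first re-learning to reproduce the
input (the same reasoning as zero-initializing residual branches in
ResNets).  The final conv's weight gradient is nonzero at step one, so the
main path engages immediately.

**Clamping.**  The [0, 1] output clamp applies in inference mode (and in
every user-facing entry point).  Training optimises the raw linear output:
clamping during training would zero gradients on saturated pixels and stall
optimisation wherever the random initial output leaves the unit interval.

## Loss

    L_total = λ1·L1 + λ2·L2 + λ3·(1 − SSIM) + λg·L_grad

- L1, L2: per-pixel mean absolute / squared error.
- SSIM: single-scale, 11×11 Gaussian window σ = 1.5, C1 = 0.01², C2 =
  0.03² with data range 1, moments computed where the window fits entirely
  inside the image (the classic MATLAB-consistent convention; verified
  against scikit-image to 1e-6).
- L_grad: mean absolute difference of Sobel gradient maps (correlation
  with S_x = [[-1,0,1],[-2,0,2],[-1,0,1]] and its transpose), in both
  directions.  Sobel filtering uses replicate padding so constant images
  have exactly zero response including at borders — zero padding would
  fabricate boundary gradients for the loss to chase.

All four terms use per-pixel **means** rather than sums, so the default
weights λ1 = 1.0, λ2 = 0.1, λ3 = 0.2, λg = 0.2 keep their meaning at any
resolution (a sum convention differs only by the constant pixel count,
absorbable into the weights).  Every term ships with its analytic gradient
with respect to the prediction (the SSIM gradient chains through the five
filtered moment maps; the Sobel and Gaussian adjoints are exact), verified
against central finite differences to < 1e-3 relative error.  Weights set
to zero skip their term entirely, enabling the loss-ablation presets
(`l1`, `l2`, `l1_ssim`, `l1_l2_ssim`, `l1_l2_ssim_grad`).

A GAN-style adversarial term is deliberately not implemented: it appears
nowhere in the objective above and is outside the package's scope.

## Training protocol

AdamW (β1 = 0.9, β2 = 0.999, decoupled weight decay 1e-4), learning rate
1e-3 multiplied by 0.2 every 1500 iterations (StepLR), batch size 30,
gradient clipping at global norm 1.0, replicate-run seeds {2025, 2026,
2027}.  Augmentation is flips-only (identity / horizontal / vertical /
both, uniform, the same flip applied to the noisy and clean image) — flips
preserve biological morphology and are exact isometries of the metrics.
Datasets split 70/10/20 (train/validation/test), stratified jointly by
modality tag and noise level with floor + largest-remainder rounding per
stratum; strata with fewer than 3 samples fall back to training with a
warning.  Validation runs every 100 iterations (default) and the
best-validation-PSNR checkpoint is restored at the end; training aborts
with a diagnostic on a non-finite loss.  All randomness (initialization,
data order, augmentation) derives from the run seed; identical seeds give
bit-identical runs.

**Desk scale.**  The package's synthetic benchmark trains on 48 phantoms
(40 train / 8 validation), 64×64, level-1 noise at the default α, σ, batch
size 8, 300 iterations — sizes chosen so a full three-seed replication runs
in minutes on one CPU while still demonstrating a clear (≈ 5 dB) denoising
gain.  The full-protocol values remain the config defaults.

## Metrics

PSNR = 10·log10(1/MSE) dB on [0, 1] data (identical images report +inf,
serialized as the string "inf"); RMSE = √MSE; SSIM shares the loss module's
implementation.  Per-set numbers are per-image metrics arithmetically
averaged.  LPIPS is exposed behind a pluggable backbone protocol (grayscale
replicated to three channels); without a pretrained perceptual backbone the
field reports as unavailable and the rest of the report is unaffected.  The
throughput probe (warm-up passes discarded, remaining passes averaged) is
informational only — it measures whatever hardware it runs on and is never
part of a quality claim.

## Numerical notes

- Activations and parameters are float32; convolutions are lowered to GEMM
  via im2col, transposed convolutions are the exact adjoint (col2im), and
  BatchNorm uses biased variance for normalisation with momentum-0.1
  running statistics (unbiased) for inference.
- Loss computations preserve float64 when given float64 inputs, so oracle
  and finite-difference tests are not precision-limited.
- Max-pooling gradients (channel and spatial attention) route to the first
  argmax on ties; |·| subgradients use sign(0) = 0.
- Images are quantized to disk with round-half-even; 8-bit and 16-bit
  files use fixed full-scale normalisation (255 / 65535), not per-image
  scaling, so training and inference share one linear intensity map.
- `denoise_image` reflect-pads inputs to the next multiple of 4 (two
  stride-2 stages) and crops back, so any size ≥ 8×8 works.

## Known limitations

- CPU-bound: practical for small images and desk-scale experiments, not
  for training at 512×512 scale.
- Single-channel by construction; colour images must be processed per
  channel.
- No noise-parameter estimation from real data (α, σ are inputs), no
  spatially varying gain, no multi-scale or tiled inference for images
  larger than memory.
- Phantom realism as discussed above: synthetic gains should be read as
  validation of the method's machinery, not as predicted performance on
  real micrographs.
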