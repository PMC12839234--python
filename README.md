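# bdnet

Real-time denoising of fluorescence micrographs with a lightweight
encoder–decoder CNN and a gradient-aware training objective.

## The problem

Fluorescence microscopy images (confocal, two-photon, wide-field) are
corrupted by a mix of signal-dependent photon shot noise and
signal-independent readout noise.  Denoisers that optimise only pixel-wise
fidelity tend to over-smooth exactly the structures biologists care about —
cell membranes, tissue boundaries, fine high-frequency texture.  This
package implements a supervised denoiser designed around that failure mode:
a small encoder–bottleneck–decoder network with a convolutional block
attention module (CBAM), trained with a hybrid loss that explicitly
penalises discrepancies in Sobel gradient maps.

Everything needed to train and validate the method end to end on synthetic
data ships with the package: a phantom generator emulating cell-like images
with sharp membranes, a Poisson–Gaussian acquisition simulator with
frame-averaging "noise levels", the network, the loss, the training
protocol, and the evaluation metrics.  No external dataset or GPU is
required; the network and its backpropagation are implemented directly in
numpy.

## The model

**Noise model.** A clean image x ∈ [0, 1]^{H×W} is observed as

    y_p = (1/α) · Poisson(α · f(x)_p) + ε_p,   ε_p ~ N(0, σ²)

with photon gain α > 0, readout std σ, and f(x) = h ∗ x an optional PSF
blur (identity by default).  A *level-L* observation averages L independent
captures, so higher levels are cleaner — the convention of paired-
acquisition microscopy benchmarks.

**Network.** Encoder Conv3×3–BatchNorm–ReLU blocks with strides 2, 2, 1, 1
and channels 1→32→64→128→256; CBAM (channel attention: pooled-vector MLP
with reduction r = 16; spatial attention: 7×7 conv on pooled maps) at the
bottleneck; decoder Conv3×3 → two stride-2 transposed convolutions → final
conv, with three additive skip connections (a 3-conv raw-texture chain from
the input, and 1×1 channel-matching convs from the first two encoder
stages).  795,586 learnable parameters; ~3.04 MB serialized in float-32.

**Objective.**

    L_total = λ1·L1 + λ2·L2 + λ3·(1 − SSIM) + λg·L_grad,
    L_grad  = ‖S_x∗x̂ − S_x∗x‖ + ‖S_y∗x̂ − S_y∗x‖   (Sobel maps, mean-|·|)

with defaults λ1 = 1.0, λ2 = 0.1, λ3 = 0.2, λg = 0.2, optimised with AdamW
(lr 1e-3, weight decay 1e-4, β = (0.9, 0.999)), StepLR ×0.2 every 1500
iterations, batch size 30, gradient clipping at global norm 1.0.

## Worked example

```python
import numpy as np
from bdnet import BDNetDenoiser, NoiseParams, generate_phantom, simulate_level, psnr

params = NoiseParams(alpha=80.0, sigma=0.02)
clean = np.stack([generate_phantom(64, 64, n_cells=6, seed=i) for i in range(48)])
noisy = np.stack([simulate_level(c, params, level=1, seed=1000 + i)
                  for i, c in enumerate(clean)])

est = BDNetDenoiser(batch_size=8, max_iterations=300, random_state=2025)
est.fit(noisy, clean)

print(f"noisy     {np.mean([psnr(n, c) for n, c in zip(noisy[40:], clean[40:])]):.2f} dB")
print(f"denoised  {est.score(noisy[40:], clean[40:]):.2f} dB")
```

Output from this exact script (a few minutes on one CPU):

```
noisy     25.30 dB
denoised  31.30 dB
```

The first number is the PSNR of the raw level-1 observations against the
clean references; the second is the PSNR after denoising — the ~6 dB gap is
the denoising gain at these acquisition settings.  `est.history_` holds the
per-iteration loss, learning-rate and gradient-norm traces plus periodic
validation reports.

The same workflow is available from the shell:

```sh
bdnet simulate -o data --n-images 48 --level 1 --seed 0
bdnet train -m data/manifest.csv -o run --set train.batch_size=8 --set train.max_iterations=300
bdnet evaluate -m data/manifest.csv -w run/weights.npz
bdnet describe          # stage-size table, parameter ledger, model size
```

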