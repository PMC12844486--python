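# mrsdenoise

Synthetic ¹H-MRS spectrum simulation, FID-domain noise modelling, 1D U-Net
denoising and cholesterol peak identification.

## The problem

Magnetic resonance spectroscopy of atherosclerotic plaque tissue on a
clinical 1.5 T system yields cholesterol spectra buried under thermal noise,
baseline drift and transient interference: low-amplitude diagnostic
resonances (such as the olefinic C5–C6 proton near 5.35 ppm) disappear into
the noise floor. `mrsdenoise` implements the full desk-scale version of a
learning-based answer: simulate clean cholesterol spectra from a reference
peak list, corrupt them with a physically motivated noise model, train a 1D
U-Net to map noisy spectra back to clean ones, quantify the gain against
four classical filters, and identify cholesterol resonances in the denoised
result.

## The model in brief

**Clean spectra.** A peak list {(δᵢ, Iᵢ)} becomes a spectrum on a 1024-point
0–10 ppm grid (63.885 MHz) as `S(δ) = Σᵢ Iᵢ·V(δ − δᵢ; σ_G, γ_L)`, with V a
unit-area Voigt profile.

**Noise.** The spectrum is treated as the real part of a zero-phase FID
(orthonormal IFFT). The FID receives exponential apodization
`FID(t)·e^(−π·LB·t)`, complex Gaussian thermal noise with per-channel
variance `σ² = P_signal/(2·SNR)` (SNR drawn from 5–15 dB), and pink (1/f)
drift noise; after a zero-filled FFT back, a polynomial-plus-smoothed-drift
baseline and sparse RF spikes are added and the result is min–max normalized.

**Denoiser.** A 1D U-Net (three Conv1D–ReLU encoder stages with 2×
max-pooling, symmetric upsampling decoder with skip concatenations, ~122k
parameters) trained with Adam on MSE over noisy→clean pairs, best-validation
model selection. The network and its backpropagation are implemented
directly on NumPy arrays; gradients are verified against finite differences
in the test suite.

**Evaluation.** SNR, PSNR, global SSIM, RMSE, MAE and Pearson r against the
clean reference, for the U-Net and for Gaussian (σ=1.5), Savitzky–Golay
(window 21, order 3), median (kernel 5) and db4 wavelet (level 3, soft
threshold) baselines, with two-sided paired t-tests per (baseline, metric).

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Render the bundled 14-peak cholesterol reference spectrum and identify its
resonances:

```bash
$ mrsdenoise simulate --peaks cholesterol --out clean.tsv
wrote clean.tsv (14 peaks rendered)

$ mrsdenoise match-peaks --in clean.tsv --out matches.csv
14/14 reference peaks matched (0 unmatched detections); wrote matches.csv

$ head -4 matches.csv
detected_ppm,reference_peak_id,delta_ppm
1.3000,7,0.0000
1.0069,5,0.0001
3.4998,13,0.0002
```

Every reference resonance is detected within a fraction of a grid bin
(the 0.0001 ppm residual on peak 5 is the parabolic-interpolation error);
the global maximum falls at 1.0068 ppm, the grid point nearest the
reference's most intense resonance at 1.007 ppm.

The same stages are available as a library:

```python
import numpy as np
from mrsdenoise import (NoiseConfig, TrainConfig, UNetConfig, build_dataset,
                        build_model, load_cholesterol_reference, train)

bundle = load_cholesterol_reference()
data = build_dataset([bundle.table], n_variants=2000, config=NoiseConfig(seed=0))
model = train(build_model(UNetConfig(), seed=0), data, TrainConfig(epochs=30, seed=0))
print(min(model.history["val_mse"]))   # ~1e-5 on the default task
```

or as CLI subcommands (`simulate`, `augment`, `train`, `denoise`,
`baseline`, `evaluate`, `match-peaks`), each reproducible from its `--seed`.

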