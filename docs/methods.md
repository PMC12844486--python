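# Methods

This note documents the models, numerical conventions and design choices
behind `mrsdenoise`: a pipeline that simulates ¹H-MRS spectra of cholesterol,
corrupts them with a physics-motivated noise model, trains a 1D U-Net to
undo the corruption, and scores it against four classical filters.

## Clean-spectrum model

A metabolite is represented as a peak list: entries `(peak_id, ppm,
intensity)` in the HMDB export style. A clean magnitude spectrum is the sum
of unit-area Voigt profiles (Gaussian ⊛ Lorentzian — the standard NMR
lineshape) centred at each chemical shift and scaled by the relative
intensity, evaluated on the canonical grid of **1024 points spanning
0–10 ppm** at a spectrometer frequency of **63.885 MHz** (a 1.5 T clinical
system; 1 ppm ≡ 63.885 Hz). The Voigt function is evaluated through the real
part of the Faddeeva function (`scipy.special.voigt_profile`); tests verify
it against a brute-force numerical convolution of the Gaussian and
Lorentzian densities.

Default widths are `gauss_width = lorentz_width = 0.005 ppm`. At the 1024
point resolution (bin ≈ 0.0098 ppm) this gives a FWHM of ≈ 0.018 ppm —
narrow enough that all fourteen cholesterol resonances in the bundled
reference table are resolvable, wide enough that each line spans several
bins. Widths are per-run configurable.

### The bundled cholesterol table

The reference table (`data/cholesterol_hmdb2491_synthetic.csv`) is a
synthetic stand-in for the full HMDB cholesterol export. Publicly documented
values are used verbatim: the most intense resonance (relative intensity
1000) at **1.007 ppm**, the hydroxyl-bearing methine at **3.5 ppm**, the
olefinic C5–C6 proton at **5.35 ppm** (sources also quote 5.348/5.356), and
printed positions 0.678, 0.876 and 1.854 ppm. The remaining entries are
placeholders chosen inside the documented ranges (peaks 1–4 below 1.0 ppm,
peaks 6–8 in 1.1–1.5 ppm, peaks 9–12 in 1.8–2.3 ppm) with plausible
intensities well below 1000. The CSV's `provenance` column marks each row as
printed or placeholder. Consequences: tests and benchmarks that depend only
on the printed anchor peaks (global argmax at 1.007 ppm, olefinic match at
5.35 ppm) are faithful; per-peak intensities elsewhere are illustrative.

## Synthetic FIDs and apodization

A rendered absorptive-mode spectrum is treated as the frequency-domain side
of a zero-phase free induction decay: `FID = IFFT(spectrum)` with the
orthonormal convention (Parseval holds with no extra scaling). The time axis
is `t_k = k·dwell`, `dwell = 1/spectral_width = 1/638.85 s` on the canonical
grid — the standard NMR convention; nothing in the pipeline depends on an
absolute time origin.

Exponential apodization multiplies the FID by `exp(−π·LB·t)`, which adds
LB Hz of Lorentzian FWHM to every line; tests verify the analytic point
value `e^(−π)` at `LB = 1 Hz, t = 1 s` and the FWHM growth on a rendered
Lorentzian line (within 5%; the two-sided circular FID makes broadening
very slightly super-linear).

Returning to the frequency domain uses a zero-filled FFT (factor 2 by
default, configurable among {1, 2, 4}); the real part is retained
(absorptive mode, amplitude-corrected for the padding) and linearly
resampled to the canonical grid. Zero-filling is exact at the original grid
positions, so the no-noise pipeline is an identity to floating tolerance.

## Noise model

Each noisy variant applies, in order:

1. **Line broadening** — LB drawn uniformly from 0.5–3 Hz, applied to the FID.
2. **Thermal noise** — complex Gaussian noise added to the FID with
   per-channel variance σ² = P_signal/(2·SNR), P_signal the mean squared FID
   magnitude, SNR drawn as 10^(dB/10) with dB uniform in **5–15 dB**. Real
   and imaginary channels are independent; the total complex noise power is
   P_signal/SNR. The ±1 dB calibration test measures SNR on the complex FID,
   where this definition lives — after retaining only the real part of the
   spectrum, half the complex noise power remains, so a frequency-domain
   reading would sit ~3 dB above the target by construction.
3. **Pink (1/f) noise** — synthesized in the frequency domain (random phases
   under a 1/√f amplitude envelope, DC bin zeroed to avoid the f→0
   divergence and to make every realization exactly zero-mean),
   inverse-transformed to correlated temporal fluctuations, independent per
   channel, per-channel SD = 0.5 × the variant's thermal σ.
4. **Baseline** — after the return to the frequency domain: a random
   polynomial of degree ≤ 3 plus white noise smoothed with a 25-bin
   Gaussian, each rescaled so its maximum magnitude is a uniform draw within
   10% (polynomial) and 5% (drift) of the clean spectrum's maximum.
5. **RF spikes** — 0–3 single-bin impulses at uniform positions with
   amplitudes 5–20% of the clean maximum, modelling transient interference.
6. **Min–max normalization** to [0, 1], matching the clean target's
   normalization.

The SNR/LB ranges and artifact amplitudes are implementer defaults (chosen
once to produce visibly degraded but recognizable spectra, comparable to a
low-field plaque acquisition); all are exposed in `NoiseConfig`. Spikes are
applied in the frequency domain, where single-bin interference lines live.

Per-pair RNG streams derive from `SeedSequence([master_seed, table_index,
variant_index])`, so datasets are bit-reproducible, order-independent and
parallelizable, and a holdout built with variant indices beyond the training
range shares no randomness with the training set.

What the generator does **not** model (and the tests therefore cannot
vouch for): J-coupling multiplets, macromolecular baselines, coil loading,
eddy-current phase errors, frequency drift, water/solvent residuals.
Performance on real scanner data is out of scope; the benchmark measures
recovery of the generator's own corruption model.

## The 1D U-Net

Encoder–decoder with `n_levels = 3`: each encoder stage is two
Conv1D(kernel 9, same zero-padding) → ReLU pairs followed by 2× max-pooling
(1024 → 512 → 256 → 128); the bottleneck repeats the double convolution; the
decoder mirrors the encoder with 2× linear-interpolation upsampling and skip
concatenation from the matching encoder stage; a final 1×1 convolution
projects to one channel. Channels start at `base_channels = 8` and double
per level (~122k parameters with the default width of 8). The channel width,
kernel size, pooling and upsampling operators are configurable; the defaults
were chosen so a full scaled benchmark trains in minutes on one CPU core
while meeting the benchmark's validation-loss targets.

The network, backpropagation and the Adam optimizer are implemented directly
on NumPy arrays (channels-last activations; convolutions as k shifted GEMMs
so BLAS does the arithmetic with no layout copies). Gradient correctness is
enforced by a finite-difference test over every parameter of a small
double-precision instance. One caveat of that test: biases are initialized
away from zero first, because with zero biases many pre-activations sit
exactly on the ReLU kink where a central difference straddles two
subgradients.

Training minimizes MSE between the denoised output and the clean target,
with MAE monitored per epoch on both splits; the optimized loss is MSE and
MAE is diagnostic. The train/validation split (10% validation) and batch
shuffling derive from `TrainConfig.seed`; batch size 32, learning rate 1e-3.
The returned model carries the weights of the epoch with the **best
validation MSE**, not the last epoch. Inference is deterministic.

## Benchmark and metrics

The scaled benchmark renders the bundled cholesterol spectrum, builds 2000
training pairs and a 64-pair holdout (seed-disjoint variant indices) at the
default noise configuration, trains the default U-Net for 30 epochs, then
scores the U-Net and the four classical baselines on the holdout:

- Gaussian smoothing, σ = 1.5 bins, kernel truncated at radius ⌈4σ⌉,
  reflective boundaries;
- Savitzky–Golay, window 21, cubic polynomial, truncated-window (polynomial
  extrapolation) edges;
- median filter, kernel 5, reflective boundaries;
- db4 wavelet shrinkage, decomposition level 3, soft thresholding with the
  universal threshold T = σ̂·√(2·ln N), σ̂ = median(|finest detail|)/0.6745,
  applied to every detail level (the threshold policy is an implementer
  default; the benchmark definition fixes only family/level/mode).

Metrics between a clean reference x and an estimate y, both on [0, 1]:
SNR = 10·log₁₀(mean(x²)/mean((y−x)²)); PSNR = 10·log₁₀(1/MSE);
SSIM in its global-statistics form over the whole 1024-point signal with
C1 = (0.01)², C2 = (0.03)² and sample (ddof = 1) variance/covariance —
this matches `skimage.metrics.structural_similarity` evaluated with one
full-signal window, which the tests use as an independent cross-check;
RMSE; MAE; Pearson r. A zero residual would make SNR/PSNR infinite; both are
capped at a 300 dB sentinel so aggregation stays finite. Significance is
assessed with two-sided paired t-tests (pairing unit = spectrum) of the
U-Net against each baseline on each metric, without multiple-testing
correction; a degenerate all-zero difference is flagged and reported as
p = 1.

Two properties of this synthetic benchmark are worth stating plainly.
First, all training and evaluation pairs derive from the single bundled
cholesterol spectrum, so the network can and does learn a strong prior for
that target; the benchmark measures corruption removal for a known
metabolite, which is the intended use, not blind denoising of arbitrary
spectra. Second, the noisy inputs carry baseline offsets and normalization
shifts that pure smoothing filters cannot remove, so the classical
baselines' absolute scores here are far below what they would achieve on
offset-free noise; the comparison is still like-for-like, since every
method sees the same inputs.

## Peak identification

Detection: local maxima with prominence ≥ 1% of the spectrum maximum
(`scipy.signal.find_peaks`), refined by 3-point parabolic interpolation for
sub-bin accuracy. Matching: candidate (detection, reference) pairs within a
tolerance of **0.05 ppm** (≈ 5 bins — separates all distinct reference
assignments while absorbing interpolation error) are accepted greedily in
order of increasing |Δppm|, ties broken toward smaller ppm, each side used
at most once. Greedy rather than optimal assignment: at cholesterol's peak
spacings the two coincide, and greedy is auditable. On the clean rendered
bundle all 14 reference peaks are recovered at the default widths; the
acceptance threshold is ≥ 12 to tolerate mergers at wider linewidths.

## Degenerate inputs and numerical conventions

- Constant spectra min–max-normalize to all zeros with a logged warning
  (batch pipelines survive degenerate augmentations) rather than erroring.
- Peaks outside the grid are skipped with a log line, not an error.
- Pearson r on a zero-variance signal raises `UndefinedCorrelationError`.
- Grids are stored ascending; descending two-column input files are
  canonicalized on read.
- Checkpoints and datasets carry JSON sidecars with configuration echoes and
  sha256 checksums; loads verify them and fail with `IntegrityError`.

## Problem sizes

Default scaled runs use 2000 training pairs (10% validation), a 64-pair
holdout, 30 epochs, and the 8-channel U-Net — sizes chosen as a desk-scale
reproduction that reaches the benchmark's quality targets in a few minutes on a
single CPU core. Larger runs (more variants per table, 80–150 epochs, wider
channels) are a matter of configuration, not code.
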