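"""Physics-motivated corruption of clean spectra and paired-dataset assembly.

The noise model emulates the main degradations of in-vivo ¹H-MRS
acquisitions, split between the two domains where they physically arise:

* time domain (on the synthetic FID): exponential line broadening drawn per
  variant, complex Gaussian thermal noise with per-channel variance
  σ² = P_signal/(2·SNR), and pink (1/f) receiver/B₀-drift noise with
  independent real and imaginary processes;
* frequency domain (on the re-transformed spectrum): a low-order random
  polynomial baseline plus a Gaussian-smoothed stochastic drift, and sparse
  single-bin RF spikes.

Each noisy variant is paired with the min–max-normalized clean spectrum it
was derived from; per-pair RNG seeds are derived deterministically from the
master seed and the (table, variant) indices so datasets are reproducible
and parallelizable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .exceptions import InvalidArgumentError
from .fid import FreeInductionDecay, apodize, fid_to_spectrum, spectrum_to_fid
from .spectra import (
    DEFAULT_GRID,
    DEFAULT_VOIGT,
    PeakTable,
    SpectralGrid,
    Spectrum,
    VoigtParams,
    minmax_normalize,
    peaks_to_spectrum,
)

__all__ = [
    "NoiseConfig",
    "AugmentationDataset",
    "thermal_noise",
    "pink_noise",
    "baseline_drift",
    "rf_spikes",
    "augment_pair",
    "build_dataset",
]


@dataclass(frozen=True)
class NoiseConfig:
    """All stochastic-corruption parameters for one augmentation run.

    Amplitude-like fields (``baseline_amplitude``, ``drift_amplitude``,
    ``spike_amplitude_range``) are fractions of the clean spectrum's maximum
    intensity; ``pink_amplitude`` scales the per-channel pink-noise standard
    deviation relative to the thermal-noise σ of the same variant.
    """

    target_snr_db: tuple[float, float] = (5.0, 15.0)
    lb_range_hz: tuple[float, float] = (0.5, 3.0)
    pink_amplitude: float = 0.5
    baseline_order: int = 3
    baseline_amplitude: float = 0.1
    drift_amplitude: float = 0.05
    drift_smoothing: float = 25.0
    spike_count_range: tuple[int, int] = (0, 3)
    spike_amplitude_range: tuple[float, float] = (0.05, 0.2)
    zero_fill_factor: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("target_snr_db", "lb_range_hz", "spike_count_range",
                     "spike_amplitude_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InvalidArgumentError(f"{name}: lo {lo} > hi {hi}")
        for name in ("pink_amplitude", "baseline_amplitude", "drift_amplitude"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.baseline_order < 0:
            raise InvalidArgumentError("baseline_order must be >= 0")


@dataclass
class AugmentationDataset:
    """Paired clean/noisy matrices plus a per-pair provenance manifest."""

    clean: np.ndarray
    noisy: np.ndarray
    manifest: list[dict]
    config: NoiseConfig

    def __post_init__(self) -> None:
        if self.clean.shape != self.noisy.shape:
            raise InvalidArgumentError("clean and noisy matrices must match in shape")
        if len(self.manifest) != self.clean.shape[0]:
            raise InvalidArgumentError("manifest rows must equal n_pairs")

    @property
    def n_pairs(self) -> int:
        return self.clean.shape[0]


def thermal_noise(
    fid: FreeInductionDecay, target_snr_linear: float, rng: np.random.Generator
) -> FreeInductionDecay:
    """Add complex Gaussian thermal noise at a target linear SNR.

    Per-channel variance is σ² = P_signal/(2·SNR) with P_signal the mean
    squared FID magnitude, so the total complex noise power is P_signal/SNR.
    Real and imaginary channels are sampled independently.
    """
    if not target_snr_linear > 0:
        raise InvalidArgumentError("target SNR must be > 0")
    p_signal = float(np.mean(np.abs(fid.samples) ** 2))
    sigma = np.sqrt(p_signal / (2.0 * target_snr_linear))
    n = fid.samples.size
    noise = rng.normal(0.0, sigma, n) + 1j * rng.normal(0.0, sigma, n)
    return FreeInductionDecay(
        samples=fid.samples + noise, dwell_time=fid.dwell_time, grid_ref=fid.grid_ref
    )


def _pink_channel(n: int, rng: np.random.Generator) -> np.ndarray:
    """One real pink-noise series, unit standard deviation, exactly zero mean."""
    n_freq = n // 2 + 1
    k = np.arange(n_freq, dtype=float)
    amp = np.zeros(n_freq)
    amp[1:] = 1.0 / np.sqrt(k[1:])  # PSD ∝ |amp|² ∝ 1/f; DC excluded
    coeffs = (rng.normal(size=n_freq) + 1j * rng.normal(size=n_freq)) * amp
    coeffs[0] = 0.0
    series = np.fft.irfft(coeffs, n=n)
    std = series.std()
    if std > 0:
        series /= std
    return series


def pink_noise(n: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Complex 1/f noise of length ``n`` with independent real/imag channels.

    Synthesized in the frequency domain (random phases under a 1/√f amplitude
    envelope, DC bin zeroed) and inverse-transformed, giving correlated
    temporal fluctuations with power spectral density ∝ 1/f.  ``amplitude``
    is the per-channel standard deviation.
    """
    if n < 2:
        raise InvalidArgumentError("pink noise needs n >= 2")
    if amplitude < 0:
        raise InvalidArgumentError("amplitude must be >= 0")
    if amplitude == 0:
        return np.zeros(n, dtype=complex)
    real = _pink_channel(n, rng)
    imag = _pink_channel(n, rng)
    return amplitude * (real + 1j * imag)


def baseline_drift(
    grid: SpectralGrid, config: NoiseConfig, rng: np.random.Generator
) -> np.ndarray:
    """Slow background: random low-order polynomial + smoothed stochastic drift.

    Returned in fractional units (relative to the clean spectrum maximum).
    The polynomial degree is drawn uniformly in [0, baseline_order] and the
    curve rescaled so its maximum magnitude is a uniform draw in
    [0, baseline_amplitude]; the drift term is white noise smoothed with a
    Gaussian of ``drift_smoothing`` bins, rescaled to a maximum magnitude
    drawn in [0, drift_amplitude].
    """
    n = grid.n_points
    out = np.zeros(n)

    if config.baseline_amplitude > 0:
        degree = int(rng.integers(0, config.baseline_order + 1))
        coeffs = rng.normal(size=degree + 1)
        x = np.linspace(-1.0, 1.0, n)
        poly = np.polyval(coeffs, x)
        peak = np.max(np.abs(poly))
        target = rng.uniform(0.0, config.baseline_amplitude)
        if peak > 0:
            out += poly * (target / peak)
    if config.drift_amplitude > 0:
        white = rng.normal(size=n)
        drift = gaussian_filter1d(white, config.drift_smoothing, mode="reflect")
        peak = np.max(np.abs(drift))
        target = rng.uniform(0.0, config.drift_amplitude)
        if peak > 0:
            out += drift * (target / peak)
    return out


def rf_spikes(
    grid: SpectralGrid, config: NoiseConfig, rng: np.random.Generator
) -> np.ndarray:
    """Sparse single-bin transient-interference impulses, in fractional units.

    The spike count is uniform over ``spike_count_range``; positions are
    drawn uniformly without replacement; amplitudes uniformly from
    ``spike_amplitude_range``.
    """
    lo, hi = config.spike_count_range
    if lo < 0:
        raise InvalidArgumentError("spike counts must be >= 0")
    if hi > grid.n_points:
        raise InvalidArgumentError("cannot place more spikes than grid points")
    out = np.zeros(grid.n_points)
    k = int(rng.integers(lo, hi + 1))
    if k == 0:
        return out
    positions = rng.choice(grid.n_points, size=k, replace=False)
    amp_lo, amp_hi = config.spike_amplitude_range
    out[positions] = rng.uniform(amp_lo, amp_hi, size=k)
    return out


def augment_pair(
    clean: Spectrum, config: NoiseConfig, rng: np.random.Generator
) -> tuple[Spectrum, Spectrum, dict]:
    """Produce one noisy variant of a clean spectrum plus its normalized target.

    Pipeline: spectrum → FID → apodize (drawn LB) → + thermal noise (drawn
    SNR) → + pink noise → back to the spectrum (real part, zero-filled FFT)
    → + baseline drift → + RF spikes → min–max normalize.  The returned
    record holds every drawn parameter.
    """
    lb = float(rng.uniform(*config.lb_range_hz))
    snr_db = float(rng.uniform(*config.target_snr_db))
    snr_linear = 10.0 ** (snr_db / 10.0)

    fid = spectrum_to_fid(clean)
    fid = apodize(fid, lb)
    p_signal = float(np.mean(np.abs(fid.samples) ** 2))
    sigma_thermal = float(np.sqrt(p_signal / (2.0 * snr_linear))) if p_signal > 0 else 0.0
    fid = thermal_noise(fid, snr_linear, rng) if p_signal > 0 else fid
    pink = pink_noise(
        clean.grid.n_points, config.pink_amplitude * sigma_thermal, rng
    )
    fid = FreeInductionDecay(
        samples=fid.samples + pink, dwell_time=fid.dwell_time, grid_ref=fid.grid_ref
    )

    noisy = fid_to_spectrum(fid, zero_fill_factor=config.zero_fill_factor)
    signal_max = float(np.max(np.abs(clean.values)))
    extra = baseline_drift(clean.grid, config, rng) + rf_spikes(clean.grid, config, rng)
    noisy_values = noisy.values + extra * signal_max
    noisy = minmax_normalize(
        Spectrum(grid=clean.grid, values=noisy_values, provenance="noisy")
    )
    clean_norm = minmax_normalize(clean).copy_with(provenance="clean")
    record = {"lb_hz": lb, "snr_db": snr_db, "sigma_thermal": sigma_thermal}
    return noisy, clean_norm, record


def pair_seed(master_seed: int, table_index: int, variant_index: int) -> np.random.SeedSequence:
    """Deterministic per-pair seed derived from the master seed and indices."""
    return np.random.SeedSequence([int(master_seed), int(table_index), int(variant_index)])


def build_dataset(
    tables: list[PeakTable],
    n_variants: int,
    config: NoiseConfig,
    grid: SpectralGrid = DEFAULT_GRID,
    voigt: VoigtParams = DEFAULT_VOIGT,
    variant_offset: int = 0,
) -> AugmentationDataset:
    """Render each table once and generate ``n_variants`` noisy pairs per table.

    ``variant_offset`` shifts the variant indices used for seed derivation so
    that holdout sets can be generated with seeds disjoint from a training
    set built from the same master seed.
    """
    if not tables:
        raise InvalidArgumentError("need at least one peak table")
    if n_variants < 1:
        raise InvalidArgumentError("n_variants must be >= 1")
    n_pairs = len(tables) * n_variants
    clean_mat = np.empty((n_pairs, grid.n_points))
    noisy_mat = np.empty((n_pairs, grid.n_points))
    manifest: list[dict] = []
    row = 0
    for ti, table in enumerate(tables):
        clean = peaks_to_spectrum(table, grid, voigt)
        for vi in range(n_variants):
            v_index = vi + variant_offset
            ss = pair_seed(config.seed, ti, v_index)
            rng = np.random.default_rng(ss)
            noisy, clean_norm, record = augment_pair(clean, config, rng)
            clean_mat[row] = clean_norm.values
            noisy_mat[row] = noisy.values
            record.update(
                table_index=ti,
                source_label=table.source_label,
                variant_index=v_index,
                seed_entropy=[int(config.seed), ti, v_index],
            )
            manifest.append(record)
            row += 1
    return AugmentationDataset(
        clean=clean_mat, noisy=noisy_mat, manifest=manifest, config=config
    )
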