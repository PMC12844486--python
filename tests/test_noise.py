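"""FID-domain noise model, frequency-domain artifacts and dataset assembly."""

import numpy as np
import pytest
from scipy import stats

from mrsdenoise import (
    DEFAULT_GRID,
    NoiseConfig,
    Spectrum,
    augment_pair,
    baseline_drift,
    build_dataset,
    make_grid,
    minmax_normalize,
    pink_noise,
    rf_spikes,
    spectrum_to_fid,
    thermal_noise,
)
from mrsdenoise.exceptions import InvalidArgumentError
from mrsdenoise.spectra import PeakTable

from conftest import silent_noise_config


def _unit_power_fid(n=1 << 20):
    grid = make_grid(n, 0, 10, 63.885)
    fid = spectrum_to_fid(Spectrum(grid=grid, values=np.zeros(n)))
    fid.samples = np.ones(n, dtype=complex)  # P_signal = 1 exactly
    return fid


class TestThermalNoise:
    def test_per_channel_variance_matches_snr_scaling(self):
        """σ² = P_signal/(2·SNR): unit power at SNR 1 gives per-channel var 0.5."""
        fid = _unit_power_fid()
        noisy = thermal_noise(fid, 1.0, np.random.default_rng(0))
        noise = noisy.samples - fid.samples
        assert np.var(noise.real) == pytest.approx(0.5, rel=0.02)
        assert np.var(noise.imag) == pytest.approx(0.5, rel=0.02)

    def test_total_noise_power_at_snr_10(self):
        fid = _unit_power_fid()
        noisy = thermal_noise(fid, 10.0, np.random.default_rng(1))
        power = np.mean(np.abs(noisy.samples - fid.samples) ** 2)
        assert power == pytest.approx(0.1, rel=0.02)

    def test_infinite_snr_limit_leaves_fid_unchanged(self):
        fid = _unit_power_fid(1024)
        noisy = thermal_noise(fid, 1e12, np.random.default_rng(2))
        np.testing.assert_allclose(noisy.samples, fid.samples, atol=1e-5)

    def test_non_positive_snr_rejected(self):
        with pytest.raises(InvalidArgumentError):
            thermal_noise(_unit_power_fid(1024), 0.0, np.random.default_rng(0))

    def test_measured_fid_snr_tracks_target(self, clean_cholesterol):
        """Empirical FID-domain SNR within ±1 dB of target over 100 variants."""
        fid = spectrum_to_fid(clean_cholesterol)
        p_signal = np.mean(np.abs(fid.samples) ** 2)
        target_db = 10.0
        measured = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = thermal_noise(fid, 10 ** (target_db / 10), rng)
            p_noise = np.mean(np.abs(noisy.samples - fid.samples) ** 2)
            measured.append(10 * np.log10(p_signal / p_noise))
        assert abs(np.mean(measured) - target_db) < 1.0


class TestPinkNoise:
    def test_zero_amplitude_gives_zeros(self):
        assert np.all(pink_noise(1024, 0.0, np.random.default_rng(0)) == 0)

    def test_psd_slope_is_one_over_f(self):
        """Log–log periodogram slope of the 1/f process lies in [−1.2, −0.8]."""
        n = 1 << 16
        slopes = []
        for seed in range(5):
            series = pink_noise(n, 1.0, np.random.default_rng(seed)).real
            psd = np.abs(np.fft.rfft(series)) ** 2
            freqs = np.arange(1, n // 2 + 1)
            slope, *_ = stats.linregress(np.log(freqs), np.log(psd[1:]))
            slopes.append(slope)
        assert -1.2 < np.mean(slopes) < -0.8

    def test_exactly_zero_mean(self):
        """DC bin is zeroed, so each realization has mean 0 to rounding."""
        for seed in range(100):
            z = pink_noise(4096, 1.0, np.random.default_rng(seed))
            assert abs(z.real.mean()) < 1e-12
            assert abs(z.imag.mean()) < 1e-12

    def test_per_channel_standard_deviation(self):
        z = pink_noise(8192, 0.37, np.random.default_rng(3))
        assert z.real.std() == pytest.approx(0.37, rel=1e-9)
        assert z.imag.std() == pytest.approx(0.37, rel=1e-9)

    def test_channels_independent(self):
        z = pink_noise(1 << 15, 1.0, np.random.default_rng(4))
        r = np.corrcoef(z.real, z.imag)[0, 1]
        assert abs(r) < 0.2


class TestBaselineDrift:
    def test_order_zero_without_drift_is_constant(self):
        cfg = NoiseConfig(baseline_order=0, drift_amplitude=0.0)
        out = baseline_drift(DEFAULT_GRID, cfg, np.random.default_rng(0))
        assert np.ptp(out) == 0.0

    def test_all_amplitudes_zero_gives_zero_vector(self):
        cfg = NoiseConfig(baseline_amplitude=0.0, drift_amplitude=0.0)
        out = baseline_drift(DEFAULT_GRID, cfg, np.random.default_rng(0))
        assert np.all(out == 0)

    def test_amplitude_bound_respected(self):
        cfg = NoiseConfig(baseline_amplitude=0.1, drift_amplitude=0.05)
        for seed in range(20):
            out = baseline_drift(DEFAULT_GRID, cfg, np.random.default_rng(seed))
            assert np.max(np.abs(out)) <= 0.15 + 1e-12

    def test_drift_is_much_smoother_than_white_noise(self):
        """Mean |second difference| of the smoothed drift ≪ that of white noise."""
        cfg = NoiseConfig(baseline_amplitude=0.0, drift_amplitude=1.0,
                          drift_smoothing=25.0)
        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            drift = baseline_drift(DEFAULT_GRID, cfg, rng)
            drift = drift / np.abs(drift).max()
            white = np.random.default_rng(1000 + seed).normal(size=drift.size)
            white = white / np.abs(white).max()
            ratios.append(
                np.mean(np.abs(np.diff(drift, 2))) / np.mean(np.abs(np.diff(white, 2)))
            )
        assert np.mean(ratios) < 0.2


class TestRfSpikes:
    def test_zero_count_range(self):
        cfg = NoiseConfig(spike_count_range=(0, 0))
        assert np.all(rf_spikes(DEFAULT_GRID, cfg, np.random.default_rng(0)) == 0)

    def test_fixed_count_gives_exact_number_of_nonzero_bins(self):
        cfg = NoiseConfig(spike_count_range=(3, 3))
        out = rf_spikes(DEFAULT_GRID, cfg, np.random.default_rng(0))
        assert np.count_nonzero(out) == 3

    def test_spike_positions_uniform(self):
        """χ² uniformity over 10 equal bins, 10⁴ single-spike draws."""
        grid = make_grid(1000, 0, 10, 63.885)
        cfg = NoiseConfig(spike_count_range=(1, 1))
        rng = np.random.default_rng(42)
        positions = [
            int(np.flatnonzero(rf_spikes(grid, cfg, rng))[0]) for _ in range(10_000)
        ]
        counts, _ = np.histogram(positions, bins=10, range=(0, 1000))
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_too_many_spikes_rejected(self):
        grid = make_grid(4, 0, 10, 63.885)
        cfg = NoiseConfig(spike_count_range=(0, 10))
        with pytest.raises(InvalidArgumentError):
            rf_spikes(grid, cfg, np.random.default_rng(0))


class TestAugmentPair:
    def test_silent_pipeline_is_identity(self, clean_cholesterol):
        noisy, clean_norm, _ = augment_pair(
            clean_cholesterol, silent_noise_config(), np.random.default_rng(0)
        )
        np.testing.assert_allclose(noisy.values, clean_norm.values, atol=1e-6)

    def test_same_seed_bit_identical(self, clean_cholesterol):
        cfg = NoiseConfig()
        a, _, ra = augment_pair(clean_cholesterol, cfg, np.random.default_rng(7))
        b, _, rb = augment_pair(clean_cholesterol, cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(a.values, b.values)
        assert ra == rb

    def test_output_normalized(self, clean_cholesterol):
        noisy, clean_norm, _ = augment_pair(
            clean_cholesterol, NoiseConfig(), np.random.default_rng(1)
        )
        assert noisy.values.min() == 0.0 and noisy.values.max() == 1.0
        assert clean_norm.values.min() == 0.0 and clean_norm.values.max() == 1.0

    def test_draws_recorded_within_configured_ranges(self, clean_cholesterol):
        cfg = NoiseConfig()
        _, _, rec = augment_pair(clean_cholesterol, cfg, np.random.default_rng(5))
        assert cfg.lb_range_hz[0] <= rec["lb_hz"] <= cfg.lb_range_hz[1]
        assert cfg.target_snr_db[0] <= rec["snr_db"] <= cfg.target_snr_db[1]


class TestBuildDataset:
    def test_pair_count_and_manifest(self, bundle):
        tables = [bundle.table] * 3
        data = build_dataset(tables, 5, NoiseConfig(seed=0))
        assert data.n_pairs == 15
        assert len(data.manifest) == 15

    def test_reproducible_and_seed_sensitive(self, bundle):
        a = build_dataset([bundle.table], 8, NoiseConfig(seed=11))
        b = build_dataset([bundle.table], 8, NoiseConfig(seed=11))
        c = build_dataset([bundle.table], 8, NoiseConfig(seed=12))
        np.testing.assert_array_equal(a.noisy, b.noisy)
        np.testing.assert_array_equal(a.clean, b.clean)
        assert not np.array_equal(a.noisy, c.noisy)

    def test_clean_rows_equal_normalized_render_exactly(
        self, bundle, clean_cholesterol_norm
    ):
        data = build_dataset([bundle.table], 4, NoiseConfig(seed=3))
        for row in data.clean:
            np.testing.assert_array_equal(row, clean_cholesterol_norm.values)

    def test_variant_offset_changes_streams(self, bundle):
        a = build_dataset([bundle.table], 4, NoiseConfig(seed=5), variant_offset=0)
        b = build_dataset([bundle.table], 4, NoiseConfig(seed=5), variant_offset=4)
        assert not np.array_equal(a.noisy, b.noisy)

    def test_empty_table_list_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_dataset([], 5, NoiseConfig())
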