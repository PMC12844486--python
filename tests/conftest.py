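"""Shared fixtures: reference bundle, rendered spectra, and the scaled benchmark.

The scaled benchmark fixture runs the full study loop once per session
(2000 training pairs, 64 holdout pairs, 30 epochs) and is shared by the
acceptance-level tests so the expensive training happens only once.
"""

from __future__ import annotations

import numpy as np
import pytest

from mrsdenoise import (
    DEFAULT_GRID,
    DEFAULT_VOIGT,
    NoiseConfig,
    load_cholesterol_reference,
    minmax_normalize,
    peaks_to_spectrum,
)
from mrsdenoise.pipeline import run_benchmark


@pytest.fixture(scope="session")
def bundle():
    return load_cholesterol_reference()


@pytest.fixture(scope="session")
def clean_cholesterol(bundle):
    """Unnormalized clean cholesterol spectrum on the canonical grid."""
    return peaks_to_spectrum(bundle.table, DEFAULT_GRID, DEFAULT_VOIGT)


@pytest.fixture(scope="session")
def clean_cholesterol_norm(clean_cholesterol):
    return minmax_normalize(clean_cholesterol)


def silent_noise_config(seed: int = 0) -> NoiseConfig:
    """A configuration with every noise source off (identity pipeline)."""
    return NoiseConfig(
        target_snr_db=(300.0, 300.0),
        lb_range_hz=(0.0, 0.0),
        pink_amplitude=0.0,
        baseline_amplitude=0.0,
        drift_amplitude=0.0,
        spike_count_range=(0, 0),
        seed=seed,
    )


@pytest.fixture(scope="session")
def benchmark_result():
    """The scaled-down study benchmark: data, training, evaluation, t-tests."""
    return run_benchmark(seed=1)
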