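"""Six-metric evaluation suite, benchmark aggregation and paired t-tests.

For a clean reference x and an estimate y (both normalized to [0, 1]):

* SNR  = 10·log₁₀(P_sig/P_nse), P_sig = mean(x²), P_nse = mean((y−x)²)
* PSNR = 10·log₁₀(MAX²/MSE), MAX = 1
* SSIM = (2μxμy+C1)(2σxy+C2) / ((μx²+μy²+C1)(σx²+σy²+C2)) computed from
  global whole-signal statistics (sample covariance), C1=(0.01·L)²,
  C2=(0.03·L)², L = 1
* RMSE, MAE: root-mean-square / mean absolute difference
* r: Pearson correlation

A perfect reconstruction would make SNR/PSNR infinite; both are capped at a
300 dB sentinel so aggregation stays finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import BaselineSpec, apply_classical
from .exceptions import InvalidArgumentError, UndefinedCorrelationError
from .noise import AugmentationDataset
from .spectra import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "SsimConstants",
    "MetricReport",
    "BenchmarkTable",
    "METRIC_NAMES",
    "HIGHER_IS_BETTER",
    "compute_metrics",
    "metrics_matrix",
    "benchmark_methods",
    "paired_ttests",
]

METRIC_NAMES = ("snr_db", "psnr_db", "ssim", "rmse", "mae", "pearson_r")

#: orientation of each metric (True: larger is better)
HIGHER_IS_BETTER = {
    "snr_db": True, "psnr_db": True, "ssim": True,
    "rmse": False, "mae": False, "pearson_r": True,
}

_DB_CAP = 300.0


@dataclass(frozen=True)
class SsimConstants:
    """SSIM stabilization constants for a given dynamic range L."""

    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 1.0

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


@dataclass(frozen=True)
class MetricReport:
    """The six metric values for one (method, spectrum) pair."""

    snr_db: float
    psnr_db: float
    ssim: float
    rmse: float
    mae: float
    pearson_r: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in METRIC_NAMES])


def _global_ssim(x: np.ndarray, y: np.ndarray, constants: SsimConstants) -> float:
    # sample (ddof=1) statistics over the whole signal, one global window
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    cxy = float(np.cov(x, y, ddof=1)[0, 1])
    c1, c2 = constants.c1, constants.c2
    return float(
        ((2 * mx * my + c1) * (2 * cxy + c2))
        / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2))
    )


def compute_metrics(
    clean: Spectrum | np.ndarray,
    estimate: Spectrum | np.ndarray,
    constants: SsimConstants = SsimConstants(),
) -> MetricReport:
    """All six metrics of an estimate against its clean reference."""
    x = clean.values if isinstance(clean, Spectrum) else np.asarray(clean, float)
    y = estimate.values if isinstance(estimate, Spectrum) else np.asarray(estimate, float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("clean and estimate must be 1-D and the same length")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("Pearson r undefined for zero-variance input")
    mse = float(np.mean((y - x) ** 2))
    p_sig = float(np.mean(x ** 2))
    if mse == 0.0:
        logger.warning("zero residual: SNR/PSNR capped at %.0f dB", _DB_CAP)
        snr = psnr = _DB_CAP
    else:
        snr = min(10.0 * np.log10(p_sig / mse), _DB_CAP)
        psnr = min(10.0 * np.log10(1.0 / mse), _DB_CAP)
    return MetricReport(
        snr_db=snr,
        psnr_db=psnr,
        ssim=_global_ssim(x, y, constants),
        rmse=float(np.sqrt(mse)),
        mae=float(np.mean(np.abs(y - x))),
        pearson_r=float(np.corrcoef(x, y)[0, 1]),
    )


@dataclass
class BenchmarkTable:
    """Mean ± SD per (method, metric) plus the retained per-spectrum matrices."""

    per_spectrum: dict[str, np.ndarray]  # method → (n_spectra, 6)

    @property
    def methods(self) -> list[str]:
        return list(self.per_spectrum)

    def summary(self) -> pd.DataFrame:
        rows = {}
        for method, mat in self.per_spectrum.items():
            row = {}
            for j, name in enumerate(METRIC_NAMES):
                row[f"{name}_mean"] = mat[:, j].mean()
                row[f"{name}_sd"] = mat[:, j].std(ddof=1) if mat.shape[0] > 1 else 0.0
            rows[method] = row
        return pd.DataFrame.from_dict(rows, orient="index")

    def mean(self, method: str, metric: str) -> float:
        j = METRIC_NAMES.index(metric)
        return float(self.per_spectrum[method][:, j].mean())


def metrics_matrix(
    clean: np.ndarray, estimates: np.ndarray,
    constants: SsimConstants = SsimConstants(),
) -> np.ndarray:
    """Per-spectrum metric matrix (n, 6) for paired clean/estimate matrices."""
    if clean.shape != estimates.shape:
        raise InvalidArgumentError("matrix shapes must match")
    return np.array([
        compute_metrics(c, e, constants).as_array()
        for c, e in zip(clean, estimates)
    ])


def benchmark_methods(
    data: AugmentationDataset,
    model,
    baselines: list[BaselineSpec],
    constants: SsimConstants = SsimConstants(),
    grid=None,
) -> BenchmarkTable:
    """Evaluate the U-Net and every classical baseline on a holdout dataset.

    Each method denoises every noisy spectrum; all six metrics are computed
    against the paired clean reference and retained per spectrum.
    """
    from .spectra import DEFAULT_GRID
    from .unet import denoise_matrix

    grid = grid or DEFAULT_GRID
    per: dict[str, np.ndarray] = {}
    per["unet"] = metrics_matrix(data.clean, denoise_matrix(model, data.noisy), constants)
    for spec in baselines:
        outs = np.empty_like(data.noisy)
        for i, row in enumerate(data.noisy):
            s = Spectrum(grid=grid, values=row, provenance="noisy", normalized=True)
            outs[i] = apply_classical(spec, s).values
        per[spec.method] = metrics_matrix(data.clean, outs, constants)
    return BenchmarkTable(per_spectrum=per)


def paired_ttests(
    table: BenchmarkTable, reference_method: str = "unet"
) -> pd.DataFrame:
    """Two-sided paired t-tests of the reference against every other method.

    Pairing unit is the spectrum.  Rows: (method, metric) with the t
    statistic, p-value and a ``degenerate`` flag; identical per-spectrum
    values give a degenerate test reported as p = 1.
    """
    ref = table.per_spectrum[reference_method]
    if ref.shape[0] < 2:
        raise InvalidArgumentError("paired t-tests need at least 2 spectra")
    records = []
    for method, mat in table.per_spectrum.items():
        if method == reference_method:
            continue
        for j, metric in enumerate(METRIC_NAMES):
            diffs = ref[:, j] - mat[:, j]
            if np.allclose(diffs, diffs[0]) and np.std(diffs) == 0 and np.all(diffs == 0):
                records.append((method, metric, 0.0, 1.0, True))
                continue
            if np.std(diffs, ddof=1) == 0:
                # constant nonzero difference: t is unbounded, p → 0
                records.append((method, metric, np.inf, 0.0, True))
                continue
            t, p = stats.ttest_rel(ref[:, j], mat[:, j])
            records.append((method, metric, float(t), float(p), False))
    return pd.DataFrame(
        records, columns=["method", "metric", "t_stat", "p_value", "degenerate"]
    )
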