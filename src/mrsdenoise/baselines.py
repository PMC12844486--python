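"""The four classical denoisers used as comparison baselines.

Defaults are the benchmark's fixed parameters: Gaussian smoothing with
σ = 1.5 bins, Savitzky–Golay with a 21-point window and cubic polynomial,
a 5-point median filter, and db4 wavelet shrinkage at decomposition level 3
with soft thresholding.  The wavelet threshold (unspecified in the source
benchmark) is the universal threshold T = σ̂·√(2·ln N) with the noise scale
σ̂ estimated as median(|finest detail|)/0.6745, applied to every detail
level.  Windowed methods handle boundaries by reflection, except
Savitzky–Golay, which fits truncated windows (polynomial extrapolation) at
the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pywt
from scipy.ndimage import gaussian_filter1d, median_filter
from scipy.signal import savgol_filter

from .exceptions import InvalidArgumentError
from .spectra import Spectrum

__all__ = ["BaselineSpec", "apply_classical", "default_baselines", "soft_threshold"]

_METHODS = ("gaussian", "savitzky_golay", "median", "wavelet")


@dataclass(frozen=True)
class BaselineSpec:
    """A classical method name plus its parameter record."""

    method: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise InvalidArgumentError(f"unknown method {self.method!r}; use {_METHODS}")


def default_baselines() -> list[BaselineSpec]:
    """The four benchmark baselines with their fixed parameters."""
    return [
        BaselineSpec("gaussian", {"sigma": 1.5}),
        BaselineSpec("savitzky_golay", {"window_length": 21, "poly_order": 3}),
        BaselineSpec("median", {"kernel_size": 5}),
        BaselineSpec("wavelet", {"family": "db4", "level": 3, "threshold_mode": "soft"}),
    ]


def soft_threshold(coeffs: np.ndarray, threshold: float) -> np.ndarray:
    """Shrink toward zero by ``threshold``: sign(c)·max(|c|−T, 0)."""
    return np.sign(coeffs) * np.maximum(np.abs(coeffs) - threshold, 0.0)


def _wavelet_denoise(values: np.ndarray, family: str, level: int, mode: str) -> np.ndarray:
    if level < 1:
        raise InvalidArgumentError("wavelet level must be >= 1")
    coeffs = pywt.wavedec(values, family, level=level, mode="symmetric")
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest)) / 0.6745
    threshold = sigma * np.sqrt(2.0 * np.log(values.size))
    out = [coeffs[0]]
    for detail in coeffs[1:]:
        if threshold == 0:
            out.append(detail)  # noiseless input: nothing to shrink
        elif mode == "soft":
            out.append(soft_threshold(detail, threshold))
        else:
            out.append(pywt.threshold(detail, threshold, mode=mode))
    rec = pywt.waverec(out, family, mode="symmetric")
    return rec[: values.size]


def apply_classical(spec: BaselineSpec, s: Spectrum) -> Spectrum:
    """Run one classical denoiser on a spectrum, preserving its length."""
    v = s.values
    p = spec.params
    if spec.method == "gaussian":
        sigma = float(p.get("sigma", 1.5))
        if sigma <= 0:
            raise InvalidArgumentError("gaussian sigma must be > 0")
        # kernel truncated at radius ceil(4σ); reflection at the boundaries
        out = gaussian_filter1d(v, sigma, mode="reflect",
                                radius=int(np.ceil(4.0 * sigma)))
    elif spec.method == "savitzky_golay":
        window = int(p.get("window_length", 21))
        order = int(p.get("poly_order", 3))
        if window % 2 != 1 or window <= order:
            raise InvalidArgumentError("window_length must be odd and > poly_order")
        out = savgol_filter(v, window, order, mode="interp")
    elif spec.method == "median":
        kernel = int(p.get("kernel_size", 5))
        if kernel % 2 != 1 or kernel < 1:
            raise InvalidArgumentError("kernel_size must be odd and >= 1")
        out = median_filter(v, size=kernel, mode="reflect")
    else:  # wavelet
        out = _wavelet_denoise(
            v,
            str(p.get("family", "db4")),
            int(p.get("level", 3)),
            str(p.get("threshold_mode", "soft")),
        )
    return s.copy_with(values=out, provenance="denoised")
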