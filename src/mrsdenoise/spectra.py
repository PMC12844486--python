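"""Peak lists, spectral grids and Voigt-rendered clean spectra.

A ¹H-MRS spectrum is represented as a real intensity vector on a fixed,
evenly spaced chemical-shift (ppm) axis.  Clean reference spectra are
rendered from a peak list by placing a unit-area Voigt profile (Gaussian ⊛
Lorentzian, the standard NMR lineshape) at each resonance and scaling it by
the peak's relative intensity.  The canonical working grid is 1024 points
spanning 0–10 ppm at a 1.5 T spectrometer frequency of 63.885 MHz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy.special import voigt_profile as _scipy_voigt

from .exceptions import InvalidArgumentError

logger = logging.getLogger(__name__)

__all__ = [
    "PeakEntry",
    "PeakTable",
    "SpectralGrid",
    "Spectrum",
    "VoigtParams",
    "DEFAULT_GRID",
    "DEFAULT_VOIGT",
    "make_grid",
    "voigt_profile",
    "peaks_to_spectrum",
    "minmax_normalize",
    "interpolate_to_grid",
]


@dataclass(frozen=True)
class PeakEntry:
    """One resonance: integer label, chemical shift (ppm), relative intensity."""

    peak_id: int
    ppm: float
    intensity: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ppm):
            raise InvalidArgumentError(f"peak {self.peak_id}: non-finite ppm")
        if not (self.intensity > 0):
            raise InvalidArgumentError(
                f"peak {self.peak_id}: intensity must be > 0, got {self.intensity}"
            )


@dataclass(frozen=True)
class PeakTable:
    """Ordered collection of resonances with a free-text source label."""

    entries: tuple[PeakEntry, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        ids = [e.peak_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise InvalidArgumentError("duplicate peak_id in peak table")

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[float, float]], source_label: str = ""
    ) -> "PeakTable":
        entries = tuple(
            PeakEntry(i + 1, float(p), float(h)) for i, (p, h) in enumerate(pairs)
        )
        return cls(entries=entries, source_label=source_label)


@dataclass(frozen=True)
class SpectralGrid:
    """Evenly spaced, endpoint-inclusive ppm axis tied to a spectrometer frequency.

    ``spectrometer_freq`` (MHz) converts chemical shift to absolute frequency:
    1 ppm ≡ ``spectrometer_freq`` Hz.
    """

    n_points: int
    ppm_min: float
    ppm_max: float
    spectrometer_freq: float

    @property
    def spacing(self) -> float:
        return (self.ppm_max - self.ppm_min) / (self.n_points - 1)

    @property
    def spectral_width_hz(self) -> float:
        return (self.ppm_max - self.ppm_min) * self.spectrometer_freq

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.ppm_min, self.ppm_max, self.n_points)


@dataclass
class Spectrum:
    """Real intensity vector on a :class:`SpectralGrid` with provenance."""

    grid: SpectralGrid
    values: np.ndarray
    provenance: str = "clean"  # clean | noisy | denoised | external
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_points,):
            raise InvalidArgumentError(
                f"values length {self.values.shape} != grid n_points {self.grid.n_points}"
            )

    def copy_with(self, **kw) -> "Spectrum":
        out = replace(self, **kw)
        return out


@dataclass(frozen=True)
class VoigtParams:
    """Voigt lineshape widths: Gaussian σ and Lorentzian HWHM, both in ppm."""

    gauss_width: float = 0.005
    lorentz_width: float = 0.005

    def __post_init__(self) -> None:
        if self.gauss_width < 0 or self.lorentz_width < 0:
            raise InvalidArgumentError("Voigt widths must be >= 0")
        if self.gauss_width == 0 and self.lorentz_width == 0:
            raise InvalidArgumentError("Voigt widths cannot both be 0")


def make_grid(
    n_points: int, ppm_min: float, ppm_max: float, spectrometer_freq: float
) -> SpectralGrid:
    """Build an endpoint-inclusive, ascending ppm grid.

    Raises :class:`InvalidArgumentError` for fewer than 2 points, inverted
    bounds or a non-positive spectrometer frequency.
    """
    if n_points < 2:
        raise InvalidArgumentError(f"n_points must be >= 2, got {n_points}")
    if not ppm_max > ppm_min:
        raise InvalidArgumentError(f"ppm_max ({ppm_max}) must exceed ppm_min ({ppm_min})")
    if not spectrometer_freq > 0:
        raise InvalidArgumentError("spectrometer_freq must be > 0")
    return SpectralGrid(int(n_points), float(ppm_min), float(ppm_max), float(spectrometer_freq))


#: Canonical working grid: 1024 points, 0–10 ppm, 1.5 T (63.885 MHz).
DEFAULT_GRID = make_grid(1024, 0.0, 10.0, 63.885)

#: Default lineshape widths; resolve the 14 cholesterol resonances at 1024 points.
DEFAULT_VOIGT = VoigtParams()


def voigt_profile(offsets: np.ndarray, params: VoigtParams) -> np.ndarray:
    """Unit-area Voigt profile evaluated at ``offsets`` (ppm from the line centre).

    Reduces to a pure Gaussian when ``lorentz_width`` is 0 and to a pure
    Lorentzian when ``gauss_width`` is 0 (the Faddeeva-based evaluation
    handles both limits).
    """
    offsets = np.asarray(offsets, dtype=float)
    return _scipy_voigt(offsets, params.gauss_width, params.lorentz_width)


def peaks_to_spectrum(
    table: PeakTable, grid: SpectralGrid, params: VoigtParams
) -> Spectrum:
    """Render a clean, unnormalized spectrum from a peak list.

    Each in-range peak contributes ``intensity × voigt(axis − ppm)``; the
    result is linear in the intensities.  Peaks outside the grid bounds are
    skipped with a warning (reference tables may extend past the window).
    """
    if len(table) == 0:
        raise InvalidArgumentError("cannot render an empty peak table")
    axis = grid.axis
    values = np.zeros(grid.n_points)
    for entry in table.entries:
        if not (grid.ppm_min <= entry.ppm <= grid.ppm_max):
            logger.warning(
                "peak %d at %.4f ppm outside grid [%g, %g]; skipped",
                entry.peak_id, entry.ppm, grid.ppm_min, grid.ppm_max,
            )
            continue
        values += entry.intensity * voigt_profile(axis - entry.ppm, params)
    return Spectrum(grid=grid, values=values, provenance="clean", normalized=False)


def minmax_normalize(s: Spectrum) -> Spectrum:
    """Affinely map a spectrum onto [0, 1] (global min–max normalization).

    A constant spectrum maps to all zeros with a logged warning so that batch
    pipelines survive degenerate inputs.  Idempotent on already-normalized data.
    """
    v = s.values
    if not np.all(np.isfinite(v)):
        raise InvalidArgumentError("cannot normalize non-finite values")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        logger.warning("degenerate constant spectrum: min-max normalization returns zeros")
        out = np.zeros_like(v)
    else:
        out = (v - lo) / (hi - lo)
    return s.copy_with(values=out, normalized=True)


def interpolate_to_grid(
    axis: np.ndarray, values: np.ndarray, grid: SpectralGrid,
    provenance: str = "external",
) -> Spectrum:
    """Linearly resample ``(axis, values)`` onto ``grid``; zero outside the source range.

    The source axis must be strictly monotone (either direction; descending
    input is flipped to the canonical ascending convention).
    """
    axis = np.asarray(axis, dtype=float)
    values = np.asarray(values, dtype=float)
    if axis.shape != values.shape or axis.ndim != 1:
        raise InvalidArgumentError("axis and values must be 1-D and the same length")
    d = np.diff(axis)
    if np.all(d < 0):
        axis, values = axis[::-1], values[::-1]
    elif not np.all(d > 0):
        raise InvalidArgumentError("source ppm axis must be strictly monotone")
    out = np.interp(grid.axis, axis, values, left=0.0, right=0.0)
    # np.interp clamps at the boundary; zero strictly outside the source range
    out[(grid.axis < axis[0]) | (grid.axis > axis[-1])] = 0.0
    return Spectrum(grid=grid, values=out, provenance=provenance, normalized=False)
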