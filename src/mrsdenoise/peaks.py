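"""Peak detection and matching against the cholesterol reference table.

Detection finds local maxima above a prominence floor and refines each
position with 3-point parabolic interpolation; matching pairs detections
with reference resonances by greedy nearest-neighbour assignment under a
ppm tolerance (each side used at most once).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .exceptions import InvalidArgumentError
from .reference import ReferenceBundle
from .spectra import Spectrum

__all__ = ["MatchResult", "detect_peaks", "match_to_reference"]

DEFAULT_TOLERANCE_PPM = 0.05


@dataclass(frozen=True)
class MatchResult:
    """Greedy one-to-one assignment of detections to reference peaks."""

    matches: tuple[tuple[float, int, float], ...]  # (detected ppm, peak_id, |Δppm|)
    unmatched_detections: tuple[float, ...]
    unmatched_references: tuple[int, ...]

    @property
    def n_matched(self) -> int:
        return len(self.matches)


def detect_peaks(s: Spectrum, min_prominence: float = 0.01) -> list[float]:
    """Detect peak positions (ppm) with prominence ≥ min_prominence × max(s).

    Positions are refined by fitting a parabola through the maximum and its
    two neighbours, giving sub-bin accuracy for symmetric lineshapes.
    """
    v = s.values
    if not np.all(np.isfinite(v)):
        raise InvalidArgumentError("spectrum must be finite")
    vmax = float(v.max())
    if vmax <= 0:
        return []
    idx, _ = find_peaks(v, prominence=min_prominence * vmax)
    axis = s.grid.axis
    out = []
    for i in idx:
        if 0 < i < v.size - 1:
            denom = v[i - 1] - 2 * v[i] + v[i + 1]
            shift = 0.5 * (v[i - 1] - v[i + 1]) / denom if denom != 0 else 0.0
            shift = float(np.clip(shift, -0.5, 0.5))
        else:
            shift = 0.0
        out.append(float(axis[i] + shift * s.grid.spacing))
    return out


def match_to_reference(
    detections: list[float],
    bundle: ReferenceBundle,
    tol_ppm: float = DEFAULT_TOLERANCE_PPM,
) -> MatchResult:
    """Greedily match detections to reference peaks within a ppm tolerance.

    Candidate pairs are considered in order of increasing |Δppm| (ties broken
    by smaller detected ppm); each detection and each reference peak is used
    at most once and only pairs within ``tol_ppm`` are kept.
    """
    if not tol_ppm > 0:
        raise InvalidArgumentError("tol_ppm must be > 0")
    refs = [(e.peak_id, e.ppm) for e in bundle.table.entries]
    candidates = []
    for di, d in enumerate(detections):
        for peak_id, ppm in refs:
            delta = abs(d - ppm)
            if delta <= tol_ppm:
                candidates.append((delta, d, di, peak_id))
    candidates.sort(key=lambda c: (c[0], c[1]))
    used_det: set[int] = set()
    used_ref: set[int] = set()
    matches = []
    for delta, d, di, peak_id in candidates:
        if di in used_det or peak_id in used_ref:
            continue
        used_det.add(di)
        used_ref.add(peak_id)
        matches.append((d, peak_id, delta))
    unmatched_det = tuple(d for i, d in enumerate(detections) if i not in used_det)
    unmatched_ref = tuple(pid for pid, _ in refs if pid not in used_ref)
    return MatchResult(
        matches=tuple(matches),
        unmatched_detections=unmatched_det,
        unmatched_references=unmatched_ref,
    )
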