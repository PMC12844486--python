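"""Bundled cholesterol reference peak table (HMDB entry 2491).

The full 14-resonance reference list for cholesterol is distributed with the
package as a small CSV.  It is a synthetic stand-in for the complete HMDB
export: peak positions and intensities that are publicly documented (the
1.007 ppm aliphatic envelope at relative intensity 1000, the 3.5 ppm
hydroxyl-bearing methine, the 5.35 ppm olefinic proton, and the printed
positions 0.678, 0.876 and 1.854 ppm) are used verbatim, while the remaining
entries are placeholders chosen inside the documented chemical-shift ranges
(peaks 1–4 below 1.0 ppm, peaks 6–8 in 1.1–1.5 ppm, peaks 9–12 in
1.8–2.3 ppm).  The per-entry ``provenance`` column in the CSV records which
is which.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .exceptions import InvalidArgumentError
from .spectra import PeakTable

__all__ = ["ReferenceBundle", "load_cholesterol_reference"]

_BUNDLE_FILE = "cholesterol_hmdb2491_synthetic.csv"


@dataclass(frozen=True)
class ReferenceBundle:
    """A reference peak table plus per-entry provenance notes."""

    table: PeakTable
    provenance: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.table) != len(self.provenance):
            raise InvalidArgumentError("provenance notes must match table entries")


def load_cholesterol_reference() -> ReferenceBundle:
    """Load the bundled 14-peak cholesterol reference table."""
    from .io import parse_peak_table_text  # local import to avoid a cycle

    path = resources.files("mrsdenoise.data").joinpath(_BUNDLE_FILE)
    text = path.read_text(encoding="utf-8")
    table, extras = parse_peak_table_text(
        text, source_label="cholesterol HMDB 2491 (synthetic bundle)"
    )
    notes = tuple(extras.get("provenance", [""] * len(table)))
    bundle = ReferenceBundle(table=table, provenance=notes)
    if len(bundle.table) != 14:
        raise InvalidArgumentError("bundled cholesterol table must have 14 entries")
    return bundle
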