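"""File formats: peak-table CSV/TSV, two-column spectra, datasets, checkpoints.

Peak tables are HMDB-export-style delimited text with header columns
``peak_id, ppm, intensity`` (an optional ``hz`` column is accepted and
cross-checked against ppm × spectrometer frequency).  Spectra are
two-column text (ppm, intensity).  Datasets and model checkpoints are
NumPy ``.npz`` archives next to JSON manifests carrying configuration,
per-pair draws and sha256 checksums.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import IntegrityError, ParseError
from .noise import AugmentationDataset, NoiseConfig
from .spectra import PeakEntry, PeakTable, SpectralGrid, Spectrum, make_grid

logger = logging.getLogger(__name__)

__all__ = [
    "load_peak_table",
    "parse_peak_table_text",
    "read_spectrum",
    "write_spectrum",
    "save_dataset",
    "load_dataset",
    "save_checkpoint",
    "load_checkpoint",
]

_REQUIRED_COLUMNS = ("peak_id", "ppm", "intensity")


def parse_peak_table_text(
    text: str,
    source_label: str = "",
    spectrometer_freq: float | None = None,
) -> tuple[PeakTable, dict[str, list]]:
    """Parse delimited peak-table text; returns the table and any extra columns.

    The delimiter (comma or tab) is sniffed from the header.  If an ``hz``
    column is present and ``spectrometer_freq`` is given, each row must
    satisfy hz ≈ ppm × spectrometer_freq within 1%.
    """
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    try:
        df = pd.read_csv(_io.StringIO(text), sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error paths vary
        raise ParseError(f"cannot parse peak table: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"missing required column {col!r}")
    entries = []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        try:
            peak_id = int(rec["peak_id"])
            ppm = float(rec["ppm"])
            intensity = float(rec["intensity"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric field in row {row_num}: {exc}") from exc
        if not np.isfinite(ppm) or not np.isfinite(intensity):
            raise ParseError(f"non-numeric field in row {row_num}")
        if "hz" in df.columns and spectrometer_freq is not None:
            hz = float(rec["hz"])
            expected = ppm * spectrometer_freq
            if expected != 0 and abs(hz - expected) > 0.01 * abs(expected):
                raise ParseError(
                    f"row {row_num}: hz column ({hz}) inconsistent with "
                    f"ppm × {spectrometer_freq} MHz ({expected:.2f})"
                )
        entries.append(PeakEntry(peak_id, ppm, intensity))
    ids = [e.peak_id for e in entries]
    if len(ids) != len(set(ids)):
        raise ParseError("duplicate peak_id values")
    extras = {
        c: df[c].tolist() for c in df.columns if c not in (*_REQUIRED_COLUMNS, "hz")
    }
    return PeakTable(entries=tuple(entries), source_label=source_label), extras


def load_peak_table(
    path: str | Path, spectrometer_freq: float | None = None
) -> PeakTable:
    """Read a peak table from a CSV/TSV file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    table, _ = parse_peak_table_text(
        text, source_label=path.stem, spectrometer_freq=spectrometer_freq
    )
    return table


def read_spectrum(
    path: str | Path, grid: SpectralGrid | None = None, provenance: str = "external"
) -> Spectrum:
    """Read a two-column (ppm, intensity) text spectrum.

    A descending ppm column is accepted and canonicalized to ascending.  If
    ``grid`` is omitted, a grid matching the file's own axis is constructed
    (spectrometer frequency defaults to the canonical 63.885 MHz).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    rows = []
    for ln, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.replace(",", " ").split()
        if ln == 1 and any(not _is_number(p) for p in parts):
            continue  # header line
        if len(parts) != 2:
            raise ParseError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
        if not all(_is_number(p) for p in parts):
            raise ParseError(f"{path}:{ln}: non-numeric value")
        rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ParseError(f"{path}: no data rows")
    arr = np.array(rows)
    axis, values = arr[:, 0], arr[:, 1]
    if axis.size > 1 and axis[0] > axis[-1]:
        axis, values = axis[::-1], values[::-1]
    if grid is not None:
        from .spectra import interpolate_to_grid

        return interpolate_to_grid(axis, values, grid, provenance=provenance)
    d = np.diff(axis)
    if axis.size > 1 and not np.all(d > 0):
        raise ParseError(f"{path}: ppm axis is not strictly monotone")
    own_grid = make_grid(axis.size, float(axis[0]), float(axis[-1]), 63.885)
    if not np.allclose(own_grid.axis, axis, atol=1e-9 * max(1.0, abs(axis[-1]))):
        logger.warning("%s: unevenly spaced axis; values kept on nominal even grid", path)
    return Spectrum(grid=own_grid, values=values, provenance=provenance)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text with full float precision."""
    path = Path(path)
    data = np.column_stack([s.grid.axis, s.values])
    header = f"ppm intensity (provenance={s.provenance}, normalized={s.normalized})"
    np.savetxt(path, data, fmt="%.17g", header=header)


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def save_dataset(data: AugmentationDataset, directory: str | Path) -> None:
    """Persist a dataset as ``arrays.npz`` + ``manifest.json`` with checksums."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "arrays.npz", clean=data.clean, noisy=data.noisy)
    manifest = {
        "n_pairs": data.n_pairs,
        "n_points": int(data.clean.shape[1]),
        "config": asdict(data.config),
        "pairs": data.manifest,
        "checksums": {"clean": _sha256(data.clean), "noisy": _sha256(data.noisy)},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_dataset(directory: str | Path) -> AugmentationDataset:
    """Load a dataset directory, verifying manifest consistency and checksums."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise IntegrityError(f"missing manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    with np.load(directory / "arrays.npz") as npz:
        clean, noisy = npz["clean"], npz["noisy"]
    if clean.shape[0] != manifest["n_pairs"]:
        raise IntegrityError("manifest n_pairs does not match array rows")
    for name, arr in (("clean", clean), ("noisy", noisy)):
        if _sha256(arr) != manifest["checksums"][name]:
            raise IntegrityError(f"checksum mismatch for {name} matrix")
    cfg = manifest["config"]
    for key in ("target_snr_db", "lb_range_hz", "spike_count_range",
                "spike_amplitude_range"):
        cfg[key] = tuple(cfg[key])
    return AugmentationDataset(
        clean=clean, noisy=noisy, manifest=manifest["pairs"],
        config=NoiseConfig(**cfg),
    )


def save_checkpoint(model, path: str | Path) -> None:
    """Serialize model weights (.npz) with a JSON sidecar (config + history)."""
    from .unet import DenoiserModel  # noqa: F401  (type reference)

    path = Path(path)
    # np.savez appends .npz itself; normalize so the sidecar name is predictable
    npz_path = path if path.suffix == ".npz" else path.with_name(path.name + ".npz")
    np.savez(npz_path, **model.net.state_dict())
    sidecar = {
        "config": asdict(model.config),
        "history": model.history,
        "n_parameters": model.n_parameters,
    }
    npz_path.with_suffix(".npz.json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path: str | Path):
    """Rebuild a DenoiserModel from a checkpoint written by save_checkpoint."""
    from .unet import DenoiserModel, UNetConfig, build_model

    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_name(path.name + ".npz")
    sidecar_path = npz_path.with_suffix(".npz.json")
    if not sidecar_path.exists():
        raise IntegrityError(f"missing checkpoint sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    config = UNetConfig(**sidecar["config"])
    model = build_model(config)
    with np.load(npz_path) as npz:
        state = {k: npz[k] for k in npz.files}
    try:
        model.net.load_state_dict(state)
    except KeyError as exc:
        raise IntegrityError(f"checkpoint incompatible with config: {exc}") from exc
    model.history = sidecar.get("history", {})
    return model
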