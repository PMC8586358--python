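"""Readers and writers for the package's standard file formats.

Canonical molecule-list dialect: comma-separated with a header row and the
columns ``x_nm,y_nm[,z_nm],frame[,photons,channel,molecule_id]``; lines
starting with ``#`` carry metadata (``# key=value``).  Third-party SMLM
exports are accommodated through ``column_map`` (rename) and
``coordinate_unit`` ("nm" or "px"; pixel coordinates are converted using the
camera pixel size).

Structure masks travel as single-channel TIFF rasters with a JSON sidecar
(``<stem>.json``) recording ``pixel_size_nm``, ``origin_nm`` and ``label``,
because raster containers do not carry physical calibration reliably.

Polygon ROIs are plain text: comment/metadata lines starting with ``#``,
then one ``x y`` vertex pair (nm) per line.

All readers reject malformed input rather than silently coercing it; error
messages name the file and offending column or line.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import (
    CANONICAL_COLUMNS,
    CameraGeometry,
    FormatError,
    LocalizationTable,
    PolygonROI,
    StructureMask,
    ValidationError,
)

_MANDATORY = ("x", "y")
_OPTIONAL = ("z", "frame", "photons", "channel", "molecule_id")
_CANONICAL_NAMES = {"x": "x_nm", "y": "y_nm", "z": "z_nm"}


def _read_metadata_lines(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_molecule_list(
    path,
    column_map: Mapping[str, str] | None = None,
    coordinate_unit: str = "nm",
    pixel_size: float | None = None,
    geometry: CameraGeometry | None = None,
) -> LocalizationTable:
    """Read a delimited molecule list into a :class:`LocalizationTable`.

    Parameters
    ----------
    column_map
        Maps logical names (``x``, ``y``, ``z``, ``frame``, ``photons``,
        ``channel``) to the column names used in the file.  Defaults to the
        canonical dialect (``x_nm``, ``y_nm``, ...).
    coordinate_unit
        "nm" (default) or "px"; pixel coordinates are converted to nm using
        ``pixel_size`` (or the attached/sidecar geometry).
    """
    path = Path(path)
    meta = _read_metadata_lines(path)
    if geometry is None and "pixel_size_nm" in meta:
        geometry = CameraGeometry(
            pixel_size=float(meta["pixel_size_nm"]),
            sensor_width=int(meta.get("sensor_width_px", 256)),
            sensor_height=int(meta.get("sensor_height_px", 256)),
        )
    try:
        raw = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas detail
        raise FormatError(f"{path}: cannot parse molecule list: {exc}") from exc

    column_map = dict(column_map or {})
    resolved: dict[str, str] = {}
    for logical in _MANDATORY + _OPTIONAL:
        candidates = [column_map[logical]] if logical in column_map else [
            _CANONICAL_NAMES.get(logical, logical),
            logical,
        ]
        for cand in candidates:
            if cand in raw.columns:
                resolved[logical] = cand
                break
    for logical in _MANDATORY:
        if logical not in resolved:
            raise FormatError(f"{path}: missing mandatory column {logical!r} (header: {list(raw.columns)})")

    out = pd.DataFrame()
    for logical, src in resolved.items():
        target = _CANONICAL_NAMES.get(logical, logical)
        col = raw[src]
        if logical in ("x", "y", "z", "photons"):
            numeric = pd.to_numeric(col, errors="coerce")
            bad = numeric.isna() & col.notna()
            if bad.any():
                # +2: one for the header line, one for 1-based numbering
                line = int(bad.idxmax()) + 2
                raise FormatError(f"{path}: non-numeric value {col[bad.idxmax()]!r} in column {src!r} at line {line}")
            col = numeric
        out[target] = col
    if coordinate_unit == "px":
        ps = pixel_size if pixel_size is not None else (geometry.pixel_size if geometry else None)
        if ps is None:
            raise FormatError(f"{path}: coordinates are in pixels but no pixel size is available")
        for axis in ("x_nm", "y_nm", "z_nm"):
            if axis in out.columns:
                out[axis] = out[axis] * ps
    elif coordinate_unit != "nm":
        raise FormatError(f"unknown coordinate unit {coordinate_unit!r}; use 'nm' or 'px'")

    # unrecognized columns are retained as extra table columns
    used = set(resolved.values())
    for col in raw.columns:
        if col not in used and col not in out.columns:
            out[col] = raw[col]
    table = LocalizationTable(out, geometry=geometry, provenance={"source": str(path), **meta})
    return table


def write_molecule_list(table: LocalizationTable, path) -> Path:
    """Write a molecule list in the canonical dialect (with metadata header)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ordered = [c for c in CANONICAL_COLUMNS if c in table.data.columns]
    ordered += [c for c in table.data.columns if c not in ordered]
    with open(path, "w") as fh:
        if table.geometry is not None:
            fh.write(f"# pixel_size_nm={table.geometry.pixel_size}\n")
            fh.write(f"# sensor_width_px={table.geometry.sensor_width}\n")
            fh.write(f"# sensor_height_px={table.geometry.sensor_height}\n")
        table.data[ordered].to_csv(fh, index=False)
    return path


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def read_mask(path, pixel_size: float | None = None) -> StructureMask:
    """Read a single-channel raster; nonzero pixels are structure."""
    path = Path(path)
    raster = tifffile.imread(path)
    if raster.ndim != 2:
        raise FormatError(
            f"{path}: expected a single-channel raster, got shape {raster.shape}; select one channel before reading"
        )
    origin = (0.0, 0.0)
    label = ""
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        pixel_size = float(meta.get("pixel_size_nm", pixel_size or 0)) or pixel_size
        origin = tuple(meta.get("origin_nm", origin))
        label = meta.get("label", "")
    if pixel_size is None:
        raise FormatError(f"{path}: no pixel size given and no sidecar {side.name} found")
    return StructureMask(raster != 0, pixel_size=pixel_size, origin=origin, label=label)


def write_mask(mask: StructureMask, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mask.pixels.astype(np.uint8))
    _sidecar(path).write_text(
        json.dumps(
            {"pixel_size_nm": mask.pixel_size, "origin_nm": list(mask.origin), "label": mask.label},
            indent=1,
        )
    )
    return path


def read_roi(path) -> PolygonROI:
    """Read a polygon ROI from the plain-text vertex format."""
    path = Path(path)
    vertices = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise FormatError(f"{path}: line {i}: expected 'x y', got {line!r}")
            try:
                vertices.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: non-numeric vertex {line!r}") from exc
    try:
        return PolygonROI(np.array(vertices).reshape(-1, 2))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_roi(roi: PolygonROI, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# polygon ROI, vertices in nm\n")
        for x, y in roi.vertices:
            fh.write(f"{float(x)!r} {float(y)!r}\n")
    return path


def read_config(path) -> dict:
    """Read a pipeline/scenario config (YAML key/value document)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping at top level")
    return cfg
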