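"""Core data containers shared across the pipeline.

Single-molecule localization microscopy (SMLM) reconstructions are molecule
lists: one row per localization point (LP), with lateral coordinates in
nanometres, the acquisition frame the blink was detected in, and optional
photon count / channel labels.  Everything downstream — density
quantification, spatial statistics, stoichiometry — operates on these
tables together with binary structure masks (binarized confocal images with
a physical pixel size) and polygonal analysis regions.

Coordinate convention: continuous nanometres, origin at the top-left camera
corner, x rightward, y downward.  Camera pixel ``i`` covers the half-open
interval ``[i*pixel_size, (i+1)*pixel_size)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely

NM_PER_UM = 1_000.0
NM2_PER_UM2 = NM_PER_UM**2

#: canonical molecule-list columns, in writing order
CANONICAL_COLUMNS = ("x_nm", "y_nm", "z_nm", "frame", "photons", "channel", "molecule_id")


class FormatError(ValueError):
    """A file did not conform to the documented dialect."""


class ValidationError(ValueError):
    """An in-memory object violated one of its invariants."""


@dataclass(frozen=True)
class CameraGeometry:
    """Physical geometry of the detector used to acquire a molecule list.

    Parameters
    ----------
    pixel_size : float
        Camera pixel size in nm/pixel (back-projected to the sample).
    sensor_width, sensor_height : int
        Sensor dimensions in pixels.
    """

    pixel_size: float = 160.0
    sensor_width: int = 256
    sensor_height: int = 256

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        if self.sensor_width < 1 or self.sensor_height < 1:
            raise ValidationError("sensor dimensions must be >= 1 pixel")

    @property
    def field_width_nm(self) -> float:
        return self.sensor_width * self.pixel_size

    @property
    def field_height_nm(self) -> float:
        return self.sensor_height * self.pixel_size

    def to_dict(self) -> dict:
        return {
            "pixel_size": self.pixel_size,
            "sensor_width": self.sensor_width,
            "sensor_height": self.sensor_height,
        }


@dataclass
class LocalizationTable:
    """A molecule list: one row per localization point (LP).

    ``data`` must contain at least ``x_nm`` and ``y_nm``; ``frame`` defaults
    to 0 when absent.  Optional columns (``z_nm``, ``photons``, ``channel``,
    ``molecule_id``) and any extra columns are carried through untouched.
    ``molecule_id`` is the simulator's ground-truth linkage (−1 = background).
    """

    data: pd.DataFrame
    geometry: CameraGeometry | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("x_nm", "y_nm"):
            if col not in self.data.columns:
                raise ValidationError(f"molecule list lacks mandatory column {col!r}")
        if "frame" not in self.data.columns:
            self.data = self.data.assign(frame=0)
        frames = np.asarray(self.data["frame"])
        if len(frames) and frames.min() < 0:
            raise ValidationError("frame indices must be >= 0")

    @classmethod
    def from_arrays(
        cls,
        x_nm: Sequence[float],
        y_nm: Sequence[float],
        frame: Sequence[int] | None = None,
        geometry: CameraGeometry | None = None,
        **extra: Sequence,
    ) -> "LocalizationTable":
        cols: dict = {"x_nm": np.asarray(x_nm, float), "y_nm": np.asarray(y_nm, float)}
        cols["frame"] = np.zeros(len(cols["x_nm"]), int) if frame is None else np.asarray(frame)
        for name, values in extra.items():
            cols[name] = np.asarray(values)
        return cls(pd.DataFrame(cols), geometry=geometry)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of lateral positions in nm."""
        return self.data[["x_nm", "y_nm"]].to_numpy(float)

    def select(self, mask: np.ndarray) -> "LocalizationTable":
        """Row subset preserving order, geometry and provenance."""
        return LocalizationTable(
            self.data.loc[np.asarray(mask)].reset_index(drop=True),
            geometry=self.geometry,
            provenance=dict(self.provenance),
        )

    def validate_in_sensor(self) -> None:
        """Check LPs lie inside the camera field (requires geometry)."""
        if self.geometry is None:
            raise ValidationError("no camera geometry attached")
        x, y = self.coords.T
        if len(x) and (
            x.min() < 0
            or y.min() < 0
            or x.max() >= self.geometry.field_width_nm
            or y.max() >= self.geometry.field_height_nm
        ):
            raise ValidationError("localization outside the camera field")


@dataclass
class StructureMask:
    """Binary raster representing a binarized confocal structure.

    ``pixels`` is indexed ``[row, col]`` = ``[y, x]``.  ``origin`` is the nm
    offset of the raster's top-left corner within the camera frame.
    """

    pixels: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValidationError("mask raster must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_nm2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size**2

    @property
    def area_um2(self) -> float:
        return self.area_nm2 / NM2_PER_UM2

    @property
    def extent_nm(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the raster in nm."""
        h, w = self.pixels.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + w * self.pixel_size, y0 + h * self.pixel_size)

    def pixel_indices(self, x_nm: np.ndarray, y_nm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map nm coordinates to (row, col); half-open pixel convention."""
        col = np.floor((np.asarray(x_nm, float) - self.origin[0]) / self.pixel_size).astype(int)
        row = np.floor((np.asarray(y_nm, float) - self.origin[1]) / self.pixel_size).astype(int)
        return row, col

    def contains(self, x_nm, y_nm) -> np.ndarray:
        """Boolean array: does each point fall on a structure pixel?"""
        row, col = self.pixel_indices(np.atleast_1d(x_nm), np.atleast_1d(y_nm))
        h, w = self.pixels.shape
        inside = (row >= 0) & (row < h) & (col >= 0) & (col < w)
        out = np.zeros(len(row), bool)
        out[inside] = self.pixels[row[inside], col[inside]]
        return out

    def union(self, other: "StructureMask") -> "StructureMask":
        if other.shape != self.shape or other.pixel_size != self.pixel_size or other.origin != self.origin:
            raise ValidationError("masks must share raster geometry to be combined")
        return StructureMask(self.pixels | other.pixels, self.pixel_size, self.origin, label="union")


def union_masks(masks: Sequence[StructureMask]) -> StructureMask:
    """Union of co-registered masks (e.g. all boutons in one field)."""
    if not masks:
        raise ValidationError("no masks to combine")
    out = masks[0]
    for m in masks[1:]:
        out = out.union(m)
    return out


@dataclass
class PolygonROI:
    """Closed planar analysis polygon in nm (plasma-membrane contour,
    analysis window, bouton outline).  Must be simple with positive area;
    the region is closed: boundary points count as inside."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError("vertices must be an (n, 2) array")
        if len(self.vertices) < 3:
            raise ValidationError("a polygon ROI needs at least 3 vertices")
        poly = shapely.Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise ValidationError("polygon ROI must be simple with positive area")
        self._polygon = poly

    @classmethod
    def rectangle(cls, x_min: float, y_min: float, x_max: float, y_max: float) -> "PolygonROI":
        return cls(np.array([[x_min, y_min], [x_max, y_min], [x_max, y_max], [x_min, y_max]]))

    @property
    def polygon(self) -> shapely.Polygon:
        return self._polygon

    @property
    def area_nm2(self) -> float:
        return float(self._polygon.area)

    @property
    def area_um2(self) -> float:
        return self.area_nm2 / NM2_PER_UM2

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self._polygon.bounds

    def contains(self, x_nm, y_nm) -> np.ndarray:
        """Closed point-in-polygon test (boundary counts as inside)."""
        return shapely.intersects_xy(self._polygon, np.atleast_1d(x_nm), np.atleast_1d(y_nm))


def region_area_um2(region: "PolygonROI | StructureMask") -> float:
    if isinstance(region, PolygonROI):
        return region.area_um2
    if isinstance(region, StructureMask):
        return region.area_um2
    raise TypeError(f"unsupported region type {type(region)!r}")
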