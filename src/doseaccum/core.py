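"""Core grid types: geometry, image volumes, structure masks and dose grids.

All grids are axis-aligned (no direction matrix): the physical coordinate of
voxel index ``i`` along an axis is ``origin + i * spacing``.  Arrays are
indexed ``[i, j, k]`` for world axes ``(x, y, z)``, matching a diagonal
NIfTI affine.  Interpolation is always performed in physical (mm)
coordinates so that grids with different spacing compose correctly.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

HU_MIN = -1024.0
HU_MAX = 3000.0

#: background fill values used when sampling outside a grid's extent
FILL_HU = -1000.0
FILL_DOSE = 0.0
FILL_MASK = False


class Modality(str, enum.Enum):
    CT = "CT"
    CBCT = "CBCT"
    MCBCT = "mCBCT"
    DENSITY = "DENSITY"


class DoseFrame(str, enum.Enum):
    PLANNING = "PLANNING"
    WEEKLY = "WEEKLY"


class GeometryError(ValueError):
    """Invalid or incompatible grid geometry."""


class UsageError(ValueError):
    """Operation called with arguments that violate its contract."""


@dataclass(frozen=True)
class GridGeometry:
    """Axis-aligned 3D sampling grid.

    Parameters
    ----------
    shape
        Number of voxels per axis ``(nx, ny, nz)``.
    spacing
        Voxel size in mm per axis; strictly positive.
    origin
        World coordinate (mm) of the *center* of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise GeometryError("geometry must be three-dimensional")
        if any(n <= 0 for n in shape):
            raise GeometryError(f"non-positive shape {shape}")
        if any(s <= 0 for s in spacing):
            raise GeometryError(f"non-positive spacing {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # -- coordinate helpers -------------------------------------------------
    @property
    def spacing_arr(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    @property
    def origin_arr(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    @property
    def extent(self) -> np.ndarray:
        """Physical size (mm) spanned from first to last voxel center."""
        return (np.asarray(self.shape) - 1) * self.spacing_arr

    @property
    def center(self) -> np.ndarray:
        """World coordinate of the grid's physical center."""
        return self.origin_arr + self.extent / 2.0

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_arr))

    def world_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of every voxel center, as three 1D axes."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def world_points(self, dtype=np.float64) -> np.ndarray:
        """Dense ``(nx, ny, nz, 3)`` array of voxel-center world coordinates."""
        ax = self.world_grid()
        pts = np.empty(self.shape + (3,), dtype=dtype)
        pts[..., 0] = ax[0][:, None, None]
        pts[..., 1] = ax[1][None, :, None]
        pts[..., 2] = ax[2][None, None, :]
        return pts

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates (..., 3) to fractional voxel indices."""
        return (np.asarray(points) - self.origin_arr) / self.spacing_arr

    def approx_equal(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    @classmethod
    def centered(
        cls,
        shape: tuple[int, int, int],
        spacing: tuple[float, float, float],
        center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "GridGeometry":
        """Grid whose physical center lies at ``center``."""
        shape = tuple(int(n) for n in shape)
        spacing = np.asarray(spacing, dtype=float)
        origin = np.asarray(center) - (np.asarray(shape) - 1) * spacing / 2.0
        return cls(shape, tuple(spacing), tuple(origin))


def _check_values(geometry: GridGeometry, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != geometry.shape:
        raise GeometryError(
            f"values shape {values.shape} does not match geometry {geometry.shape}"
        )
    return values


@dataclass
class ImageVolume:
    """Scalar HU (or relative-density) volume on a grid."""

    geometry: GridGeometry
    values: np.ndarray
    modality: Modality = Modality.CT

    def __post_init__(self) -> None:
        self.values = _check_values(self.geometry, self.values).astype(
            np.float32, copy=False
        )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        self.modality = Modality(self.modality)

    def clipped_hu(self) -> "ImageVolume":
        """Clip to the supported HU range (applied on ingest)."""
        return dataclasses.replace(
            self, values=np.clip(self.values, HU_MIN, HU_MAX)
        )


@dataclass
class StructureMask:
    """Binary structure mask sharing its parent volume's grid.

    ``indicator`` optionally carries the partial-volume fraction in [0, 1]
    (e.g. from supersampled voxelisation).  When present it is what warping
    and resampling interpolate before thresholding at 0.5, which keeps
    structure surfaces sub-voxel accurate; the boolean ``values`` remain
    the authoritative voxel classification (``indicator >= 0.5``).
    """

    geometry: GridGeometry
    values: np.ndarray
    name: str = ""
    indicator: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = _check_values(self.geometry, self.values)
        if values.dtype != bool:
            values = values > 0.5
        self.values = values
        if self.indicator is not None:
            ind = _check_values(self.geometry, self.indicator)
            self.indicator = np.clip(ind.astype(np.float32), 0.0, 1.0)

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cc(self) -> float:
        """Structure volume in cubic centimetres."""
        return self.voxel_count * self.geometry.voxel_volume_mm3 / 1000.0

    def com(self) -> np.ndarray:
        """Center of mass in world coordinates (mm)."""
        if self.voxel_count == 0:
            raise ValueError(f"empty mask {self.name!r} has no center of mass")
        idx = np.array(ndimage.center_of_mass(self.values))
        return self.geometry.origin_arr + idx * self.geometry.spacing_arr


@dataclass
class DoseGrid:
    """Absorbed dose (Gy) on a grid, tagged with its reference frame."""

    geometry: GridGeometry
    values: np.ndarray
    frame: DoseFrame = DoseFrame.PLANNING

    def __post_init__(self) -> None:
        self.values = _check_values(self.geometry, self.values).astype(
            np.float64, copy=False
        )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose contains non-finite values")
        if self.values.min() < -1e-9:
            raise ValueError("dose contains negative values")
        self.values = np.maximum(self.values, 0.0)
        self.frame = DoseFrame(self.frame)


GridObject = ImageVolume | StructureMask | DoseGrid


def _fill_value(obj: GridObject) -> float:
    if isinstance(obj, StructureMask):
        return 0.0
    if isinstance(obj, DoseGrid):
        return FILL_DOSE
    return FILL_HU


def sample_at_points(
    obj: GridObject, points: np.ndarray, mode: str = "linear"
) -> np.ndarray:
    """Interpolate ``obj`` at world coordinates ``points`` (..., 3).

    Points outside the source extent receive the type's background fill
    (-1000 HU, 0 Gy, or 0 for masks).
    """
    if mode not in ("linear", "nearest"):
        raise UsageError(f"unknown interpolation mode {mode!r}")
    order = 1 if mode == "linear" else 0
    idx = obj.geometry.world_to_index(points)
    src = obj.values
    if isinstance(obj, StructureMask) and mode == "linear" and obj.indicator is not None:
        # anti-aliased indicator: cubic interpolation removes the curvature
        # bias (~spacing^2 / structure radius) that trilinear warping of a
        # convex surface would introduce before thresholding
        src = obj.indicator
        order = 3
    if src.dtype == bool:
        src = src.astype(np.float32)
    coords = np.moveaxis(idx, -1, 0)
    out = ndimage.map_coordinates(
        src, coords, order=order, mode="grid-constant", cval=_fill_value(obj)
    )
    return out


def _rewrap(obj: GridObject, geometry: GridGeometry, values: np.ndarray) -> GridObject:
    if isinstance(obj, StructureMask):
        ind = None
        if obj.indicator is not None and values.dtype != bool:
            ind = values  # interpolated partial-volume fraction
        return StructureMask(geometry, values > 0.5, name=obj.name, indicator=ind)
    if isinstance(obj, DoseGrid):
        return DoseGrid(geometry, np.maximum(values, 0.0), frame=obj.frame)
    return ImageVolume(geometry, values, modality=obj.modality)


def resample(
    obj: GridObject, target: GridGeometry, mode: str = "linear"
) -> GridObject:
    """Resample onto ``target`` by interpolation at target voxel centers.

    Masks must use ``mode='nearest'``; outside-extent voxels get the
    background fill of the object kind.
    """
    if isinstance(obj, StructureMask) and mode == "linear":
        raise UsageError("masks must be resampled with mode='nearest'")
    if obj.geometry.approx_equal(target):
        return _rewrap(obj, target, obj.values.copy())
    pts = target.world_points(dtype=np.float32)
    vals = sample_at_points(obj, pts, mode=mode)
    return _rewrap(obj, target, vals)
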