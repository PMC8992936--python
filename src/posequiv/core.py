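"""Core in-memory containers shared by all pipeline stages.

Coordinate convention (used everywhere in this package): right-handed,
LPS-like patient axes — x along right→left (R-L), y along
anterior→posterior (P-A), z along inferior→superior (I-S).  All world
coordinates are in millimetres.  Volume arrays are indexed ``[ix, iy, iz]``
along those same axes; the world position of voxel ``(i, j, k)`` is
``origin + (i, j, k) * spacing`` (voxel centres, 0-based indices).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError

#: direction labels in canonical order: three translations then the
#: rotations about the same axes (pitch about R-L, yaw about P-A, roll
#: about I-S).
DIRECTIONS = ("RL", "PA", "IS", "pitch", "yaw", "roll")
TRANSLATION_DIRECTIONS = DIRECTIONS[:3]
ROTATION_DIRECTIONS = DIRECTIONS[3:]


@dataclass
class VolumeImage:
    """A 3D scalar grid (typically Hounsfield Units) with geometry.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny, nz)``; axis order x (R-L), y (P-A),
        z (I-S).
    spacing
        Voxel size in mm per axis.
    origin
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError(
                f"volume must be 3D, got shape {self.values.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"non-positive spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def center(self) -> np.ndarray:
        """World coordinate (mm) of the geometric centre of the grid."""
        return np.asarray(self.origin) + (
            (np.asarray(self.shape) - 1) / 2.0
        ) * np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices for world points (mm)."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_centers(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """World coordinates (n, 3) of voxel centres, optionally masked."""
        if mask is None:
            idx = np.stack(
                np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"),
                axis=-1,
            ).reshape(-1, 3)
        else:
            idx = np.argwhere(mask)
        return self.index_to_world(idx)

    def like(self, values: np.ndarray) -> "VolumeImage":
        """New volume on this grid with different values."""
        return VolumeImage(values, self.spacing, self.origin)


@dataclass
class Projection:
    """A 2D parallel-ray projection of a volume.

    ``direction`` is ``"frontal"`` (rays along P-A, image axes x, z) or
    ``"lateral"`` (rays along R-L, image axes y, z).
    """

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float]
    direction: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("projection must be a 2D image")
        if self.direction not in ("frontal", "lateral"):
            raise ValidationError(f"unknown projection direction {self.direction!r}")


@dataclass
class StructureSet:
    """Ordered planar contour stack, e.g. a PTV from a DICOM-RT Struct.

    ``contours`` is a list of ``(n_i, 3)`` arrays of world points (mm);
    point order within each contour is meaningful and preserved by all
    operations (index correspondence is how paired-transform distances
    are defined).  Contours are stored open: the closing edge from the
    last back to the first point is implicit.
    """

    name: str
    contours: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for i, c in enumerate(self.contours):
            c = np.asarray(c, dtype=float)
            if c.ndim != 2 or c.shape[1] != 3:
                raise ValidationError(f"contour {i} must have shape (n, 3)")
            if c.shape[0] < 3:
                raise ValidationError(f"contour {i} has fewer than 3 points")
            if not np.all(np.isfinite(c)):
                raise ValidationError(f"contour {i} contains non-finite points")
            # drop a duplicated closure point so index correspondence
            # counts each vertex exactly once
            if np.allclose(c[0], c[-1]):
                c = c[:-1]
            cleaned.append(c)
        self.contours = cleaned

    @property
    def n_points(self) -> int:
        return sum(c.shape[0] for c in self.contours)

    def all_points(self) -> np.ndarray:
        """All contour points stacked in order, shape (n_points, 3)."""
        if not self.contours:
            return np.zeros((0, 3))
        return np.concatenate(self.contours, axis=0)

    def is_empty(self) -> bool:
        return self.n_points == 0


@dataclass
class DisplacementField:
    """Dense per-voxel 3D displacement vectors u(x) in mm.

    The deformation maps ``x -> x + u(x)``.  ``vectors`` has shape
    ``(nx, ny, nz, 3)`` on the same grid convention as `VolumeImage`.
    ``metadata`` may carry an analytic Jacobian-determinant callable
    (``jd_analytic(points_mm) -> values``) for synthetic fields.
    """

    vectors: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[3] != 3:
            raise ValidationError(
                f"displacement field must have shape (nx, ny, nz, 3), "
                f"got {self.vectors.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"non-positive spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    def grid_coordinates(self) -> tuple[np.ndarray, ...]:
        """1D world coordinate arrays per axis (mm)."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )
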