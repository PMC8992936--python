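"""Rigid-transform algebra for couch-correction parameters.

A setup correction is a six-degree-of-freedom (6-DoF) rigid transform:
translations tx, ty, tz in mm along the R-L, P-A and I-S patient axes,
and rotations pitch (about R-L), yaw (about P-A) and roll (about I-S) in
degrees.  2D orthogonal-projection workflows cannot correct roll, so
their results are 5-DoF with roll pinned at zero.

Convention (fixed throughout the package): rotations are extrinsic about
the fixed patient axes, composed as ``Rz(roll) @ Ry(yaw) @ Rx(pitch)``,
applied about an explicit rotation centre (the plan isocenter), followed
by the translation.  At the sub-2-degree magnitudes typical of setup
corrections the choice of composition order changes point positions by
well under 0.01 mm, but one order must be fixed for matrices to be
comparable — this is it.  Degrees at every interface, radians only
internally.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import StructureSet
from .errors import ValidationError

_EULER_SEQ = "xyz"  # extrinsic: Rz(roll) @ Ry(yaw) @ Rx(pitch)


@dataclass(frozen=True)
class SixDoF:
    """6-DoF rigid parameters: mm translations, degree rotations."""

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    pitch: float = 0.0
    yaw: float = 0.0
    roll: float = 0.0

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValidationError(f"non-finite 6-DoF parameters {vals}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.tx, self.ty, self.tz, self.pitch, self.yaw, self.roll],
            dtype=float,
        )

    @classmethod
    def from_array(cls, a) -> "SixDoF":
        a = np.asarray(a, dtype=float)
        if a.shape != (6,):
            raise ValidationError(f"expected 6 parameters, got shape {a.shape}")
        return cls(*a)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz])

    @property
    def rotation(self) -> np.ndarray:
        return np.array([self.pitch, self.yaw, self.roll])

    def __neg__(self) -> "SixDoF":
        return SixDoF.from_array(-self.as_array())


@dataclass
class RigidMatrix:
    """4x4 homogeneous rigid transform with its rotation centre (mm)."""

    matrix: np.ndarray
    rotation_center: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.rotation_center = np.asarray(self.rotation_center, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValidationError("rigid matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-9):
            raise ValidationError("last row of a rigid matrix must be (0,0,0,1)")
        R = self.matrix[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValidationError("rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation block has determinant -1 (reflection)")

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def offset(self) -> np.ndarray:
        return self.matrix[:3, 3]


def _rotation_from_params(p: SixDoF) -> Rotation:
    return Rotation.from_euler(_EULER_SEQ, [p.pitch, p.yaw, p.roll], degrees=True)


def build_matrix(p: SixDoF, center=(0.0, 0.0, 0.0)) -> RigidMatrix:
    """Homogeneous matrix for parameters ``p`` rotating about ``center``.

    Maps a point x to ``R @ (x - c) + c + t``.  All-zero parameters give
    the identity regardless of centre.
    """
    if not isinstance(p, SixDoF):
        p = SixDoF.from_array(p)
    c = np.asarray(center, dtype=float)
    if c.shape != (3,) or not np.all(np.isfinite(c)):
        raise ValidationError(f"rotation centre must be a finite 3-vector, got {c}")
    R = _rotation_from_params(p).as_matrix()
    m = np.eye(4)
    m[:3, :3] = R
    m[:3, 3] = c - R @ c + p.translation
    return RigidMatrix(m, c)


def params_from_matrix(m: RigidMatrix, center=None) -> SixDoF:
    """Recover 6-DoF parameters from a rigid matrix.

    Inverse of `build_matrix` within the |rotation| < 90 degree regime.
    Near yaw = ±90 degrees the Euler decomposition is gimbal-degenerate;
    a warning is emitted and one of the infinitely many valid solutions
    is returned.
    """
    if center is None:
        center = m.rotation_center
    c = np.asarray(center, dtype=float)
    R = m.rotation
    gimbal = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            angles = Rotation.from_matrix(R).as_euler(_EULER_SEQ, degrees=True)
    except UserWarning:
        gimbal = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            angles = Rotation.from_matrix(R).as_euler(_EULER_SEQ, degrees=True)
    if gimbal:
        warnings.warn(
            "gimbal lock: yaw within numerical precision of ±90°, "
            "pitch/roll split is not unique",
            stacklevel=2,
        )
    t = m.offset - (c - R @ c)
    return SixDoF(t[0], t[1], t[2], angles[0], angles[1], angles[2])


def apply_to_points(m: RigidMatrix, pts) -> np.ndarray:
    """Apply the transform to an (n, 3) array of points (mm)."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    if pts.shape[1] != 3:
        raise ValidationError("points must have shape (n, 3)")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("points contain non-finite coordinates")
    return pts @ m.rotation.T + m.offset


def transform_structure(m: RigidMatrix, s: StructureSet) -> StructureSet:
    """Transform every contour point, preserving contour grouping/order."""
    return StructureSet(s.name, [apply_to_points(m, c) for c in s.contours])


def compose(outer: RigidMatrix, inner: RigidMatrix) -> RigidMatrix:
    """Composition outer ∘ inner (inner applied first)."""
    return RigidMatrix(outer.matrix @ inner.matrix, inner.rotation_center)


def invert(m: RigidMatrix) -> RigidMatrix:
    Rt = m.rotation.T
    inv = np.eye(4)
    inv[:3, :3] = Rt
    inv[:3, 3] = -Rt @ m.offset
    return RigidMatrix(inv, m.rotation_center)


@dataclass
class PairedRegResult:
    """Setup-correction parameters for one case (and observer) obtained
    twice: once against the CT-derived reference and once against the
    synthetic-CT-derived reference.  ``modality`` distinguishes 3D
    volumetric positioning ("3D-CBCT") from 2D orthogonal-projection
    positioning ("2D-orth", 5-DoF)."""

    case: int
    ct: SixDoF
    sct: SixDoF
    observer: int | None = None
    modality: str = "3D-CBCT"

    def __post_init__(self) -> None:
        if self.modality not in ("3D-CBCT", "2D-orth"):
            raise ValidationError(f"unknown modality {self.modality!r}")


def restrict_to_5dof(p: SixDoF) -> SixDoF:
    """Pin roll (rotation about I-S) to zero: the 5-DoF regime of 2D
    orthogonal-projection positioning, where the in-plane couch rotation
    cannot be corrected.  Idempotent."""
    return SixDoF(p.tx, p.ty, p.tz, p.pitch, p.yaw, 0.0)
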