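"""Synthetic inputs with known ground truth for every pipeline stage.

No patient imaging ships with this package.  Instead, a parametric
head-and-neck phantom stands in for the planning CT: a soft-tissue
ellipsoid ("body contour") in a -1000 HU air background, containing
analytic bone solids — a skull-like spherical shell, a vertebral column
of stacked cylinders and a mandible-like half-annulus arc.  Because the
solids are analytic, bone volumes, masks and landmark positions all have
closed-form oracles.

A synthetic-CT surrogate is derived from the phantom by scaling bone
contrast toward soft tissue, Gaussian blurring and optional HU noise —
the qualitative degradations (blurred edges, reduced bone contrast) seen
in CNN-generated synthetic CT.  Smooth displacement fields with attached
analytic Jacobian determinants feed the deformation-QA stage, elliptical
contour stacks stand in for the PTV structure, and Gaussian paired
registration tables emulate observed per-direction positioning
differences at requested means/SDs.

All generators are bit-reproducible for a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import VolumeImage, StructureSet, DisplacementField
from .errors import ValidationError
from .geometry import SixDoF, PairedRegResult, restrict_to_5dof

# --------------------------------------------------------------------------
# analytic bone primitives


@dataclass(frozen=True)
class SphericalShell:
    """Hollow sphere (cranial vault surrogate)."""

    center: tuple[float, float, float]
    r_inner: float
    r_outer: float

    def contains(self, x, y, z):
        r2 = (
            (x - self.center[0]) ** 2
            + (y - self.center[1]) ** 2
            + (z - self.center[2]) ** 2
        )
        return (r2 >= self.r_inner**2) & (r2 <= self.r_outer**2)

    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * (self.r_outer**3 - self.r_inner**3)

    def validate(self) -> None:
        if not 0 < self.r_inner < self.r_outer:
            raise ValidationError("shell requires 0 < r_inner < r_outer")


@dataclass(frozen=True)
class Cylinder:
    """z-axis-aligned solid cylinder (vertebral body surrogate)."""

    center_xy: tuple[float, float]
    radius: float
    z_lo: float
    z_hi: float

    def contains(self, x, y, z):
        r2 = (x - self.center_xy[0]) ** 2 + (y - self.center_xy[1]) ** 2
        return (r2 <= self.radius**2) & (z >= self.z_lo) & (z <= self.z_hi)

    def volume(self) -> float:
        return math.pi * self.radius**2 * (self.z_hi - self.z_lo)

    def validate(self) -> None:
        if self.radius <= 0 or self.z_hi <= self.z_lo:
            raise ValidationError("cylinder requires radius > 0 and z_hi > z_lo")


@dataclass(frozen=True)
class HalfAnnulusSlab:
    """Anterior half of an annular slab (mandible arc surrogate).

    The annulus is centred on ``center_xy`` in a z-slab; only the
    anterior half (y <= center_y) is kept, so the closed-form volume is
    exactly half the full annular slab.
    """

    center_xy: tuple[float, float]
    r_inner: float
    r_outer: float
    z_lo: float
    z_hi: float

    def contains(self, x, y, z):
        r2 = (x - self.center_xy[0]) ** 2 + (y - self.center_xy[1]) ** 2
        return (
            (r2 >= self.r_inner**2)
            & (r2 <= self.r_outer**2)
            & (y <= self.center_xy[1])
            & (z >= self.z_lo)
            & (z <= self.z_hi)
        )

    def volume(self) -> float:
        return (
            0.5
            * math.pi
            * (self.r_outer**2 - self.r_inner**2)
            * (self.z_hi - self.z_lo)
        )

    def validate(self) -> None:
        if not 0 < self.r_inner < self.r_outer or self.z_hi <= self.z_lo:
            raise ValidationError("arc requires 0 < r_inner < r_outer, z_hi > z_lo")


def default_bone_elements() -> list:
    """Skull shell, five-segment cervical column, mandible arc.

    All solids are mutually disjoint and lie strictly inside the default
    body ellipsoid, so the total bone volume is the plain sum of the
    closed-form solid volumes.
    """
    elements: list = [SphericalShell((0.0, 0.0, 35.0), 44.0, 50.0)]
    z = -76.0
    for _ in range(5):  # vertebral bodies, 10 mm high, 2 mm disc gaps
        elements.append(Cylinder((0.0, 25.0), 10.0, z, z + 10.0))
        z += 12.0
    elements.append(HalfAnnulusSlab((0.0, 0.0), 35.0, 45.0, -20.0, -6.0))
    return elements


#: labelled anatomical-landmark surrogates (mm, patient coordinates),
#: placed on the analytic bone solids in the spirit of the clinical
#: bone-landmark set: mandibular condyles, mastoid region, mentum,
#: spinal-canal midpoints at two vertebral levels, hyoid region.
DEFAULT_LANDMARKS: dict[str, tuple[float, float, float]] = {
    "condyle_R": (-40.0, 0.0, -12.5),
    "condyle_L": (40.0, 0.0, -12.5),
    "mastoid_R": (-46.0, 0.0, 15.0),
    "mastoid_L": (46.0, 0.0, 15.0),
    "mentum": (0.0, -40.0, -12.5),
    "canal_C2": (0.0, 25.0, -22.0),
    "canal_C4": (0.0, 25.0, -46.0),
    "hyoid": (0.0, -15.0, -30.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the head-and-neck CT phantom.

    Defaults approximate clinical head-and-neck CT geometry: finer
    in-plane resolution than slice thickness, ~190 mm field of view, and
    HU values of -1000 (air), 40 (soft tissue) and 900 (bone, inside the
    clinical 200–1700 HU bone window).
    """

    grid_shape: tuple[int, int, int] = (128, 128, 96)
    spacing: tuple[float, float, float] = (1.5, 1.5, 2.0)
    body_axes: tuple[float, float, float] = (70.0, 80.0, 90.0)
    bone_elements: tuple = field(default_factory=lambda: tuple(default_bone_elements()))
    hu_soft: float = 40.0
    hu_bone: float = 900.0
    hu_air: float = -1000.0
    hu_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if any(n < 16 for n in self.grid_shape):
            raise ValidationError(f"grid_shape must be >= 16 per axis, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"non-positive spacing {self.spacing}")
        if any(a <= 0 for a in self.body_axes):
            raise ValidationError(f"non-positive body semi-axis in {self.body_axes}")
        if not self.hu_air < self.hu_soft < self.hu_bone:
            raise ValidationError("require hu_air < hu_soft < hu_bone")
        if not 200.0 <= self.hu_bone <= 1700.0:
            raise ValidationError(
                "hu_bone must lie in the 200–1700 HU bone window so bone "
                "survives thresholding"
            )
        if self.hu_noise_sd < 0:
            raise ValidationError("hu_noise_sd must be >= 0")
        for e in self.bone_elements:
            e.validate()

    def bone_volume_mm3(self) -> float:
        """Closed-form total bone volume (solids are disjoint)."""
        return sum(e.volume() for e in self.bone_elements)

    def grid_volume_mm3(self) -> float:
        return float(np.prod(self.grid_shape) * np.prod(self.spacing))


@dataclass
class GroundTruth:
    """Truth channel attached to every generated phantom."""

    applied_transform: SixDoF
    landmark_positions: dict[str, np.ndarray]
    ptv_center: np.ndarray
    body_mask: np.ndarray


def _world_grids(shape, spacing, origin):
    xs = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    return np.meshgrid(*xs, indexing="ij", sparse=True)


def _centered_origin(shape, spacing) -> tuple[float, float, float]:
    return tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[VolumeImage, GroundTruth]:
    """Rasterize the phantom and its ground-truth sidecar.

    The grid is centred on the body: world (0, 0, 0) is the body centre
    and the default isocenter.  Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    origin = _centered_origin(spec.grid_shape, spec.spacing)
    X, Y, Z = _world_grids(spec.grid_shape, spec.spacing, origin)

    a, b, c = spec.body_axes
    body = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    values = np.full(spec.grid_shape, spec.hu_air, dtype=float)
    values[body] = spec.hu_soft

    bone = np.zeros(spec.grid_shape, dtype=bool)
    for e in spec.bone_elements:
        bone |= e.contains(X, Y, Z)
    if np.any(bone & ~body):
        raise ValidationError("bone element extends outside the body contour")
    values[bone] = spec.hu_bone

    if spec.hu_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.hu_noise_sd, size=values.shape)
        values[~body] = spec.hu_air  # keep the -1000 HU background rule exact

    vol = VolumeImage(values, spec.spacing, origin)
    landmarks = {k: np.asarray(v, dtype=float) for k, v in DEFAULT_LANDMARKS.items()}
    idx = np.rint(vol.world_to_index(np.array(list(landmarks.values())))).astype(int)
    inside = body[idx[:, 0], idx[:, 1], idx[:, 2]]
    if not np.all(inside):
        bad = [k for k, ok in zip(landmarks, inside) if not ok]
        raise ValidationError(f"landmarks outside body mask: {bad}")
    truth = GroundTruth(
        applied_transform=SixDoF(),
        landmark_positions=landmarks,
        ptv_center=np.array([0.0, -5.0, -35.0]),
        body_mask=body,
    )
    return vol, truth


def make_sct_surrogate(
    ct: VolumeImage,
    blur_sigma_mm: float = 1.5,
    bone_contrast_scale: float = 0.8,
    noise_sd_hu: float = 15.0,
    seed: int = 0,
    hu_soft: float = 40.0,
    bone_threshold_hu: float = 200.0,
) -> VolumeImage:
    """Synthetic-CT surrogate: reduced bone contrast, blurred edges, noise.

    Voxels above ``bone_threshold_hu`` are pulled toward soft tissue,
    ``v -> hu_soft + bone_contrast_scale * (v - hu_soft)``, then the
    whole volume is Gaussian-blurred with ``blur_sigma_mm`` (mm) and
    Gaussian HU noise of SD ``noise_sd_hu`` is added.  Defaults emulate a
    synthetic CT whose bone is visibly softer and blurrier than the
    planning CT while remaining usable for bone-based positioning.
    """
    if not 0.0 < bone_contrast_scale <= 1.0:
        raise ValidationError(
            f"bone_contrast_scale must be in (0, 1], got {bone_contrast_scale}"
        )
    if blur_sigma_mm < 0:
        raise ValidationError("blur_sigma_mm must be >= 0")
    if noise_sd_hu < 0:
        raise ValidationError("noise_sd_hu must be >= 0")
    values = np.array(ct.values, dtype=float)
    bone = values >= bone_threshold_hu
    values[bone] = hu_soft + bone_contrast_scale * (values[bone] - hu_soft)
    if blur_sigma_mm > 0:
        sigma_vox = [blur_sigma_mm / s for s in ct.spacing]
        values = gaussian_filter(values, sigma=sigma_vox)
    if noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd_hu, size=values.shape)
    return ct.like(values)


# --------------------------------------------------------------------------
# deformation fields with analytic Jacobian determinants

DEFORMATION_KINDS = ("identity", "affine_scale", "gaussian_bump", "folding")


def _grid_descriptor(grid):
    if isinstance(grid, (VolumeImage, DisplacementField)):
        return grid.shape, grid.spacing, grid.origin
    shape, spacing, origin = grid
    return tuple(shape), tuple(spacing), tuple(origin)


def make_deformation(grid, kind: str, params: Optional[dict] = None, seed: int = 0) -> DisplacementField:
    """Synthetic displacement field u(x) with known analytic Jacobian.

    Kinds
    -----
    identity
        u = 0; JD = 1 everywhere.
    affine_scale
        u = (S - I)(x - c) for diagonal scaling S about the grid centre;
        JD = sx*sy*sz everywhere.  params: ``scale`` (3-tuple).
    gaussian_bump
        Displacement along one axis with Gaussian radial profile,
        u_k = A exp(-|x - c|^2 / 2 sigma^2); JD = 1 + du_k/dx_k has a
        closed form.  params: ``amplitude_mm``, ``sigma_mm``, ``axis``,
        optional ``center``.
    folding
        A gaussian_bump steep enough that JD < 0 near the bump centre —
        a physically unrealistic (non-invertible) deformation used to
        exercise the QA stage.  Default amplitude 3*sigma gives analytic
        min JD = 1 - 3 e^{-1/2} ≈ -0.82.

    The analytic determinant is attached as
    ``metadata["jd_analytic"]`` (callable on (n, 3) mm points) together
    with ``metadata["jd_analytic_min"]``.
    """
    if kind not in DEFORMATION_KINDS:
        raise ValidationError(f"unknown deformation kind {kind!r}; known: {DEFORMATION_KINDS}")
    shape, spacing, origin = _grid_descriptor(grid)
    params = dict(params or {})
    X, Y, Z = _world_grids(shape, spacing, origin)
    center_default = tuple(
        origin[a] + (shape[a] - 1) / 2.0 * spacing[a] for a in range(3)
    )
    vectors = np.zeros(shape + (3,), dtype=float)

    if kind == "identity":
        jd: Callable[[np.ndarray], np.ndarray] = lambda pts: np.ones(len(np.atleast_2d(pts)))
        jd_min = 1.0
    elif kind == "affine_scale":
        scale = np.asarray(params.get("scale", (1.1, 1.0, 0.9)), dtype=float)
        if scale.shape != (3,):
            raise ValidationError("affine_scale needs a 3-component 'scale'")
        c = np.asarray(params.get("center", center_default), dtype=float)
        vectors[..., 0] = (scale[0] - 1.0) * (X - c[0])
        vectors[..., 1] = (scale[1] - 1.0) * (Y - c[1])
        vectors[..., 2] = (scale[2] - 1.0) * (Z - c[2])
        det = float(np.prod(scale))
        jd = lambda pts, det=det: np.full(len(np.atleast_2d(pts)), det)
        jd_min = det
    else:  # gaussian_bump / folding
        sigma = float(params.get("sigma_mm", 10.0))
        if sigma <= 0:
            raise ValidationError("sigma_mm must be > 0")
        if kind == "folding":
            # amplitude above sigma*sqrt(e) makes 1 + du/dx dip below zero
            amp = float(params.get("amplitude_mm", 3.0 * sigma))
            if amp / sigma <= math.sqrt(math.e):
                raise ValidationError(
                    "folding requires amplitude_mm > sigma_mm*sqrt(e) for a "
                    "negative analytic Jacobian determinant"
                )
        else:
            amp = float(params.get("amplitude_mm", 3.0))
        axis = int(params.get("axis", 2))
        if axis not in (0, 1, 2):
            raise ValidationError("axis must be 0, 1 or 2")
        c = np.asarray(params.get("center", center_default), dtype=float)
        r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        vectors[..., axis] = amp * np.exp(-r2 / (2.0 * sigma**2))

        def jd(pts, amp=amp, sigma=sigma, c=c, axis=axis):
            pts = np.atleast_2d(np.asarray(pts, dtype=float))
            r2 = np.sum((pts - c) ** 2, axis=1)
            g = np.exp(-r2 / (2.0 * sigma**2))
            return 1.0 - amp * (pts[:, axis] - c[axis]) / sigma**2 * g

        jd_min = 1.0 - (amp / sigma) * math.exp(-0.5)

    return DisplacementField(
        vectors,
        spacing,
        origin,
        metadata={
            "kind": kind,
            "params": params,
            "seed": seed,
            "jd_analytic": jd,
            "jd_analytic_min": jd_min,
        },
    )


# --------------------------------------------------------------------------
# PTV contour stacks


def make_ptv(
    center=(0.0, -5.0, -35.0),
    semi_axes=(20.0, 20.0, 20.0),
    n_slices: int = 10,
    pts_per_contour: int = 64,
    name: str = "PTV",
) -> StructureSet:
    """Ellipsoidal PTV as a stack of planar elliptical contours.

    Contour planes sit at the centres of ``n_slices`` equal-height bands
    of the ellipsoid; each contour samples the ellipse cross-section at
    ``pts_per_contour`` equal angles.  Two calls with identical
    parameters give point-identical structures, so index correspondence
    across transformed copies is exact.
    """
    center = np.asarray(center, dtype=float)
    a, b, c = (float(v) for v in semi_axes)
    if min(a, b, c) <= 0:
        raise ValidationError(f"degenerate PTV semi-axis in {semi_axes}")
    if n_slices < 2:
        raise ValidationError("n_slices must be >= 2")
    if pts_per_contour < 8:
        raise ValidationError("pts_per_contour must be >= 8")
    angles = 2.0 * math.pi * np.arange(pts_per_contour) / pts_per_contour
    contours = []
    for k in range(n_slices):
        zr = -1.0 + (2.0 * k + 1.0) / n_slices  # band-centre height in [-1, 1]
        shrink = math.sqrt(max(0.0, 1.0 - zr**2))
        pts = np.column_stack(
            [
                center[0] + a * shrink * np.cos(angles),
                center[1] + b * shrink * np.sin(angles),
                np.full(pts_per_contour, center[2] + c * zr),
            ]
        )
        contours.append(pts)
    return StructureSet(name, contours)


# --------------------------------------------------------------------------
# paired registration tables and landmark placements


def sample_paired_registrations(
    n_cases: int,
    n_observers: int,
    per_direction_mean: Sequence[float],
    per_direction_sd: Sequence[float],
    seed: int = 0,
    modality: str = "2D-orth",
    baseline_sd: Sequence[float] = (2.0, 2.0, 2.0, 1.0, 1.0, 1.0),
) -> list[PairedRegResult]:
    """Paired CT/sCT setup corrections with Gaussian per-direction
    differences.

    Each case draws a shared baseline correction (the actual setup
    displacement, SD ``baseline_sd``); each observer's CT-based result
    adds small observer noise, and the sCT-based result adds on top a
    difference drawn per direction from N(mean, sd).  For 2D modality
    the roll component of both results is pinned to zero (5-DoF).
    """
    mean = np.asarray(per_direction_mean, dtype=float)
    sd = np.asarray(per_direction_sd, dtype=float)
    if mean.shape != (6,) or sd.shape != (6,):
        raise ValidationError("per_direction_mean/sd must have 6 components")
    if np.any(sd < 0):
        raise ValidationError("per_direction_sd must be >= 0")
    if n_cases < 1 or n_observers < 1:
        raise ValidationError("need n_cases >= 1 and n_observers >= 1")
    baseline_sd = np.asarray(baseline_sd, dtype=float)
    rng = np.random.default_rng(seed)
    out: list[PairedRegResult] = []
    for case in range(1, n_cases + 1):
        case_base = rng.normal(0.0, 1.0, size=6) * baseline_sd
        for obs in range(1, n_observers + 1):
            ct = case_base + rng.normal(0.0, 1.0, size=6) * 0.3 * (baseline_sd > 0)
            diff = mean + rng.normal(0.0, 1.0, size=6) * sd
            ct_p = SixDoF.from_array(ct)
            sct_p = SixDoF.from_array(ct + diff)
            if modality == "2D-orth":
                ct_p = restrict_to_5dof(ct_p)
                sct_p = restrict_to_5dof(sct_p)
            out.append(
                PairedRegResult(
                    case=case,
                    ct=ct_p,
                    sct=sct_p,
                    observer=obs if n_observers > 1 or modality == "2D-orth" else None,
                    modality=modality,
                )
            )
    return out


def place_landmarks(
    truth: GroundTruth,
    jitter_sd_mm: float = 1.0,
    n_repeats: int = 1,
    seed: int = 0,
) -> list[dict[str, np.ndarray]]:
    """``n_repeats`` jittered placements of every ground-truth landmark.

    Jitter is isotropic Gaussian in 3D, emulating manual click
    uncertainty; the default 1 mm SD corresponds to a mean radial
    placement error of about 1.6 mm.
    """
    if jitter_sd_mm < 0:
        raise ValidationError("jitter_sd_mm must be >= 0")
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    repeats = []
    for _ in range(n_repeats):
        repeats.append(
            {
                label: pos + rng.normal(0.0, jitter_sd_mm, size=3)
                for label, pos in truth.landmark_positions.items()
            }
        )
    return repeats
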