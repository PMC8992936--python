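"""Interobserver positioning metrics on PTV structures.

When setup corrections include rotations, a per-axis parameter
difference is hard to translate into a clinical effect.  The metric
implemented here makes the effect explicit: apply the CT-based and the
synthetic-CT-based registration matrices separately to the original PTV
contour points and measure the Euclidean distance between corresponding
points.  A pure relative translation t makes the distance histogram a
spike at |t|; a relative rotation spreads it (each point at radius r
from the rotation axis moves by 2 r sin(delta/2)).

Dice overlap of the two registered PTVs complements the point-wise
distances: observers may disagree in individual parameters yet produce
nearly identical target positions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon

from .core import StructureSet, VolumeImage
from .errors import ValidationError
from .geometry import RigidMatrix, apply_to_points

HISTOGRAM_BIN_MM = 0.25


@dataclass
class DistanceReport:
    """Per-point Euclidean distances between two registered copies of a
    structure, with summary statistics and a fixed-width histogram."""

    per_point_distances: np.ndarray  # mm, ordered as the structure's points
    mean: float
    sd: float
    max: float
    histogram_edges: np.ndarray  # mm, 0.25 mm bins from 0 to ceil(max)
    histogram_counts: np.ndarray


@dataclass
class OverlapReport:
    dsc: float
    count_a: int
    count_b: int
    count_intersection: int


@dataclass
class CaseSummary:
    """Per-case pooling of per-observer distance reports."""

    n_observers: int
    mean_of_observer_means: float
    sd_of_observer_means: float
    worst_observer: int  # index into the input report list
    worst_observer_mean: float
    worst_observer_sd: float
    max_distance: float


def paired_ptv_distances(
    ptv: StructureSet, m_ref_a: RigidMatrix, m_ref_b: RigidMatrix
) -> DistanceReport:
    """Euclidean distance ``|A p_i - B p_i|`` for every structure point.

    Correspondence is by index: the same original point transformed by
    each matrix.  Composing the same extra rigid transform onto both
    matrices leaves every distance unchanged.
    """
    if ptv.is_empty():
        raise ValidationError(f"structure {ptv.name!r} has no points")
    pts = ptv.all_points()
    d = np.linalg.norm(
        apply_to_points(m_ref_a, pts) - apply_to_points(m_ref_b, pts), axis=1
    )
    top = max(1.0, math.ceil(float(d.max())))
    edges = np.arange(0.0, top + HISTOGRAM_BIN_MM / 2, HISTOGRAM_BIN_MM)
    counts, _ = np.histogram(d, bins=edges)
    return DistanceReport(
        per_point_distances=d,
        mean=float(d.mean()),
        sd=float(d.std(ddof=1)) if d.size > 1 else 0.0,
        max=float(d.max()),
        histogram_edges=edges,
        histogram_counts=counts,
    )


def _slice_tolerance(z_planes: np.ndarray, grid_spacing: float) -> float:
    if len(z_planes) > 1:
        return 0.5 * float(np.median(np.diff(np.sort(z_planes))))
    return 0.5 * grid_spacing


def rasterize_structure(
    s: StructureSet,
    grid_spacing_mm: float = 1.0,
    bounds: Optional[tuple] = None,
) -> VolumeImage:
    """Binary volume of the contour stack on an isotropic grid.

    Each grid z-plane is assigned the nearest contour plane (within half
    the contour pitch, so the stack extends half a slice beyond the
    terminal contours); voxel centres inside that polygon are marked.
    ``bounds`` (``(lo_xyz, hi_xyz)`` in mm) lets two structures share a
    grid for overlap computation; by default the structure's bounding
    box padded by two voxels is used.
    """
    if s.is_empty():
        raise ValidationError(f"structure {s.name!r} has no points")
    if grid_spacing_mm <= 0:
        raise ValidationError("grid_spacing_mm must be > 0")
    for i, c in enumerate(s.contours):
        if np.ptp(c[:, 2]) > 1e-6:
            raise ValidationError(f"contour {i} of {s.name!r} is not planar in z")
        if not Polygon(c[:, :2]).is_valid:
            raise ValidationError(f"contour {i} of {s.name!r} self-intersects")

    pts = s.all_points()
    h = float(grid_spacing_mm)
    if bounds is None:
        lo = pts.min(axis=0) - 2 * h
        hi = pts.max(axis=0) + 2 * h
    else:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
    shape = tuple(int(np.floor((hi[a] - lo[a]) / h)) + 1 for a in range(3))
    xs = lo[0] + np.arange(shape[0]) * h
    ys = lo[1] + np.arange(shape[1]) * h
    zs = lo[2] + np.arange(shape[2]) * h

    z_planes = np.array([c[0, 2] for c in s.contours])
    tol = _slice_tolerance(z_planes, h) + 1e-9
    mask = np.zeros(shape, dtype=bool)
    xy = np.column_stack(
        [np.repeat(xs, shape[1]), np.tile(ys, shape[0])]
    )
    for k, z in enumerate(zs):
        j = int(np.argmin(np.abs(z_planes - z)))
        if abs(z_planes[j] - z) > tol:
            continue
        path = MplPath(s.contours[j][:, :2], closed=False)
        inside = path.contains_points(xy)
        mask[:, :, k] = inside.reshape(shape[0], shape[1])
    return VolumeImage(mask, (h, h, h), tuple(lo))


def dice(a, b) -> OverlapReport:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) of two binary
    masks on the same grid (3D volumes or 2D projected masks)."""
    av = a.values if isinstance(a, VolumeImage) else np.asarray(a)
    bv = b.values if isinstance(b, VolumeImage) else np.asarray(b)
    if av.shape != bv.shape:
        raise ValidationError(f"mask grids differ: {av.shape} vs {bv.shape}")
    av = av.astype(bool)
    bv = bv.astype(bool)
    na, nb = int(av.sum()), int(bv.sum())
    if na + nb == 0:
        raise ValidationError("both masks are empty; DSC undefined")
    ni = int((av & bv).sum())
    return OverlapReport(
        dsc=2.0 * ni / (na + nb), count_a=na, count_b=nb, count_intersection=ni
    )


def registered_overlap(
    s: StructureSet,
    m_ref_a: RigidMatrix,
    m_ref_b: RigidMatrix,
    grid_spacing_mm: float = 1.0,
) -> OverlapReport:
    """DSC between two rigidly registered copies of one structure.

    The original (planar) contour stack is rasterized once; each
    registered copy's mask is obtained by mapping voxel centres of a
    common grid back through the inverse transform and looking them up
    in the base mask (nearest neighbour).  This handles the general
    case where rotation tilts the contour planes off the grid axes.
    """
    from scipy.ndimage import map_coordinates

    from .geometry import invert

    base = rasterize_structure(s, grid_spacing_mm)
    pts = s.all_points()
    moved = np.vstack([apply_to_points(m_ref_a, pts), apply_to_points(m_ref_b, pts)])
    h = float(grid_spacing_mm)
    lo = moved.min(axis=0) - 2 * h
    hi = moved.max(axis=0) + 2 * h
    shape = tuple(int(np.floor((hi[a] - lo[a]) / h)) + 1 for a in range(3))
    centers = np.stack(
        np.meshgrid(
            *[lo[a] + np.arange(shape[a]) * h for a in range(3)], indexing="ij"
        ),
        axis=-1,
    ).reshape(-1, 3)
    masks = []
    for m in (m_ref_a, m_ref_b):
        back = apply_to_points(invert(m), centers)
        idx = base.world_to_index(back).T
        vals = map_coordinates(
            base.values.astype(np.float32), idx, order=0, mode="constant", cval=0.0
        )
        masks.append((vals > 0.5).reshape(shape))
    return dice(masks[0], masks[1])


def project_mask(mask: VolumeImage, direction: str = "frontal") -> np.ndarray:
    """2D projected binary mask (beam's-eye-view style) for the optional
    2D overlap variant."""
    axis = {"frontal": 1, "lateral": 0}.get(direction)
    if axis is None:
        raise ValidationError(f"unknown projection direction {direction!r}")
    return mask.values.astype(bool).any(axis=axis)


def observer_summary(reports: Sequence[DistanceReport]) -> CaseSummary:
    """Pool per-observer distance reports for one case.

    Reports the mean ± SD of the per-observer mean distances, and
    identifies the worst-case observer (largest per-observer mean),
    quoting that observer's mean ± SD together with the global maximum
    distance over all observers.
    """
    if len(reports) == 0:
        raise ValidationError("need at least one observer report")
    means = np.array([r.mean for r in reports])
    worst = int(np.argmax(means))
    return CaseSummary(
        n_observers=len(reports),
        mean_of_observer_means=float(means.mean()),
        sd_of_observer_means=float(means.std(ddof=1)) if len(means) > 1 else 0.0,
        worst_observer=worst,
        worst_observer_mean=float(reports[worst].mean),
        worst_observer_sd=float(reports[worst].sd),
        max_distance=float(max(r.max for r in reports)),
    )
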