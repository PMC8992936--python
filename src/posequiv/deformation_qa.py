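"""Quality assurance of deformable-registration outputs.

A deformable registration that folds tissue is not physically credible:
the Jacobian determinant (JD) of the mapping x -> x + u(x) must stay
positive wherever anatomy exists.  JD > 1 means local expansion, JD < 1
contraction, JD <= 0 a non-invertible folding.  `jacobian_determinant`
evaluates det(I + grad u) by finite differences within a body mask and
flags fields containing any non-positive JD as unrealistic.

Anatomical correspondence after registration is checked with labelled
bone landmarks: within-image distances defined along a patient axis (or
as Euclidean point offsets) are measured in both images and differenced,
and repeated manual placements of a single landmark quantify the
placement reproducibility that bounds what landmark offsets can detect.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import DisplacementField
from .errors import ValidationError

_AXIS_INDEX = {"RL": 0, "PA": 1, "IS": 2}


@dataclass
class JdReport:
    jd_field: np.ndarray  # NaN outside the mask
    min_jd: float
    max_jd: float
    fraction_nonpositive: float
    realistic: bool  # true iff JD > 0 everywhere in the mask


@dataclass
class LandmarkDefinition:
    """A measurable bone-landmark quantity.

    ``labels`` holds one or two landmark labels.  With two labels and a
    patient axis ("RL", "PA", "IS"), the measure is the signed
    coordinate difference between the two landmarks along that axis
    (within one image); with two labels and axis "euclidean" it is their
    Euclidean separation.  With a single label and a patient axis the
    measure is that landmark's coordinate; a single label with
    "euclidean" measures the between-image point offset directly.
    """

    name: str
    labels: tuple[str, ...]
    axis: str = "euclidean"

    def __post_init__(self) -> None:
        if self.axis not in ("RL", "PA", "IS", "euclidean"):
            raise ValidationError(f"unknown axis {self.axis!r}")
        if len(self.labels) not in (1, 2):
            raise ValidationError("definition needs 1 or 2 landmark labels")


#: default definitions for the phantom landmark set: bilateral
#: horizontal separations, vertical mentum/hyoid-to-column distances and
#: spinal-canal coordinates at two vertebral levels.
DEFAULT_DEFINITIONS: list[LandmarkDefinition] = [
    LandmarkDefinition("condyle_separation_RL", ("condyle_R", "condyle_L"), "RL"),
    LandmarkDefinition("mastoid_separation_RL", ("mastoid_R", "mastoid_L"), "RL"),
    LandmarkDefinition("mentum_to_canal_IS", ("mentum", "canal_C2"), "IS"),
    LandmarkDefinition("canal_C2_IS", ("canal_C2",), "IS"),
    LandmarkDefinition("canal_C2_RL", ("canal_C2",), "RL"),
    LandmarkDefinition("mandible_angle_separation_RL", ("condyle_R", "condyle_L"), "euclidean"),
    LandmarkDefinition("canal_C4_IS", ("canal_C4",), "IS"),
    LandmarkDefinition("canal_C4_RL", ("canal_C4",), "RL"),
    LandmarkDefinition("hyoid_to_canal_IS", ("hyoid", "canal_C4"), "IS"),
]


@dataclass
class LandmarkReport:
    """Per-definition differences between two landmark sets, pooled over
    cases."""

    per_definition: dict[str, np.ndarray]  # name -> differences per case
    mean_sd: dict[str, tuple[float, float]]  # name -> (mean, sd) mm
    euclidean_offsets: dict[str, np.ndarray]  # label -> |pA - pB| per case


def _masked_derivative(f: np.ndarray, axis: int, h: float, mask: np.ndarray) -> np.ndarray:
    """Finite-difference df/dx_axis using only in-mask neighbours:
    central where both neighbours are in the mask, one-sided at mask
    borders, zero where the voxel has no in-mask neighbour along the
    axis."""
    fp = np.roll(f, -1, axis=axis)
    fm = np.roll(f, 1, axis=axis)
    mp = np.roll(mask, -1, axis=axis)
    mm = np.roll(mask, 1, axis=axis)
    # rolled-in wraparound values are never valid
    head = [slice(None)] * f.ndim
    head[axis] = slice(-1, None)
    mp[tuple(head)] = False
    tail = [slice(None)] * f.ndim
    tail[axis] = slice(0, 1)
    mm[tuple(tail)] = False

    d = np.zeros_like(f)
    both = mp & mm
    d[both] = (fp[both] - fm[both]) / (2.0 * h)
    fwd = mp & ~mm
    d[fwd] = (fp[fwd] - f[fwd]) / h
    bwd = mm & ~mp
    d[bwd] = (f[bwd] - fm[bwd]) / h
    return d


def jacobian_determinant(field: DisplacementField, mask: np.ndarray) -> JdReport:
    """JD of x -> x + u(x): det(I + grad u) by finite differences.

    Derivatives use the voxel spacing in mm and fall back to one-sided
    differences at mask borders, so the body surface does not produce
    spurious negative determinants from out-of-mask garbage.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match field grid {field.shape}"
        )
    if not mask.any():
        raise ValidationError("mask is empty")
    grad = np.zeros(field.shape + (3, 3), dtype=float)
    for comp in range(3):
        for axis in range(3):
            grad[..., comp, axis] = _masked_derivative(
                field.vectors[..., comp], axis, field.spacing[axis], mask
            )
    jac = grad + np.eye(3)
    jd = np.linalg.det(jac)
    jd_masked = jd[mask]
    jd_out = np.where(mask, jd, np.nan)
    frac = float(np.mean(jd_masked <= 0.0))
    return JdReport(
        jd_field=jd_out,
        min_jd=float(jd_masked.min()),
        max_jd=float(jd_masked.max()),
        fraction_nonpositive=frac,
        realistic=bool(frac == 0.0),
    )


def _measure(points: dict[str, np.ndarray], d: LandmarkDefinition) -> float:
    for label in d.labels:
        if label not in points:
            raise ValidationError(f"landmark label {label!r} missing from point set")
    if len(d.labels) == 2:
        pa, pb = points[d.labels[0]], points[d.labels[1]]
        if d.axis == "euclidean":
            return float(np.linalg.norm(np.asarray(pb) - np.asarray(pa)))
        return float(pb[_AXIS_INDEX[d.axis]] - pa[_AXIS_INDEX[d.axis]])
    p = np.asarray(points[d.labels[0]], dtype=float)
    if d.axis == "euclidean":
        raise ValidationError(
            f"definition {d.name!r}: single-label euclidean has no "
            "within-image measure"
        )
    return float(p[_AXIS_INDEX[d.axis]])


def landmark_offsets(
    points_a,
    points_b,
    definitions: Sequence[LandmarkDefinition] = tuple(DEFAULT_DEFINITIONS),
) -> LandmarkReport:
    """Differences of landmark measures between two images, A minus B.

    ``points_a``/``points_b`` are label -> (3,) mm dicts for one case,
    or lists of such dicts over cases; ``mean_sd`` pools over cases.
    Single-label "euclidean" definitions are evaluated as the
    between-image offset |pA - pB| (which is also reported for every
    label under ``euclidean_offsets``).
    """
    if isinstance(points_a, dict):
        points_a = [points_a]
        points_b = [points_b]
    if len(points_a) != len(points_b):
        raise ValidationError("point-set lists must have equal length")
    per_def: dict[str, list[float]] = {d.name: [] for d in definitions}
    labels = set()
    for pa in points_a:
        labels |= set(pa)
    eucl: dict[str, list[float]] = {lab: [] for lab in sorted(labels)}
    for pa, pb in zip(points_a, points_b):
        for lab in eucl:
            if lab not in pa or lab not in pb:
                raise ValidationError(f"landmark label {lab!r} missing from point set")
            eucl[lab].append(float(np.linalg.norm(np.asarray(pa[lab]) - np.asarray(pb[lab]))))
        for d in definitions:
            if len(d.labels) == 1 and d.axis == "euclidean":
                lab = d.labels[0]
                per_def[d.name].append(
                    float(np.linalg.norm(np.asarray(pa[lab]) - np.asarray(pb[lab])))
                )
            else:
                per_def[d.name].append(_measure(pa, d) - _measure(pb, d))
    per_def_arr = {k: np.asarray(v) for k, v in per_def.items()}
    mean_sd = {
        k: (float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0)
        for k, v in per_def_arr.items()
    }
    return LandmarkReport(
        per_definition=per_def_arr,
        mean_sd=mean_sd,
        euclidean_offsets={k: np.asarray(v) for k, v in eucl.items()},
    )


def landmark_reproducibility(
    repeats: Sequence, method: str = "centroid"
) -> tuple[float, float]:
    """Placement reproducibility of one repeatedly placed landmark.

    ``method="centroid"`` (default): Euclidean distance of every repeat
    to the centroid of all repeats, reported as (mean, max) in mm.
    ``method="pairwise"``: mean and max over all distinct pairwise
    distances instead.
    """
    pts = np.asarray([np.asarray(p, dtype=float) for p in repeats])
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValidationError("need at least 2 repeats of a 3D landmark")
    if method == "centroid":
        d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    elif method == "pairwise":
        iu = np.triu_indices(len(pts), k=1)
        d = np.linalg.norm(pts[iu[0]] - pts[iu[1]], axis=1)
    else:
        raise ValidationError(f"unknown reproducibility method {method!r}")
    return float(d.mean()), float(d.max())
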