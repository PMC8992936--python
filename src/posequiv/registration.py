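"""Rigid auto-registration with a mutual-information metric on bone.

The protocol mirrors clinical bone-based setup verification: the
reference image (CT or synthetic CT) is thresholded to the 200–1700 HU
bone window inside a volume of interest, and a downhill-simplex
(Nelder–Mead) search maximizes the mutual information between the
masked reference voxels and the moving image resampled under candidate
rigid transforms.  Volume-to-volume registration optimizes all six
degrees of freedom; DRR-to-orthogonal-projection registration optimizes
five (roll, the rotation about the inferior–superior axis, cannot be
corrected from 2D projections and is pinned at zero).

Everything here is deterministic: a fixed initial simplex, dense joint
histograms, trilinear resampling with out-of-grid samples excluded.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import binary_dilation, map_coordinates
from scipy.optimize import minimize

from .core import VolumeImage, Projection
from .errors import ValidationError
from .geometry import SixDoF, build_matrix, apply_to_points, restrict_to_5dof


@dataclass
class RegistrationConfig:
    """Protocol parameters for bone-based rigid registration.

    ``hu_lo``/``hu_hi`` define the bone threshold window (HU); ``voi``
    is an optional axis-aligned box ``(lo_xyz, hi_xyz)`` in mm limiting
    the mask to the clinically relevant bony anatomy.  The mask is
    dilated by ``mask_dilation_vox`` voxels before computing mutual
    information so that the bone/soft-tissue edges that actually drive
    the similarity metric are retained.
    """

    hu_lo: float = 200.0
    hu_hi: float = 1700.0
    voi: Optional[tuple] = None  # ((x0,y0,z0), (x1,y1,z1)) in mm
    n_bins: int = 64
    max_iter: int = 600
    xtol: float = 0.01  # mm / degrees
    ftol: float = 1e-6  # nats
    multires_levels: int = 1
    init: SixDoF = field(default_factory=SixDoF)
    mask_dilation_vox: int = 2
    rotation_center: Optional[tuple] = None  # defaults to reference grid centre
    simplex_step_mm: float = 2.0
    simplex_step_deg: float = 1.0

    def validate(self) -> None:
        if not self.hu_lo < self.hu_hi:
            raise ValidationError("require hu_lo < hu_hi")
        if self.n_bins < 8:
            raise ValidationError("n_bins must be >= 8")
        if self.xtol <= 0 or self.ftol <= 0:
            raise ValidationError("tolerances must be > 0")
        if self.multires_levels not in (1, 2):
            raise ValidationError("multires_levels must be 1 or 2")


@dataclass
class RegistrationResult:
    params: SixDoF
    final_metric: float  # mutual information, nats
    n_evaluations: int
    converged: bool


def bone_mask(vol: VolumeImage, cfg: RegistrationConfig) -> np.ndarray:
    """Boolean mask of voxels in the bone HU window, inside the VOI."""
    cfg.validate()
    mask = (vol.values >= cfg.hu_lo) & (vol.values <= cfg.hu_hi)
    if cfg.voi is not None:
        lo = np.asarray(cfg.voi[0], dtype=float)
        hi = np.asarray(cfg.voi[1], dtype=float)
        coords = [
            vol.origin[a] + np.arange(vol.shape[a]) * vol.spacing[a] for a in range(3)
        ]
        inside = (
            ((coords[0] >= lo[0]) & (coords[0] <= hi[0]))[:, None, None]
            & ((coords[1] >= lo[1]) & (coords[1] <= hi[1]))[None, :, None]
            & ((coords[2] >= lo[2]) & (coords[2] <= hi[2]))[None, None, :]
        )
        mask &= inside
    if not mask.any():
        raise ValidationError(
            f"bone mask empty: no voxels in [{cfg.hu_lo}, {cfg.hu_hi}] HU "
            "within the volume of interest"
        )
    return mask


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def mutual_information(a, b, mask=None, n_bins: int = 64) -> float:
    """MI in nats from a dense joint histogram: H(A) + H(B) - H(A,B).

    ``a`` and ``b`` are arrays on the same grid (or flat sample
    vectors); ``mask`` restricts the evaluation.  A constant image under
    the mask carries no information: MI is 0 and a warning is emitted.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValidationError("images must share a grid for mutual information")
    if mask is not None:
        av = av[mask]
        bv = bv[mask]
    av = av.ravel()
    bv = bv.ravel()
    if av.size == 0:
        raise ValidationError("empty sample for mutual information")
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        warnings.warn("constant image under mask: mutual information is 0")
        return 0.0
    joint, _, _ = np.histogram2d(av, bv, bins=n_bins)
    p = joint / joint.sum()
    mi = _entropy(p.sum(axis=1)) + _entropy(p.sum(axis=0)) - _entropy(p.ravel())
    return max(mi, 0.0)


def _bin_index(vals: np.ndarray, edges: np.ndarray) -> np.ndarray:
    n = len(edges) - 1
    return np.clip(np.digitize(vals, edges) - 1, 0, n - 1)


def _mi_soft(ref_idx, mov_vals, mov_lo, mov_width, n_bins) -> float:
    """MI with hard-binned reference and partial-volume (linearly
    soft-binned) moving samples.

    Hard binning of the resampled moving intensities makes the metric
    piecewise constant over sub-bin transform changes, stalling the
    simplex on plateaus; distributing each sample linearly over its two
    neighbouring bins restores a smooth response.  NaN samples (outside
    the moving grid) are excluded.
    """
    ok = np.isfinite(mov_vals)
    if ok.sum() < 2:
        return 0.0
    ri = ref_idx[ok]
    u = np.clip((mov_vals[ok] - mov_lo) / mov_width, 0.0, n_bins - 1 - 1e-9)
    i0 = u.astype(np.intp)
    frac = u - i0
    flat_lo = ri * n_bins + i0
    joint = np.bincount(flat_lo, weights=1.0 - frac, minlength=n_bins * n_bins)
    joint += np.bincount(
        np.minimum(flat_lo + 1, n_bins * n_bins - 1), weights=frac,
        minlength=n_bins * n_bins,
    )
    p = (joint / joint.sum()).reshape(n_bins, n_bins)
    return max(
        _entropy(p.sum(axis=1)) + _entropy(p.sum(axis=0)) - _entropy(p.ravel()), 0.0
    )


def _sample_volume(vol: VolumeImage, pts_world: np.ndarray) -> np.ndarray:
    """Trilinear samples at world points; NaN outside the grid."""
    idx = vol.world_to_index(pts_world).T
    return map_coordinates(
        vol.values.astype(float), idx, order=1, mode="constant", cval=np.nan
    )


def transform_volume(vol: VolumeImage, p: SixDoF, center=None) -> VolumeImage:
    """Resample ``vol`` so its content is moved by the rigid transform
    ``p`` (about ``center``): the returned image at x equals
    ``vol(M^{-1} x)``."""
    if center is None:
        center = vol.center
    m = build_matrix(p, center)
    from .geometry import invert

    minv = invert(m)
    pts = vol.voxel_centers()
    vals = _sample_volume(vol, apply_to_points(minv, pts))
    out = vals.reshape(vol.shape)
    out = np.where(np.isfinite(out), out, np.nanmin(vol.values))
    return vol.like(out)


def _downsample(vol: VolumeImage) -> VolumeImage:
    return VolumeImage(
        vol.values[::2, ::2, ::2],
        tuple(2 * s for s in vol.spacing),
        vol.origin,
    )


def _fixed_bin_edges(vals: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(np.min(vals)), float(np.max(vals))
    if hi <= lo:
        hi = lo + 1.0
    return np.linspace(lo, hi, n_bins + 1)


def _simplex(x0: np.ndarray, steps: np.ndarray) -> np.ndarray:
    sim = np.tile(x0, (len(x0) + 1, 1))
    for i in range(len(x0)):
        sim[i + 1, i] += steps[i]
    return sim


def _optimize(cost, x0, steps, cfg: RegistrationConfig):
    """Deterministic Nelder–Mead with one restart from the incumbent."""
    nfev = 0
    converged = True
    x = np.asarray(x0, dtype=float)
    for attempt, scale in enumerate((1.0, 0.5)):
        res = minimize(
            cost,
            x,
            method="Nelder-Mead",
            options={
                "initial_simplex": _simplex(x, steps * scale),
                "xatol": cfg.xtol,
                "fatol": cfg.ftol,
                "maxiter": cfg.max_iter,
                "maxfev": 4 * cfg.max_iter,
            },
        )
        nfev += res.nfev
        x = res.x
        converged = bool(res.success)
    return x, nfev, converged


def register_rigid_3d(
    moving: VolumeImage, reference: VolumeImage, cfg: Optional[RegistrationConfig] = None
) -> RegistrationResult:
    """6-DoF rigid registration of ``moving`` onto ``reference``.

    Maximizes MI between reference voxels in the (dilated) bone mask and
    the moving image sampled at those positions mapped through the
    candidate transform.  The returned parameters are the transform
    that, applied to the reference grid, aligns the moving content with
    the reference — i.e. they recover the displacement applied to a
    moved copy of the reference.
    """
    cfg = cfg or RegistrationConfig()
    cfg.validate()
    center = (
        np.asarray(cfg.rotation_center, dtype=float)
        if cfg.rotation_center is not None
        else reference.center
    )

    levels = [(reference, moving)]
    if cfg.multires_levels == 2:
        levels.insert(0, (_downsample(reference), _downsample(moving)))

    x = cfg.init.as_array()
    steps = np.array(
        [cfg.simplex_step_mm] * 3 + [cfg.simplex_step_deg] * 3, dtype=float
    )
    nfev_total = 0
    converged = True
    final_metric = 0.0
    for ref, mov in levels:
        mask = bone_mask(ref, cfg)
        if cfg.mask_dilation_vox > 0:
            mask = binary_dilation(mask, iterations=cfg.mask_dilation_vox)
        ref_vals = ref.values[mask].astype(float)
        pts = ref.voxel_centers(mask)
        ref_idx = _bin_index(ref_vals, _fixed_bin_edges(ref_vals, cfg.n_bins))
        mov_lo = float(np.min(mov.values))
        mov_width = (float(np.max(mov.values)) - mov_lo) / cfg.n_bins or 1.0

        def cost(params):
            m = build_matrix(SixDoF.from_array(params), center)
            mov_vals = _sample_volume(mov, apply_to_points(m, pts))
            return -_mi_soft(ref_idx, mov_vals, mov_lo, mov_width, cfg.n_bins)

        x, nfev, conv = _optimize(cost, x, steps, cfg)
        nfev_total += nfev
        converged = converged and conv
        final_metric = -cost(x)

    return RegistrationResult(
        params=SixDoF.from_array(x),
        final_metric=final_metric,
        n_evaluations=nfev_total,
        converged=converged,
    )


# --------------------------------------------------------------------------
# parallel-ray projections (DRR stand-ins) and 2D registration


def project_drr(vol: VolumeImage, direction: str = "frontal") -> Projection:
    """Parallel-ray attenuation-sum projection of an HU volume.

    Attenuation is taken proportional to HU + 1000 (clipped at 0, so air
    contributes nothing) and summed along the ray axis weighted by the
    voxel size: frontal rays run along P-A (image axes x, z), lateral
    rays along R-L (image axes y, z).
    """
    mu = np.clip(vol.values.astype(float) + 1000.0, 0.0, None) / 1000.0
    if direction == "frontal":
        img = mu.sum(axis=1) * vol.spacing[1]
        spacing = (vol.spacing[0], vol.spacing[2])
        origin = (vol.origin[0], vol.origin[2])
    elif direction == "lateral":
        img = mu.sum(axis=0) * vol.spacing[0]
        spacing = (vol.spacing[1], vol.spacing[2])
        origin = (vol.origin[1], vol.origin[2])
    else:
        raise ValidationError(f"unknown projection direction {direction!r}")
    return Projection(img, spacing, origin, direction)


def register_rigid_2d(
    moving_vol: VolumeImage,
    proj_pair: tuple[Projection, Projection],
    cfg: Optional[RegistrationConfig] = None,
) -> RegistrationResult:
    """5-DoF registration of a volume to orthogonal 2D projections.

    The five free parameters (three translations, pitch, yaw) move the
    volume, which is re-projected frontally and laterally; the cost is
    the summed MI against the two acquired projections.  Roll is frozen
    at exactly 0 in the result.
    """
    cfg = cfg or RegistrationConfig()
    cfg.validate()
    projs = {p.direction: p for p in proj_pair}
    if set(projs) != {"frontal", "lateral"}:
        raise ValidationError("need one frontal and one lateral projection")
    center = (
        np.asarray(cfg.rotation_center, dtype=float)
        if cfg.rotation_center is not None
        else moving_vol.center
    )
    ref_idx = {}
    drr_range = {}
    for d in projs:
        edges = _fixed_bin_edges(projs[d].values.ravel(), cfg.n_bins)
        ref_idx[d] = _bin_index(projs[d].values.ravel(), edges)
        lo, hi = float(edges[0]), float(edges[-1])
        drr_range[d] = (lo, (hi - lo) / cfg.n_bins or 1.0)

    def cost(params5):
        p = SixDoF(params5[0], params5[1], params5[2], params5[3], params5[4], 0.0)
        moved = transform_volume(moving_vol, p, center)
        total = 0.0
        for d in ("frontal", "lateral"):
            drr = project_drr(moved, d)
            lo, width = drr_range[d]
            total += _mi_soft(ref_idx[d], drr.values.ravel(), lo, width, cfg.n_bins)
        return -total

    x0 = cfg.init.as_array()[:5]
    steps = np.array(
        [cfg.simplex_step_mm] * 3 + [cfg.simplex_step_deg] * 2, dtype=float
    )
    x, nfev, converged = _optimize(cost, x0, steps, cfg)
    params = SixDoF(x[0], x[1], x[2], x[3], x[4], 0.0)
    return RegistrationResult(
        params=restrict_to_5dof(params),
        final_metric=-cost(x),
        n_evaluations=nfev,
        converged=converged,
    )
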