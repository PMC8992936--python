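"""PTV point-distance metric, rasterization, Dice overlap and observer
pooling."""
import math

import numpy as np
import pytest

from posequiv import (
    SixDoF,
    StructureSet,
    build_matrix,
    compose,
    dice,
    make_ptv,
    observer_summary,
    paired_ptv_distances,
    rasterize_structure,
)
from posequiv.structure_metrics import registered_overlap
from posequiv.errors import ValidationError

ISO = (0.0, 0.0, 0.0)


class TestPairedPtvDistances:
    def test_equal_matrices_give_zero_spike(self, sphere_ptv):
        m = build_matrix(SixDoF(1.0, -2.0, 3.0, 1.0, 0.5, -0.5), ISO)
        rep = paired_ptv_distances(sphere_ptv, m, m)
        assert np.all(rep.per_point_distances == 0)
        assert rep.histogram_counts[0] == sphere_ptv.n_points

    def test_pure_relative_translation_is_exact_spike(self, sphere_ptv):
        # relative translation (1, 2, 2) mm: every distance exactly 3 mm
        ma = build_matrix(SixDoF(), ISO)
        mb = build_matrix(SixDoF(1.0, 2.0, 2.0), ISO)
        rep = paired_ptv_distances(sphere_ptv, ma, mb)
        np.testing.assert_allclose(rep.per_point_distances, 3.0, atol=1e-12)
        # histogram is a spike at 3 mm (at most two adjacent bins when the
        # value sits on a bin edge to rounding)
        occupied = np.nonzero(rep.histogram_counts)[0]
        assert len(occupied) <= 2 and np.all(np.diff(occupied) == 1)
        assert rep.histogram_edges[occupied[0]] <= 3.0 <= rep.histogram_edges[occupied[-1] + 1]
        assert rep.histogram_counts.sum() == sphere_ptv.n_points

    def test_pure_rotation_matches_chord_length(self, sphere_ptv):
        delta = 3.0  # degrees about the I-S axis through the isocenter
        ma = build_matrix(SixDoF(), ISO)
        mb = build_matrix(SixDoF(roll=delta), ISO)
        rep = paired_ptv_distances(sphere_ptv, ma, mb)
        pts = sphere_ptv.all_points()
        r = np.linalg.norm(pts[:, :2], axis=1)  # radius from the z rotation axis
        expected = 2.0 * r * math.sin(math.radians(delta) / 2.0)
        np.testing.assert_allclose(rep.per_point_distances, expected, atol=1e-9)

    def test_invariant_under_common_extra_transform(self, sphere_ptv):
        ma = build_matrix(SixDoF(0.5, -0.3, 0.2, 0.4, -0.2, 0.6), ISO)
        mb = build_matrix(SixDoF(-0.4, 0.8, -0.6, -0.3, 0.5, -0.2), ISO)
        extra = build_matrix(SixDoF(5.0, -7.0, 2.0, 4.0, 3.0, -6.0), (10.0, 0.0, -20.0))
        base = paired_ptv_distances(sphere_ptv, ma, mb)
        moved = paired_ptv_distances(
            sphere_ptv, compose(extra, ma), compose(extra, mb)
        )
        np.testing.assert_allclose(
            moved.per_point_distances, base.per_point_distances, atol=1e-9
        )

    def test_max_at_point_furthest_from_rotation_axis(self, sphere_ptv):
        ma = build_matrix(SixDoF(), ISO)
        mb = build_matrix(SixDoF(1.0, 0.5, -0.5, 1.5, -1.0, 2.0), ISO)
        rep = paired_ptv_distances(sphere_ptv, ma, mb)
        # brute force with plain numpy, independent of apply_to_points
        pts = sphere_ptv.all_points()
        A, B = ma.matrix, mb.matrix
        hom = np.hstack([pts, np.ones((len(pts), 1))])
        brute = np.linalg.norm((hom @ A.T - hom @ B.T)[:, :3], axis=1)
        assert rep.max == pytest.approx(brute.max(), abs=1e-12)
        assert np.argmax(rep.per_point_distances) == np.argmax(brute)

    def test_empty_structure_rejected(self):
        empty = StructureSet("PTV", [])
        m = build_matrix(SixDoF(), ISO)
        with pytest.raises(ValidationError):
            paired_ptv_distances(empty, m, m)


class TestRasterizeStructure:
    def test_ellipsoid_volume_within_5_percent(self):
        s = make_ptv(center=(0, 0, 0), semi_axes=(20, 25, 15), n_slices=15)
        mask = rasterize_structure(s, grid_spacing_mm=1.0)
        vol = mask.values.sum() * 1.0
        analytic = 4.0 / 3.0 * math.pi * 20 * 25 * 15
        assert abs(vol / analytic - 1.0) < 0.05

    def test_empty_structure_rejected(self):
        with pytest.raises(ValidationError):
            rasterize_structure(StructureSet("x", []))

    def test_shift_by_one_grid_step_shifts_mask(self):
        s = make_ptv(center=(0, 0, 0), semi_axes=(12, 12, 12), n_slices=8)
        shifted = StructureSet("x", [c + [2.0, 0.0, 0.0] for c in s.contours])
        bounds = ((-20.0, -20.0, -20.0), (22.0, 20.0, 20.0))
        a = rasterize_structure(s, 2.0, bounds)
        b = rasterize_structure(shifted, 2.0, bounds)
        np.testing.assert_array_equal(
            b.values[1:, :, :], a.values[:-1, :, :]
        )

    def test_self_intersecting_contour_rejected(self):
        bowtie = np.array(
            [[0, 0, 0], [10, 10, 0], [10, 0, 0], [0, 10, 0]], dtype=float
        )
        with pytest.raises(ValidationError, match="self-intersect"):
            rasterize_structure(StructureSet("x", [bowtie, bowtie + [0, 0, 5]]))


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((10, 10, 10), bool)
        m[2:8, 2:8, 2:8] = True
        assert dice(m, m).dsc == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[:3], b[7:] = True, True
        assert dice(a, b).dsc == 0.0

    def test_half_overlapping_cubes(self):
        # unit cubes of 4^3 voxels overlapping in half their volume
        a = np.zeros((12, 8, 8), bool)
        b = np.zeros((12, 8, 8), bool)
        a[0:4, 0:4, 0:4] = True
        b[2:6, 0:4, 0:4] = True
        rep = dice(a, b)
        assert rep.dsc == pytest.approx(0.5)
        assert rep.count_intersection == 32

    def test_symmetry_and_empty_rejection(self, rng):
        a = rng.uniform(size=(8, 8, 8)) > 0.5
        b = rng.uniform(size=(8, 8, 8)) > 0.5
        assert dice(a, b).dsc == dice(b, a).dsc
        with pytest.raises(ValidationError):
            dice(np.zeros((4, 4, 4), bool), np.zeros((4, 4, 4), bool))

    def test_dsc_decreases_with_separation(self):
        s = make_ptv(center=(0, 0, 0), semi_axes=(15, 15, 15), n_slices=10)
        iso = ISO
        last = 1.01
        for shift in (0.0, 2.0, 5.0, 10.0):
            ma = build_matrix(SixDoF(), iso)
            mb = build_matrix(SixDoF(tx=shift), iso)
            d = registered_overlap(s, ma, mb, 1.5).dsc
            assert d < last + 1e-9
            last = d


class TestObserverSummary:
    def _report(self, distances):
        from posequiv.structure_metrics import DistanceReport

        d = np.asarray(distances, dtype=float)
        return DistanceReport(
            per_point_distances=d,
            mean=float(d.mean()),
            sd=float(d.std(ddof=1)) if d.size > 1 else 0.0,
            max=float(d.max()),
            histogram_edges=np.array([0.0, 1.0]),
            histogram_counts=np.array([d.size]),
        )

    def test_single_observer(self):
        s = observer_summary([self._report([1.0, 2.0, 3.0])])
        assert s.mean_of_observer_means == pytest.approx(2.0)
        assert s.sd_of_observer_means == 0.0

    def test_constant_distances(self):
        reps = [self._report([4.0] * 10) for _ in range(3)]
        s = observer_summary(reps)
        assert s.mean_of_observer_means == pytest.approx(4.0)
        assert s.max_distance == pytest.approx(4.0)

    def test_six_observers_match_recomputation(self, rng):
        samples = [rng.uniform(0, 5, size=30) for _ in range(6)]
        s = observer_summary([self._report(x) for x in samples])
        means = np.array([x.mean() for x in samples])
        assert s.mean_of_observer_means == pytest.approx(means.mean())
        assert s.sd_of_observer_means == pytest.approx(means.std(ddof=1))
        worst = int(np.argmax(means))
        assert s.worst_observer == worst
        assert s.worst_observer_mean == pytest.approx(means[worst])
        assert s.max_distance == pytest.approx(max(x.max() for x in samples))


def test_setup_scale_differences_give_low_millimetre_distances(sphere_ptv):
    """Order-of-magnitude check: ~2 mm / ~1.5 degree relative parameter
    differences on a PTV whose points lie 30-80 mm from the isocenter
    produce mean point distances of a few millimetres."""
    iso = (0.0, 0.0, 20.0)  # puts the PTV points ~30-80 mm from the isocenter
    pts = sphere_ptv.all_points()
    radii = np.linalg.norm(pts - iso, axis=1)
    assert radii.min() > 30 and radii.max() < 80
    ma = build_matrix(SixDoF(), iso)
    mb = build_matrix(SixDoF(0.0, 2.4, 1.9, 1.7, 0.9, 0.0), iso)
    rep = paired_ptv_distances(sphere_ptv, ma, mb)
    assert 1.0 < rep.mean < 10.0
    assert rep.max < 15.0
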