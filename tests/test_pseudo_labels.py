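import warnings

import numpy as np
import pytest

from sacseg.imageio_points import UNLABELED, PointSet
from sacseg.pseudo_labels import (color_normalize, make_superpixel_label,
                                  make_voronoi_label, perturb_points,
                                  voronoi_partition)


def brute_force_nearest(points: PointSet, shape):
    """O(H*W*n) oracle: per-pixel scan over all points, ties to lowest index."""
    H, W = shape
    pts = points.as_array()
    out = np.empty((H, W), dtype=np.int64)
    for r in range(H):
        for c in range(W):
            best, best_d = 0, None
            for k, (pr, pc) in enumerate(pts):
                d = (r - pr) ** 2 + (c - pc) ** 2
                if best_d is None or d < best_d:
                    best, best_d = k, d
            out[r, c] = best
    return out


class TestVoronoiPartition:
    def test_single_point_owns_everything(self):
        pts = PointSet(((13, 7),), (32, 32))
        assert (voronoi_partition(pts, (32, 32)) == 0).all()

    def test_two_points_on_a_row_split_at_midpoint(self):
        pts = PointSet(((0, 0), (0, 31)), (1, 32))
        cell = voronoi_partition(pts, (1, 32))
        assert (cell[0, :16] == 0).all()
        assert (cell[0, 16:] == 1).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        coords = set()
        while len(coords) < n:
            coords.add((int(rng.integers(0, 64)), int(rng.integers(0, 64))))
        pts = PointSet(tuple(sorted(coords)), (64, 64))
        assert np.array_equal(voronoi_partition(pts, (64, 64)),
                              brute_force_nearest(pts, (64, 64)))

    def test_empty_pointset_is_an_error(self):
        with pytest.raises(ValueError):
            voronoi_partition(PointSet((), (8, 8)), (8, 8))

    def test_each_cell_contains_exactly_one_point(self):
        rng = np.random.default_rng(7)
        coords = {(int(rng.integers(0, 48)), int(rng.integers(0, 48)))
                  for _ in range(12)}
        pts = PointSet(tuple(sorted(coords)), (48, 48))
        cell = voronoi_partition(pts, (48, 48))
        for k, (r, c) in enumerate(pts.coords):
            assert cell[r, c] == k
        assert len(np.unique(cell)) == len(pts)


class TestVoronoiLabel:
    def test_single_point_disc_no_negatives(self):
        pts = PointSet(((16, 16),), (32, 32))
        v = make_voronoi_label(pts, (32, 32), r_pt=2, ridge_width=1)
        vals = v.label.values
        assert (vals == 0).sum() == 0
        assert (vals == 1).sum() > 0
        rr, cc = np.nonzero(vals == 1)
        assert np.all((rr - 16) ** 2 + (cc - 16) ** 2 <= 4.0 + 1e-9)

    def test_negatives_exactly_at_cell_boundary(self):
        pts = PointSet(((0, 0), (0, 31)), (1, 32))
        v = make_voronoi_label(pts, (1, 32), r_pt=2, ridge_width=1)
        neg_cols = set(np.nonzero(v.label.values[0] == 0)[0].tolist())
        # oracle: columns whose 1-neighbourhood spans both cells
        cell = voronoi_partition(pts, (1, 32))[0]
        expect = {c for c in range(32)
                  if len({cell[max(0, c - 1)], cell[c],
                          cell[min(31, c + 1)]}) > 1}
        expect -= set(np.nonzero(v.label.values[0] == 1)[0].tolist())
        assert neg_cols == expect

    def test_r_pt_zero_marks_exactly_the_points(self):
        pts = PointSet(((3, 3), (20, 25), (9, 14)), (32, 32))
        v = make_voronoi_label(pts, (32, 32), r_pt=0, ridge_width=1)
        assert (v.label.values == 1).sum() == 3

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            make_voronoi_label(PointSet(((1, 1),), (8, 8)), (8, 8), r_pt=-1)

    def test_tristate_partition_is_exhaustive(self, small_scene):
        v = make_voronoi_label(small_scene.points, small_scene.gt_mask.shape)
        vals = v.label.values
        assert set(np.unique(vals)) <= {0, 1, UNLABELED}
        pos, neg = vals == 1, vals == 0
        assert not np.any(pos & neg)


class TestSuperpixelLabel:
    def test_zero_points_warns_and_returns_background(self, small_scene):
        empty = PointSet((), small_scene.points.image_shape)
        with pytest.warns(UserWarning):
            s = make_superpixel_label(small_scene.image, empty)
        assert (s.label.values == 0).all()

    def test_foreground_ids_equal_pointed_superpixels(self, small_scene):
        s = make_superpixel_label(small_scene.image, small_scene.points)
        pts = small_scene.points.as_array()
        expect = set(np.unique(s.sp_index[pts[:, 0], pts[:, 1]]).tolist())
        got = set(np.unique(s.sp_index[s.label.values == 1]).tolist())
        assert got == expect

    def test_every_point_is_foreground(self, small_scene):
        s = make_superpixel_label(small_scene.image, small_scene.points)
        for r, c in small_scene.points.coords:
            assert s.label.values[r, c] == 1

    def test_invariant_under_point_permutation(self, small_scene):
        pts = small_scene.points
        rev = PointSet(tuple(reversed(pts.coords)), pts.image_shape)
        a = make_superpixel_label(small_scene.image, pts)
        b = make_superpixel_label(small_scene.image, rev)
        assert np.array_equal(a.label.values, b.label.values)


class TestPerturbPoints:
    def test_zero_radius_is_identity(self):
        pts = PointSet(((5, 5), (20, 30)), (64, 64))
        assert perturb_points(pts, 0, seed=1) is pts

    @pytest.mark.parametrize("r", [3, 5])
    def test_displacement_norm_within_half_pixel(self, r):
        H = W = 200
        rng = np.random.default_rng(0)
        count = 0
        for seed in range(25):
            coords = set()
            while len(coords) < 40:
                coords.add((int(rng.integers(50, 150)),
                            int(rng.integers(50, 150))))
            pts = PointSet(tuple(sorted(coords)), (H, W))
            out = perturb_points(pts, r, seed=seed)
            for (r0, c0), (r1, c1) in zip(pts.coords, out.coords):
                norm = np.hypot(r1 - r0, c1 - c0)
                assert r - 0.5 <= norm <= r + 0.5
                count += 1
        assert count >= 1000

    def test_deterministic_per_seed(self):
        pts = PointSet(((5, 5), (20, 30), (40, 40)), (64, 64))
        assert perturb_points(pts, 3, seed=9).coords == \
            perturb_points(pts, 3, seed=9).coords

    def test_range_mode_draws_radius_between_3_and_5(self):
        pts = PointSet(tuple((10 + 7 * i, 10 + 5 * i) for i in range(10)),
                       (128, 128))
        out = perturb_points(pts, 3, seed=2, mode="range")
        for (r0, c0), (r1, c1) in zip(pts.coords, out.coords):
            assert 2.5 <= np.hypot(r1 - r0, c1 - c0) <= 5.5


class TestColorNormalize:
    def test_self_reference_is_near_fixed_point(self, small_scene):
        out = color_normalize(small_scene.image, small_scene.image)
        diff = out.astype(float).mean(axis=(0, 1)) - \
            small_scene.image.astype(float).mean(axis=(0, 1))
        assert np.all(np.abs(diff) <= 1.0)

    def test_lab_means_match_reference(self, small_scene):
        from skimage.color import rgb2lab
        other = np.roll(small_scene.image, 7, axis=0)[:, ::-1]
        ref = (small_scene.image.astype(np.int64) * 2 // 3).astype(np.uint8)
        out = color_normalize(other, ref)
        lab_out = rgb2lab(out / 255.0).reshape(-1, 3).mean(axis=0)
        lab_ref = rgb2lab(ref / 255.0).reshape(-1, 3).mean(axis=0)
        assert np.all(np.abs(lab_out - lab_ref) <= 0.5)

    def test_constant_image_warns_and_passes_through(self):
        const = np.full((16, 16, 3), 90, np.uint8)
        ref = np.zeros((8, 8, 3), np.uint8)
        with pytest.warns(UserWarning):
            out = color_normalize(const, ref)
        assert np.array_equal(out, const)
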