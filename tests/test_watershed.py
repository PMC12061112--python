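"""Watershed stage: each operation against independent brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from wbcseg import watershed as W
from wbcseg.watershed import DegenerateInputError, MarkerSet


def brute_sobel(gray):
    """Naive per-pixel 3x3 window Sobel magnitude with reflected borders."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)
    ky = kx.T
    pad = np.pad(gray, 1, mode="symmetric")  # edge-repeating reflection
    out = np.zeros_like(gray, dtype=float)
    for i in range(gray.shape[0]):
        for j in range(gray.shape[1]):
            win = pad[i:i + 3, j:j + 3]
            # scipy convolution flips the kernel; do the same here
            gx = (win * kx[::-1, ::-1]).sum()
            gy = (win * ky[::-1, ::-1]).sum()
            out[i, j] = np.hypot(gx, gy)
    return out


def plateau_extrema(field, minima=False):
    """Flood-fill connected equal-value plateaus; keep strict extrema (8-conn)."""
    field = np.asarray(field, dtype=float)
    h, w = field.shape
    seen = np.zeros((h, w), dtype=bool)
    mask = np.zeros((h, w), dtype=bool)
    for si in range(h):
        for sj in range(w):
            if seen[si, sj]:
                continue
            val = field[si, sj]
            stack = [(si, sj)]
            plateau = []
            is_extreme = True
            seen[si, sj] = True
            while stack:
                i, j = stack.pop()
                plateau.append((i, j))
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = i + di, j + dj
                        if not (0 <= ni < h and 0 <= nj < w):
                            continue
                        if field[ni, nj] == val:
                            if not seen[ni, nj]:
                                seen[ni, nj] = True
                                stack.append((ni, nj))
                        elif (field[ni, nj] < val) == minima:
                            is_extreme = False
            if is_extreme:
                for i, j in plateau:
                    mask[i, j] = True
    return mask


def two_disc_map(size=128, centers=((64, 49), (64, 79)), radius=20, blur=1.0):
    yy, xx = np.mgrid[0:size, 0:size]
    mask = np.zeros((size, size), dtype=bool)
    for cy, cx in centers:
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
    return np.clip(ndi.gaussian_filter(mask.astype(float), blur), 0, 1)


class TestSobelGradient:
    def test_constant_field_zero(self):
        np.testing.assert_array_equal(W.sobel_gradient(np.full((16, 16), 3.0)),
                                      0.0)

    def test_vertical_step_edge(self):
        field = np.zeros((16, 16))
        field[:, 8:] = 1.0
        g = W.sobel_gradient(field)
        assert g[:, 7:9].min() > 0
        assert np.all(g[:, :5] == 0) and np.all(g[:, 12:] == 0)

    def test_matches_brute_force_window_oracle(self, rng):
        field = rng.random((16, 16))
        np.testing.assert_allclose(W.sobel_gradient(field),
                                   brute_sobel(field), atol=1e-10)

    def test_multichannel_rejected(self, rng):
        with pytest.raises(ValueError):
            W.sobel_gradient(rng.random((8, 8, 3)))


class TestReconstructOpenClose:
    def test_constant_unchanged(self):
        field = np.full((32, 32), 7.0)
        np.testing.assert_allclose(W.reconstruct_open_close(field, 3), field)

    def test_single_bright_pixel_removed(self):
        field = np.zeros((32, 32))
        field[16, 16] = 1.0
        out = W.reconstruct_open_close(field, 3)
        assert out.max() == 0.0

    def test_large_disc_preserved(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disc = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 100).astype(float)
        out = W.reconstruct_open_close(disc, 3)
        assert (out > 0.5).sum() >= 0.95 * disc.sum()

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            W.reconstruct_open_close(np.zeros((8, 8)), 0)


class TestForegroundMarkers:
    def test_single_gaussian_blob_one_marker(self):
        yy, xx = np.mgrid[0:64, 0:64]
        blob = np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / 100.0)
        labels = W.foreground_markers(blob, min_marker_area=1)
        assert labels.max() == 1

    def test_two_separated_blobs_two_markers(self):
        yy, xx = np.mgrid[0:64, 0:64]
        blob = (np.exp(-((yy - 16) ** 2 + (xx - 16) ** 2) / 50.0)
                + np.exp(-((yy - 48) ** 2 + (xx - 48) ** 2) / 50.0))
        labels = W.foreground_markers(blob, min_marker_area=1)
        assert labels.max() == 2

    def test_matches_plateau_oracle(self, rng):
        field = ndi.gaussian_filter(rng.random((32, 32)), 2.0)
        labels = W.foreground_markers(field, min_marker_area=1)
        oracle = plateau_extrema(field)
        np.testing.assert_array_equal(labels > 0, oracle)
        _, n = ndi.label(oracle, structure=np.ones((3, 3)))
        assert labels.max() == n


class TestBackgroundMarkers:
    def test_two_discs_ridge_is_equidistant(self):
        # separated discs: the background ridge runs midway between them
        prob = two_disc_map(centers=((64, 35), (64, 93)))
        ridge = W.background_markers(prob, 0.5)
        yy, xx = np.mgrid[0:128, 0:128]
        d1 = np.hypot(yy - 64, xx - 35)[ridge]
        d2 = np.hypot(yy - 64, xx - 93)[ridge]
        between = (np.abs(yy[ridge] - 64) < 15)
        assert between.any()
        assert np.all(np.abs(d1[between] - d2[between]) <= 3.0)

    def test_single_disc_no_ridge_inside(self):
        prob = two_disc_map(centers=((64, 64),))
        ridge = W.background_markers(prob, 0.5)
        binary = prob > 0.5
        assert not np.any(ridge & binary)

    def test_empty_field_empty_ridge(self):
        ridge = W.background_markers(np.zeros((32, 32)), 0.5)
        assert ridge.sum() == 0

    def test_constant_field_has_empty_ridge(self):
        # range-relative binarization maps a constant field to background
        ridge = W.background_markers(np.ones((16, 16)), 0.5)
        assert ridge.sum() == 0


class TestImposeMinima:
    def _random_markers(self, shape, rng):
        fg = np.zeros(shape, dtype=int)
        for k in range(1, 4):
            i, j = rng.integers(2, shape[0] - 2, size=2)
            fg[i, j] = k
        bg = np.zeros(shape, dtype=bool)
        bg[0, :] = True
        bg &= fg == 0
        return MarkerSet(foreground=fg, background=bg)

    def test_regional_minima_equal_marker_set(self, rng):
        """The defining postcondition, against the plateau-minima oracle."""
        for _ in range(5):
            grad = ndi.gaussian_filter(rng.random((24, 24)), 1.0)
            markers = self._random_markers(grad.shape, rng)
            out = W.impose_minima(grad, markers)
            minima = plateau_extrema(out, minima=True)
            expected = (markers.foreground > 0) | markers.background
            np.testing.assert_array_equal(minima, expected)

    def test_idempotent_ordering(self, rng):
        grad = ndi.gaussian_filter(rng.random((24, 24)), 1.0)
        markers = self._random_markers(grad.shape, rng)
        once = W.impose_minima(grad, markers)
        twice = W.impose_minima(once, markers)
        minima = plateau_extrema(twice, minima=True)
        expected = (markers.foreground > 0) | markers.background
        np.testing.assert_array_equal(minima, expected)

    def test_empty_marker_set_rejected(self):
        empty = MarkerSet(foreground=np.zeros((8, 8), dtype=int),
                          background=np.zeros((8, 8), dtype=bool))
        with pytest.raises(DegenerateInputError):
            W.impose_minima(np.zeros((8, 8)), empty)

    def test_overlapping_markers_rejected(self):
        fg = np.zeros((8, 8), dtype=int); fg[2, 2] = 1
        bg = np.zeros((8, 8), dtype=bool); bg[2, 2] = True
        with pytest.raises(ValueError):
            MarkerSet(foreground=fg, background=bg)


class TestWatershedSegment:
    def test_one_marker_one_instance(self):
        prob = two_disc_map(centers=((64, 64),))
        labels = W.separate_cells(prob)
        assert labels.max() == 1

    def test_k_markers_k_instances(self):
        prob = two_disc_map(centers=((30, 30), (30, 90), (90, 30), (90, 90)),
                            radius=15)
        labels = W.separate_cells(prob)
        assert labels.max() == 4

    def test_no_markers_degenerate(self):
        empty = MarkerSet(foreground=np.zeros((8, 8), dtype=int),
                          background=np.zeros((8, 8), dtype=bool))
        with pytest.raises(DegenerateInputError):
            W.watershed_segment(np.zeros((8, 8)), empty)


class TestSeparateCells:
    def test_two_overlapping_discs_split_near_bisector(self):
        """Centers 30 px apart, radius 20: the split line is the bisector."""
        labels = W.separate_cells(two_disc_map())
        assert labels.max() == 2
        l1, l2 = labels == 1, labels == 2
        touching = (ndi.binary_dilation(l1) & l2) | (ndi.binary_dilation(l2) & l1)
        cols = np.nonzero(touching)[1]
        assert np.all(np.abs(cols - 64.0) <= 2.0)

    def test_isolated_cell_covered(self, small_scenes):
        from wbcseg import synthetic
        import dataclasses
        spec = synthetic.SceneSpec(n_wbc=1, cluster_prob=0.0, seed=11)
        scene = synthetic.generate_scene(spec)
        prob = synthetic.ground_truth_probability(scene)
        labels = W.separate_cells(prob)
        assert labels.max() == 1
        truth = scene.instances > 0
        covered = np.count_nonzero((labels > 0) & truth) / truth.sum()
        assert covered >= 0.90

    def test_three_cell_cluster_three_instances(self):
        from wbcseg import synthetic
        spec = synthetic.SceneSpec(n_wbc=3, cluster_prob=1.0, seed=2)
        scene = synthetic.generate_scene(spec)
        assert scene.n_cells == 3
        labels = W.separate_cells(synthetic.ground_truth_probability(scene))
        assert labels.max() == 3

    def test_all_zero_map_empty(self):
        labels = W.separate_cells(np.zeros((64, 64)))
        assert labels.max() == 0 and labels.shape == (64, 64)

    def test_deterministic(self):
        prob = two_disc_map()
        np.testing.assert_array_equal(W.separate_cells(prob),
                                      W.separate_cells(prob))

    def test_output_is_partition_of_connected_instances(self, small_scenes):
        from wbcseg import synthetic
        for scene in small_scenes[:4]:
            labels = W.separate_cells(synthetic.ground_truth_probability(scene))
            for lab in range(1, int(labels.max()) + 1):
                comp, n = ndi.label(labels == lab, structure=np.ones((3, 3)))
                assert n == 1, f"instance {lab} disconnected"

    def test_instance_count_equals_marker_count(self):
        """One output instance per foreground marker (over-segmentation
        suppression stated testably)."""
        prob = two_disc_map(centers=((40, 40), (40, 88), (90, 64)), radius=18)
        arr = prob
        lo, hi = arr.min(), arr.max()
        binary = arr > lo + 0.5 * (hi - lo)
        fg = W._distance_markers(binary, 20, 1.5, 0.7)
        labels = W.separate_cells(prob)
        assert labels.max() == fg.max()


def test_label_overlay_shapes(rng):
    img = rng.integers(0, 255, size=(32, 32, 3), dtype=np.uint8)
    labels = np.zeros((32, 32), dtype=int)
    labels[4:10, 4:10] = 1
    out = W.label_overlay(img, labels, seed=0)
    assert out.shape == (32, 32, 3) and out.dtype == np.uint8
    assert not np.array_equal(out[5, 5], img[5, 5])
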