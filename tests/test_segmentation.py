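import numpy as np
import pytest

from polorder import (SegmentedObject, azimuthal_disorder, build_mask,
                      circular_std_axial_deg, filter_objects, label_objects,
                      measure_objects, object_of, signal_to_background)
from polorder.orientation import OrientationMaps


def otsu_bruteforce(image, nbins=256):
    """Exhaustive between-class variance maximization over histogram splits."""
    hist, edges = np.histogram(image.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_t, best_v = None, -1.0
    total = hist.sum()
    for k in range(1, nbins):
        w0 = hist[:k].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:k] * centers[:k]).sum() / hist[:k].sum()
        m1 = (hist[k:] * centers[k:]).sum() / hist[k:].sum()
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, centers[k - 1]  # ties break toward the lower threshold
    return best_t


def flood_fill_components(mask):
    """Brute-force 4-connected component count via explicit flood fill."""
    mask = mask.copy()
    h, w = mask.shape
    count = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                count += 1
                stack = [(i, j)]
                mask[i, j] = False
                while stack:
                    r, c = stack.pop()
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                            mask[rr, cc] = False
                            stack.append((rr, cc))
    return count


def uniform_maps(shape, of=0.5, azimuth=10.0):
    of_map = np.full(shape, of)
    az = np.full(shape, azimuth)
    valid = of_map > 0
    az = np.where(valid, az, np.nan)
    return OrientationMaps(of_map, az, valid)


class TestMask:
    def test_constant_image_empty_mask_with_warning(self):
        with pytest.warns(UserWarning, match="no foreground"):
            m = build_mask(np.full((16, 16), 7.0))
        assert not m.mask.any()

    def test_bright_square_recovered_exactly(self):
        img = np.zeros((20, 20))
        img[8:11, 8:11] = 100.0
        m = build_mask(img)
        expected = img > 0
        assert np.array_equal(m.mask, expected)

    def test_otsu_threshold_matches_bruteforce_oracle(self, rng):
        img = np.full((64, 64), 50.0) + np.linspace(0, 20, 64)[None, :]
        img[10:20, 10:20] = 200.0
        img[40:45, 30:40] = 200.0
        img += rng.normal(0, 3, size=img.shape)
        img = np.clip(img, 0, None)
        m = build_mask(img)
        from skimage.morphology import disk, white_tophat
        tophat = white_tophat(img, footprint=disk(3))
        assert m.threshold_value == pytest.approx(otsu_bruteforce(tophat), rel=1e-12)


class TestLabeling:
    def test_diagonal_pixels_are_two_objects(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        _, objs = label_objects(mask)
        assert len(objs) == 2

    def test_plus_sign_single_object(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 1:4] = True
        mask[1:4, 2] = True
        _, objs = label_objects(mask)
        assert len(objs) == 1
        assert objs[0].n_pixels == 5

    def test_component_count_matches_flood_fill_oracle(self, rng):
        mask = rng.random((40, 40)) < 0.35
        _, objs = label_objects(mask)
        assert len(objs) == flood_fill_components(mask)

    def test_labels_row_major_order(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[4, 1] = True   # later in row-major order
        mask[0, 5] = True   # first foreground pixel scanned
        _, objs = label_objects(mask)
        assert objs[0].pixel_indices[0][0] == 0
        assert objs[1].pixel_indices[0][0] == 4


class TestObjectMetrics:
    def test_mean_of_simple(self):
        maps = uniform_maps((2, 2))
        maps.of_map[0, 0], maps.of_map[0, 1] = 0.2, 0.4
        obj = SegmentedObject(1, (np.array([0, 0]), np.array([0, 1])))
        assert object_of(obj, maps) == pytest.approx(0.3)

    def test_uniform_of_field_identity(self):
        maps = uniform_maps((8, 8), of=0.77)
        obj = SegmentedObject(1, tuple(np.nonzero(np.ones((8, 8), dtype=bool))))
        assert object_of(obj, maps) == pytest.approx(0.77)

    def test_identical_azimuths_zero_csd(self):
        assert circular_std_axial_deg(np.full(10, 33.0)) == 0.0

    def test_axial_antipodes_infinite_csd(self):
        assert np.isinf(circular_std_axial_deg(np.array([0.0, 90.0, 0.0, 90.0])))

    def test_wrapped_normal_recovery_at_10deg(self):
        rng = np.random.default_rng(7)
        az = 45.0 + rng.normal(0, 10.0, size=10_000)
        assert circular_std_axial_deg(az) == pytest.approx(10.0, abs=0.5)

    def test_csd_matches_scalar_loop_oracle(self, rng):
        az = rng.uniform(-90, 90, size=500)
        # independent scalar computation of the doubled-angle resultant
        sr = sum(np.cos(2 * np.radians(a)) for a in az) / len(az)
        si = sum(np.sin(2 * np.radians(a)) for a in az) / len(az)
        r = np.hypot(sr, si)
        expected = np.degrees(np.sqrt(-2 * np.log(r)) / 2)
        assert circular_std_axial_deg(az) == pytest.approx(expected, abs=1e-12)

    def test_csd_invariant_to_pixel_order(self, rng):
        az = rng.uniform(-90, 90, size=64)
        perm = rng.permutation(64)
        assert circular_std_axial_deg(az) == pytest.approx(
            circular_std_axial_deg(az[perm]), abs=1e-12)


class TestSignalToBackground:
    def _scene(self, object_value, ring_value):
        """5x5 object at the center of a large frame, controlled ring intensity."""
        avg = np.full((32, 32), ring_value)
        mask = np.zeros((32, 32), dtype=bool)
        mask[14:19, 14:19] = True
        avg[mask] = object_value
        return avg, mask

    def test_boundary_exactly_three_retained(self):
        avg, mask = self._scene(30.0, 10.0)
        _, objs = label_objects(mask)
        sb = signal_to_background(objs[0], avg, mask)
        assert sb == pytest.approx(3.0, abs=1e-12)
        objs[0].sb_ratio, objs[0].mean_of, objs[0].azimuth_csd_deg = sb, 0.5, 5.0
        assert len(filter_objects(objs)) == 1

    def test_just_below_three_excluded(self):
        avg, mask = self._scene(29.9, 10.0)
        _, objs = label_objects(mask)
        sb = signal_to_background(objs[0], avg, mask)
        assert sb == pytest.approx(2.99, abs=1e-12)
        objs[0].sb_ratio, objs[0].mean_of, objs[0].azimuth_csd_deg = sb, 0.5, 5.0
        assert len(filter_objects(objs)) == 0

    def test_buffer_ring_geometry_vs_distance_oracle(self):
        """Single-pixel object: ring = city-block shells 4-5, buffer 1-3 excluded."""
        avg = np.zeros((21, 21))
        mask = np.zeros((21, 21), dtype=bool)
        mask[10, 10] = True
        # paint city-block distance into the image so the mean identifies the shells
        rr, cc = np.mgrid[0:21, 0:21]
        d = np.abs(rr - 10) + np.abs(cc - 10)
        avg[:] = np.where((d >= 4) & (d <= 5), 1.0, 1000.0)
        avg[10, 10] = 500.0
        _, objs = label_objects(mask)
        sb = signal_to_background(objs[0], avg, mask)
        # if any buffer (d 1-3) or far (d > 5) pixel leaked in, the mean exceeds 1
        assert sb == pytest.approx(500.0, abs=1e-9)

    def test_neighbor_objects_excluded_from_background(self):
        avg = np.full((40, 40), 10.0)
        mask = np.zeros((40, 40), dtype=bool)
        mask[18:21, 10:13] = True        # object under test
        mask[18:21, 17:20] = True        # bright neighbor inside the ring zone
        avg[18:21, 10:13] = 50.0
        avg[18:21, 17:20] = 500.0
        _, objs = label_objects(mask)
        sb = signal_to_background(objs[0], avg, mask)
        assert sb == pytest.approx(5.0, abs=1e-9)  # neighbor never counted

    def test_clipped_edge_object_flagged(self):
        avg = np.full((6, 6), 10.0)
        mask = np.ones((6, 6), dtype=bool)  # object fills the frame: no ring
        _, objs = label_objects(mask)
        sb = signal_to_background(objs[0], avg, mask)
        assert np.isnan(sb)
        assert "empty background ring" in objs[0].flags

    def test_zero_background_infinite(self):
        avg = np.zeros((32, 32))
        mask = np.zeros((32, 32), dtype=bool)
        mask[15:18, 15:18] = True
        avg[mask] = 10.0
        _, objs = label_objects(mask)
        assert np.isinf(signal_to_background(objs[0], avg, mask))


class TestFiltering:
    def _obj(self, sb):
        o = SegmentedObject(1, (np.array([0]), np.array([0])))
        o.sb_ratio, o.mean_of, o.azimuth_csd_deg = sb, 0.5, 5.0
        return o

    def test_strict_threshold(self):
        objs = [self._obj(2.5), self._obj(3.0), self._obj(8.1)]
        assert len(filter_objects(objs)) == 2

    def test_empty_input(self):
        assert filter_objects([]) == []

    def test_metrics_invariant_to_labeling_order(self, rng):
        maps = uniform_maps((30, 30))
        maps.of_map[:] = rng.uniform(0.1, 1.0, size=(30, 30))
        maps.azimuth_deg[:] = rng.uniform(-90, 90, size=(30, 30))
        avg = rng.uniform(5, 10, size=(30, 30))
        mask = np.zeros((30, 30), dtype=bool)
        mask[3:6, 3:6] = True
        mask[20:24, 18:22] = True
        objs = measure_objects(mask, maps, avg)
        flipped = measure_objects(mask[::-1, ::-1].copy(),
                                  OrientationMaps(maps.of_map[::-1, ::-1].copy(),
                                                  maps.azimuth_deg[::-1, ::-1].copy(),
                                                  maps.valid_mask[::-1, ::-1].copy()),
                                  avg[::-1, ::-1].copy())
        got = sorted((o.mean_of, o.azimuth_csd_deg, o.sb_ratio) for o in objs)
        exp = sorted((o.mean_of, o.azimuth_csd_deg, o.sb_ratio) for o in flipped)
        assert np.allclose(got, exp)
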