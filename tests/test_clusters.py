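import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ryrclust as rc
from ryrclust.clusters import (ClusterSet, cluster_density, estimate_channels,
                               nearest_neighbor_distances, segment_clusters)
from ryrclust.render import RenderedImage
from oracles import brute_force_nnd, random_blob_mask


def image_from(px, pixel_size=5.0):
    return RenderedImage(np.asarray(px, dtype=float), pixel_size)


def clusterset_from_labels(labels, pixel_size=5.0):
    img = image_from((labels > 0).astype(float) * 10.0, pixel_size)
    return segment_clusters(img, threshold=5.0, min_events=0.0,
                            roi=np.ones_like(labels, dtype=bool))


class TestSegmentation:
    def test_all_zero_image_yields_no_clusters(self):
        cs = segment_clusters(image_from(np.zeros((50, 50))), threshold=1.0)
        assert len(cs) == 0

    def test_two_separated_squares(self):
        px = np.zeros((40, 40))
        px[5:10, 5:10] = 10.0   # 25 pixels
        px[20:28, 20:28] = 10.0  # 64 pixels
        cs = segment_clusters(image_from(px), threshold=5.0)
        assert len(cs) == 2
        assert sorted(c.n_pixels for c in cs.clusters) == [25, 64]
        for c in cs.clusters:
            assert c.area_nm2 == c.n_pixels * 25.0
            assert c.mean_intensity == pytest.approx(10.0)

    def test_min_events_filters_small_components(self):
        px = np.zeros((30, 30))
        px[2, 2] = 1.0            # mass 1 < 3 -> dropped
        px[10:13, 10:13] = 1.0    # mass 9 -> kept
        cs = segment_clusters(image_from(px), threshold=0.5, min_events=3.0)
        assert len(cs) == 1
        assert cs.clusters[0].n_pixels == 9

    def test_border_components_flagged(self):
        px = np.zeros((30, 30))
        px[0:4, 10:14] = 5.0
        px[15:19, 15:19] = 5.0
        cs = segment_clusters(image_from(px), threshold=1.0)
        flags = sorted(c.touches_border for c in cs.clusters)
        assert flags == [False, True]

    def test_idempotence_on_own_mask(self):
        px = np.zeros((40, 40))
        px[5:12, 5:9] = 3.0
        px[25:30, 20:33] = 7.0
        cs1 = segment_clusters(image_from(px), threshold=2.0, min_events=0.0)
        cs2 = clusterset_from_labels(cs1.labels)
        assert len(cs1) == len(cs2)
        np.testing.assert_array_equal(cs1.mask, cs2.mask)
        assert sorted(c.n_pixels for c in cs1.clusters) == \
            sorted(c.n_pixels for c in cs2.clusters)

    def test_roi_restricts_mask_and_area(self):
        px = np.full((20, 20), 5.0)
        roi = np.zeros((20, 20), dtype=bool)
        roi[:10, :] = True
        cs = segment_clusters(image_from(px), threshold=1.0, roi=roi)
        assert cs.analysis_area_um2 == pytest.approx(200 * 25 * 1e-6)
        assert all(not c.touches_border or True for c in cs.clusters)
        assert cs.mask.sum() == 200


class TestEstimateChannels:
    @pytest.mark.parametrize("area,expected", [
        (16200.0, 18),   # one mean-sized cluster
        (450.0, 1),      # clamp at one channel
        (900.0, 1),
        (1350.0, 2),     # round half up
    ])
    def test_area_to_channels(self, area, expected):
        assert estimate_channels(area, 900.0) == expected

    def test_monotone_in_area(self, rng):
        areas = np.sort(rng.uniform(100, 100000, size=50))
        counts = [estimate_channels(a) for a in areas]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    @settings(derandomize=True, max_examples=100)
    @given(a=st.floats(min_value=0.0, max_value=1e6),
           b=st.floats(min_value=0.0, max_value=1e6))
    def test_monotone_and_floored_property(self, a, b):
        lo, hi = sorted((a, b))
        assert 1 <= estimate_channels(lo) <= estimate_channels(hi)


class TestClusterDensity:
    def test_zero_clusters(self):
        cs = segment_clusters(image_from(np.zeros((20, 20))), threshold=1.0,
                              roi=np.ones((20, 20), dtype=bool))
        assert cluster_density(cs) == 0.0

    def test_arithmetic(self):
        # 43 single-pixel clusters in a 10 µm² ROI -> 4.3 per µm²
        px = np.zeros((800, 500))  # 400,000 px x 25 nm² = 10 µm²
        idx = [(10 + 30 * (k % 20), 10 + 30 * (k // 20)) for k in range(43)]
        for r, c in idx:
            px[r, c] = 10.0
        roi = np.ones_like(px, dtype=bool)
        cs = segment_clusters(image_from(px), threshold=1.0, min_events=0.0,
                              roi=roi)
        assert cluster_density(cs) == pytest.approx(4.3)

    def test_missing_area_errors(self):
        px = np.zeros((20, 20))
        px[5, 5] = 10.0
        cs = segment_clusters(image_from(px), threshold=1.0, min_events=0.0)
        cs.analysis_area_um2 = None
        with pytest.raises(ValueError, match="ROI"):
            cluster_density(cs)


class TestNearestNeighborDistances:
    def test_two_point_clusters_30px_apart(self):
        px = np.zeros((64, 64))
        px[20, 10] = 10.0
        px[20, 40] = 10.0
        cs = segment_clusters(image_from(px), threshold=1.0, min_events=0.0)
        nnds = nearest_neighbor_distances(cs)
        assert len(nnds) == 2
        assert nnds[0] == pytest.approx(150.0, abs=5.0)

    def test_one_pixel_gap(self):
        px = np.zeros((30, 30))
        px[10, 5:10] = 10.0
        px[10, 11:16] = 10.0
        cs = segment_clusters(image_from(px), threshold=1.0, min_events=0.0)
        nnds = nearest_neighbor_distances(cs)
        # adjacent across one background pixel: one-pixel-scale distance
        assert nnds[0] == pytest.approx(5.0, abs=5.0)

    def test_single_cluster_warns_empty(self):
        px = np.zeros((20, 20))
        px[5:8, 5:8] = 10.0
        cs = segment_clusters(image_from(px), threshold=1.0, min_events=0.0)
        with pytest.warns(UserWarning):
            nnds = nearest_neighbor_distances(cs)
        assert nnds.size == 0

    def test_matches_brute_force_on_random_masks(self, rng):
        """Windowed-EDT production path equals O(n²) boundary-pair scan."""
        for _ in range(20):
            labels = random_blob_mask(rng, size=128)
            cs = clusterset_from_labels(labels)
            nearest_neighbor_distances(cs)
            ref = brute_force_nnd(cs.labels)
            for rec in cs.clusters:
                want = ref[rec.id + 1] * cs.pixel_size
                assert rec.nnd_edge_nm == pytest.approx(want, abs=1e-9)

    def test_global_minimum_is_mutual(self, rng):
        labels = random_blob_mask(rng, size=256, n_blobs=8)
        cs = clusterset_from_labels(labels)
        nearest_neighbor_distances(cs)
        vals = [c.nnd_edge_nm for c in cs.clusters]
        gmin = min(vals)
        assert sum(1 for v in vals if v == pytest.approx(gmin)) >= 2

    def test_recovery_mean_nnd_within_10pct(self, recovery_runs):
        """Pipeline NND on default scenes tracks ground truth within 10%."""
        rel = []
        for scene, result in recovery_runs:
            truth = np.asarray(scene.true_metrics["nnd_nm"], dtype=float)
            truth = truth[np.isfinite(truth)]
            got = result.summary["mean_nnd_nm"]
            rel.append(got / truth.mean())
        assert np.mean(rel) == pytest.approx(1.0, abs=0.10)
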