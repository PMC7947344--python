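import numpy as np
import pytest

import ryrclust as rc
from ryrclust.clusters import segment_clusters
from ryrclust.render import RenderedImage
from ryrclust.zdisk import (cluster_zdisk_alignment,
                            labeling_fraction_near_zdisk, segment_zdisks)


def band_scene(field=(2000.0, 4000.0), bands=((1000.0, 200.0), (2800.0, 200.0))):
    cfg = rc.SimulationConfig(cluster_density=0.0, field_size=field)
    scene = rc.build_scene(cfg)
    scene.zdisk_bands = list(bands)
    return scene


class TestSegmentZdisks:
    def test_all_zero_image_errors(self):
        img = RenderedImage(np.zeros((20, 20)), 5.0)
        with pytest.raises(ValueError, match="no z-disk signal"):
            segment_zdisks(img)

    def test_distance_map_geometry_single_pixel(self):
        px = np.zeros((40, 40))
        px[20, 20] = 1.0
        img = RenderedImage(px, 5.0)
        z = segment_zdisks(img, policy="fixed", threshold=0.5)
        assert z.mask.sum() == 1
        assert z.distance_map_nm[20, 20] == 0.0
        assert z.distance_map_nm[20, 30] == pytest.approx(10 * 5.0)
        assert (z.distance_map_nm >= 0).all()
        assert (z.distance_map_nm[z.mask] == 0).all()

    def test_band_mask_matches_blur_limited_prediction(self):
        """Otsu mask width of PSF-blurred bands matches the closed form.

        A 200 nm band blurred by a 250 nm Gaussian PSF has a half-maximum
        half-width of 302 nm (erf oracle), i.e. an area fraction of 0.336 at
        1800 nm spacing — the diffraction limit, not the 200 nm band itself.
        """
        scene = band_scene()
        img = rc.simulate_actinin_widefield(scene, psf_sigma=250.0)
        z = segment_zdisks(img)
        predicted = 2 * 604.6 / 4000.0  # two half-max-width ridges in 4 µm
        assert z.area_fraction == pytest.approx(predicted, rel=0.25)
        # ridge rows sit on the band centre-lines
        rows = np.nonzero(z.mask.any(axis=1))[0] * 5.0
        assert ((np.abs(rows - 1000.0) < 450) | (np.abs(rows - 2800.0) < 450)).all()
        assert z.mask[200, :].all() and z.mask[560, :].all()


class TestAlignment:
    def make_clusters(self, centroids_nm, shape=(800, 400)):
        px = np.zeros(shape)
        for x, y in centroids_nm:
            r, c = int(y / 5), int(x / 5)
            px[r - 1:r + 2, c - 1:c + 2] = 10.0
        img = RenderedImage(px, 5.0)
        return segment_clusters(img, threshold=1.0, min_events=0.0,
                                roi=np.ones(shape, dtype=bool))

    def test_all_centroids_on_mask(self):
        mask = np.ones((800, 400), dtype=bool)
        z = rc.ZDiskMask(mask, np.zeros((800, 400)), 5.0)
        cs = self.make_clusters([(500.0, 1000.0), (1000.0, 2000.0)])
        assert cluster_zdisk_alignment(cs, z) == 100.0

    def test_empty_mask_zero_aligned(self):
        mask = np.zeros((800, 400), dtype=bool)
        dist = np.full((800, 400), 1e9)
        z = rc.ZDiskMask(mask, dist, 5.0)
        cs = self.make_clusters([(500.0, 1000.0), (1000.0, 2000.0)])
        assert cluster_zdisk_alignment(cs, z) == 0.0

    def test_empty_cluster_set_missing(self):
        z = rc.ZDiskMask(np.ones((10, 10), dtype=bool), np.zeros((10, 10)), 5.0)
        img = RenderedImage(np.zeros((10, 10)), 5.0)
        cs = segment_clusters(img, threshold=1.0)
        assert cluster_zdisk_alignment(cs, z) is None

    def test_uniform_null_matches_mask_area_fraction(self):
        """Uniformly placed clusters align at the mask's area fraction."""
        rng = np.random.default_rng(99)
        scene = band_scene(field=(4000.0, 4000.0),
                           bands=((800.0, 200.0), (2600.0, 200.0)))
        img = rc.simulate_actinin_widefield(scene, psf_sigma=250.0)
        z = segment_zdisks(img)
        pcts = []
        for _ in range(30):
            pts = rng.uniform(10, 3990, size=(40, 2))
            cs = self.make_clusters(pts, shape=(800, 800))
            pcts.append(cluster_zdisk_alignment(cs, z))
        pcts = np.asarray(pcts)
        se = pcts.std(ddof=1) / np.sqrt(len(pcts))
        assert abs(pcts.mean() - 100.0 * z.area_fraction) <= 3 * se + 1e-9


class TestLabelingFraction:
    def test_all_inside_mask_distance_zero(self):
        px = np.zeros((40, 40))
        px[10:20, 10:20] = 3.0
        ryr = RenderedImage(px, 5.0)
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:20, 10:20] = True
        from scipy import ndimage
        dist = ndimage.distance_transform_edt(~mask) * 5.0
        z = rc.ZDiskMask(mask, dist, 5.0)
        assert labeling_fraction_near_zdisk(ryr, z, 0.0) == pytest.approx(1.0)

    def test_exhaustive_window_captures_everything(self):
        rng = np.random.default_rng(3)
        px = rng.uniform(0, 1, size=(50, 50))
        ryr = RenderedImage(px, 5.0)
        mask = np.zeros((50, 50), dtype=bool)
        mask[0, 0] = True
        from scipy import ndimage
        dist = ndimage.distance_transform_edt(~mask) * 5.0
        z = rc.ZDiskMask(mask, dist, 5.0)
        diag = 50 * 5.0 * np.sqrt(2)
        assert labeling_fraction_near_zdisk(ryr, z, diag) == pytest.approx(1.0)

    def test_monotone_in_distance(self, recovery_runs):
        scene, result = recovery_runs[0]
        z = result.zdisk
        prev = -1.0
        for d in (0.0, 100.0, 300.0, 1000.0):
            f = labeling_fraction_near_zdisk(result.image, z, d)
            assert 0.0 <= f <= 1.0
            assert f >= prev
            prev = f

    def test_zero_intensity_missing(self):
        ryr = RenderedImage(np.zeros((10, 10)), 5.0)
        z = rc.ZDiskMask(np.ones((10, 10), dtype=bool), np.zeros((10, 10)), 5.0)
        assert labeling_fraction_near_zdisk(ryr, z, 100.0) is None

    def test_known_fraction_recovery(self, recovery_runs):
        """Recovered fraction within 300 nm tracks the channel-level truth."""
        scene, result = recovery_runs[0]
        z = result.zdisk
        px = result.image.pixel_size
        rows = np.clip((scene.channel_positions[:, 1] / px).astype(int),
                       0, z.mask.shape[0] - 1)
        cols = np.clip((scene.channel_positions[:, 0] / px).astype(int),
                       0, z.mask.shape[1] - 1)
        true_frac = (z.distance_map_nm[rows, cols] <= 300.0).mean()
        got = labeling_fraction_near_zdisk(result.image, z, 300.0)
        assert got == pytest.approx(true_frac, abs=0.05)
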