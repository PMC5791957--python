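"""Bolus segmentation: mean shift, distance map, K-Means composition."""

import numpy as np
import pytest
from skimage.color import rgb2luv

from gummix.errors import InputError, ParameterError, SegmentationError
from gummix.segmentation import (RegionMask, SegmentationParams, distance_map,
                                 jaccard, kmeans_region_classify,
                                 mean_shift_filter, segment)


def _disk_image(size=96, radius=28, fg=(198, 40, 55), bg=200):
    img = np.full((size, size, 3), bg, dtype=np.uint8)
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    mask = np.hypot(yy - c, xx - c) <= radius
    img[mask] = fg
    return img, mask


class TestDistanceMap:
    def test_centre_zero_corner_one(self):
        d = distance_map((65, 65))
        assert d[32, 32] == 0.0
        assert d[0, 0] == 1.0
        assert d.max() == 1.0

    def test_3x3_hand_computed(self):
        d = distance_map((3, 3))
        # raw distances: corners sqrt(2), edges 1, centre 0; max = sqrt(2)
        want = np.array([[np.sqrt(2), 1, np.sqrt(2)],
                         [1, 0, 1],
                         [np.sqrt(2), 1, np.sqrt(2)]]) / np.sqrt(2)
        assert np.allclose(d, want)

    def test_empty_shape_rejected(self):
        with pytest.raises(InputError):
            distance_map((0, 10))


class TestMeanShiftFilter:
    def test_constant_image_unchanged(self):
        img = np.full((40, 40, 3), 120, dtype=np.uint8)
        out = mean_shift_filter(img)
        assert np.allclose(out, 120.0, atol=1e-3)

    def test_flat_halves_preserved_away_from_boundary(self):
        img = np.full((40, 60, 3), 30, dtype=np.uint8)
        img[:, 30:] = 220  # colour distance >> range bandwidth
        out = mean_shift_filter(img, spatial_bandwidth=5, range_bandwidth=10)
        assert np.allclose(out[:, :20], 30.0, atol=1.0)
        assert np.allclose(out[:, 40:], 220.0, atol=1.0)

    def test_reduces_noise_variance_on_uniform_blob(self, specimen_t0):
        # a single-phase (unchewed) face: mode seeking averages the
        # scanner noise away, so the intra-ROI colour variance drops
        img = specimen_t0.images[0]
        mask = specimen_t0.roi_truth[0]
        out = mean_shift_filter(img)
        var_before = rgb2luv(img / 255.0)[mask].var(axis=0).sum()
        var_after = rgb2luv(out / 255.0)[mask].var(axis=0).sum()
        assert var_after < var_before

    def test_invalid_bandwidth(self):
        with pytest.raises(ParameterError):
            mean_shift_filter(np.zeros((8, 8, 3)), spatial_bandwidth=0)


class TestKMeansRegionClassify:
    def test_flat_disk_recovered_exactly(self):
        img, truth = _disk_image()
        mask = segment(img)
        assert jaccard(mask.mask, truth) == 1.0

    def test_deterministic(self, specimen_t20):
        m1 = segment(specimen_t20.images[0])
        m2 = segment(specimen_t20.images[0])
        assert np.array_equal(m1.mask, m2.mask)

    def test_degenerate_input_rejected(self):
        feats = np.ones((100, 4))
        with pytest.raises(SegmentationError):
            kmeans_region_classify(feats, (10, 10))


class TestSegment:
    def test_specimen_fixture_quality(self, specimen_t20):
        for side in (0, 1):
            mask = segment(specimen_t20.images[side])
            truth = specimen_t20.roi_truth[side]
            assert jaccard(mask.mask, truth) >= 0.95
            # scale sanity
            assert abs(mask.roi_pixel_count - truth.sum()) / truth.sum() <= 0.10

    def test_pure_red_face_hue(self, specimen_t0):
        mask = segment(specimen_t0.images[0])
        from gummix.colorspaces import channel_set
        cs = channel_set(specimen_t0.images[0])
        sel = mask.mask & cs.hue_defined
        mean_hue = np.arctan2(np.sin(cs.channels["H"][sel]).mean(),
                              np.cos(cs.channels["H"][sel]).mean()) % (2 * np.pi)
        # red band: within ~0.5 rad of the 0/2pi axis
        assert min(mean_hue, 2 * np.pi - mean_hue) < 0.5

    def test_background_only_image_fails(self, rng):
        img = np.clip(rng.normal(200, 5, size=(96, 96, 3)), 0, 255).astype(np.uint8)
        with pytest.raises(SegmentationError):
            segment(img)

    def test_constant_image_fails(self):
        img = np.full((96, 96, 3), 180, dtype=np.uint8)
        with pytest.raises(SegmentationError):
            segment(img)

    def test_full_variant_beats_km_only(self, default_config):
        from gummix.synthetic import generate_specimen
        full, km = [], []
        for seed in range(6):
            s = generate_specimen((5, 10, 15, 20)[seed % 4], 0.05,
                                  default_config, seed=300 + seed)
            truth = s.roi_truth[0]
            full.append(jaccard(segment(s.images[0]).mask, truth))
            try:
                m = segment(s.images[0], SegmentationParams(variant="km"))
                km.append(jaccard(m.mask, truth))
            except SegmentationError:
                km.append(0.0)  # a failed ablation counts as zero overlap
        assert np.mean(full) >= np.mean(km)

    def test_mask_partition(self, specimen_t20):
        mask = segment(specimen_t20.images[0])
        assert isinstance(mask, RegionMask)
        assert mask.mask.dtype == bool
        assert mask.mask.shape == specimen_t20.images[0].shape[:2]
        assert mask.roi_pixel_count > 0
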