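"""MP feature extraction: histogram models, circular hue variance, registry."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import iv

from gummix.errors import FeatureError, InputError, RegistryError
from gummix.features import (ChannelHistogram, cvoh, default_registry,
                             extract_feature, extract_mp, histogram,
                             pool_roi_pixels)


def _hist_from_counts(counts):
    counts = np.asarray(counts, dtype=np.int64)
    return ChannelHistogram(counts=counts, edges=np.arange(counts.size + 1, dtype=float))


class TestHistogram:
    def test_one_value_per_level(self):
        h = histogram(np.arange(256, dtype=float), "R")
        assert np.all(h.counts == 1)
        assert h.total == 256

    def test_constant_input_single_bin(self):
        h = histogram(np.full(500, 42.0), "R")
        assert h.counts.max() == 500
        assert (h.counts > 0).sum() == 1

    def test_uniform_sample_binomial_bound(self, rng):
        n = 100_000
        h = histogram(rng.uniform(0, 255, size=n), "R")
        assert np.abs(h.counts - n / 256).max() < 5 * np.sqrt(n / 256)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            histogram(np.array([]), "R")


class TestExtractFeature:
    def test_uniform_histogram_closed_forms(self):
        h = _hist_from_counts(np.full(256, 10))
        assert extract_feature("Eh", hist=h) == pytest.approx(8.0)
        assert extract_feature("Gh", hist=h) == pytest.approx(1 / 256)
        assert extract_feature("Vh", hist=h) == 0.0

    def test_single_bin_histogram(self):
        counts = np.zeros(256, dtype=int)
        counts[100] = 1000
        h = _hist_from_counts(counts)
        assert extract_feature("Eh", hist=h) == 0.0
        assert extract_feature("Gh", hist=h) == 1.0
        assert extract_feature("Nh", hist=h) == 1.0
        assert extract_feature("V1", hist=h) == 1000.0
        assert extract_feature("V2", hist=h) == 0.0    # sentinel: <2 peaks
        assert extract_feature("P2", hist=h) == -1.0   # sentinel: <2 peaks

    def test_bimodal_histogram_two_peaks(self, rng):
        vals = np.concatenate([rng.normal(64, 6, 5000), rng.normal(192, 6, 5000)])
        h = histogram(np.clip(vals, 0, 255), "R")
        assert extract_feature("Nh", hist=h) == 2.0
        v1 = extract_feature("V1", hist=h)
        v2 = extract_feature("V2", hist=h)
        assert abs(v1 - v2) / v1 < 0.05
        p2 = extract_feature("P2", hist=h)
        assert p2 in range(50, 80) or p2 in range(180, 210)

    def test_pixel_models_match_numpy(self, rng):
        x = rng.normal(100, 20, size=5000)
        assert extract_feature("Mp", pixels=x) == pytest.approx(x.mean())
        assert extract_feature("Vp", pixels=x) == pytest.approx(x.var())

    def test_histogram_skewness_matches_expanded_oracle(self, rng):
        counts = rng.integers(0, 50, size=256)
        h = _hist_from_counts(counts)
        expanded = np.repeat(np.arange(256), counts)
        assert extract_feature("Sh", hist=h) == pytest.approx(
            stats.skew(expanded), abs=1e-9)

    def test_unknown_model_rejected(self):
        with pytest.raises(RegistryError):
            extract_feature("Xx", hist=_hist_from_counts(np.ones(256, dtype=int)))


class TestCVOH:
    def test_identical_hues(self):
        assert cvoh(np.full(100, 1.3)) == 0.0

    def test_antipodal_hues_cancel(self):
        assert cvoh(np.array([0.0, np.pi] * 50)) == pytest.approx(1.0)

    def test_von_mises_closed_form(self, rng):
        kappa = 2.0
        sample = rng.vonmises(0.0, kappa, size=10_000)
        expected = 1.0 - iv(1, kappa) / iv(0, kappa)
        assert cvoh(sample) == pytest.approx(expected, abs=0.02)

    def test_matches_scipy_circvar(self, rng):
        sample = rng.uniform(0, 2 * np.pi, size=3000)
        assert cvoh(sample) == pytest.approx(
            stats.circvar(sample, high=2 * np.pi), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(FeatureError):
            cvoh(np.array([]))


class TestPooling:
    def test_additivity(self, rng):
        img = rng.integers(0, 255, size=(60, 60, 3)).astype(np.uint8)
        mask_a = np.zeros((60, 60), bool)
        mask_a[5:30, 5:45] = True            # 1000 px
        mask_b = np.zeros((60, 60), bool)
        mask_b[31:55, 5:55] = True           # 1200 px
        pooled = pool_roi_pixels([img, img], [mask_a, mask_b])
        assert pooled["R"].size == mask_a.sum() + mask_b.sum()

    def test_one_empty_side_equals_other(self, rng):
        img = rng.integers(0, 255, size=(40, 40, 3)).astype(np.uint8)
        mask = np.zeros((40, 40), bool)
        mask[10:30, 10:30] = True
        empty = np.zeros((40, 40), bool)
        a = pool_roi_pixels([img, img], [mask, empty])
        b = pool_roi_pixels([img], [mask])
        assert np.array_equal(np.sort(a["G"]), np.sort(b["G"]))

    def test_both_empty_rejected(self, rng):
        img = rng.integers(0, 255, size=(40, 40, 3)).astype(np.uint8)
        empty = np.zeros((40, 40), bool)
        with pytest.raises(FeatureError):
            pool_roi_pixels([img, img], [empty, empty])


class TestExtractMP:
    def test_vector_has_121_features(self, specimen_t20):
        mp = extract_mp(specimen_t20.images, list(specimen_t20.roi_truth))
        assert len(mp) == 121
        assert list(mp.index) == default_registry()
        assert not mp.isna().any()

    def test_deterministic(self, specimen_t20):
        mp1 = extract_mp(specimen_t20.images, list(specimen_t20.roi_truth))
        mp2 = extract_mp(specimen_t20.images, list(specimen_t20.roi_truth))
        assert np.array_equal(mp1.to_numpy(), mp2.to_numpy())

    def test_mixing_separates_hue_histogram_variance(self, specimen_t0, specimen_t20):
        mp0 = extract_mp(specimen_t0.images, list(specimen_t0.roi_truth))
        mp20 = extract_mp(specimen_t20.images, list(specimen_t20.roi_truth))
        assert mp0["VhH"] != mp20["VhH"]
        assert mp0["CVOH"] != mp20["CVOH"]

    def test_permutation_invariance(self, rng):
        """Histogram/pixel statistics ignore pixel order."""
        x = rng.normal(128, 30, size=4000).clip(0, 255)
        shuffled = rng.permutation(x)
        for model in ("Mp", "Vp"):
            assert extract_feature(model, pixels=x) == pytest.approx(
                extract_feature(model, pixels=shuffled))
        h1, h2 = histogram(x, "R"), histogram(shuffled, "R")
        assert np.array_equal(h1.counts, h2.counts)

    def test_mixture_index_monotone_over_cycles(self, default_config):
        """Per-class mean CVOH is strictly monotone across cycle counts."""
        from gummix.synthetic import generate_specimen
        cycles = (0, 5, 10, 15, 20)
        means = []
        for t in cycles:
            vals = []
            for rep in range(10):
                s = generate_specimen(t, 0.05, default_config, seed=500 + rep)
                mp = extract_mp(s.images, list(s.roi_truth))
                vals.append(mp["CVOH"])
            means.append(np.mean(vals))
        rho = stats.spearmanr(cycles, means).statistic
        assert abs(rho) == pytest.approx(1.0)
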