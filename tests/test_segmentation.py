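import math

import numpy as np
import pytest
import scipy.ndimage as ndi

from mpquant import (
    RGBMicrograph,
    ScaleCalibration,
    ThresholdFailedError,
    binarize,
    combine_channels,
    histogram256,
    make_histogram_fixture,
    render_touching_pair,
    select_threshold_method,
    threshold_intermodes,
    threshold_renyi,
    watershed_split,
)

STRUCT8 = np.ones((3, 3), dtype=bool)


def _img(r, g, b, shape=(4, 4)):
    px = np.zeros(shape + (3,), dtype=np.uint8)
    px[:, :, 0], px[:, :, 1], px[:, :, 2] = r, g, b
    return RGBMicrograph(pixels=px)


class TestCombineChannels:
    @pytest.mark.parametrize("r,g,b,expected", [
        (200, 10, 30, 20),     # red ignored
        (255, 0, 0, 0),        # pure red -> zero
        (0, 11, 30, 21),       # 20.5 rounds half-up to 21
        (0, 255, 255, 255),
    ])
    def test_pixel_rule(self, r, g, b, expected):
        out = combine_channels(_img(r, g, b))
        assert out.dtype == np.uint8
        assert np.all(out == expected)

    def test_red_has_no_influence(self):
        rng = np.random.default_rng(0)
        px = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        a = combine_channels(RGBMicrograph(pixels=px))
        px2 = px.copy()
        px2[:, :, 0] = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
        b = combine_channels(RGBMicrograph(pixels=px2))
        assert np.array_equal(a, b)


def _naive_intermodes(hist, max_iter=10_000):
    """Independent smoothing-iteration oracle (exact integer convolution)."""
    h = np.array([int(x) for x in hist], dtype=object)
    kernel = np.array([1, 1, 1], dtype=object)
    for _ in range(max_iter):
        inner = (h[1:-1] > h[:-2]) & (h[1:-1] > h[2:])
        peaks = np.flatnonzero(inner) + 1
        if len(peaks) == 2:
            return int(peaks[0] + peaks[1]) // 2
        if len(peaks) < 2:
            return None
        h = np.convolve(h, kernel)[1:-1]  # full conv trimmed == zero-padded
    return None


class TestIntermodes:
    def test_two_spikes_midpoint(self):
        h = make_histogram_fixture("two_spikes", b1=50, b2=150)
        assert threshold_intermodes(h) == 100
        assert _naive_intermodes(h) == 100

    def test_bimodal_gaussian_between_modes(self):
        h = make_histogram_fixture("bimodal_gaussian", m1=60, m2=180)
        t = threshold_intermodes(h)
        assert 60 < t < 180
        assert t == _naive_intermodes(h)

    def test_unimodal_fails_cleanly(self):
        with pytest.raises(ThresholdFailedError):
            threshold_intermodes(make_histogram_fixture("unimodal"))

    def test_matches_naive_oracle_on_random_histograms(self, random_histograms):
        for h in random_histograms[:30]:
            want = _naive_intermodes(h)
            if want is None:
                with pytest.raises(ThresholdFailedError):
                    threshold_intermodes(h)
            else:
                assert threshold_intermodes(h) == want

    def test_reflection_symmetry(self, random_histograms):
        """Reflecting the histogram about bin 127.5 maps T to 255-T (+/-1)."""
        for h in random_histograms[:20]:
            try:
                t = threshold_intermodes(h)
            except ThresholdFailedError:
                continue
            t_ref = threshold_intermodes(h[::-1].copy())
            assert abs(t_ref - (255 - t)) <= 1


def _naive_renyi(hist, alpha):
    """Exhaustive-search maximizer of background+foreground Renyi entropy."""
    total = float(sum(hist))
    p = [c / total for c in hist]
    best_t, best_v = None, -math.inf
    for t in range(256):
        if sum(hist[: t + 1]) == 0 or sum(hist[t + 1:]) == 0:
            continue  # all mass on one side: no split
        pb = sum(p[: t + 1])
        pf = sum(p[t + 1:])
        back = [x / pb for x in p[: t + 1] if x > 0]
        fore = [x / pf for x in p[t + 1:] if x > 0]
        if alpha == 1.0:
            hb = -sum(q * math.log(q) for q in back)
            hf = -sum(q * math.log(q) for q in fore)
        else:
            hb = math.log(sum(q**alpha for q in back)) / (1 - alpha)
            hf = math.log(sum(q**alpha for q in fore)) / (1 - alpha)
        if hb + hf > best_v:
            best_v, best_t = hb + hf, t
    return best_t


class TestRenyi:
    @pytest.mark.parametrize("alpha", [1.0, 2.0])
    def test_uniform_histogram_symmetric_split(self, alpha):
        assert threshold_renyi(make_histogram_fixture("uniform"), alpha) == 127

    def test_two_spikes_smallest_argmax(self):
        assert threshold_renyi(make_histogram_fixture("two_spikes"), 2.0) == 50

    def test_single_occupied_bin_fails(self):
        h = np.zeros(256, dtype=np.int64)
        h[40] = 100
        with pytest.raises(ThresholdFailedError):
            threshold_renyi(h, 2.0)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    def test_matches_exhaustive_oracle(self, random_histograms, alpha):
        for h in random_histograms:
            assert threshold_renyi(h, alpha) == _naive_renyi(h, alpha)

    def test_alpha_to_one_continuity(self, random_histograms):
        """alpha = 1 +/- 1e-3 agrees with the Shannon limit to within 1 bin."""
        for h in random_histograms[:25]:
            t1 = threshold_renyi(h, 1.0)
            assert abs(threshold_renyi(h, 1.0 - 1e-3) - t1) <= 1
            assert abs(threshold_renyi(h, 1.0 + 1e-3) - t1) <= 1


class TestMethodSelection:
    def _intensity(self, frac_bright):
        img = np.full((100, 100), 10, dtype=np.uint8)
        n = int(round(frac_bright * img.size))
        img.ravel()[:n] = 200
        return img

    def test_dense_image_uses_intermodes(self):
        assert select_threshold_method(self._intensity(0.10), "auto") == "intermodes"

    def test_sparse_image_uses_renyi(self):
        assert select_threshold_method(self._intensity(0.005), "auto") == "renyi"

    @pytest.mark.parametrize("policy", ["intermodes", "renyi"])
    def test_explicit_policy_passthrough(self, policy):
        assert select_threshold_method(self._intensity(0.5), policy) == policy

    def test_flat_image_defaults_to_renyi(self):
        assert select_threshold_method(np.zeros((8, 8), np.uint8), "auto") == "renyi"


class TestBinarize:
    def test_strict_inequality(self):
        img = np.full((5, 5), 20, dtype=np.uint8)
        assert binarize(img, 19).all()
        assert not binarize(img, 20).any()

    def test_foreground_is_bright_spike(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[2:4, 2:4] = 150
        img[img == 0] = 50
        mask = binarize(img, 100)
        assert mask.sum() == 4 and mask[2:4, 2:4].all()

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
        prev = binarize(img, 0)
        for t in range(1, 256, 17):
            cur = binarize(img, t)
            assert not np.any(cur & ~prev)  # raising t only shrinks foreground
            prev = cur


class TestWatershed:
    SCALE = ScaleCalibration(2.0)

    def _pair_mask(self, distance_um):
        img, _ = render_touching_pair(100.0, distance_um, self.SCALE)
        comp = combine_channels(img)
        return binarize(comp, 100)

    def test_single_disc_unsplit(self):
        rr, cc = np.mgrid[0:80, 0:80]
        mask = (rr - 40.0) ** 2 + (cc - 40.0) ** 2 <= 25.0**2
        labels = watershed_split(mask)
        assert labels.max() == 1
        assert np.array_equal(labels > 0, mask)  # pixel set unchanged

    def test_touching_pair_split_in_two(self):
        mask = self._pair_mask(80.0)
        _, n_blobs = ndi.label(mask, structure=STRUCT8)
        assert n_blobs == 1  # overlapping discs rasterize to one blob
        labels = watershed_split(mask)
        assert labels.max() == 2

    def test_separated_discs_match_connected_components(self):
        rr, cc = np.mgrid[0:100, 0:400]
        mask = ((rr - 50.0) ** 2 + (cc - 60.0) ** 2 <= 25**2) | (
            (rr - 50.0) ** 2 + (cc - 310.0) ** 2 <= 25**2
        )
        labels = watershed_split(mask)
        cc_labels, n = ndi.label(mask, structure=STRUCT8)
        assert labels.max() == n == 2
        assert np.array_equal(labels > 0, cc_labels > 0)

    def test_empty_mask(self):
        labels = watershed_split(np.zeros((10, 10), dtype=bool))
        assert labels.max() == 0

    def test_never_creates_foreground_or_merges_components(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            field = ndi.gaussian_filter(rng.normal(size=(96, 96)), 4)
            mask = field > np.quantile(field, 0.85)
            labels = watershed_split(mask)
            assert not np.any((labels > 0) & ~mask)
            _, n_before = ndi.label(mask, structure=STRUCT8)
            assert labels.max() >= n_before


class TestHistogram256:
    def test_counts_every_pixel(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, size=(13, 7), dtype=np.uint8)
        h = histogram256(img)
        assert h.sum() == img.size
        assert h[int(img[0, 0])] >= 1
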