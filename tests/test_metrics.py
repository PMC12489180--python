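"""Quality metrics: SSIM, NMI, JSD, AES sharpness, SNR/CNR, segmentation."""

import numpy as np
import pytest
from scipy import ndimage

from reconformer import (
    PhantomSpec,
    TissueMasks,
    Volume,
    aes,
    cnr,
    jsd,
    jsd_hist,
    make_phantom,
    mutual_information,
    nmi,
    normalized_sharpness,
    segment_simple,
    snr,
    ssim,
)
from reconformer.metrics import MetricError, NoEdgesError, dice


def _vol(data):
    return Volume(np.asarray(data, dtype=float), spacing=(1.0, 1.0, 1.0))


@pytest.fixture(scope="module")
def structured():
    ph, labels = make_phantom(PhantomSpec(shape=(48, 48, 48),
                                          spacing=(1.0,) * 3, seed=3))
    return ph, labels


class TestSSIM:
    def test_self_similarity_is_one(self, structured):
        ph, _ = structured
        assert ssim(ph, ph) == pytest.approx(1.0, abs=1e-12)

    def test_inverted_binary_image_is_anticorrelated(self, rng):
        x = (rng.random((32, 32, 32)) > 0.5).astype(float)
        v = _vol(ndimage.gaussian_filter(x, 1.0))
        inv = _vol(1.0 - v.data)
        assert ssim(inv, v) < 0.0

    def test_agrees_with_direct_formula_implementation(self, rng):
        # independent direct evaluation of the local-statistics formula
        a = ndimage.gaussian_filter(rng.random((24, 24, 24)), 1.0)
        b = a + 0.1 * rng.standard_normal(a.shape)
        drange = b.max() - b.min()
        sig, trunc = 1.5, 3.5
        f = lambda z: ndimage.gaussian_filter(z, sig, truncate=trunc)
        mu_a, mu_b = f(a), f(b)
        va = f(a * a) - mu_a**2
        vb = f(b * b) - mu_b**2
        cov = f(a * b) - mu_a * mu_b
        c1, c2 = (0.01 * drange) ** 2, (0.03 * drange) ** 2
        smap = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
            (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
        )
        pad = int(trunc * sig + 0.5)
        expected = smap[(slice(pad, -pad),) * 3].mean()
        got = ssim(_vol(a), _vol(b))
        assert got == pytest.approx(expected, abs=1e-6)


class TestNMI:
    def test_identical_images_give_two(self, structured):
        ph, _ = structured
        assert nmi(ph, ph, bins=64) == pytest.approx(2.0, abs=1e-9)

    def test_independent_noise_near_one(self):
        r1 = np.random.default_rng(0).random((64, 64, 64))
        r2 = np.random.default_rng(1).random((64, 64, 64))
        assert nmi(_vol(r1), _vol(r2), bins=32) < 1.02

    def test_invariant_under_bin_relabeling(self, rng):
        # permuting histogram bin labels permutes joint-histogram rows,
        # which leaves all three entropies unchanged
        from reconformer.metrics import _entropy_bits, _joint_hist

        a, b = rng.random(5000), rng.random(5000)
        pxy = _joint_hist(a, b, 16)
        perm = rng.permutation(16)
        permuted = pxy[perm, :]
        assert _entropy_bits(pxy.ravel()) == pytest.approx(
            _entropy_bits(permuted.ravel()), abs=1e-12)
        assert _entropy_bits(pxy.sum(axis=1)) == pytest.approx(
            _entropy_bits(permuted.sum(axis=1)), abs=1e-12)

    def test_constant_image_rejected(self):
        with pytest.raises(MetricError):
            nmi(_vol(np.ones((8, 8, 8))), _vol(np.zeros((8, 8, 8))))


class TestMutualInformation:
    def test_self_mi_equals_marginal_entropy(self, structured):
        ph, _ = structured
        from reconformer.metrics import _entropy_bits, _joint_hist

        h = _entropy_bits(_joint_hist(ph.data, ph.data, 32).sum(axis=1))
        assert mutual_information(ph, ph, bins=32) == pytest.approx(h, abs=1e-9)
        assert h > 0

    def test_invariant_to_affine_rescale(self, structured):
        ph, _ = structured
        scaled = ph.with_data(3.0 * ph.data + 10.0)
        a = mutual_information(ph, ph, bins=32)
        b = mutual_information(ph, scaled, bins=32)
        assert b == pytest.approx(a, abs=1e-6)

    def test_independent_volumes_near_zero(self):
        r1 = np.random.default_rng(0).random((64, 64, 64))
        r2 = np.random.default_rng(1).random((64, 64, 64))
        assert mutual_information(_vol(r1), _vol(r2), bins=32) < 0.05


class TestJSD:
    def test_identical_distributions_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jsd_hist(p, p) == 0.0

    def test_disjoint_support_is_one(self):
        assert jsd_hist(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == (
            pytest.approx(1.0, abs=1e-12))

    def test_hand_computed_value(self):
        assert jsd_hist(np.array([1.0, 0.0]), np.array([0.5, 0.5])) == (
            pytest.approx(0.3113, abs=1e-4))

    def test_symmetric_and_bounded_on_random_histograms(self, rng):
        for _ in range(20):
            p = rng.random(16); p /= p.sum()
            q = rng.random(16); q /= q.sum()
            d = jsd_hist(p, q)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(jsd_hist(q, p), abs=1e-12)

    def test_image_level_jsd_zero_for_identical(self, structured):
        ph, _ = structured
        assert jsd(ph, ph, bins=64) == pytest.approx(0.0, abs=1e-12)


class TestAES:
    def _step_image(self, h=2.0, ncols=32):
        img = np.zeros((32, ncols, 3))
        img[:, ncols // 2:, :] = h
        return _vol(img)

    def test_ideal_step_matches_prewitt_closed_form(self):
        # unnormalized 3x3 Prewitt on an ideal step of height h responds with
        # |G| = 3h at every edge pixel, so squared AES is exactly 9 h^2
        h = 2.0
        assert aes(self._step_image(h)) == pytest.approx(9 * h * h, rel=1e-9)

    def test_intensity_scaling_homogeneity(self):
        v = self._step_image(1.5)
        scaled = _vol(v.data * 4.0)
        assert aes(scaled) == pytest.approx(16.0 * aes(v), rel=1e-9)
        assert aes(scaled, exponent="magnitude") == pytest.approx(
            4.0 * aes(v, exponent="magnitude"), rel=1e-9)

    def test_uniform_image_raises(self):
        with pytest.raises(NoEdgesError):
            aes(_vol(np.full((16, 16, 4), 3.0)))

    def test_monotone_decrease_under_blur_ladder(self, structured):
        ph, _ = structured
        vals = [aes(_vol(ndimage.gaussian_filter(ph.data, s)))
                for s in (0.5, 1.0, 1.5, 2.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestNormalizedSharpness:
    def test_identical_pair_is_one(self, structured):
        ph, _ = structured
        assert normalized_sharpness(ph, ph) == pytest.approx(1.0, abs=1e-12)

    def test_blurred_reconstruction_below_one(self, structured):
        ph, _ = structured
        blurred = _vol(ndimage.gaussian_filter(ph.data, 1.5))
        assert normalized_sharpness(blurred, ph) < 1.0
        assert normalized_sharpness(ph, blurred) > 1.0


class TestSNRCNR:
    def _exact_case(self):
        # GM: 300 voxels at 120; WM: 100 at 80; background alternating +-5
        arr = np.zeros((10, 10, 10))
        labels = np.zeros((10, 10, 10), dtype=int)
        flat = arr.reshape(-1)
        lab = labels.reshape(-1)
        flat[:300] = 120.0; lab[:300] = 2
        flat[300:400] = 80.0; lab[300:400] = 3
        bg = np.arange(400, 1000)
        flat[bg] = np.where(bg % 2 == 0, 105.0, 95.0)  # mean 100, std 5
        masks = TissueMasks.from_labels(labels)
        return _vol(arr), masks

    def test_weighted_mean_snr(self):
        v, m = self._exact_case()
        # s = (120*300 + 80*100)/400 = 110, sigma = 5 -> SNR = 22
        assert snr(v, m) == pytest.approx(22.0, rel=1e-12)

    def test_cnr_from_tissue_means(self):
        v, m = self._exact_case()
        assert cnr(v, m) == pytest.approx(8.0, rel=1e-12)

    def test_scale_invariance(self):
        v, m = self._exact_case()
        doubled = _vol(v.data * 2.0)
        assert snr(doubled, m) == pytest.approx(snr(v, m), rel=1e-12)
        assert cnr(doubled, m) == pytest.approx(cnr(v, m), rel=1e-12)

    def test_swapping_gm_wm_leaves_cnr(self):
        v, m = self._exact_case()
        swapped = TissueMasks(gm=m.wm, wm=m.gm, csf=m.csf, background=m.background)
        assert cnr(v, swapped) == pytest.approx(cnr(v, m), rel=1e-12)

    def test_simple_arithmetic_case(self):
        labels = np.zeros((10, 10, 10), dtype=int)
        arr = np.zeros((10, 10, 10))
        arr.reshape(-1)[:400] = 100.0
        labels.reshape(-1)[:400] = 2
        bg = np.arange(400, 1000)
        arr.reshape(-1)[bg] = np.where(bg % 2 == 0, 5.0, -5.0)
        m = TissueMasks.from_labels(labels)
        assert snr(_vol(arr), m) == pytest.approx(20.0, rel=1e-12)


class TestSegmentation:
    def test_phantom_tissues_recovered(self, structured):
        ph, labels = structured
        noisy = _vol(ph.data + 0.02 * np.random.default_rng(0).standard_normal(ph.shape))
        masks = segment_simple(noisy, contrast="t2")
        truth = TissueMasks.from_labels(labels)
        assert dice(masks.gm, truth.gm) >= 0.9
        assert dice(masks.wm, truth.wm) >= 0.9
        assert dice(masks.csf, truth.csf) >= 0.9

    def test_all_background_rejected(self):
        with pytest.raises(MetricError):
            segment_simple(_vol(np.zeros((16, 16, 16))))

    def test_masks_satisfy_invariants(self, structured):
        ph, _ = structured
        masks = segment_simple(ph)
        tissue = (masks.gm > 0) | (masks.wm > 0) | (masks.csf > 0)
        assert not np.any(tissue & (masks.background > 0))
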