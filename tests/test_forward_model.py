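"""Acquisition-model operators: slice blur, decimation, transforms, noise."""

import numpy as np
import pytest
from scipy import ndimage

from reconformer import (
    AcquisitionGeometry,
    DegradeOperator,
    RigidTransform,
    Volume,
    add_noise,
    apply_transform,
    blur_along_axis,
    degrade,
    downsample_freq,
    make_slice_kernel,
)
from reconformer.forward_model import FWHM_TO_SIGMA, BlurKernel, _decimate_freq_1d
from reconformer.volume import VolumeError


class TestSliceKernel:
    @pytest.mark.parametrize(
        "thickness,inplane,expected_sigma",
        [(2.0, 0.5, (2.0 / FWHM_TO_SIGMA) / 0.5),  # ~1.6986
         (0.5, 0.5, (0.5 / FWHM_TO_SIGMA) / 0.5)],  # ~0.4247, near-delta
    )
    def test_sigma_from_fwhm(self, thickness, inplane, expected_sigma):
        g = AcquisitionGeometry(1, thickness, inplane)
        k = make_slice_kernel(g)
        assert k.sigma_voxels == pytest.approx(expected_sigma, rel=1e-12)
        assert k.axis == 1

    def test_taps_normalized_symmetric_odd(self):
        for thickness in (1.0, 1.5, 2.0, 2.5, 3.0):
            k = make_slice_kernel(AcquisitionGeometry(0, thickness, 0.5))
            assert len(k.taps) % 2 == 1
            assert k.taps.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(k.taps, k.taps[::-1], atol=1e-15)

    def test_blur_preserves_constant(self):
        v = Volume(np.full((8, 8, 16), 4.2), spacing=(0.5, 0.5, 0.5))
        k = make_slice_kernel(AcquisitionGeometry(2, 2.0, 0.5))
        np.testing.assert_allclose(blur_along_axis(v, k).data, 4.2, atol=1e-12)

    def test_delta_kernel_is_identity(self, rng):
        v = Volume(rng.random((8, 8, 8)), spacing=(1, 1, 1))
        k = BlurKernel(taps=np.array([1.0]), axis=0, sigma_voxels=0.0)
        np.testing.assert_array_equal(blur_along_axis(v, k).data, v.data)

    def test_impulse_response_reproduces_taps(self):
        g = AcquisitionGeometry(2, 2.0, 0.5)
        k = make_slice_kernel(g)
        data = np.zeros((4, 4, 33))
        data[2, 2, 16] = 1.0
        out = blur_along_axis(Volume(data, spacing=(0.5,) * 3), k).data
        r = len(k.taps) // 2
        np.testing.assert_allclose(out[2, 2, 16 - r:16 + r + 1], k.taps, atol=1e-14)
        assert np.all(out[0, 0, :] == 0)

    def test_kernel_longer_than_axis_rejected(self):
        v = Volume(np.zeros((4, 4, 4)), spacing=(0.5,) * 3)
        k = make_slice_kernel(AcquisitionGeometry(2, 3.0, 0.5))
        with pytest.raises(VolumeError):
            blur_along_axis(v, k)


class TestRigidTransform:
    def test_compose_with_inverse_is_identity(self):
        t = RigidTransform(rotation=(0.1, -0.2, 0.05), translation=(3, -1, 2),
                           center=(10, 12, 8))
        c = t.compose(t.inverse())
        assert max(abs(a) for a in c.rotation) < 1e-9
        assert max(abs(a) for a in c.translation) < 1e-9

    def test_identity_transform_is_noop(self, rng):
        v = Volume(rng.random((8, 8, 8)), spacing=(1, 1, 1))
        np.testing.assert_allclose(
            apply_transform(v, RigidTransform.identity()).data, v.data, atol=1e-9
        )

    def test_one_voxel_translation_equals_roll(self, rng):
        data = rng.standard_normal((12, 12, 12))
        v = Volume(data, spacing=(1, 1, 1))
        t = RigidTransform(translation=(1.0, 0.0, 0.0))
        out = apply_transform(v, t, "trilinear")
        np.testing.assert_array_equal(out.data[1:], np.roll(data, 1, axis=0)[1:])

    def test_round_trip_on_smooth_volume(self, phantom48):
        ph, _ = phantom48
        smooth = ph.with_data(ndimage.gaussian_filter(ph.data, 2.0))
        t = RigidTransform(rotation=(0.02, -0.01, 0.03), translation=(1, -2, 0.5),
                           center=(24, 24, 24))
        back = apply_transform(apply_transform(smooth, t, "bspline3"),
                               t.inverse(), "bspline3")
        interior = (slice(8, -8),) * 3
        err = np.abs(back.data - smooth.data)[interior].max()
        drange = smooth.data.max() - smooth.data.min()
        assert err < 1e-2 * drange


class TestDownsampleFreq:
    def test_constant_preserved(self):
        for f in (1, 2, 4):
            g = AcquisitionGeometry(2, 0.5 * f, 0.5)
            v = Volume(np.full((4, 4, 16), 3.7), spacing=(0.5,) * 3)
            out = downsample_freq(v, g)
            assert out.shape[2] == 16 // f
            np.testing.assert_allclose(out.data, 3.7, atol=1e-12)

    def test_factor_one_is_identity(self, rng):
        v = Volume(rng.random((6, 6, 8)), spacing=(0.5,) * 3)
        out = downsample_freq(v, AcquisitionGeometry(2, 0.5, 0.5))
        np.testing.assert_allclose(out.data, v.data, atol=1e-12)

    def test_band_limited_cosine_decimates_to_analytic_samples(self):
        N, f, q = 32, 4, 3  # |q| < N/(2f) = 4: strictly inside the band
        n = np.arange(N)
        data = np.broadcast_to(np.cos(2 * np.pi * q * n / N), (4, 4, N)).copy()
        v = Volume(data, spacing=(0.5,) * 3)
        out = downsample_freq(v, AcquisitionGeometry(2, 2.0, 0.5))
        coarse = np.cos(2 * np.pi * q * (f * np.arange(N // f)) / N)
        np.testing.assert_allclose(out.data, np.broadcast_to(coarse, (4, 4, N // f)),
                                   atol=1e-9)

    def test_band_limited_signal_equals_subsampling_oracle(self, rng):
        # a signal supported strictly inside the retained band is unchanged
        # by band truncation, so decimation must equal plain subsampling
        N, f = 24, 3
        m = N // f
        spec = np.zeros(N, dtype=complex)
        for q in range(1, (m - 1) // 2 + 1):
            c = rng.standard_normal() + 1j * rng.standard_normal()
            spec[q], spec[N - q] = c, np.conj(c)
        spec[0] = rng.standard_normal()
        x = np.real(np.fft.ifft(spec))
        out = _decimate_freq_1d(np.broadcast_to(x, (3, 3, N)).copy(), 2, f)
        np.testing.assert_allclose(out, np.broadcast_to(x[::f], (3, 3, m)),
                                   atol=1e-6)

    def test_non_divisible_extent_padded(self):
        v = Volume(np.full((4, 4, 10), 1.0), spacing=(0.5,) * 3)
        out = downsample_freq(v, AcquisitionGeometry(2, 1.5, 0.5))  # factor 3
        assert out.shape[2] == 4  # padded 10 -> 12, then / 3

    def test_output_spacing_scaled(self):
        v = Volume(np.zeros((4, 4, 16)), spacing=(0.5, 0.5, 0.5))
        out = downsample_freq(v, AcquisitionGeometry(2, 2.0, 0.5))
        assert out.spacing == (0.5, 0.5, 2.0)


class TestNoise:
    def test_zero_sigma_identity(self, rng):
        v = Volume(rng.random((8, 8, 8)), spacing=(1, 1, 1))
        np.testing.assert_array_equal(add_noise(v, 0.0, 3).data, v.data)

    def test_same_seed_reproducible(self, rng):
        v = Volume(rng.random((8, 8, 8)), spacing=(1, 1, 1))
        a = add_noise(v, 0.1, 42)
        b = add_noise(v, 0.1, 42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_sample_sigma_matches_specification(self):
        v = Volume(np.full((100, 100, 100), 100.0), spacing=(1, 1, 1))
        out = add_noise(v, 0.1, 7)
        sd = (out.data - v.data).std()
        assert 9.9 <= sd <= 10.1

    def test_negative_sigma_rejected(self):
        v = Volume(np.zeros((4, 4, 4)), spacing=(1, 1, 1))
        with pytest.raises(VolumeError):
            add_noise(v, -0.1, 0)


class TestDegradeOperator:
    def setup_method(self):
        self.geom = AcquisitionGeometry(2, 2.0, 0.5)
        self.op = DegradeOperator((8, 8, 8), (0.5,) * 3, self.geom)

    def test_linearity_superposition(self, rng):
        x1, x2 = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        a, b = 2.3, -0.7
        lhs = self.op.forward(a * x1 + b * x2)
        rhs = a * self.op.forward(x1) + b * self.op.forward(x2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_adjoint_identity(self, rng):
        x = rng.standard_normal((8, 8, 8))
        y = rng.standard_normal(self.op.lr_shape)
        lhs = np.vdot(self.op.forward(x), y)
        rhs = np.vdot(x, self.op.adjoint(y))
        assert abs(lhs - rhs) <= 1e-6 * max(abs(lhs), abs(rhs))

    def test_matches_dense_matrix(self, rng):
        A = self.op.dense()
        x = rng.standard_normal((8, 8, 8))
        np.testing.assert_allclose(A @ x.ravel(), self.op.forward(x).ravel(),
                                   atol=1e-8)

    def test_output_axis_length(self):
        assert self.op.lr_shape == (8, 8, 2)

    def test_degenerate_pipeline_close_to_input(self, phantom48):
        ph, _ = phantom48
        smooth = ph.with_data(ndimage.gaussian_filter(ph.data, 1.5))
        g = AcquisitionGeometry(2, 1.0, 1.0)  # factor 1, near-delta blur
        out = degrade(smooth, g)
        assert out.shape == smooth.shape
        err = np.abs(out.data - smooth.data).max()
        assert err < 0.1 * (smooth.data.max() - smooth.data.min())

    def test_degrade_with_transform_has_exact_adjoint(self, rng):
        t = RigidTransform(rotation=(0.05, 0.0, -0.03), translation=(0.7, -0.4, 0.2),
                           center=(2.0, 2.0, 2.0))
        op = DegradeOperator((8, 8, 8), (0.5,) * 3, self.geom, transform=t)
        x = rng.standard_normal((8, 8, 8))
        y = rng.standard_normal(op.lr_shape)
        lhs = np.vdot(op.forward(x), y)
        rhs = np.vdot(x, op.adjoint(y))
        assert abs(lhs - rhs) <= 1e-6 * max(abs(lhs), abs(rhs), 1e-12)
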