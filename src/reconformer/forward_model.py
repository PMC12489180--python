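"""Forward acquisition model for multi-orientation thick-slice MRI.

A low-resolution stack y is modelled from the high-resolution volume x as

    y = D ( b * (m o x) ) + e

where ``m`` is a rigid head-pose transform, ``b`` a 1-D Gaussian slice
profile whose FWHM equals the slice thickness, ``D`` frequency-domain
decimation along the slice-select axis, and ``e`` additive Gaussian noise.
With noise off the map is linear; :class:`DegradeOperator` exposes the exact
matrix-free forward and adjoint used by both reconstruction methods.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, sparse
from scipy.spatial.transform import Rotation

from .volume import AcquisitionGeometry, Volume, VolumeError

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = 2*sqrt(2 ln 2) * sigma


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid map ``T(p) = R (p - c) + c + t`` in world mm.

    ``rotation`` holds fixed-axes XYZ Euler angles in radians, ``translation``
    the shift ``t`` in mm and ``center`` the rotation centre ``c``.
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation).as_matrix()

    def as_homogeneous(self) -> np.ndarray:
        """4x4 world-space matrix of the forward map."""
        R = self.matrix
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        H = np.eye(4)
        H[:3, :3] = R
        H[:3, 3] = c + t - R @ c
        return H

    def inverse(self) -> "RigidTransform":
        R = Rotation.from_euler("xyz", self.rotation)
        Rinv = R.inv()
        t = np.asarray(self.translation)
        return RigidTransform(
            rotation=tuple(Rinv.as_euler("xyz")),
            translation=tuple(-(Rinv.as_matrix() @ t)),
            center=self.center,
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other (apply ``other`` first), centred at other.center."""
        H = self.as_homogeneous() @ other.as_homogeneous()
        R = H[:3, :3]
        c = np.asarray(other.center)
        rot = Rotation.from_matrix(R)
        # T(p) = R(p - c) + c + t  =>  t = H c + H_t ... solve from H @ [c,1]
        t = (H @ np.r_[c, 1.0])[:3] - c
        return RigidTransform(
            rotation=tuple(rot.as_euler("xyz")),
            translation=tuple(t),
            center=tuple(c),
        )

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            max(abs(a) for a in self.rotation) <= tol
            and max(abs(a) for a in self.translation) <= tol
        )


# ---------------------------------------------------------------------------
# slice-profile blur
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlurKernel:
    """1-D Gaussian slice-profile kernel on the HR lattice."""

    taps: np.ndarray
    axis: int
    sigma_voxels: float

    def __post_init__(self) -> None:
        taps = np.asarray(self.taps, dtype=np.float64)
        object.__setattr__(self, "taps", taps)
        if taps.ndim != 1 or len(taps) % 2 != 1:
            raise VolumeError("kernel taps must be 1-D with odd length")
        if np.any(taps < 0) or abs(taps.sum() - 1.0) > 1e-12:
            raise VolumeError("kernel taps must be nonnegative and sum to 1")
        if not np.allclose(taps, taps[::-1], atol=1e-12):
            raise VolumeError("kernel taps must be symmetric")


def make_slice_kernel(geom: AcquisitionGeometry, truncate: float = 4.0) -> BlurKernel:
    """Gaussian slice profile with FWHM equal to the slice thickness.

    The kernel lives on the HR lattice (sigma expressed in in-plane voxels)
    and is truncated at ``truncate`` sigma, rounded up to an odd length, then
    renormalized to unit sum.
    """
    sigma_mm = geom.slice_thickness / FWHM_TO_SIGMA
    sigma_vox = sigma_mm / geom.inplane_spacing
    radius = max(1, int(np.ceil(truncate * sigma_vox)))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    taps = np.exp(-0.5 * (x / sigma_vox) ** 2)
    taps /= taps.sum()
    return BlurKernel(taps=taps, axis=geom.slice_axis, sigma_voxels=sigma_vox)


def blur_along_axis(vol: Volume, k: BlurKernel) -> Volume:
    """1-D convolution along the kernel axis with reflective boundaries."""
    if len(k.taps) > vol.shape[k.axis]:
        raise VolumeError("kernel longer than the volume axis")
    out = ndimage.correlate1d(vol.data, k.taps, axis=k.axis, mode="reflect")
    return vol.with_data(out)


# ---------------------------------------------------------------------------
# frequency-domain decimation
# ---------------------------------------------------------------------------


def _decimate_freq_1d(arr: np.ndarray, axis: int, factor: int) -> np.ndarray:
    """Keep the central 1/factor frequency band along ``axis``, scale so
    constants are preserved, and return the N/factor grid. At the Nyquist tie
    the positive-frequency bin is kept."""
    n = arr.shape[axis]
    m = n // factor
    X = np.fft.fft(arr, axis=axis)
    idx_out = np.arange(m)
    freq = np.where(idx_out < (m + 1) // 2, idx_out, idx_out - m)
    if m % 2 == 0:
        freq = np.where(idx_out == m // 2, m // 2, freq)  # positive Nyquist bin
    src = np.mod(freq, n)
    Y = np.take(X, src, axis=axis)
    y = np.fft.ifft(Y, axis=axis) * (m / n)
    return np.real(y)


def downsample_freq(vol: Volume, geom: AcquisitionGeometry) -> Volume:
    """Frequency-domain downsampling along the slice-select axis.

    Axis extents not divisible by the factor are zero-padded symmetrically to
    the next multiple first. Output spacing along the axis is multiplied by
    the factor; DC is preserved exactly.
    """
    f = geom.factor
    axis = geom.slice_axis
    n = vol.shape[axis]
    if f > n:
        raise VolumeError(f"factor {f} exceeds axis extent {n}")
    data = vol.data
    pad_before = 0
    if n % f != 0:
        total = f - n % f
        pad_before = total // 2
        pads = [(0, 0)] * 3
        pads[axis] = (pad_before, total - pad_before)
        data = np.pad(data, pads)
    if f == 1:
        out = data
    else:
        out = _decimate_freq_1d(data, axis, f)
    new_spacing = list(vol.spacing)
    new_spacing[axis] *= f
    new_affine = vol.affine.copy()
    new_affine[:3, axis] *= f
    # symmetric zero-padding shifts the origin by -pad_before fine voxels
    new_affine[:3, 3] -= vol.affine[:3, axis] * pad_before
    return Volume(data=out, spacing=tuple(new_spacing), affine=new_affine)


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------


def add_noise(vol: Volume, sigma_fraction: float, seed: int) -> Volume:
    """Add i.i.d. Gaussian noise with sigma = sigma_fraction * max(vol)."""
    if sigma_fraction < 0:
        raise VolumeError("sigma_fraction must be nonnegative")
    if sigma_fraction == 0:
        return vol.with_data(vol.data.copy())
    sigma = sigma_fraction * float(vol.data.max())
    rng = np.random.default_rng(seed)
    return vol.with_data(vol.data + rng.normal(0.0, sigma, size=vol.shape))


# ---------------------------------------------------------------------------
# rigid resampling
# ---------------------------------------------------------------------------


def _voxel_map(vol: Volume, t: RigidTransform) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-space pull map of ``t``: output voxel v -> input voxel coords."""
    Hinv = t.inverse().as_homogeneous()
    A = vol.affine
    V = np.linalg.inv(A) @ Hinv @ A
    return V[:3, :3], V[:3, 3]


def apply_transform(
    vol: Volume, t: RigidTransform, interpolation: str = "trilinear"
) -> Volume:
    """Resample ``vol`` through the rigid map on its own lattice.

    The value at world point ``w`` of the output is ``vol`` at ``t^{-1}(w)``
    (the object moves by ``t``); out-of-field voxels are zero.
    """
    if t.is_identity():
        return vol.with_data(vol.data.copy())
    order = {"trilinear": 1, "bspline3": 3}[interpolation]
    matrix, offset = _voxel_map(vol, t)
    out = ndimage.affine_transform(
        vol.data, matrix, offset=offset, order=order, mode="constant", cval=0.0
    )
    return vol.with_data(out)


def _transform_matrix(vol: Volume, t: RigidTransform) -> sparse.csr_matrix:
    """Sparse trilinear interpolation matrix of :func:`apply_transform`."""
    shape = vol.shape
    matrix, offset = _voxel_map(vol, t)
    grid = np.indices(shape).reshape(3, -1).T.astype(np.float64)
    src = grid @ matrix.T + offset
    base = np.floor(src).astype(np.int64)
    frac = src - base
    n_out = grid.shape[0]
    rows, cols, vals = [], [], []
    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        idx = base + off
        w = np.prod(np.where(off == 1, frac, 1.0 - frac), axis=1)
        ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1) & (w > 0)
        flat = np.ravel_multi_index(idx[ok].T, shape)
        rows.append(np.nonzero(ok)[0])
        cols.append(flat)
        vals.append(w[ok])
    return sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_out, int(np.prod(shape))),
    )


# ---------------------------------------------------------------------------
# composed linear degradation operator
# ---------------------------------------------------------------------------


def _axis_matvec(mat: np.ndarray, arr: np.ndarray, axis: int) -> np.ndarray:
    """Apply a 1-D operator matrix along one axis of a 3-D array."""
    moved = np.moveaxis(arr, axis, 0)
    out = np.tensordot(mat, moved, axes=(1, 0))
    return np.moveaxis(out, 0, axis)


class DegradeOperator:
    """Matrix-free linear operator A for one stack (noise off).

    ``forward`` maps an HR array to the LR stack array; ``adjoint`` is the
    exact transpose, used for gradients of the data-consistency term. The 1-D
    blur and decimation stages are materialized as small per-axis matrices
    built from the same routines as the public functions, so forward/adjoint
    agree with them to machine precision.
    """

    def __init__(
        self,
        hr_shape: tuple[int, int, int],
        hr_spacing: tuple[float, float, float],
        geom: AcquisitionGeometry,
        transform: RigidTransform | None = None,
        kernel_truncate: float = 4.0,
    ):
        self.hr_shape = tuple(hr_shape)
        self.hr_spacing = tuple(hr_spacing)
        self.geom = geom
        self.transform = transform or RigidTransform.identity()
        axis = geom.slice_axis
        n = self.hr_shape[axis]
        f = geom.factor
        kern = make_slice_kernel(geom, truncate=kernel_truncate)
        eye = np.eye(n)
        self._B = ndimage.correlate1d(eye, kern.taps, axis=0, mode="reflect")
        # symmetric zero-pad to the next multiple of the factor, then decimate;
        # the composed 1-D operator stays an explicit (exactly adjointable) matrix
        n_pad = int(np.ceil(n / f) * f)
        pad_before = (n_pad - n) // 2
        P = np.zeros((n_pad, n))
        P[pad_before : pad_before + n, :] = eye
        self._D = _decimate_freq_1d(np.eye(n_pad), 0, f) @ P if f > 1 else eye
        self._axis = axis
        ref = Volume(np.zeros(self.hr_shape), self.hr_spacing)
        self._W = (
            None if self.transform.is_identity() else _transform_matrix(ref, self.transform)
        )
        self.lr_shape = tuple(
            self._D.shape[0] if i == axis else m for i, m in enumerate(self.hr_shape)
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self._W is not None:
            x = (self._W @ x.ravel()).reshape(self.hr_shape)
        x = _axis_matvec(self._B, x, self._axis)
        return _axis_matvec(self._D, x, self._axis)

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        x = _axis_matvec(self._D.T, y, self._axis)
        x = _axis_matvec(self._B.T, x, self._axis)
        if self._W is not None:
            x = (self._W.T @ x.ravel()).reshape(self.hr_shape)
        return x

    def dense(self) -> np.ndarray:
        """Explicit matrix (rows = LR voxels), for small-grid verification."""
        n_in = int(np.prod(self.hr_shape))
        cols = []
        e = np.zeros(n_in)
        for j in range(n_in):
            e[j] = 1.0
            cols.append(self.forward(e.reshape(self.hr_shape)).ravel())
            e[j] = 0.0
        return np.array(cols).T

    def lr_spacing(self) -> tuple[float, float, float]:
        s = list(self.hr_spacing)
        s[self._axis] *= self.geom.factor
        return tuple(s)


def degrade(
    x: Volume,
    geom: AcquisitionGeometry,
    t: RigidTransform | None = None,
    sigma_fraction: float = 0.0,
    seed: int = 0,
    kernel_truncate: float = 4.0,
) -> Volume:
    """Simulate one LR stack: transform, blur, decimate, then noise."""
    op = DegradeOperator(
        x.shape, x.spacing, geom, transform=t, kernel_truncate=kernel_truncate
    )
    lr = op.forward(x.data)
    new_spacing = op.lr_spacing()
    new_affine = x.affine.copy()
    new_affine[:3, geom.slice_axis] *= geom.factor
    out = Volume(data=lr, spacing=new_spacing, affine=new_affine)
    if sigma_fraction > 0:
        out = add_noise(out, sigma_fraction, seed)
    return out
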