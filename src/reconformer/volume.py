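"""Canonical 3-D volume container, NIfTI I/O and lattice resampling.

Every image in the pipeline is a :class:`Volume`: a 3-D intensity grid with
per-axis voxel spacing in millimetres and a 4x4 voxel-to-world affine. All
in-memory volumes live in canonical RAS orientation with 0-based voxel
indices; orientation juggling happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class VolumeError(ValueError):
    """Invalid volume construction or a degenerate volume operation."""


class FormatError(VolumeError):
    """A file on disk is not a usable single-image 3-D NIfTI."""


_INTERP_ORDER = {"nearest": 0, "trilinear": 1, "bspline3": 3}


@dataclass
class Volume:
    """A 3-D image with physical spacing and a world affine.

    Parameters
    ----------
    data:
        3-D floating point intensity array (arbitrary units).
    spacing:
        Per-axis voxel size in mm, positive.
    affine:
        4x4 voxel-index -> world-mm map. The column norms of the upper-left
        3x3 block must equal ``spacing``.
    intensity_range:
        ``(min, max)`` of the original intensities, recorded by
        :func:`normalize_unit` so the scaling can be inverted exactly.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]
    intensity_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeError(f"volume data must be 3-D, got {self.data.ndim} axes")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise VolumeError("affine must be 4x4")
        col_norms = np.linalg.norm(self.affine[:3, :3], axis=0)
        if not np.allclose(col_norms, self.spacing, atol=1e-6):
            raise VolumeError(
                f"affine column norms {col_norms} inconsistent with spacing {self.spacing}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same geometry, new intensities (shape must match)."""
        if np.shape(data) != self.shape:
            raise VolumeError("with_data requires matching shape")
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        homog = np.c_[ijk, np.ones(len(ijk))]
        return (self.affine @ homog.T).T[:, :3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(xyz)
        inv = np.linalg.inv(self.affine)
        homog = np.c_[xyz, np.ones(len(xyz))]
        return (inv @ homog.T).T[:, :3]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Slice geometry of one thick-slice stack.

    The downsampling factor is the ratio of through-plane to in-plane
    resolution; non-integer ratios are rejected because the frequency-domain
    decimation is defined for integer factors only.
    """

    slice_axis: int
    slice_thickness: float
    inplane_spacing: float

    def __post_init__(self) -> None:
        if self.slice_axis not in (0, 1, 2):
            raise VolumeError(f"slice_axis must be 0, 1 or 2, got {self.slice_axis}")
        if self.slice_thickness <= 0 or self.inplane_spacing <= 0:
            raise VolumeError("thickness and spacing must be positive")
        ratio = self.slice_thickness / self.inplane_spacing
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise VolumeError(
                f"thickness/in-plane ratio {ratio} is not a positive integer"
            )

    @property
    def factor(self) -> int:
        return int(round(self.slice_thickness / self.inplane_spacing))


def read_nifti(path: str | Path) -> Volume:
    """Read a single-image 3-D NIfTI, reorienting to canonical RAS."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 3:
        raise FormatError(f"expected a 3-D image, file has {img.ndim} dimensions")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing=spacing, affine=np.asarray(img.affine))


def write_nifti(vol: Volume, path: str | Path) -> None:
    """Write a volume as float32 NIfTI-1 with its spacing and affine."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def resample_to_lattice(
    vol: Volume,
    target_spacing: tuple[float, float, float],
    target_shape: tuple[int, int, int],
    interpolation: str = "trilinear",
) -> Volume:
    """Resample onto a new lattice covering the same world extent.

    The output lattice shares the input's world origin and axis directions;
    only spacing and shape change. Intensities are interpolated with the
    named scheme (``nearest`` | ``trilinear`` | ``bspline3``).
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    target_shape = tuple(int(n) for n in target_shape)
    if any(s <= 0 for s in target_spacing):
        raise VolumeError("target spacing must be positive")
    if any(n <= 0 for n in target_shape):
        raise VolumeError("target shape must be positive")
    order = _INTERP_ORDER[interpolation]
    if target_spacing == vol.spacing and target_shape == vol.shape:
        return replace(vol, data=vol.data.copy())
    # voxel map: out index j -> in index j * (target_spacing / spacing)
    zoom = np.array(target_spacing) / np.array(vol.spacing)
    matrix = np.diag(zoom)
    out = ndimage.affine_transform(
        vol.data, matrix, output_shape=target_shape, order=order, mode="nearest"
    )
    new_affine = vol.affine.copy()
    scale = np.array(target_spacing) / np.array(vol.spacing)
    new_affine[:3, :3] = vol.affine[:3, :3] * scale[np.newaxis, :]
    return Volume(data=out, spacing=target_spacing, affine=new_affine)


def normalize_unit(vol: Volume) -> Volume:
    """Map intensities affinely onto [0, 1], recording (min, max)."""
    data = vol.data
    if not np.all(np.isfinite(data)):
        raise VolumeError("volume has non-finite intensities")
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        raise VolumeError("constant volume cannot be unit-normalized")
    scaled = (data - lo) / (hi - lo)
    return replace(vol, data=scaled, intensity_range=(lo, hi))


def denormalize(vol: Volume) -> Volume:
    """Invert :func:`normalize_unit` using the recorded intensity range."""
    if vol.intensity_range is None:
        raise VolumeError("volume has no recorded intensity range")
    lo, hi = vol.intensity_range
    return replace(vol, data=vol.data * (hi - lo) + lo, intensity_range=None)
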