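"""Rigid alignment of the low-resolution stacks into a common frame.

The recipe is mutual information as the similarity criterion, third-order
B-spline interpolation during resampling, and Powell's derivative-free
optimizer, run coarse-to-fine. ``register_rigid``/``register_group`` are
backed by SimpleITK's registration framework (Mattes MI with full voxel
sampling, so runs are deterministic); ``mutual_information`` itself is a
plain dense-joint-histogram implementation usable as a standalone score.

In simulated pipelines the ground-truth poses are known and registration
can be bypassed entirely, which isolates reconstruction behaviour from
registration error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy.spatial.transform import Rotation

from .forward_model import RigidTransform
from .metrics import mutual_information  # noqa: F401  (re-exported, shared impl)
from .volume import Volume, VolumeError


@dataclass(frozen=True)
class RegistrationConfig:
    histogram_bins: int = 32
    max_iterations: int = 200
    parameter_tolerance: float = 1e-6
    multiresolution_levels: tuple[int, ...] = (4, 2, 1)

    def __post_init__(self) -> None:
        if self.histogram_bins < 8:
            raise VolumeError("histogram_bins must be >= 8")
        if self.parameter_tolerance <= 0:
            raise VolumeError("tolerances must be positive")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    final_metric: float
    converged: bool


def _to_sitk(vol: Volume) -> sitk.Image:
    # SimpleITK arrays are indexed [z, y, x]
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.affine[:3, 3]))
    direction = vol.affine[:3, :3] / np.array(vol.spacing)[np.newaxis, :]
    img.SetDirection(tuple(direction.ravel()))
    return img


def _from_euler3d(t: sitk.Euler3DTransform) -> RigidTransform:
    R = np.array(t.GetMatrix()).reshape(3, 3)
    return RigidTransform(
        rotation=tuple(Rotation.from_matrix(R).as_euler("xyz")),
        translation=tuple(t.GetTranslation()),
        center=tuple(t.GetCenter()),
    )


def register_rigid(
    fixed: Volume, moving: Volume, cfg: RegistrationConfig = RegistrationConfig()
) -> RegistrationResult:
    """Estimate the rigid pose of ``moving`` relative to ``fixed``.

    Returns the transform in the same convention the forward model uses: if
    ``moving`` shows the object displaced by ``t`` relative to ``fixed``,
    the recovered transform is ``t``.
    """
    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=cfg.histogram_bins)
    reg.SetMetricSamplingStrategy(reg.NONE)  # full sampling: deterministic
    reg.SetInterpolator(sitk.sitkBSpline)
    reg.SetOptimizerAsPowell(
        numberOfIterations=cfg.max_iterations,
        maximumLineIterations=50,
        stepLength=1.0,
        stepTolerance=cfg.parameter_tolerance,
        valueTolerance=cfg.parameter_tolerance,
    )
    levels = list(cfg.multiresolution_levels)
    reg.SetShrinkFactorsPerLevel(levels)
    reg.SetSmoothingSigmasPerLevel([max(0.0, lv / 2.0) for lv in levels])
    reg.SetSmoothingSigmasAreSpecifiedInPhysicalUnits(False)
    init = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg.SetInitialTransform(init, inPlace=True)
    final = reg.Execute(f_img, m_img)
    euler = sitk.Euler3DTransform(final)
    converged = "Convergence" in reg.GetOptimizerStopConditionDescription() or (
        reg.GetOptimizerIteration() < cfg.max_iterations
    )
    return RegistrationResult(
        transform=_from_euler3d(euler),
        final_metric=float(reg.GetMetricValue()),
        converged=bool(converged),
    )


def register_group(
    stacks: list[Volume],
    geoms=None,
    cfg: RegistrationConfig = RegistrationConfig(),
    reference_index: int = 0,
) -> list[RigidTransform]:
    """Register every stack to the reference stack (star topology).

    The reference stack (first by default) defines the common frame and gets
    the identity transform.
    """
    if not stacks:
        raise VolumeError("at least one stack required")
    out: list[RigidTransform] = []
    ref = stacks[reference_index]
    for i, s in enumerate(stacks):
        if i == reference_index:
            out.append(RigidTransform.identity())
        else:
            out.append(register_rigid(ref, s, cfg).transform)
    return out


def transform_to_text(t: RigidTransform) -> str:
    """Serialize as a 4x4 world matrix plus the 6-parameter vector."""
    H = t.as_homogeneous()
    lines = [" ".join(f"{v:.12g}" for v in row) for row in H]
    params = list(t.rotation) + list(t.translation)
    lines.append("# params(rx ry rz tx ty tz): " + " ".join(f"{v:.12g}" for v in params))
    lines.append("# center: " + " ".join(f"{v:.12g}" for v in t.center))
    return "\n".join(lines) + "\n"


def transform_from_text(text: str) -> RigidTransform:
    rot = trans = center = None
    for line in text.strip().splitlines():
        if line.startswith("# params"):
            vals = [float(v) for v in line.split(":")[1].split()]
            rot, trans = tuple(vals[:3]), tuple(vals[3:])
        elif line.startswith("# center"):
            center = tuple(float(v) for v in line.split(":")[1].split())
    if rot is None or center is None:
        raise VolumeError("malformed transform file")
    return RigidTransform(rotation=rot, translation=trans, center=center)
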