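"""Procedural brain-like digital phantom and thick-slice study simulation.

The phantom is a nested-ellipsoid head: an outer CSF envelope, a cortical
grey-matter band, a white-matter core with embedded CSF ventricles, all with
seeded lobular boundary perturbations so the image carries structure at many
scales. Tissue intensities are piecewise constant and exactly consistent
with the emitted label masks, which is what makes the phantom usable as
ground truth for segmentation, registration and reconstruction tests.

``simulate_study`` degrades the phantom into multi-orientation thick-slice
stacks through the forward acquisition model, with per-stack Gaussian noise
at a stated fraction of each stack's maximum intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .forward_model import RigidTransform, degrade
from .volume import AcquisitionGeometry, Volume, VolumeError

PLANE_AXES = {"axial": 2, "coronal": 1, "sagittal": 0}

# T2-like contrast: CSF bright, WM dark. T1-like reverses CSF/WM ordering.
T2_MEANS = {"background": 0.0, "csf": 1.0, "gm": 0.55, "wm": 0.3}
T1_MEANS = {"background": 0.0, "csf": 0.12, "gm": 0.55, "wm": 0.85}


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one procedural phantom."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    means: dict = field(default_factory=lambda: dict(T2_MEANS))
    lobular_amplitude: float = 0.07
    cortical_band: float = 0.16  # GM band thickness, fraction of head radius
    csf_rim: float = 0.08  # outer CSF rim thickness, fraction of head radius
    contrast: str = "t2"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 32 for s in self.shape):
            raise VolumeError("phantom shape must be at least 32 per axis")
        if len(set(self.means.values())) != 4:
            raise VolumeError("the four tissue means must be distinct")


@dataclass
class StackRecord:
    """Provenance of one simulated LR stack."""

    volume: Volume
    geometry: AcquisitionGeometry
    transform: RigidTransform
    plane: str
    noise_seed: int
    sigma_fraction: float


@dataclass
class SimulatedStudy:
    """Ground truth plus the simulated stacks and their manifest."""

    ground_truth: Volume
    labels: np.ndarray  # 0 background, 1 CSF, 2 GM, 3 WM
    stacks: list[StackRecord]
    manifest: dict


def _smooth_angular_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Seeded smooth random field in [-1, 1] for lobular perturbations."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="wrap")
    peak = np.abs(smooth).max()
    return smooth / peak if peak > 0 else smooth


def make_phantom(spec: PhantomSpec) -> tuple[Volume, np.ndarray]:
    """Build the phantom; returns (volume, integer label map).

    Labels: 0 background, 1 CSF, 2 grey matter, 3 white matter. The volume's
    intensities equal ``spec.means`` exactly on each label.
    """
    rng = np.random.default_rng(spec.seed)
    shape = np.array(spec.shape)
    coords = np.indices(spec.shape).astype(np.float64)
    centre = (shape - 1) / 2.0
    # anisotropic head: normalized ellipsoidal radius in [0, ~sqrt(3)]
    semi = shape / 2.0 * np.array([0.92, 0.80, 0.86])
    u = [(coords[i] - centre[i]) / semi[i] for i in range(3)]
    r = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    # lobular perturbation: modulate the radius with a smooth seeded field
    bump = _smooth_angular_field(rng, spec.shape, sigma=min(spec.shape) / 8.0)
    r_mod = r * (1.0 + spec.lobular_amplitude * bump)

    labels = np.zeros(spec.shape, dtype=np.int8)
    head = r_mod <= 1.0
    labels[head] = 1  # CSF envelope
    inner = r_mod <= 1.0 - spec.csf_rim
    labels[inner] = 2  # cortical GM band
    core = r_mod <= 1.0 - spec.csf_rim - spec.cortical_band
    labels[core] = 3  # WM core

    # ventricles: two CSF ellipsoids inside the WM core, mirrored about x
    for sign in (-1.0, 1.0):
        vc = centre + np.array([sign * shape[0] * 0.08, 0.0, shape[2] * 0.02])
        vs = shape * np.array([0.045, 0.16, 0.10])
        vr = sum(((coords[i] - vc[i]) / vs[i]) ** 2 for i in range(3))
        labels[(vr <= 1.0) & core] = 1

    # deep GM nuclei: small ellipsoids in the core, seeded positions
    for _ in range(4):
        nc = centre + rng.uniform(-0.18, 0.18, 3) * shape
        ns = shape * rng.uniform(0.03, 0.06, 3)
        nr = sum(((coords[i] - nc[i]) / ns[i]) ** 2 for i in range(3))
        labels[(nr <= 1.0) & (labels == 3)] = 2

    means = dict(spec.means) if spec.contrast == "t2" else dict(T1_MEANS)
    lut = np.array([means["background"], means["csf"], means["gm"], means["wm"]])
    data = lut[labels]
    vol = Volume(data=data, spacing=spec.spacing)
    return vol, labels


def simulate_study(
    phantom: Volume,
    labels: np.ndarray,
    thicknesses: list[float],
    planes: list[str] = ("axial", "coronal", "sagittal"),
    sigma_fraction: float = 0.1,
    transforms: list[RigidTransform] | None = None,
    seed: int = 0,
) -> SimulatedStudy:
    """Degrade the phantom into one LR stack per (thickness, plane).

    Noise sigma is computed per stack from that stack's own maximum; each
    stack draws from an independent seed derived deterministically from the
    master seed, so the whole study regenerates bit-exactly.
    """
    combos = [(th, pl) for th in thicknesses for pl in planes]
    if transforms is not None and len(transforms) != len(combos):
        raise VolumeError("transforms list must match the number of stacks")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(combos))]
    stacks: list[StackRecord] = []
    manifest: dict = {
        "seed": int(seed),
        "sigma_fraction": float(sigma_fraction),
        "phantom_shape": list(phantom.shape),
        "phantom_spacing": list(phantom.spacing),
        "stacks": [],
    }
    for k, (thickness, plane) in enumerate(combos):
        axis = PLANE_AXES[plane]
        inplane = phantom.spacing[(axis + 1) % 3]
        geom = AcquisitionGeometry(
            slice_axis=axis, slice_thickness=thickness, inplane_spacing=inplane
        )
        t = transforms[k] if transforms is not None else RigidTransform.identity()
        lr = degrade(
            phantom, geom, t=t, sigma_fraction=sigma_fraction, seed=child_seeds[k]
        )
        stacks.append(
            StackRecord(
                volume=lr,
                geometry=geom,
                transform=t,
                plane=plane,
                noise_seed=child_seeds[k],
                sigma_fraction=sigma_fraction,
            )
        )
        manifest["stacks"].append(
            {
                "plane": plane,
                "slice_axis": axis,
                "slice_thickness": float(thickness),
                "inplane_spacing": float(inplane),
                "factor": geom.factor,
                "noise_seed": child_seeds[k],
                "rotation": list(t.rotation),
                "translation": list(t.translation),
                "center": list(t.center),
            }
        )
    return SimulatedStudy(
        ground_truth=phantom, labels=labels, stacks=stacks, manifest=manifest
    )


def reference_protocols(scale: float = 1.0) -> dict:
    """Canned study recipes mirroring the published protocols.

    ``simulation``: a 500-um isotropic ground truth degraded to slice
    thicknesses {1, 1.5, 2, 2.5, 3} mm in 3 orthogonal planes with 10% noise.
    ``clinical``: two stacks (axial + coronal), 500-um in-plane, 2-mm slices
    (factor 4). ``scale`` > 1 coarsens both recipes for desk-size grids.
    """
    spacing = 0.5 * scale
    return {
        "simulation": {
            "hr_spacing_mm": spacing,
            "thicknesses_mm": [t * scale for t in (1.0, 1.5, 2.0, 2.5, 3.0)],
            "planes": ["axial", "coronal", "sagittal"],
            "sigma_fraction": 0.1,
        },
        "clinical": {
            "hr_spacing_mm": spacing,
            "thicknesses_mm": [2.0 * scale],
            "planes": ["axial", "coronal"],
            "sigma_fraction": 0.1,
            "factor": 4,
        },
    }
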