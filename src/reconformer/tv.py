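"""Total-variation-regularized super-resolution baseline.

Minimizes

    f(x) = sum_i || y_i - A_i x ||_2^2  +  lambda * TV_eps(x)

where A_i is the noise-free degradation operator of each stack and
TV_eps(x) = sum_v sqrt(||grad x(v)||^2 + eps^2) is smoothed isotropic total
variation on forward differences. The solver is monotone accelerated
gradient descent: a Nesterov extrapolation step is accepted only when it
decreases the objective, otherwise the iteration falls back to a plain
backtracked gradient step, so the objective trace is non-increasing by
construction. This doubles as the generator of the transformer network's
input image (short schedule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_model import DegradeOperator, RigidTransform
from .volume import AcquisitionGeometry, Volume, VolumeError


@dataclass(frozen=True)
class TVConfig:
    lambda_tv: float = 1e-2
    step_size: float = 0.5
    max_iterations: int = 200
    tv_epsilon: float = 1e-3
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.lambda_tv < 0 or self.tv_epsilon <= 0 or self.max_iterations < 1:
            raise VolumeError("invalid TV configuration")


def build_operators(
    hr_shape: tuple[int, int, int],
    hr_spacing: tuple[float, float, float],
    geoms: list[AcquisitionGeometry],
    transforms: list[RigidTransform] | None = None,
) -> list[DegradeOperator]:
    transforms = transforms or [RigidTransform.identity()] * len(geoms)
    return [
        DegradeOperator(hr_shape, hr_spacing, g, transform=t)
        for g, t in zip(geoms, transforms)
    ]


def data_objective(
    x: Volume,
    stacks: list[Volume],
    geoms: list[AcquisitionGeometry],
    transforms: list[RigidTransform] | None = None,
) -> float:
    """Sum of squared residuals of the noise-free forward model."""
    ops = build_operators(x.shape, x.spacing, geoms, transforms)
    total = 0.0
    for op, y in zip(ops, stacks):
        if op.lr_shape != y.shape:
            raise VolumeError(
                f"stack shape {y.shape} inconsistent with operator output {op.lr_shape}"
            )
        r = op.forward(x.data) - y.data
        total += float(np.sum(r * r))
    return total


def _tv_value_grad(x: np.ndarray, eps: float) -> tuple[float, np.ndarray]:
    """Smoothed isotropic TV and its gradient (forward differences)."""
    gx = np.diff(x, axis=0, append=x[-1:, :, :])
    gy = np.diff(x, axis=1, append=x[:, -1:, :])
    gz = np.diff(x, axis=2, append=x[:, :, -1:])
    mag = np.sqrt(gx * gx + gy * gy + gz * gz + eps * eps)
    value = float(mag.sum())
    nx, ny, nz = gx / mag, gy / mag, gz / mag
    # negative divergence of the normalized gradient field
    grad = np.zeros_like(x)
    grad[:-1, :, :] -= nx[:-1, :, :]
    grad[1:, :, :] += nx[:-1, :, :]
    grad[:, :-1, :] -= ny[:, :-1, :]
    grad[:, 1:, :] += ny[:, :-1, :]
    grad[:, :, :-1] -= nz[:, :, :-1]
    grad[:, :, 1:] += nz[:, :, :-1]
    return value, grad


def tv_seminorm(x: np.ndarray, eps: float = 0.0) -> float:
    gx = np.diff(x, axis=0, append=x[-1:, :, :])
    gy = np.diff(x, axis=1, append=x[:, -1:, :])
    gz = np.diff(x, axis=2, append=x[:, :, -1:])
    return float(np.sqrt(gx * gx + gy * gy + gz * gz + eps * eps).sum())


def back_projection_init(
    ops: list[DegradeOperator], stacks: list[Volume]
) -> np.ndarray:
    """Adjoint-based average: sum A_i^T y_i / sum A_i^T A_i 1 (guarded)."""
    num = np.zeros(ops[0].hr_shape)
    den = np.zeros(ops[0].hr_shape)
    ones = np.ones(ops[0].hr_shape)
    for op, y in zip(ops, stacks):
        num += op.adjoint(y.data)
        den += op.adjoint(op.forward(ones))
    floor = 1e-6 * max(den.max(), 1e-30)
    return num / np.maximum(den, floor)


def tv_reconstruct(
    stacks: list[Volume],
    geoms: list[AcquisitionGeometry],
    transforms: list[RigidTransform] | None = None,
    cfg: TVConfig = TVConfig(),
    hr_shape: tuple[int, int, int] | None = None,
    hr_spacing: tuple[float, float, float] | None = None,
) -> tuple[Volume, list[float]]:
    """Reconstruct the HR volume; returns (volume, objective trace).

    The HR lattice defaults to the isotropic lattice implied by the first
    stack: in-plane spacing in all axes, slice axis extent multiplied by the
    stack's factor.
    """
    if not stacks:
        raise VolumeError("at least one stack required")
    if hr_shape is None or hr_spacing is None:
        g0, y0 = geoms[0], stacks[0]
        hr_spacing = (g0.inplane_spacing,) * 3
        hr_shape = tuple(
            n * g0.factor if i == g0.slice_axis else n
            for i, n in enumerate(y0.shape)
        )
    ops = build_operators(hr_shape, hr_spacing, geoms, transforms)
    for op, y in zip(ops, stacks):
        if op.lr_shape != y.shape:
            raise VolumeError(
                f"stack shape {y.shape} inconsistent with operator output {op.lr_shape}"
            )
    ys = [y.data for y in stacks]

    def objective(x: np.ndarray) -> float:
        val = sum(float(np.sum((op.forward(x) - y) ** 2)) for op, y in zip(ops, ys))
        if cfg.lambda_tv > 0:
            val += cfg.lambda_tv * tv_seminorm(x, cfg.tv_epsilon)
        return val

    def gradient(x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(x)
        for op, y in zip(ops, ys):
            g += 2.0 * op.adjoint(op.forward(x) - y)
        if cfg.lambda_tv > 0:
            _, tg = _tv_value_grad(x, cfg.tv_epsilon)
            g += cfg.lambda_tv * tg
        return g

    x = back_projection_init(ops, stacks)
    fx = objective(x)
    trace = [fx]
    step = cfg.step_size
    x_prev = x.copy()
    t_momentum = 1.0
    for _ in range(cfg.max_iterations):
        # Nesterov extrapolation, accepted only if it decreases the objective
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_momentum**2))
        z = x + ((t_momentum - 1.0) / t_next) * (x - x_prev)
        g = gradient(z)
        accepted = False
        for _ in range(30):
            cand = z - step * g
            fc = objective(cand)
            if fc <= fx:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # fall back to a plain backtracked step from x
            g = gradient(x)
            for _ in range(30):
                cand = x - step * g
                fc = objective(cand)
                if fc <= fx:
                    accepted = True
                    break
                step *= 0.5
            t_next = 1.0
        if not accepted:
            break
        x_prev, x = x, cand
        t_momentum = t_next
        step *= 1.3  # allow the step to grow back after backtracking
        rel_change = abs(fx - fc) / max(fx, 1e-30)
        fx = fc
        trace.append(fx)
        if rel_change < cfg.tolerance:
            break
    vol = Volume(data=x, spacing=hr_spacing)
    return vol, trace
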