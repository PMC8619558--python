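"""Rigid MDCT -> DE-CBCT registration and ROI transfer.

A multi-resolution (3-level by default) intensity-based rigid registration
aligns the MDCT volume (moving) to the DE-CBCT volume (fixed). The
optimization is initialized by matching the intensity centroids of
thresholded bone voxels, then refines the 6 rigid parameters with
regular-step gradient descent on mean squared error (default) or Mattes
mutual information. Sampling is dense by default so results are exactly
reproducible; stochastic subsampling is available behind a seed.

The estimated transform is reported in the direction MDCT-world ->
DE-CBCT-world; its inverse carries cylindrical ROIs selected in DE-CBCT
space into MDCT space, where statistics are read off the native MDCT grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import SimpleITK as sitk

from .errors import RegistrationError
from .geometry import RigidTransform, VoxelVolume
from .roi import transform_cylinder  # re-export: ROI transfer belongs to this surface

__all__ = [
    "RegistrationParams",
    "RegistrationResult",
    "estimate_rigid",
    "invert",
    "transform_cylinder",
    "save_transform_json",
    "load_transform_json",
]


@dataclass(frozen=True)
class RegistrationParams:
    metric: str = "mse"  # "mse" | "mattes"
    shrink_factors: tuple[int, ...] = (8, 4, 2)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0)
    iterations: int = 200
    learning_rate: float = 1.0
    min_step: float = 1e-4
    relaxation_factor: float = 0.5
    sampling_fraction: float | None = None  # None = dense, deterministic
    sampling_seed: int = 12345
    bone_threshold: float = 300.0


@dataclass
class RegistrationResult:
    """Estimated rigid map MDCT-world -> DE-CBCT-world plus diagnostics."""

    transform: RigidTransform
    final_metric: float
    iterations: int
    converged: bool
    # per resolution level: (level, first iteration's metric, last iteration's metric)
    level_metrics: list = field(default_factory=list)


def _to_sitk(volume: VoxelVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    img.SetDirection(tuple(volume.direction.flatten()))
    return sitk.Cast(img, sitk.sitkFloat32)


def _bone_centroid(volume: VoxelVolume, threshold: float) -> np.ndarray:
    mask = volume.values > threshold
    if not mask.any():
        raise RegistrationError(
            f"no voxels above the bone threshold ({threshold}); cannot initialize"
        )
    idx = np.argwhere(mask)
    return volume.grid.index_to_world(idx.mean(axis=0))


def _world_bbox(volume: VoxelVolume) -> tuple[np.ndarray, np.ndarray]:
    dims = np.asarray(volume.dims) - 1
    corners = np.array(
        [[x, y, z] for x in (0, dims[0]) for y in (0, dims[1]) for z in (0, dims[2])],
        dtype=float,
    )
    world = volume.grid.index_to_world(corners)
    return world.min(axis=0), world.max(axis=0)


def estimate_rigid(
    fixed: VoxelVolume,
    moving: VoxelVolume,
    params: RegistrationParams | None = None,
) -> RegistrationResult:
    """Estimate the rigid transform aligning ``moving`` (MDCT) to ``fixed`` (DE-CBCT).

    Raises :class:`RegistrationError` when the bone-centroid initialization
    leaves the two fields of view without overlap or no bone is found —
    mirroring clinical registration failures, which are excluded upstream.
    """
    p = params or RegistrationParams()

    c_fixed = _bone_centroid(fixed, p.bone_threshold)
    c_moving = _bone_centroid(moving, p.bone_threshold)

    init = sitk.Euler3DTransform()
    init.SetCenter(tuple(c_fixed))
    init.SetTranslation(tuple(c_moving - c_fixed))

    # overlap check: image of the fixed bbox under the initial map vs moving bbox
    init_rigid = _sitk_euler_to_rigid(init)
    f_lo, f_hi = _world_bbox(fixed)
    m_lo, m_hi = _world_bbox(moving)
    corners = np.array(
        [[x, y, z] for x in (f_lo[0], f_hi[0]) for y in (f_lo[1], f_hi[1]) for z in (f_lo[2], f_hi[2])]
    )
    mapped = init_rigid.apply(corners)
    if np.any(mapped.max(axis=0) < m_lo) or np.any(mapped.min(axis=0) > m_hi):
        raise RegistrationError("no field-of-view overlap after centroid initialization")

    reg = sitk.ImageRegistrationMethod()
    if p.metric == "mse":
        reg.SetMetricAsMeanSquares()
    elif p.metric == "mattes":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    else:
        raise ValueError(f"unknown metric {p.metric!r}")
    if p.sampling_fraction is not None:
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(p.sampling_fraction, p.sampling_seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=p.learning_rate,
        minStep=p.min_step,
        numberOfIterations=p.iterations,
        relaxationFactor=p.relaxation_factor,
        gradientMagnitudeTolerance=1e-8,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    n_levels = len(p.shrink_factors)
    reg.SetShrinkFactorsPerLevel(list(p.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(p.smoothing_sigmas[:n_levels]))
    reg.SetInitialTransform(init, inPlace=True)

    trace: list[tuple[int, float]] = []

    def _on_iteration():
        trace.append((reg.GetCurrentLevel(), reg.GetMetricValue()))

    reg.AddCommand(sitk.sitkIterationEvent, _on_iteration)
    reg.Execute(_to_sitk(fixed), _to_sitk(moving))

    stop = reg.GetOptimizerStopConditionDescription()
    final_metric = float(reg.GetMetricValue())
    level_metrics = []
    for level in sorted({lv for lv, _ in trace}):
        vals = [m for lv, m in trace if lv == level]
        level_metrics.append((level, vals[0], vals[-1]))

    cbct_to_mdct = _sitk_euler_to_rigid(init)
    return RegistrationResult(
        transform=cbct_to_mdct.inverse(),  # MDCT-world -> DE-CBCT-world
        final_metric=final_metric,
        iterations=len(trace),
        converged="maximum number of iterations" not in stop.lower(),
        level_metrics=level_metrics,
    )


def _sitk_euler_to_rigid(tx: sitk.Euler3DTransform) -> RigidTransform:
    """Flatten sitk's centered parameterization p -> R(p-c)+c+t to R, b."""
    r = np.array(tx.GetMatrix()).reshape(3, 3)
    c = np.array(tx.GetCenter())
    t = np.array(tx.GetTranslation())
    return RigidTransform(rotation=r, translation=c + t - r @ c)


def invert(result) -> RigidTransform:
    """Exact algebraic inverse (R^T, -R^T t) of a result's (or bare) transform."""
    t = result.transform if isinstance(result, RegistrationResult) else result
    return t.inverse()


def save_transform_json(transform: RigidTransform, path) -> None:
    """4x4 homogeneous matrix, row-major, mm, LPS."""
    with open(path, "w") as fh:
        json.dump({"matrix": transform.as_matrix().tolist()}, fh, indent=2)


def load_transform_json(path) -> RigidTransform:
    with open(path) as fh:
        d = json.load(fh)
    return RigidTransform.from_matrix(np.asarray(d["matrix"]))
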