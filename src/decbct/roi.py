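"""Oriented cylindrical ROIs and native-grid voxel statistics.

A cylinder is placed in world space by its center, height, diameter, and
three rotation angles (about world x, y, z, composed in z*y*x order, i.e.
``R = Rz(gamma) @ Ry(beta) @ Rx(alpha)``). Membership is by voxel-center
inclusion on the volume's native grid — no interpolation and no
partial-volume weighting — and statistics are plain descriptive statistics
over member voxel values, the mean serving as the ROI's representative
value.

Default validation warns when geometry leaves the clinically used ranges
(height 4.0–5.0 mm, diameter 1.0–1.4 mm, angles within +/-90 degrees);
these are adjustment ranges, not hard limits, so ``validate=False`` or the
emitted warning lets callers proceed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import EmptyROIError, GeometryError
from .geometry import RigidTransform, VoxelVolume

__all__ = [
    "CylinderROI",
    "ROIStatistics",
    "MeasurementPair",
    "PairedROIResult",
    "cylinder_mask",
    "roi_statistics",
    "transform_cylinder",
    "paired_roi_means",
    "read_rois_csv",
    "write_rois_csv",
    "statistics_frame",
]

HEIGHT_RANGE = (4.0, 5.0)
DIAMETER_RANGE = (1.0, 1.4)
ANGLE_RANGE = (-90.0, 90.0)


@dataclass(frozen=True)
class CylinderROI:
    """Oriented cylinder in world space (mm, degrees)."""

    label: str
    center: tuple[float, float, float]
    height: float = 4.5
    diameter: float = 1.2
    angles: tuple[float, float, float] = (0.0, 0.0, 0.0)
    group: str | None = None
    validate: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if self.height <= 0 or self.diameter <= 0:
            raise GeometryError("cylinder height and diameter must be positive")
        if self.validate:
            msgs = []
            if not HEIGHT_RANGE[0] <= self.height <= HEIGHT_RANGE[1]:
                msgs.append(f"height {self.height} outside {HEIGHT_RANGE}")
            if not DIAMETER_RANGE[0] <= self.diameter <= DIAMETER_RANGE[1]:
                msgs.append(f"diameter {self.diameter} outside {DIAMETER_RANGE}")
            for a in self.angles:
                if not ANGLE_RANGE[0] <= a <= ANGLE_RANGE[1]:
                    msgs.append(f"angle {a} outside {ANGLE_RANGE}")
                    break
            if msgs:
                warnings.warn(
                    f"ROI {self.label!r}: " + "; ".join(msgs) + " (proceeding)",
                    stacklevel=3,
                )

    @property
    def rotation(self) -> np.ndarray:
        """Orientation matrix: z*y*x composition of the three world-axis angles."""
        return Rotation.from_euler("xyz", self.angles, degrees=True).as_matrix()

    @property
    def axis(self) -> np.ndarray:
        """Unit vector along the cylinder axis (local z) in world space."""
        return self.rotation @ np.array([0.0, 0.0, 1.0])

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership of world points (N, 3)."""
        rel = np.atleast_2d(points) - np.asarray(self.center, dtype=float)
        local = rel @ self.rotation  # R^T applied to rows
        r2 = local[:, 0] ** 2 + local[:, 1] ** 2
        return (np.abs(local[:, 2]) <= self.height / 2.0) & (r2 <= self.radius**2)


@dataclass(frozen=True)
class ROIStatistics:
    label: str
    n_voxels: int
    mean: float
    sd: float
    min: float
    max: float
    single_voxel: bool = False


@dataclass(frozen=True)
class MeasurementPair:
    """Paired ROI means: reference modality (MDCT) vs DE-CBCT."""

    label: str
    group: str
    mean_mdct: float
    mean_decbct: float


@dataclass
class PairedROIResult:
    pairs: list[MeasurementPair]
    excluded: list[tuple[str, str]]  # (label, reason); never silently dropped


def cylinder_mask(volume: VoxelVolume, roi: CylinderROI) -> np.ndarray:
    """Integer index array (n, 3) of voxels whose centers fall inside the ROI.

    Only the ROI's bounding box of the grid is scanned, so masks of small
    clinical ROIs are cheap even on full CT grids.
    """
    grid = volume.grid
    c = np.asarray(roi.center, dtype=float)
    # bounding sphere around the cylinder
    rad = float(np.hypot(roi.height / 2.0, roi.radius))
    corners = c + rad * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    cidx = grid.world_to_continuous_index(corners)
    lo = np.maximum(np.floor(cidx.min(axis=0)).astype(int), 0)
    hi = np.minimum(np.ceil(cidx.max(axis=0)).astype(int), np.asarray(grid.dims) - 1)
    if np.any(lo > hi):
        raise EmptyROIError(f"ROI {roi.label!r} does not intersect the volume extent")
    ranges = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = grid.index_to_world(idx)
    inside = roi.contains(centers)
    if not inside.any():
        raise EmptyROIError(f"ROI {roi.label!r} contains no voxel centers")
    return idx[inside]


def roi_statistics(volume: VoxelVolume, roi: CylinderROI) -> ROIStatistics:
    """Descriptive statistics over member voxel values (sample SD, n-1)."""
    idx = cylinder_mask(volume, roi)
    vals = volume.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    n = len(vals)
    single = n == 1
    if single:
        warnings.warn(f"ROI {roi.label!r} covers a single voxel; SD reported as 0", stacklevel=2)
    return ROIStatistics(
        label=roi.label,
        n_voxels=n,
        mean=float(vals.mean()),
        sd=0.0 if single else float(vals.std(ddof=1)),
        min=float(vals.min()),
        max=float(vals.max()),
        single_voxel=single,
    )


def transform_cylinder(roi: CylinderROI, transform: RigidTransform) -> CylinderROI:
    """Carry the ROI through a rigid world-to-world map.

    The center is mapped through the transform and the orientation is
    left-composed with the transform's rotation; height and diameter are
    unchanged (rigidity preserves shape, hence volume). The recovered Euler
    angles may leave the +/-90 degree adjustment range, so the returned ROI
    skips range validation.
    """
    if not isinstance(transform, RigidTransform):
        raise GeometryError("transform_cylinder supports rigid transforms only")
    new_center = transform.apply(np.asarray(roi.center, dtype=float))
    new_rot = transform.rotation @ roi.rotation
    angles = Rotation.from_matrix(new_rot).as_euler("xyz", degrees=True)
    return replace(
        roi,
        center=tuple(new_center),
        angles=tuple(float(a) for a in angles),
        validate=False,
    )


def paired_roi_means(
    vol_decbct: VoxelVolume,
    vol_mdct: VoxelVolume,
    rois: list[CylinderROI],
    inverse_transform: RigidTransform,
) -> PairedROIResult:
    """Measure each ROI in DE-CBCT space and, transformed, in MDCT space.

    ``inverse_transform`` maps DE-CBCT world points into MDCT world points
    (the inverted registration transform). ROIs empty in either volume are
    reported in ``excluded`` with the failing side, never silently dropped.
    """
    pairs: list[MeasurementPair] = []
    excluded: list[tuple[str, str]] = []
    for roi in rois:
        try:
            stats_cbct = roi_statistics(vol_decbct, roi)
        except EmptyROIError as exc:
            excluded.append((roi.label, f"DE-CBCT: {exc}"))
            continue
        roi_m = transform_cylinder(roi, inverse_transform)
        try:
            stats_mdct = roi_statistics(vol_mdct, roi_m)
        except EmptyROIError as exc:
            excluded.append((roi.label, f"MDCT: {exc}"))
            continue
        pairs.append(
            MeasurementPair(
                label=roi.label,
                group=roi.group or roi.label.split("_")[0],
                mean_mdct=stats_mdct.mean,
                mean_decbct=stats_cbct.mean,
            )
        )
    return PairedROIResult(pairs=pairs, excluded=excluded)


# ---------------------------------------------------------------------------
# file formats: ROI definitions as CSV (label, group, center, size, angles)
# ---------------------------------------------------------------------------

_ROI_COLUMNS = ["label", "group", "cx", "cy", "cz", "height", "diameter", "alpha", "beta", "gamma"]


def read_rois_csv(path, validate: bool = True) -> list[CylinderROI]:
    df = pd.read_csv(path)
    missing = [c for c in _ROI_COLUMNS if c not in df.columns and c != "group"]
    if missing:
        raise GeometryError(f"ROI file missing columns: {missing}")
    rois = []
    for _, row in df.iterrows():
        rois.append(
            CylinderROI(
                label=str(row["label"]),
                center=(float(row["cx"]), float(row["cy"]), float(row["cz"])),
                height=float(row["height"]),
                diameter=float(row["diameter"]),
                angles=(float(row["alpha"]), float(row["beta"]), float(row["gamma"])),
                group=str(row["group"]) if "group" in df.columns and pd.notna(row["group"]) else None,
                validate=validate,
            )
        )
    return rois


def write_rois_csv(rois: list[CylinderROI], path) -> None:
    rows = [
        {
            "label": r.label,
            "group": r.group,
            "cx": r.center[0],
            "cy": r.center[1],
            "cz": r.center[2],
            "height": r.height,
            "diameter": r.diameter,
            "alpha": r.angles[0],
            "beta": r.angles[1],
            "gamma": r.angles[2],
        }
        for r in rois
    ]
    pd.DataFrame(rows, columns=_ROI_COLUMNS).to_csv(path, index=False)


def statistics_frame(stats: list[ROIStatistics], modality: str | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "label": s.label,
                "n_voxels": s.n_voxels,
                "mean": s.mean,
                "sd": s.sd,
                "min": s.min,
                "max": s.max,
            }
            for s in stats
        ]
    )
    if modality is not None:
        df.insert(1, "modality", modality)
    return df
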