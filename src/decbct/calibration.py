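"""Dual-energy Hounsfield-unit calibration.

The method estimates HU from a pair of CBCT volumes acquired at low and high
kVp on the same grid. Mean CT numbers of phantom regions (hydroxyapatite
inserts of known HU, acrylic, air) form points in the (low-kVp, high-kVp)
value plane. A *density line* is fitted through those points; each voxel's
value pair is orthogonally projected onto the line, and the signed line
coordinate is mapped to HU by an affine map fitted against the regions of
known HU. Application is strictly voxel-by-voxel on identical grids — no
resampling happens on the calibration path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, GeometryError
from .geometry import VoxelVolume

__all__ = [
    "RegionSample",
    "DensityLine",
    "HUMap",
    "CalibrationModel",
    "extract_region_samples",
    "fit_density_line",
    "project_to_density",
    "fit_hu_map",
    "apply_calibration",
]


@dataclass(frozen=True)
class RegionSample:
    """Per-region mean CT numbers in the two energy channels."""

    label: str
    mean_low: float
    mean_high: float
    known_hu: float | None = None

    @property
    def point(self) -> np.ndarray:
        return np.array([self.mean_low, self.mean_high])


@dataclass(frozen=True)
class DensityLine:
    """Line in the (low, high) CT-number plane: point ``p0``, unit direction ``u``."""

    p0: tuple[float, float]
    u: tuple[float, float]

    def __post_init__(self) -> None:
        norm = float(np.hypot(*self.u))
        if abs(norm - 1.0) > 1e-12:
            raise DegenerateFitError(f"direction must be a unit vector (|u| = {norm})")


@dataclass(frozen=True)
class HUMap:
    """Affine map from density-line coordinate to HU."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope == 0.0:
            raise DegenerateFitError("HU-map slope must be finite and nonzero")
        if not np.isfinite(self.intercept):
            raise DegenerateFitError("HU-map intercept must be finite")


def extract_region_samples(
    vol_low: VoxelVolume,
    vol_high: VoxelVolume,
    masks: dict[str, np.ndarray],
    known_hu_table: dict[str, float] | None = None,
    min_voxels: int = 10,
) -> list[RegionSample]:
    """Mean low/high CT numbers per labelled region.

    Both volumes must share one grid; each mask is a boolean array on that
    grid. ``known_hu_table`` attaches certified HU values where available.
    """
    if not vol_low.grid.same_geometry(vol_high.grid):
        raise GeometryError("low- and high-kVp volumes must share identical geometry")
    known_hu_table = known_hu_table or {}
    samples = []
    for label, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vol_low.dims:
            raise GeometryError(f"mask {label!r} shape {mask.shape} != volume dims {vol_low.dims}")
        n = int(mask.sum())
        if n == 0:
            raise DegenerateFitError(f"region mask {label!r} is empty")
        if n < min_voxels:
            raise DegenerateFitError(
                f"region mask {label!r} has {n} voxels (< floor of {min_voxels})"
            )
        samples.append(
            RegionSample(
                label=label,
                mean_low=float(vol_low.values[mask].mean()),
                mean_high=float(vol_high.values[mask].mean()),
                known_hu=known_hu_table.get(label),
            )
        )
    return samples


def fit_density_line(samples, method: str = "tls") -> DensityLine:
    """Fit the density line through region samples in the (low, high) plane.

    ``method="tls"`` (default) is total least squares: ``p0`` is the centroid
    and ``u`` the first principal direction, minimizing orthogonal residuals
    — both coordinates are noisy measurements, so neither axis is privileged.
    ``method="ols_high_on_low"`` regresses high on low instead.
    """
    pts = np.array([s.point for s in samples], dtype=float)
    if len(pts) < 2:
        raise DegenerateFitError("need at least 2 region samples to fit a line")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.allclose(centered, 0.0, atol=1e-12):
        raise DegenerateFitError("all region samples coincide; density line undefined")
    if method == "tls":
        # first right-singular vector = first principal direction
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        u = vt[0]
    elif method == "ols_high_on_low":
        sxx = float(centered[:, 0] @ centered[:, 0])
        if sxx == 0.0:
            raise DegenerateFitError("zero variance in low-kVp means; OLS slope undefined")
        slope = float(centered[:, 0] @ centered[:, 1]) / sxx
        u = np.array([1.0, slope])
        u /= np.linalg.norm(u)
    else:
        raise ValueError(f"unknown line-fit method {method!r}")
    # deterministic sign: point toward increasing low-kVp value
    if u[0] < 0 or (u[0] == 0 and u[1] < 0):
        u = -u
    return DensityLine(p0=tuple(centroid), u=tuple(u))


def project_to_density(pair, line: DensityLine):
    """Signed orthogonal-projection coordinate of value pair(s) onto the line.

    ``pair`` may be a single (low, high) pair or an (N, 2) array.
    """
    p = np.asarray(pair, dtype=float)
    rel = p - np.asarray(line.p0)
    t = rel @ np.asarray(line.u)
    return float(t) if p.ndim == 1 else t


def fit_hu_map(samples, line: DensityLine) -> HUMap:
    """OLS fit of known HU against each known-HU sample's line coordinate."""
    known = [s for s in samples if s.known_hu is not None]
    if len(known) < 2:
        raise DegenerateFitError(
            f"need at least 2 samples with known HU, got {len(known)}"
        )
    t = np.array([project_to_density(s.point, line) for s in known])
    hu = np.array([s.known_hu for s in known], dtype=float)
    tc = t - t.mean()
    stt = float(tc @ tc)
    if stt < 1e-12:
        raise DegenerateFitError("zero variance in projected coordinates; HU map undefined")
    slope = float(tc @ (hu - hu.mean())) / stt
    intercept = float(hu.mean() - slope * t.mean())
    return HUMap(slope=slope, intercept=intercept)


def apply_calibration(
    vol_low: VoxelVolume,
    vol_high: VoxelVolume,
    line: DensityLine,
    hu_map: HUMap,
) -> VoxelVolume:
    """Voxel-by-voxel HU volume from the low/high pair (identical grids only)."""
    if not vol_low.grid.same_geometry(vol_high.grid):
        raise GeometryError("apply_calibration requires identical grids (no resampling)")
    u = np.asarray(line.u)
    p0 = np.asarray(line.p0)
    t = (vol_low.values - p0[0]) * u[0] + (vol_high.values - p0[1]) * u[1]
    hu = hu_map.slope * t + hu_map.intercept
    return VoxelVolume(values=hu, grid=vol_low.grid, value_kind="hu")


@dataclass(frozen=True)
class CalibrationModel:
    """Serializable bundle: density line + HU map (+ fit provenance)."""

    line: DensityLine
    hu_map: HUMap
    samples: tuple = ()

    @classmethod
    def fit(cls, samples, line_method: str = "tls") -> "CalibrationModel":
        line = fit_density_line(samples, method=line_method)
        hu_map = fit_hu_map(samples, line)
        return cls(line=line, hu_map=hu_map, samples=tuple(samples))

    def apply(self, vol_low: VoxelVolume, vol_high: VoxelVolume) -> VoxelVolume:
        return apply_calibration(vol_low, vol_high, self.line, self.hu_map)

    def predict_hu(self, pair) -> float:
        return self.hu_map.slope * project_to_density(pair, self.line) + self.hu_map.intercept

    def to_dict(self) -> dict:
        return {
            "p0": list(self.line.p0),
            "u": list(self.line.u),
            "slope": self.hu_map.slope,
            "intercept": self.hu_map.intercept,
            "samples": [
                {
                    "label": s.label,
                    "mean_low": s.mean_low,
                    "mean_high": s.mean_high,
                    "known_hu": s.known_hu,
                }
                for s in self.samples
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            line=DensityLine(p0=tuple(d["p0"]), u=tuple(d["u"])),
            hu_map=HUMap(slope=d["slope"], intercept=d["intercept"]),
            samples=tuple(
                RegionSample(
                    label=s["label"],
                    mean_low=s["mean_low"],
                    mean_high=s["mean_high"],
                    known_hu=s.get("known_hu"),
                )
                for s in d.get("samples", ())
            ),
        )

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
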