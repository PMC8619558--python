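"""World-referenced voxel grids, rigid transforms, and resampling.

All geometry lives in the DICOM LPS patient frame, in millimetres. Voxel
indices are 0-based and refer to voxel *centers*: the world position of
index ``(i, j, k)`` is ``origin + D @ (spacing * (i, j, k))`` where ``D``
is the 3x3 orthonormal direction-cosine matrix. Direction matrices are
restricted to orthonormal maps (no shear); sheared/affine grids are out of
scope because rigid anatomy is carried by rigid transforms only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import BoundsError, GeometryError

__all__ = [
    "Grid",
    "VoxelVolume",
    "RigidTransform",
    "resample",
]

_ORTHO_TOL = 1e-9


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size != 3:
        raise GeometryError(f"{name} must have 3 components, got {v.size}")
    return v


def _check_direction(direction: np.ndarray) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    if d.shape != (3, 3):
        raise GeometryError(f"direction must be 3x3, got {d.shape}")
    if not np.allclose(d @ d.T, np.eye(3), atol=1e-8):
        raise GeometryError("direction matrix is not orthonormal")
    if abs(abs(np.linalg.det(d)) - 1.0) > _ORTHO_TOL:
        raise GeometryError("direction matrix determinant is not +/-1")
    return d


@dataclass
class Grid:
    """Regular 3D sampling grid with world geometry (mm, LPS)."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise GeometryError(f"degenerate grid dims {self.dims}")
        sp = _as_vec3(self.spacing, "spacing")
        if np.any(sp <= 0):
            raise GeometryError(f"spacing must be positive, got {tuple(sp)}")
        self.spacing = tuple(sp)
        self.origin = tuple(_as_vec3(self.origin, "origin"))
        self.direction = _check_direction(self.direction)

    # -- coordinate maps ---------------------------------------------------

    def index_to_world(self, index) -> np.ndarray:
        """Map (continuous or integer) voxel indices to world mm (centers)."""
        idx = np.asarray(index, dtype=float)
        sp = np.asarray(self.spacing)
        return np.asarray(self.origin) + (idx * sp) @ self.direction.T

    def world_to_continuous_index(self, point) -> np.ndarray:
        """Exact algebraic inverse of :meth:`index_to_world`.

        May return indices outside ``[0, dims)``; callers decide membership.
        """
        p = np.asarray(point, dtype=float)
        rel = p - np.asarray(self.origin)
        return (rel @ self.direction) / np.asarray(self.spacing)

    def contains_index(self, index) -> bool:
        idx = np.asarray(index)
        return bool(np.all(idx >= 0) and np.all(idx < np.asarray(self.dims)))

    @classmethod
    def centered(cls, dims, spacing, direction=None) -> "Grid":
        """Grid whose world center is the origin of the world frame."""
        dims = tuple(int(d) for d in dims)
        sp = _as_vec3(spacing, "spacing")
        d = np.eye(3) if direction is None else _check_direction(direction)
        half = (np.asarray(dims, dtype=float) - 1.0) / 2.0 * sp
        origin = -(d @ half)
        return cls(dims=dims, spacing=tuple(sp), origin=tuple(origin), direction=d)

    def same_geometry(self, other: "Grid", atol: float = 1e-9) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )


@dataclass
class VoxelVolume:
    """3D scalar field (CT number or HU) on a :class:`Grid`.

    ``values`` is indexed ``[i, j, k]`` matching the grid's (x, y, z) axes.
    ``value_kind`` records the value semantics: ``"raw_ct"`` for uncalibrated
    per-channel CT numbers, ``"hu"`` for calibrated Hounsfield units.
    """

    values: np.ndarray
    grid: Grid
    value_kind: str = "raw_ct"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise GeometryError("values must be a 3D array")
        if self.values.shape != self.grid.dims:
            raise GeometryError(
                f"values shape {self.values.shape} does not match grid dims {self.grid.dims}"
            )
        if self.value_kind not in ("raw_ct", "hu"):
            raise GeometryError(f"unknown value_kind {self.value_kind!r}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.grid.dims

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.grid.origin

    @property
    def direction(self) -> np.ndarray:
        return self.grid.direction

    def index_to_world(self, index) -> np.ndarray:
        idx = np.asarray(index)
        if idx.ndim == 1 and not self.grid.contains_index(idx):
            raise BoundsError(f"index {tuple(idx)} outside dims {self.dims}")
        return self.grid.index_to_world(idx)

    def world_to_continuous_index(self, point) -> np.ndarray:
        return self.grid.world_to_continuous_index(point)


@dataclass
class RigidTransform:
    """6-DOF world-to-world map ``p -> R @ p + t`` (mm, LPS)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3) or not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise GeometryError("rotation must be a 3x3 orthonormal matrix")
        if abs(np.linalg.det(r) - 1.0) > 1e-8:
            raise GeometryError("rotation determinant must be +1 (proper rotation)")
        self.rotation = r
        self.translation = _as_vec3(self.translation, "translation")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler(cls, angles_deg, translation=(0.0, 0.0, 0.0), center=None) -> "RigidTransform":
        """Rotation about world x, y, z applied in z*y*x order, then translation.

        With ``center`` given, rotation is about that world point.
        """
        r = Rotation.from_euler("xyz", np.asarray(angles_deg, dtype=float), degrees=True).as_matrix()
        t = _as_vec3(translation, "translation")
        if center is not None:
            c = _as_vec3(center, "center")
            t = t + c - r @ c
        return cls(rotation=r, translation=t)

    @classmethod
    def from_matrix(cls, matrix) -> "RigidTransform":
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise GeometryError("homogeneous matrix must be 4x4")
        return cls(rotation=m[:3, :3], translation=m[:3, 3])

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self  o  other`` (apply ``other`` first)."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    def euler_angles_deg(self) -> np.ndarray:
        """Angles (about x, y, z; z*y*x composition order) in degrees."""
        return Rotation.from_matrix(self.rotation).as_euler("xyz", degrees=True)


def resample(
    volume: VoxelVolume,
    target: Grid,
    transform: RigidTransform | None = None,
    interpolation: str = "trilinear",
    fill_value: float = -1000.0,
) -> VoxelVolume:
    """Resample ``volume`` onto ``target``, pulling values through ``transform``.

    ``transform`` maps target world space into source world space (identity if
    omitted). Each target voxel center is mapped into the source volume and
    interpolated; points outside the source extent receive ``fill_value``
    (default -1000, air on the CT scale).
    """
    if interpolation not in ("trilinear", "nearest"):
        raise GeometryError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "trilinear" else 0
    if transform is None:
        transform = RigidTransform.identity()

    nx, ny, nz = target.dims
    out = np.empty(target.dims, dtype=float)
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    idx_plane = np.stack([ii.ravel(), jj.ravel(), np.zeros(ii.size)], axis=1)
    # slice-by-slice keeps peak memory modest on full scanner-sized grids
    for k in range(nz):
        idx_plane[:, 2] = k
        world = target.index_to_world(idx_plane)
        src_pts = transform.apply(world)
        cidx = volume.world_to_continuous_index(src_pts)
        vals = ndimage.map_coordinates(
            volume.values,
            cidx.T,
            order=order,
            mode="constant",
            cval=fill_value,
            prefilter=False,
        )
        out[:, :, k] = vals.reshape(nx, ny)
    return VoxelVolume(values=out, grid=target, value_kind=volume.value_kind)
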