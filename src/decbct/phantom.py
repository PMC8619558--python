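"""Synthetic dual-energy phantom and jaw-like test scenes.

Volumes are rendered directly in the image domain from analytic scene
geometry: no projection physics (spectra, scatter, reconstruction) is
simulated. Each voxel center is classified against the scene's primitives in
painter's order and assigned the material's CT number at the requested
energy channel, ``1000 * (mu - mu_water) / mu_water``, optionally plus a
radially quadratic bias field (a cone-beam cupping surrogate) and Gaussian
noise.

Material model
--------------
Every phantom/bone material belongs to a one-parameter *bone-equivalent
density* family: ``mu_channel = kappa_channel * rho`` with a per-channel
mass-attenuation constant ``kappa`` shared by the family and ``rho = 0`` for
air. Water has its own composition (``mu_water`` per channel), so the
low/high-kVp CT-number pairs of all family materials are exactly collinear
in the (low, high) plane — through air at (-1000, -1000) — and the material's
reference Hounsfield unit (its CT number at the MDCT effective energy) is
exactly affine along that line. This is precisely the assumption the
dual-energy density-line calibration makes, so on noiseless renders the
calibration is exact; noise and inter-modality bias are then added on top as
explicit, configurable corruptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ConfigurationError
from .geometry import Grid, RigidTransform, VoxelVolume

__all__ = [
    "MaterialSpec",
    "bone_equivalent_material",
    "default_materials",
    "Cylinder",
    "Tube",
    "Box",
    "ArchSegment",
    "Anchor",
    "PhantomScene",
    "NoiseConfig",
    "SimulatedStudy",
    "build_calibration_phantom",
    "build_jaw_scene",
    "render_ct",
    "region_masks",
    "simulate_paired_study",
    "default_cbct_grid",
    "default_mdct_grid",
    "WATER_MU",
    "BONE_KAPPA",
]

# linear attenuation of water (1/cm) at the three effective energies
WATER_MU = {"low": 0.22, "high": 0.18, "mdct": 0.20}
# linear attenuation per unit bone-equivalent density (1/cm per g/cm^3)
BONE_KAPPA = {"low": 0.30, "high": 0.21, "mdct": 0.25}

CHANNELS = ("low", "high", "mdct")


@dataclass(frozen=True)
class MaterialSpec:
    """Material with per-channel linear attenuation (1/cm)."""

    name: str
    mu_low: float
    mu_high: float
    mu_mdct: float | None = None
    known_hu: float | None = None
    is_bone: bool = False

    def __post_init__(self) -> None:
        for v, label in ((self.mu_low, "mu_low"), (self.mu_high, "mu_high")):
            if not math.isfinite(v) or v < 0:
                raise ConfigurationError(f"{self.name}: {label} must be finite and >= 0")

    def mu(self, channel: str) -> float:
        if channel == "low":
            return self.mu_low
        if channel == "high":
            return self.mu_high
        if channel == "mdct":
            if self.mu_mdct is None:
                raise ConfigurationError(f"material {self.name!r} has no mu for channel 'mdct'")
            return self.mu_mdct
        raise ConfigurationError(f"unknown channel {channel!r}")

    def ct_number(self, channel: str) -> float:
        """CT number 1000*(mu - mu_water)/mu_water at the channel's energy."""
        mu_w = WATER_MU[channel]
        return 1000.0 * (self.mu(channel) - mu_w) / mu_w


def bone_equivalent_material(
    name: str, hu: float, is_bone: bool = False, known: bool = False
) -> MaterialSpec:
    """Material from the bone-equivalent density family with reference HU ``hu``.

    ``rho`` is chosen so that the MDCT-channel CT number equals ``hu``; the
    low/high channel attenuations follow from the family's kappa constants.
    ``known=True`` certifies the HU for use as a calibration anchor.
    """
    rho = WATER_MU["mdct"] * (1.0 + hu / 1000.0) / BONE_KAPPA["mdct"]
    if rho < 0:
        raise ConfigurationError(f"{name}: HU {hu} below air (-1000)")
    return MaterialSpec(
        name=name,
        mu_low=BONE_KAPPA["low"] * rho,
        mu_high=BONE_KAPPA["high"] * rho,
        mu_mdct=BONE_KAPPA["mdct"] * rho,
        known_hu=hu if known else None,
        is_bone=is_bone,
    )


def default_materials() -> dict[str, MaterialSpec]:
    """Material table shared by the built-in scenes."""
    mats = [
        MaterialSpec("water", WATER_MU["low"], WATER_MU["high"], WATER_MU["mdct"]),
        bone_equivalent_material("air", -1000.0, known=True),
        bone_equivalent_material("acrylic", 120.0),
        bone_equivalent_material("soft_tissue", 40.0),
        bone_equivalent_material("trabecular", 150.0, is_bone=True),
        bone_equivalent_material("cortical", 800.0, is_bone=True),
    ]
    return {m.name: m for m in mats}


# ---------------------------------------------------------------------------
# scene primitives (painter's order: later primitives override earlier ones)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cylinder:
    material: str
    center: tuple[float, float, float]
    radius: float
    height: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        rel = points - np.asarray(self.center)
        r2 = rel[:, 0] ** 2 + rel[:, 1] ** 2
        return (r2 <= self.radius**2) & (np.abs(rel[:, 2]) <= self.height / 2.0)


@dataclass(frozen=True)
class Tube:
    material: str
    center: tuple[float, float, float]
    inner_radius: float
    outer_radius: float
    height: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        rel = points - np.asarray(self.center)
        r2 = rel[:, 0] ** 2 + rel[:, 1] ** 2
        return (
            (r2 >= self.inner_radius**2)
            & (r2 <= self.outer_radius**2)
            & (np.abs(rel[:, 2]) <= self.height / 2.0)
        )


@dataclass(frozen=True)
class Box:
    material: str
    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def contains(self, points: np.ndarray) -> np.ndarray:
        rel = np.abs(points - np.asarray(self.center))
        half = np.asarray(self.size) / 2.0
        return np.all(rel <= half, axis=1)


@dataclass(frozen=True)
class ArchSegment:
    """Partial annulus about the z axis: a horseshoe building block."""

    material: str
    center: tuple[float, float, float]
    inner_radius: float
    outer_radius: float
    height: float
    theta_start_deg: float
    theta_end_deg: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        rel = points - np.asarray(self.center)
        r2 = rel[:, 0] ** 2 + rel[:, 1] ** 2
        theta = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
        span = (self.theta_end_deg - self.theta_start_deg) % 360.0
        off = (theta - self.theta_start_deg) % 360.0
        return (
            (r2 >= self.inner_radius**2)
            & (r2 <= self.outer_radius**2)
            & (np.abs(rel[:, 2]) <= self.height / 2.0)
            & (off <= span)
        )


@dataclass(frozen=True)
class Anchor:
    label: str
    point: tuple[float, float, float]
    group: str | None = None


@dataclass
class PhantomScene:
    """Analytic scene: materials, primitives in painter's order, named anchors."""

    materials: dict[str, MaterialSpec]
    background: str
    primitives: list
    anchors: list[Anchor] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if self.background not in self.materials:
            raise ConfigurationError(f"background material {self.background!r} not in table")
        for prim in self.primitives:
            if prim.material not in self.materials:
                raise ConfigurationError(f"primitive references unknown material {prim.material!r}")

    @property
    def material_names(self) -> list[str]:
        """Background first, then primitive materials in first-use order."""
        names = [self.background]
        for prim in self.primitives:
            if prim.material not in names:
                names.append(prim.material)
        return names

    def material_index_at(self, points: np.ndarray) -> np.ndarray:
        """Index into :attr:`material_names` for each world point (painter's order)."""
        names = self.material_names
        lookup = {n: i for i, n in enumerate(names)}
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.zeros(len(pts), dtype=np.int16)
        for prim in self.primitives:
            inside = prim.contains(pts)
            out[inside] = lookup[prim.material]
        return out

    def material_at(self, points: np.ndarray) -> np.ndarray:
        names = np.asarray(self.material_names)
        return names[self.material_index_at(points)]

    def material_index_map(
        self, grid: Grid, world_transform: RigidTransform | None = None
    ) -> np.ndarray:
        """Material index for every voxel center of ``grid``.

        ``world_transform`` maps grid world points into scene world points
        (used to render a rigidly misaligned acquisition of the same scene).
        """
        nx, ny, nz = grid.dims
        out = np.empty(grid.dims, dtype=np.int16)
        ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        idx_plane = np.stack([ii.ravel(), jj.ravel(), np.zeros(ii.size)], axis=1)
        for k in range(nz):
            idx_plane[:, 2] = k
            pts = grid.index_to_world(idx_plane)
            if world_transform is not None:
                pts = world_transform.apply(pts)
            out[:, :, k] = self.material_index_at(pts).reshape(nx, ny)
        return out


# ---------------------------------------------------------------------------
# built-in scenes
# ---------------------------------------------------------------------------

DEFAULT_HA_INSERTS = (
    ("ha200", 250.0),
    ("ha400", 450.0),
    ("ha800", 850.0),
    ("ha1200", 1250.0),
)


def build_calibration_phantom(
    densities=DEFAULT_HA_INSERTS,
    base_radius: float = 40.0,
    insert_radius: float = 6.0,
    height: float = 16.0,
) -> PhantomScene:
    """Acrylic cylinder with one air insert and HA inserts on a ring.

    ``densities`` is a sequence of ``(name, known_hu)`` pairs for the
    hydroxyapatite inserts; each insert (plus the air bore) gets a named
    anchor at its center.
    """
    densities = list(densities)
    if len(densities) < 2:
        raise ConfigurationError("need at least 2 HA inserts")
    materials = default_materials()
    for name, hu in densities:
        materials[name] = bone_equivalent_material(name, float(hu), known=True)

    n_inserts = len(densities) + 1  # air + HA
    ring_radius = base_radius / 2.0
    if ring_radius + insert_radius >= base_radius:
        raise ConfigurationError("insert ring does not fit inside the base")
    min_gap = 2.0 * ring_radius * math.sin(math.pi / n_inserts)
    if min_gap <= 2.0 * insert_radius:
        raise ConfigurationError("inserts overlap on the ring")

    prims: list = [Cylinder("acrylic", (0.0, 0.0, 0.0), base_radius, height)]
    anchors: list[Anchor] = []
    names = ["air"] + [name for name, _ in densities]
    for i, name in enumerate(names):
        theta = 2.0 * math.pi * i / n_inserts
        c = (ring_radius * math.cos(theta), ring_radius * math.sin(theta), 0.0)
        prims.append(Cylinder(name, c, insert_radius, height))
        anchors.append(Anchor(label=name, point=c))
    return PhantomScene(materials=materials, background="water", primitives=prims, anchors=anchors)


def build_jaw_scene(
    arch_radius: float = 25.0,
    cortical_thickness: float = 3.0,
    n_mandible_anchors: int = 9,
    n_maxilla_anchors: int = 6,
    bone_width: float = 9.0,
    bone_height: float = 12.0,
) -> PhantomScene:
    """Horseshoe cortical shell with trabecular core in soft tissue.

    Anchors sit in the cortical wall: ``n_mandible_anchors`` along the outer
    cortical band and ``n_maxilla_anchors`` along the inner band, labelled by
    group so downstream agreement reports can split mandible vs maxilla.
    The defaults leave each anchor's 1.4 mm x 5 mm reference cylinder fully
    inside cortical material.
    """
    if cortical_thickness < 2.0:
        raise ConfigurationError("cortical_thickness must be >= 2 mm to admit the largest ROI")
    if bone_width <= 2.0 * cortical_thickness:
        raise ConfigurationError("bone_width leaves no trabecular core")
    if bone_height < 5.0 + 2.0:
        raise ConfigurationError("bone_height too small for a 5 mm ROI with margin")

    materials = default_materials()
    r_in = arch_radius - bone_width / 2.0
    r_out = arch_radius + bone_width / 2.0
    t = cortical_thickness
    theta0, theta1 = -30.0, 210.0
    inset_deg = math.degrees(t / r_in)
    prims = [
        ArchSegment("cortical", (0, 0, 0), r_in, r_out, bone_height, theta0, theta1),
        ArchSegment(
            "trabecular",
            (0, 0, 0),
            r_in + t,
            r_out - t,
            bone_height - 2.0 * t,
            theta0 + inset_deg,
            theta1 - inset_deg,
        ),
    ]

    anchors: list[Anchor] = []
    r_mand = r_out - t / 2.0
    for i, theta in enumerate(np.linspace(0.0, 180.0, n_mandible_anchors)):
        th = math.radians(theta)
        anchors.append(
            Anchor(
                label=f"mandible_{i + 1}",
                point=(r_mand * math.cos(th), r_mand * math.sin(th), 0.0),
                group="mandible",
            )
        )
    r_max = r_in + t / 2.0
    for i, theta in enumerate(np.linspace(15.0, 165.0, n_maxilla_anchors)):
        th = math.radians(theta)
        anchors.append(
            Anchor(
                label=f"maxilla_{i + 1}",
                point=(r_max * math.cos(th), r_max * math.sin(th), 0.0),
                group="maxilla",
            )
        )
    return PhantomScene(
        materials=materials, background="soft_tissue", primitives=prims, anchors=anchors
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def default_cbct_grid(nz: int = 64) -> Grid:
    """334 x 334 in-plane at 0.3 mm pitch, 0.3 mm slices, centered on the scene."""
    return Grid.centered((334, 334, nz), (0.3, 0.3, 0.3))


def default_mdct_grid(nz: int = 32) -> Grid:
    """512 x 512 in-plane at 0.332 mm pitch, 0.75 mm slices, centered on the scene."""
    return Grid.centered((512, 512, nz), (0.332, 0.332, 0.75))


def render_ct(
    scene: PhantomScene,
    grid: Grid,
    channel: str,
    noise_sd: float = 0.0,
    bias_amplitude: float = 0.0,
    seed=None,
    world_transform: RigidTransform | None = None,
    value_bias: dict[str, float] | None = None,
) -> VoxelVolume:
    """Render the scene on ``grid`` at one energy channel.

    ``value_bias`` optionally multiplies selected materials' CT numbers
    (used to inject a known inter-modality offset on bone). The radial bias
    field, when enabled, is ``bias_amplitude * ((r/r_ref)^2 - 1/2)`` with
    ``r`` the in-plane distance from the grid's world center. Deterministic
    for a fixed ``seed``.
    """
    if channel not in CHANNELS:
        raise ConfigurationError(f"unknown channel {channel!r}")
    names = scene.material_names
    table = np.empty(len(names))
    for i, n in enumerate(names):
        ct = scene.materials[n].ct_number(channel)  # raises if mu missing
        if value_bias and n in value_bias:
            ct = ct * value_bias[n]
        table[i] = ct

    mat_map = scene.material_index_map(grid, world_transform=world_transform)
    values = table[mat_map]

    if bias_amplitude != 0.0:
        nx, ny, _ = grid.dims
        sp = np.asarray(grid.spacing)
        xs = (np.arange(nx) - (nx - 1) / 2.0) * sp[0]
        ys = (np.arange(ny) - (ny - 1) / 2.0) * sp[1]
        r2 = xs[:, None] ** 2 + ys[None, :] ** 2
        r_ref2 = max(xs[-1] ** 2, ys[-1] ** 2)
        values += (bias_amplitude * (r2 / r_ref2 - 0.5))[:, :, None]

    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)

    kind = "hu" if channel == "mdct" else "raw_ct"
    return VoxelVolume(values=values, grid=grid, value_kind=kind)


def region_masks(
    scene: PhantomScene, grid: Grid, include_background: bool = False
) -> dict[str, np.ndarray]:
    """Boolean voxel mask per material on ``grid`` (painter's order resolved)."""
    mat_map = scene.material_index_map(grid)
    names = scene.material_names
    out = {}
    for i, n in enumerate(names):
        if i == 0 and not include_background:
            continue
        out[n] = mat_map == i
    return out


@dataclass(frozen=True)
class NoiseConfig:
    """Additive corruption levels (CT-number units)."""

    cbct_sd: float = 30.0
    mdct_sd: float = 15.0
    bias_amplitude: float = 0.0

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(cbct_sd=0.0, mdct_sd=0.0, bias_amplitude=0.0)


@dataclass
class SimulatedStudy:
    """Paired dual-energy CBCT + misaligned MDCT render of one scene."""

    vol_low: VoxelVolume
    vol_high: VoxelVolume
    vol_mdct: VoxelVolume
    true_transform: RigidTransform
    region_masks: dict[str, np.ndarray]
    scene: PhantomScene
    seed: int


def simulate_paired_study(
    scene: PhantomScene,
    misalignment: RigidTransform | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    cbct_grid: Grid | None = None,
    mdct_grid: Grid | None = None,
    mdct_bone_bias: float = 0.95,
) -> SimulatedStudy:
    """Render the study: low/high-kVp CBCT on one grid, MDCT on another.

    ``misalignment`` maps MDCT world points to scene (CBCT) world points and
    is recorded as the study's ground-truth registration transform.
    ``mdct_bone_bias`` multiplies bone materials' MDCT CT numbers (default
    0.95, i.e. the DE-CBCT reads ~5% higher than MDCT on bone).
    """
    if misalignment is None:
        misalignment = RigidTransform.identity()
    if noise is None:
        noise = NoiseConfig()
    cbct_grid = cbct_grid or default_cbct_grid()
    mdct_grid = mdct_grid or default_mdct_grid()

    seeds = np.random.SeedSequence(seed).spawn(3)
    vol_low = render_ct(
        scene, cbct_grid, "low", noise_sd=noise.cbct_sd,
        bias_amplitude=noise.bias_amplitude, seed=seeds[0],
    )
    vol_high = render_ct(
        scene, cbct_grid, "high", noise_sd=noise.cbct_sd,
        bias_amplitude=noise.bias_amplitude, seed=seeds[1],
    )
    bias_table = {
        m.name: mdct_bone_bias for m in scene.materials.values() if m.is_bone
    } if mdct_bone_bias != 1.0 else None
    vol_mdct = render_ct(
        scene, mdct_grid, "mdct", noise_sd=noise.mdct_sd, seed=seeds[2],
        world_transform=misalignment, value_bias=bias_table,
    )
    masks = region_masks(scene, cbct_grid)
    return SimulatedStudy(
        vol_low=vol_low,
        vol_high=vol_high,
        vol_mdct=vol_mdct,
        true_transform=misalignment,
        region_masks=masks,
        scene=scene,
        seed=seed,
    )
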