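import numpy as np
import pytest

from decbct.geometry import Grid, RigidTransform
from decbct.phantom import (
    NoiseConfig,
    build_calibration_phantom,
    build_jaw_scene,
    render_ct,
    region_masks,
    simulate_paired_study,
)


def rotation_error_deg(r_est: np.ndarray, r_true: np.ndarray) -> float:
    """Geodesic angle between two rotation matrices, in degrees."""
    c = (np.trace(r_est @ r_true.T) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def transform_errors(est: RigidTransform, true: RigidTransform) -> tuple[float, float]:
    """(translation error in mm, rotation error in degrees)."""
    dt = float(np.linalg.norm(est.translation - true.translation))
    return dt, rotation_error_deg(est.rotation, true.rotation)


@pytest.fixture(scope="session")
def small_grid() -> Grid:
    """Coarse grid that still resolves the calibration phantom's inserts."""
    return Grid.centered((120, 120, 40), (0.8, 0.8, 0.5))


@pytest.fixture(scope="session")
def cal_scene():
    return build_calibration_phantom()


@pytest.fixture(scope="session")
def cal_noiseless(cal_scene, small_grid):
    """Noiseless low/high renders + region masks of the calibration phantom."""
    vol_low = render_ct(cal_scene, small_grid, "low")
    vol_high = render_ct(cal_scene, small_grid, "high")
    masks = region_masks(cal_scene, small_grid)
    return vol_low, vol_high, masks


@pytest.fixture(scope="session")
def jaw_scene():
    return build_jaw_scene()


# reduced grids: same scene and physics as the full study at ~2x coarser pitch,
# keeping registration unit tests fast
REDUCED_CBCT = ((167, 167, 48), (0.6, 0.6, 0.4))
REDUCED_MDCT = ((256, 256, 24), (0.664, 0.664, 1.0))


def reduced_study(scene, misalignment=None, noise=None, seed=0, mdct_bone_bias=0.95):
    return simulate_paired_study(
        scene,
        misalignment=misalignment,
        noise=noise or NoiseConfig.none(),
        seed=seed,
        cbct_grid=Grid.centered(*REDUCED_CBCT),
        mdct_grid=Grid.centered(*REDUCED_MDCT),
        mdct_bone_bias=mdct_bone_bias,
    )


@pytest.fixture(scope="session")
def jaw_study_reduced(jaw_scene):
    """Noiseless reduced-grid study with a known 3 mm / 5 deg misalignment."""
    t = RigidTransform.from_euler((0.0, 0.0, 5.0), translation=(3.0, 0.0, 0.0))
    return reduced_study(jaw_scene, misalignment=t, seed=11)
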