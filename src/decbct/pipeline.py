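"""End-to-end assembly: phantom calibration -> jaw study -> agreement report.

This module chains the package's stages on synthetic data with known ground
truth: fit the dual-energy calibration on a rendered calibration phantom,
render a paired jaw study with a known rigid misalignment and an injected
inter-modality bone bias, calibrate the CBCT pair to HU, register the MDCT
volume (or use the known truth), transfer the anchor ROIs, and run the
agreement analysis. Both the CLI `pipeline` command and the acceptance
checks drive these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agreement import AgreementReport, agreement_report
from .calibration import CalibrationModel, extract_region_samples
from .geometry import Grid, RigidTransform
from .phantom import (
    NoiseConfig,
    PhantomScene,
    SimulatedStudy,
    build_calibration_phantom,
    build_jaw_scene,
    default_cbct_grid,
    default_mdct_grid,
    render_ct,
    region_masks,
    simulate_paired_study,
)
from .registration import RegistrationParams, RegistrationResult, estimate_rigid
from .roi import CylinderROI, PairedROIResult, paired_roi_means

__all__ = [
    "known_hu_table",
    "calibrate_synthetic_phantom",
    "rois_from_anchors",
    "default_misalignment",
    "EndToEndResult",
    "run_end_to_end",
]


def known_hu_table(scene: PhantomScene) -> dict[str, float]:
    """Certified HU anchors (air + HA inserts) from the scene's material table."""
    return {
        a.label: scene.materials[a.label].known_hu
        for a in scene.anchors
        if scene.materials.get(a.label) is not None
        and scene.materials[a.label].known_hu is not None
    }


def calibrate_synthetic_phantom(
    seed: int = 0,
    noise: NoiseConfig | None = None,
    grid: Grid | None = None,
    scene: PhantomScene | None = None,
    line_method: str = "tls",
):
    """Render the calibration phantom and fit the dual-energy model.

    Returns ``(model, scene, vol_low, vol_high, masks)``.
    """
    scene = scene or build_calibration_phantom()
    grid = grid or default_cbct_grid()
    noise = noise if noise is not None else NoiseConfig()
    s_low, s_high = np.random.SeedSequence(seed).spawn(2)
    vol_low = render_ct(scene, grid, "low", noise_sd=noise.cbct_sd,
                        bias_amplitude=noise.bias_amplitude, seed=s_low)
    vol_high = render_ct(scene, grid, "high", noise_sd=noise.cbct_sd,
                         bias_amplitude=noise.bias_amplitude, seed=s_high)
    masks = region_masks(scene, grid)
    samples = extract_region_samples(vol_low, vol_high, masks, known_hu_table(scene))
    model = CalibrationModel.fit(samples, line_method=line_method)
    return model, scene, vol_low, vol_high, masks


def rois_from_anchors(
    scene: PhantomScene, height: float = 4.5, diameter: float = 1.2
) -> list[CylinderROI]:
    """Axis-aligned clinical-size cylinders at every scene anchor."""
    return [
        CylinderROI(label=a.label, center=tuple(a.point), height=height,
                    diameter=diameter, group=a.group)
        for a in scene.anchors
    ]


def default_misalignment() -> RigidTransform:
    """Plausible inter-scan pose change: a few mm / a few degrees."""
    return RigidTransform.from_euler((2.0, -3.0, 5.0), translation=(3.0, -2.0, 1.5))


@dataclass
class EndToEndResult:
    model: CalibrationModel
    study: SimulatedStudy
    vol_hu: object  # calibrated DE-CBCT VoxelVolume
    registration: RegistrationResult | None
    paired: PairedROIResult
    report: AgreementReport


def run_end_to_end(
    seed: int = 0,
    misalignment: RigidTransform | None = None,
    noise: NoiseConfig | None = None,
    mdct_bone_bias: float = 0.95,
    use_registration: bool = True,
    cbct_grid: Grid | None = None,
    mdct_grid: Grid | None = None,
    jaw_scene: PhantomScene | None = None,
    registration_params: RegistrationParams | None = None,
    roi_height: float = 4.5,
    roi_diameter: float = 1.2,
) -> EndToEndResult:
    """Run the whole synthetic study and return every stage's output.

    With ``use_registration=False`` the known ground-truth transform stands
    in for the estimate, isolating downstream stages from registration error.
    """
    misalignment = misalignment if misalignment is not None else default_misalignment()
    noise = noise if noise is not None else NoiseConfig()
    cbct_grid = cbct_grid or default_cbct_grid()
    mdct_grid = mdct_grid or default_mdct_grid()

    ss = np.random.SeedSequence(seed)
    cal_seed, study_seed = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))

    model, _, _, _, _ = calibrate_synthetic_phantom(seed=cal_seed, noise=noise, grid=cbct_grid)

    scene = jaw_scene or build_jaw_scene()
    study = simulate_paired_study(
        scene,
        misalignment=misalignment,
        noise=noise,
        seed=study_seed,
        cbct_grid=cbct_grid,
        mdct_grid=mdct_grid,
        mdct_bone_bias=mdct_bone_bias,
    )
    vol_hu = model.apply(study.vol_low, study.vol_high)

    registration = None
    if use_registration:
        registration = estimate_rigid(vol_hu, study.vol_mdct, registration_params)
        mdct_to_cbct = registration.transform
    else:
        mdct_to_cbct = study.true_transform

    rois = rois_from_anchors(scene, height=roi_height, diameter=roi_diameter)
    paired = paired_roi_means(vol_hu, study.vol_mdct, rois, mdct_to_cbct.inverse())
    report = agreement_report(paired.pairs)
    return EndToEndResult(
        model=model, study=study, vol_hu=vol_hu,
        registration=registration, paired=paired, report=report,
    )
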