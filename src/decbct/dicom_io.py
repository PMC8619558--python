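"""Single-frame CT DICOM series reading/writing and NIfTI export.

The interchange dialect is one file per axial slice with consistent
geometry tags (ImagePositionPatient, ImageOrientationPatient, PixelSpacing,
rescale slope/intercept). Reading sorts slices by their projected position
along the slice normal — never by filename — and rejects mixed series and
non-uniform slice spacing. The world frame is LPS; a volume round-trips
through the writer/reader bit-exactly in geometry and within rescale
quantization in values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .errors import DicomIOError
from .geometry import Grid, VoxelVolume

__all__ = [
    "SeriesMetadata",
    "read_dicom_series",
    "write_dicom_series",
    "write_nifti",
]

_SPACING_TOL = 1e-3  # mm tolerance for slice-stack uniformity


@dataclass
class SeriesMetadata:
    modality: str
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    rescale_slope: float
    rescale_intercept: float
    series_uid: str
    study_uid: str
    n_slices: int
    value_kind: str = "raw_ct"


def read_dicom_series(directory) -> tuple[VoxelVolume, SeriesMetadata]:
    """Load one single-frame CT series from ``directory``.

    Values are mapped through rescale slope/intercept; geometry is assembled
    from the DICOM tags into an LPS :class:`VoxelVolume`.
    """
    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if f.lower().endswith(".dcm")
    )
    if not files:
        raise DicomIOError(f"no .dcm files in {directory}")
    slices = [pydicom.dcmread(f) for f in files]

    series_uids = {s.SeriesInstanceUID for s in slices}
    if len(series_uids) != 1:
        raise DicomIOError(f"directory mixes {len(series_uids)} series")

    iop = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    dir_x, dir_y = iop[:3], iop[3:]
    normal = np.cross(dir_x, dir_y)
    # sort by projected position along the slice normal, not by filename
    slices.sort(key=lambda s: float(np.dot(np.asarray(s.ImagePositionPatient, float), normal)))

    positions = np.array([np.dot(np.asarray(s.ImagePositionPatient, float), normal) for s in slices])
    if len(slices) > 1:
        gaps = np.diff(positions)
        if np.any(gaps <= 0):
            raise DicomIOError("duplicate or non-monotone slice positions")
        if np.ptp(gaps) > _SPACING_TOL:
            k = int(np.argmax(np.abs(gaps - np.median(gaps))))
            raise DicomIOError(
                f"non-uniform slice spacing: gap of {gaps[k]:.4f} mm after slice {k} "
                f"(median {np.median(gaps):.4f} mm)"
            )
        dz = float(np.mean(gaps))
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))

    ps = np.asarray(slices[0].PixelSpacing, dtype=float)  # (row, col) = (dy, dx)
    slope = float(getattr(slices[0], "RescaleSlope", 1.0))
    intercept = float(getattr(slices[0], "RescaleIntercept", 0.0))

    ny, nx = int(slices[0].Rows), int(slices[0].Columns)
    nz = len(slices)
    values = np.empty((nx, ny, nz), dtype=float)
    for k, s in enumerate(slices):
        if (int(s.Rows), int(s.Columns)) != (ny, nx):
            raise DicomIOError("inconsistent slice dimensions within series")
        arr = s.pixel_array.astype(float) * float(getattr(s, "RescaleSlope", slope)) + float(
            getattr(s, "RescaleIntercept", intercept)
        )
        values[:, :, k] = arr.T  # pixel_array is (rows=y, cols=x)

    direction = np.column_stack([dir_x, dir_y, normal])
    grid = Grid(
        dims=(nx, ny, nz),
        spacing=(float(ps[1]), float(ps[0]), dz),
        origin=tuple(np.asarray(slices[0].ImagePositionPatient, dtype=float)),
        direction=direction,
    )
    desc = str(getattr(slices[0], "SeriesDescription", ""))
    value_kind = "hu" if "HU" in desc.upper() else "raw_ct"
    meta = SeriesMetadata(
        modality=str(getattr(slices[0], "Modality", "CT")),
        pixel_spacing=(float(ps[0]), float(ps[1])),
        slice_thickness=dz,
        rescale_slope=slope,
        rescale_intercept=intercept,
        series_uid=slices[0].SeriesInstanceUID,
        study_uid=str(getattr(slices[0], "StudyInstanceUID", "")),
        n_slices=nz,
        value_kind=value_kind,
    )
    return VoxelVolume(values=values, grid=grid, value_kind=value_kind), meta


def write_dicom_series(
    volume: VoxelVolume,
    directory,
    series_description: str | None = None,
    rescale_intercept: float = -1024.0,
    rescale_slope: float = 1.0,
    study_uid: str | None = None,
) -> list[str]:
    """Write one file per slice; round-trips through :func:`read_dicom_series`.

    Stored pixels are unsigned 16-bit: ``stored = round((value - intercept)/slope)``.
    Values that do not fit the stored range after rescale raise an error
    rather than silently clipping.
    """
    os.makedirs(directory, exist_ok=True)
    stored = np.round((volume.values - rescale_intercept) / rescale_slope)
    if stored.min() < 0 or stored.max() > 65535:
        raise DicomIOError(
            f"values [{volume.values.min():.1f}, {volume.values.max():.1f}] do not fit "
            f"uint16 with slope {rescale_slope}, intercept {rescale_intercept}"
        )
    stored = stored.astype(np.uint16)

    series_uid = generate_uid()
    study_uid = study_uid or generate_uid()
    frame_uid = generate_uid()
    nx, ny, nz = volume.dims
    d = volume.direction
    desc = series_description or ("HU volume" if volume.value_kind == "hu" else "raw CT volume")

    paths = []
    for k in range(nz):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesDescription = desc
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = ny, nx
        ds.PixelSpacing = [f"{volume.spacing[1]:.10g}", f"{volume.spacing[0]:.10g}"]
        ds.SliceThickness = f"{volume.spacing[2]:.10g}"
        pos = volume.grid.index_to_world((0, 0, k))
        ds.ImagePositionPatient = [f"{v:.10g}" for v in pos]
        ds.ImageOrientationPatient = [f"{v:.10g}" for v in np.concatenate([d[:, 0], d[:, 1]])]
        ds.RescaleSlope = f"{rescale_slope:.10g}"
        ds.RescaleIntercept = f"{rescale_intercept:.10g}"
        ds.RescaleType = "HU" if volume.value_kind == "hu" else "US"
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()
        path = os.path.join(directory, f"slice_{k:04d}.dcm")
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def write_nifti(volume: VoxelVolume, path) -> None:
    """Debug-convenience NIfTI export (RAS affine derived from the LPS grid)."""
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = volume.direction @ np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    # LPS -> RAS: flip the first two world axes
    flip = np.diag([-1.0, -1.0, 1.0, 1.0])
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), flip @ affine), str(path))
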