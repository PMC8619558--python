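"""Typed exception hierarchy shared across the package."""


class DecbctError(Exception):
    """Base class for all package errors."""


class GeometryError(DecbctError, ValueError):
    """Invalid grid/transform geometry or mismatched volume grids."""


class BoundsError(DecbctError, IndexError):
    """Voxel index outside a volume's extent."""


class ConfigurationError(DecbctError, ValueError):
    """Invalid scene, material, or pipeline configuration."""


class DegenerateFitError(DecbctError, ValueError):
    """A model fit with no unique solution (coincident points, zero variance)."""


class EmptyROIError(DecbctError, ValueError):
    """A region of interest containing no voxel centers."""


class RegistrationError(DecbctError, RuntimeError):
    """Registration failed (no overlap, no bone voxels, divergence)."""


class DicomIOError(DecbctError, ValueError):
    """Malformed or inconsistent DICOM series."""
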