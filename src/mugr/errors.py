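"""Exception types raised across the pipeline."""


class MugrError(ValueError):
    """Base class for all package-specific errors."""


class SizingError(MugrError):
    """Zone layout does not tile the requested number of muscle units."""


class ResolutionError(MugrError):
    """Pixel size too coarse to resolve the junction-depth criterion."""


class CalibrationError(MugrError):
    """Missing or invalid micron-per-pixel calibration."""


class FragmentedTissueError(MugrError):
    """Muscle band broken; no single component spans the longitudinal axis."""


class DegenerateImageError(MugrError):
    """Channel carries no usable signal (constant intensity)."""


class InsufficientReplicatesError(MugrError):
    """Fewer sections supplied than required for patient-level averaging."""


class SchemaError(MugrError):
    """Object table does not match its declared column schema."""
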