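"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes (config -> 2, data -> 3, numerical -> 4).
"""


class AAAQuantError(Exception):
    """Base class for all package errors."""


class ConfigError(AAAQuantError):
    """Invalid configuration: unknown keys, out-of-range parameters, missing coefficients."""


class DataError(AAAQuantError):
    """Invalid or inconsistent input data (masks, meshes, volumes, tables)."""


class SizingError(DataError):
    """Geometry incompatible with the voxel grid (wall thinner than a voxel, landmark outside)."""


class VolumeFormatError(DataError):
    """A volume file could not be parsed as NIfTI or has a malformed header."""


class NumericalError(AAAQuantError):
    """Solver failure: singular stiffness, non-finite results."""


class UnsupportedFeatureError(AAAQuantError):
    """A requested operation is deliberately out of scope (e.g. non-rigid registration)."""
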