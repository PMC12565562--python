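"""Exception hierarchy for the radiomics pipeline.

Distinct error types per failure mode so callers (and the CLI exit-code
mapping) can distinguish data problems from contract violations.
"""


class RadiomicsError(Exception):
    """Base class for all package errors."""


class ShapeMismatchError(RadiomicsError):
    """Volume and mask (or paired arrays) do not share a shape."""


class VolumeDimensionError(RadiomicsError):
    """An image is not a 3D volume."""


class EmptyMaskError(RadiomicsError):
    """A tumor mask contains no voxels (or an empty intersection)."""


class DegenerateMaskError(RadiomicsError):
    """Synthetic mask generation failed to produce a usable VOI."""


class DegenerateVoiError(RadiomicsError):
    """A VOI cannot support the requested texture matrix (e.g. no voxel pairs)."""


class MissingFeatureError(RadiomicsError):
    """A required feature value is absent from a feature table."""


class ScreeningError(RadiomicsError):
    """Feature screening could not supply what descriptor derivation needs."""


class IntegrityError(RadiomicsError):
    """A serialized artifact fails its content-hash check."""


class ConfigError(RadiomicsError):
    """A study configuration is malformed or inconsistent."""
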