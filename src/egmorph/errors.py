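"""Exception hierarchy for egmorph.

All package-specific errors derive from :class:`EgmorphError` so callers can
catch one base class at pipeline boundaries.
"""


class EgmorphError(Exception):
    """Base class for all egmorph errors."""


class ConfigError(EgmorphError, ValueError):
    """A configuration value is missing, unknown or out of range."""


class MetadataError(EgmorphError, ValueError):
    """Required recording metadata is absent or unparseable."""


class ShapeError(EgmorphError, ValueError):
    """Sample matrix shape is inconsistent with the electrode grid."""


class SchemaError(EgmorphError, ValueError):
    """A serialized feature table does not match the expected schema."""


class UnsupportedFormatError(EgmorphError, ValueError):
    """The requested I/O format is not available in this build."""


class SamplingRateError(EgmorphError, ValueError):
    """Sampling rate too low to honour the acquisition band."""


class StimulusDetectionError(EgmorphError, RuntimeError):
    """No pacing stimuli could be located in a recording."""


class NoComplexError(EgmorphError, RuntimeError):
    """A beat window contains no detectable activation complex."""


class SingularityError(EgmorphError, ValueError):
    """An electrode coincides with a tissue node (1/r kernel diverges)."""


class EmptyConditionError(EgmorphError, ValueError):
    """A summary was requested for a condition with too few beats."""


class FitError(EgmorphError, RuntimeError):
    """A model fit failed to converge from every starting point."""
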