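"""Exception hierarchy.

``ValidationError`` subclasses signal malformed or contract-violating input
(CLI exit code 1); any other :class:`NiaflushError` is a runtime failure
(CLI exit code 2).
"""


class NiaflushError(Exception):
    """Base class for all errors raised by niaflush."""


class ValidationError(NiaflushError):
    """Invalid input: bad file, bad annotation, contract violation."""


class UnsupportedImageError(ValidationError):
    """Image is not decodable as 8-bit RGB."""


class AnnotationError(ValidationError):
    """Annotation sidecar is malformed or unparseable."""


class ShapeMismatchError(ValidationError):
    """Mask shape does not match the image."""


class OverlappingAreasError(ValidationError):
    """Irritated and control areas intersect."""


class EmptyAreaError(ValidationError):
    """A required pixel region is empty."""


class DuplicateMeasurementError(ValidationError):
    """More than one record for a (concentration, time) grid cell."""


class OffGridError(ValidationError):
    """Concentration or time point outside the measurement grid."""


class IncompleteSessionError(ValidationError):
    """A response call was requested for a session with missing cells."""


class ConfigError(ValidationError):
    """Configuration file is malformed or holds invalid values."""


class AnalysisError(NiaflushError):
    """Statistical analysis cannot be carried out on the given data."""
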