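"""Exception hierarchy shared across the package.

Every error raised by the analysis carries enough context (nucleus id,
locus name, file/line) to locate the offending input record.
"""


class NucorgError(Exception):
    """Base class for all package errors."""


class InvalidInputError(NucorgError, ValueError):
    """An argument violates a documented precondition."""


class ConfigError(NucorgError, ValueError):
    """A configuration value is malformed or inconsistent."""


class OutOfNucleusError(NucorgError):
    """A spot lies outside its nucleus beyond the clamping tolerance.

    Usually indicates a segmentation/ellipsoid-fit mismatch.
    """


class PairingError(NucorgError):
    """Two spots that must share a nucleus do not."""


class AnnotationError(NucorgError):
    """Locus annotation is inconsistent (e.g. chromosome mismatch)."""


class DataCompletenessError(NucorgError):
    """A joined analysis is missing required records; lists what is absent."""


class ResolutionError(NucorgError):
    """Voxel spacing too coarse to represent the object."""


class ParseError(NucorgError, ValueError):
    """A table could not be parsed; message names file, line and column."""


class PipelineOrderError(NucorgError):
    """An operation ran before one of its prerequisites (e.g. BH adjustment)."""


class InsufficientDataError(NucorgError):
    """Not enough observations for the requested statistic."""
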