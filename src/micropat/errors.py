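"""Exception hierarchy for the micropat pipeline.

Every stage raises a subclass of :class:`MicropatError` so that the CLI can
report failures with a stage name and a cause without a traceback.
"""


class MicropatError(Exception):
    """Base class for all package errors."""


class FormatError(MicropatError):
    """An input file is not in a supported format (wrong bit depth, RGB, ...)."""


class ValidationError(MicropatError):
    """A domain object violates its invariants (bad polygon, bad intensities)."""


class SchemaError(MicropatError):
    """Tabular records do not share a key set, or a requested key is absent."""


class DetectionError(MicropatError):
    """No island could be found in the image."""


class AmbiguityError(DetectionError):
    """Several foreground components of comparable size; the island is ambiguous."""

    def __init__(self, message, candidate_areas=None):
        super().__init__(message)
        self.candidate_areas = list(candidate_areas or [])


class GeometryError(MicropatError):
    """A geometric construction failed (ray misses boundary, segment off-image)."""


class ParameterError(MicropatError):
    """A parameter value is outside its valid domain."""


class EmptyInputError(MicropatError):
    """An operation received no data to work on."""


class PlacementError(MicropatError):
    """A sampling ROI does not fit inside the island boundary."""


class QuantificationError(MicropatError):
    """A sampling region contains no pixels."""


class ArithmeticDomainError(MicropatError):
    """A ratio or other derived quantity is undefined (non-positive denominator)."""


class AlignmentError(MicropatError):
    """Profiles to be averaged do not share length or sample spacing."""


class PackingError(MicropatError):
    """Requested cell count cannot be placed at the required minimum separation."""


class StageError(MicropatError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
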