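"""Exception hierarchy for the processing pipeline.

All errors raised deliberately by this package derive from :class:`GcmsPipeError`
so callers can catch pipeline problems without masking programming errors.
"""


class GcmsPipeError(Exception):
    """Base class for all errors raised by gcmspipe."""


class FormatError(GcmsPipeError):
    """A file could not be parsed under its declared format."""


class DataError(GcmsPipeError):
    """A file parsed, but its content violates a data invariant."""


class InputError(GcmsPipeError):
    """An in-memory argument violates an operation precondition."""


class CalibrationError(GcmsPipeError):
    """Retention-index calibration could not be established."""


class LibraryValidationError(GcmsPipeError):
    """An MSRI library entry violates a library invariant."""


class DesignError(GcmsPipeError):
    """A synthetic experiment design is infeasible under its constraints."""


class PipelineError(GcmsPipeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
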