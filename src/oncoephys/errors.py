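"""Exception hierarchy.

Everything derives from :class:`OncoephysError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from the closest builtin so generic handling keeps working.
"""


class OncoephysError(Exception):
    """Base class for all errors raised by this package."""


class UnitError(OncoephysError, ValueError):
    """A time series carries the wrong unit tag for the operation."""


class ParameterError(OncoephysError, ValueError):
    """A physical or model parameter violates its constraints."""


class InputError(OncoephysError, ValueError):
    """Degenerate or malformed input data (too short, empty, inconsistent)."""


class DataError(OncoephysError, ValueError):
    """Non-finite or otherwise corrupt sample data."""


class FormatError(OncoephysError, ValueError):
    """A file does not conform to the expected on-disk layout."""


class AnnotationError(OncoephysError, ValueError):
    """Phase or segment annotations are inconsistent (overlap, bad order)."""


class ResolutionError(OncoephysError, ValueError):
    """Requested structure is unresolvable at the given sampling rate."""


class PipelineError(OncoephysError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
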