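"""Exception hierarchy shared across the package."""


class MycolinguaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MycolinguaError):
    """A text file does not conform to the documented on-disk layout."""


class ValidationError(MycolinguaError):
    """A domain object violates one of its invariants."""


class InputTooShortError(MycolinguaError):
    """A signal is shorter than the analysis window requires."""


class EstimationError(MycolinguaError):
    """Not enough data to estimate the requested quantity."""


class FitUndefinedError(MycolinguaError):
    """A model fit is requested on degenerate data."""


class PlacementError(MycolinguaError):
    """A synthetic feature does not fit inside the recording."""


class UsageError(MycolinguaError):
    """An unknown option, preset name or mode string was supplied."""


class PipelineError(MycolinguaError):
    """A pipeline stage failed; the message names the stage and cause."""
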