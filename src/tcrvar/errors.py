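"""Exception hierarchy shared across the package."""


class TcrvarError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TcrvarError):
    """An input object violates a documented invariant."""


class FormatError(TcrvarError):
    """A file or table does not match the expected layout."""


class AlignmentError(TcrvarError):
    """Sample identifiers of two inputs do not line up."""


class UndefinedCorrelationError(TcrvarError):
    """A correlation is requested on data with zero rank variance or too few points."""


class UndefinedFitError(TcrvarError):
    """A regression fit is requested on degenerate data."""


class PipelineError(TcrvarError):
    """A pipeline stage failed or its prerequisites are missing."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
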