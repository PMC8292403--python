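"""Exception hierarchy shared across the package."""


class GravisynError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(GravisynError, ValueError):
    """An argument is outside its documented domain."""


class InsufficientDataError(GravisynError, ValueError):
    """Not enough data to perform the requested operation."""


class DegenerateInputError(GravisynError, ValueError):
    """Input is structurally valid but degenerate (e.g. all-zero matrix)."""


class DegenerateChannelError(DegenerateInputError):
    """A specific muscle channel is constant / zero-variance.

    Carries the offending channel label so callers can report it.
    """

    def __init__(self, label: str, message: str | None = None):
        self.label = label
        super().__init__(message or f"degenerate channel: {label!r}")
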