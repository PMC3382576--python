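"""Exception hierarchy shared across the package."""


class FossilCompError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(FossilCompError):
    """A delimited input file does not have the expected structure."""


class TableValidationError(FossilCompError, ValueError):
    """A parsed table violates one of its invariants."""


class UnknownKeyError(FossilCompError, KeyError):
    """An element/part key is absent from the active contribution table."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


class BinLookupError(FossilCompError, KeyError):
    """A substage identifier cannot be resolved against the time-bin table."""

    def __str__(self) -> str:
        return self.args[0] if self.args else ""


class InsufficientDataError(FossilCompError, ValueError):
    """Too few complete observations for the requested fit or test."""


class DegenerateModelError(FossilCompError, ValueError):
    """The sampling model cannot be fitted (e.g. zero proxy variance)."""


class UndefinedStatisticError(FossilCompError, ValueError):
    """A rank statistic is undefined (e.g. zero variance in ranks)."""
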