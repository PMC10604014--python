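"""Exception hierarchy shared across the package."""


class CTPScreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CTPScreenError, ValueError):
    """An invalid parameter or simulation configuration."""


class UniverseError(CTPScreenError, ValueError):
    """Gene identifiers requested that are absent from a profile universe."""


class DisjointSetError(CTPScreenError, ValueError):
    """A query gene set shares no members with the profile universe."""


class MatrixFormatError(CTPScreenError, ValueError):
    """A matrix file violates its declared layout (ragged, duplicates,
    invalid permutation, negative expression)."""


class GMTFormatError(CTPScreenError, ValueError):
    """A malformed GMT line; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class UndefinedMetricError(CTPScreenError, ValueError):
    """A performance metric requested on an empty ground-truth category."""
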