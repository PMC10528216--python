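"""Exception hierarchy shared by all pipeline stages.

Every error carries a stable ``category`` so the CLI can map failures to
exit codes without inspecting messages.
"""

from __future__ import annotations


class SecMpError(Exception):
    """Base class for all package errors."""

    category: str = "error"
    exit_code: int = 1


class ParseError(SecMpError):
    """Malformed input file (bad delimiter, non-numeric row, missing column)."""

    category = "parse"
    exit_code = 2

    def __init__(self, message: str, *, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)


class DomainError(SecMpError):
    """Input violates a physical or geometric precondition."""

    category = "domain"
    exit_code = 3


class ConfigurationError(SecMpError):
    """Missing or inconsistent configuration."""

    category = "configuration"
    exit_code = 4


class InsufficientDataError(SecMpError):
    """Not enough events / signal to carry out the requested analysis."""

    category = "insufficient-data"
    exit_code = 5


class ConditioningError(DomainError):
    """Extinction-coefficient matrix too close to singular to invert reliably."""


class InconsistencyError(DomainError):
    """Absorbance channels imply a strongly negative concentration."""


class PeakNotFoundError(DomainError):
    """No usable apex inside the requested search window."""
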