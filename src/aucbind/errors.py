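"""Exception hierarchy.

``ValidationError`` maps to CLI exit code 2, ``ConvergenceError`` to 3.
"""


class AucbindError(Exception):
    """Base class for all package errors."""


class ValidationError(AucbindError, ValueError):
    """Invalid parameter, configuration or input data."""


class ParseError(ValidationError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f", line {line}"
        super().__init__(f"{message} ({loc})" if loc else message)
        self.path = path
        self.line = line


class ConvergenceError(AucbindError, RuntimeError):
    """Optimizer failed to converge after all restarts."""
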