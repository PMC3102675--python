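"""Exception types shared across the package."""


class RechipError(Exception):
    """Base class for package errors."""


class ConfigurationError(RechipError, ValueError):
    """A simulation or pipeline configuration is infeasible or inconsistent."""


class ParseError(RechipError, ValueError):
    """An input file failed to parse.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" in {path}"
        if line is not None:
            loc += f" at line {line}"
        super().__init__(message + loc)


class GridMismatchError(RechipError, ValueError):
    """Window grids of two inputs (conditions, mapability track) disagree."""
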