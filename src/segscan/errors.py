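"""Exception hierarchy shared across the package."""


class SegscanError(Exception):
    """Base class for all package-specific errors."""


class InputError(SegscanError, ValueError):
    """Malformed or out-of-contract input data."""


class SchemaError(InputError):
    """A table file violates its declared schema (carries a line hint when known)."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ConfigError(SegscanError, ValueError):
    """Invalid configuration values."""


class StructuralError(SegscanError, ValueError):
    """Inconsistent object structure (mismatched maps, missing probe-pair members)."""


class UndefinedStatisticError(SegscanError, ArithmeticError):
    """A statistic is undefined for the given data (e.g. zero segregant variance)."""


class DegenerateNormalizationError(SegscanError, ArithmeticError):
    """Parental anchors coincide, so the affine normalization cannot be solved."""
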