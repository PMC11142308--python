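"""Exception types shared across the package."""


class AsocError(Exception):
    """Base class for package errors."""


class ConfigError(AsocError, ValueError):
    """Invalid simulation or analysis configuration."""


class GenerationError(AsocError, RuntimeError):
    """A synthetic dataset could not be generated under the constraints."""


class ParseError(AsocError, ValueError):
    """A malformed input row; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class SchemaError(AsocError, ValueError):
    """An input table is missing required columns."""
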