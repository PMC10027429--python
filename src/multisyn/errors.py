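"""Exception hierarchy shared across the package."""

from __future__ import annotations


class MultisynError(Exception):
    """Base class for all package errors."""


class FormatError(MultisynError):
    """Malformed input file.

    Carries the offending path and 1-based line number when known so CLI
    messages can point at the exact spot.
    """

    def __init__(self, message: str, *, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += str(path)
        if line is not None:
            prefix += f":{line}" if prefix else f"line {line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class ConfigError(MultisynError):
    """Invalid configuration file or parameter value."""


class LayoutError(MultisynError):
    """Geometry cannot be constructed from the given inputs."""


class RenderError(MultisynError):
    """SVG/PNG serialization failure."""
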