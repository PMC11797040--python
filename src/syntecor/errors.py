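"""Exception hierarchy shared by all syntecor modules.

Every error raised by the library derives from :class:`SyntecorError` so
callers (and the CLI) can map failures onto stable exit codes:
parse errors, validation/addressing errors, and I/O errors are distinct.
"""

from __future__ import annotations


class SyntecorError(Exception):
    """Base class for all syntecor errors."""


class ParseError(SyntecorError):
    """A file could not be parsed; carries the path and 1-based line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += str(path)
        if line is not None:
            prefix += f":{line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class StructuralError(ParseError):
    """A file parsed but violates a structural invariant (e.g. AGP gaps)."""


class ValidationError(SyntecorError):
    """An operation or parameter set is invalid."""


class AddressError(ValidationError):
    """An edit operation names a chromosome or block that does not exist."""


class UndoError(ValidationError):
    """Undo was requested but no prior state is stored."""


class GeneMappingError(ValidationError):
    """A gene position does not fall inside any contig interval."""
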