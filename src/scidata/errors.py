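"""Exception hierarchy for the scidata package.

All library errors derive from :class:`ScidataError` so callers can catch
one base class.  Parse-type errors carry location information where the
underlying source makes it available.
"""

from __future__ import annotations


class ScidataError(Exception):
    """Base class for all errors raised by this package."""


class ModelError(ScidataError):
    """Invalid construction or mutation of a model object."""


class NotFoundError(ScidataError):
    """An IRI or name did not resolve.

    ``candidates`` lists nearest-miss identifiers to aid debugging.
    """

    def __init__(self, message: str, candidates: list[str] | None = None):
        if candidates:
            message = f"{message} (nearest matches: {', '.join(candidates)})"
        super().__init__(message)
        self.candidates = candidates or []


class CycleError(ModelError):
    """A datagroup nesting operation would create a reference cycle."""


class UnitError(ScidataError):
    """Invalid unit definition or unit arithmetic."""


class IncompatibleUnitsError(UnitError):
    """Conversion attempted between units of different dimension."""


class CodecError(ScidataError):
    """JSON-LD serialization/deserialization failure."""


class ContextError(CodecError):
    """Invalid or unresolvable JSON-LD context."""


class SerializationError(CodecError):
    """Document failed strict-mode validation before serialization."""


class ParseError(CodecError):
    """Malformed input text.  ``line`` is 1-based when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class QueryError(ScidataError):
    """Ill-formed graph-pattern query."""


class JcampError(ScidataError):
    """Base for JCAMP-DX reader errors."""


class MalformedJcampError(JcampError, ParseError):
    """Structurally invalid JCAMP-DX file (missing ##TITLE= or ##END=)."""


class JcampIntegrityError(JcampError):
    """Declared and decoded point counts disagree."""


class UnsupportedEncodingError(JcampError):
    """Data table uses a compression scheme this reader does not decode."""
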