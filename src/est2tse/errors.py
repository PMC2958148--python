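"""Exception hierarchy.

Errors are categorized so the CLI can map them to distinct exit messages:
parse (malformed input text), integrity (references that do not resolve,
duplicates), spec (infeasible generator specifications), data (semantically
invalid values such as a missing control gene or negative follow-up time).
"""


class Est2TseError(Exception):
    """Base class for all package errors."""

    category = "error"


class ParseError(Est2TseError):
    """Malformed record in an input file; carries the offending line number."""

    category = "parse"

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f"{path}:"
        if line is not None:
            where += f"{line}: "
        elif where:
            where += " "
        super().__init__(where + message)


class IntegrityError(Est2TseError):
    """Cross-reference or uniqueness violation within a corpus or table."""

    category = "integrity"


class SpecError(Est2TseError):
    """Infeasible synthetic-fixture specification."""

    category = "spec"


class DataError(Est2TseError):
    """Semantically invalid data values."""

    category = "data"
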