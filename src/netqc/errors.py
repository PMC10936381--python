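"""Exception hierarchy shared by all netqc modules.

Each class maps to a distinct CLI exit code (see :mod:`netqc.cli`).
"""


class NetQCError(Exception):
    """Base class for all netqc errors."""

    exit_code = 1


class FormatError(NetQCError):
    """A file could not be parsed: missing column, non-numeric field, bad layout."""

    exit_code = 3


class ValidationError(NetQCError):
    """Input data violates a contract: duplicate ids, unknown class, empty input."""

    exit_code = 4


class GenerationError(NetQCError):
    """A synthetic generator could not satisfy its constraints."""

    exit_code = 5
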