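"""Exception hierarchy for the registry engine.

Every failure mode a caller can act on has its own class; the CLI maps
them onto exit codes (usage problems -> 2, data/integrity problems -> 3).
"""


class ChemXRefError(Exception):
    """Base class for all package errors."""


class NotFoundError(ChemXRefError):
    """A referenced source, release or store object does not exist."""


class ConflictError(ChemXRefError):
    """An object with the same unique key is already registered."""


class StoreIntegrityError(ChemXRefError):
    """An operation would violate an immutability or uniqueness contract."""


class KeyGenerationError(ChemXRefError):
    """The InChIKey backend could not produce a key for the given string."""


class InChIKeyFormatError(ChemXRefError):
    """A supplied InChIKey does not have the 27-character hyphenated form."""


class DumpParseError(ChemXRefError):
    """A source dump line could not be parsed; carries the line number."""

    def __init__(self, message: str, line_no: int | None = None):
        super().__init__(message)
        self.line_no = line_no


class EmptyReleaseError(ChemXRefError):
    """A load would leave the source with no accepted records (guarded)."""


class UnsupportedRollbackError(ChemXRefError):
    """Only the most recent non-rolled-back release of a source can be undone."""


class UnsupportedUrlsError(ChemXRefError):
    """The target source has no base URL, so URLs cannot be constructed."""
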