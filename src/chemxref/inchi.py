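"""Standard InChI validation, InChIKey generation and record filtering.

The registry accepts a record only after it survives five filtering rules:

R1  provided InChIKey does not match the key computed from the InChI
R2  no Standard InChI given
R3  an InChIKey cannot be generated from the given InChI
R4  no source compound identifier given
R5  the InChI string is longer than 2000 characters

Rules are evaluated in a fixed cheap-first order (R4, R2, R5, R3, R1) so
each rejected record is blamed on exactly one rule. Key generation is
delegated to an injectable backend: :class:`RDKitBackend` wraps the IUPAC
InChI library shipped with RDKit, while :class:`MockKeyBackend` is a
deterministic hash usable for registry/loader logic tests that do not
need real chemistry.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional, Protocol

from .errors import KeyGenerationError

STANDARD_PREFIX = "InChI=1S/"
NONSTANDARD_PREFIX = "InChI=1/"
MAX_INCHI_LENGTH = 2000
INCHIKEY_LENGTH = 27

RULES = ("R1", "R2", "R3", "R4", "R5")

RULE_DESCRIPTIONS = {
    "R1": "InChI / InChIKey mismatch",
    "R2": "no Standard InChI provided",
    "R3": "InChIKey could not be generated from the InChI",
    "R4": "no src_compound_id provided",
    "R5": "Standard InChI longer than 2000 characters",
}


@dataclass(frozen=True)
class SourceRecord:
    """One parsed row of a three-column source dump, prior to filtering."""

    src_compound_id: str
    std_inchi: Optional[str]
    std_inchikey: Optional[str]
    line_no: int


@dataclass(frozen=True)
class ValidationOutcome:
    """Result of running the filtering rules over one record."""

    accepted: bool
    rule_violated: Optional[str] = None
    computed_inchikey: Optional[str] = None
    comment: Optional[str] = None

    def __post_init__(self):
        assert self.accepted == (self.rule_violated is None)


class InChIKeyBackend(Protocol):
    """Contract: text InChI in, 27-character key out, or a typed failure."""

    name: str

    def key_from_inchi(self, std_inchi: str) -> str: ...


class RDKitBackend:
    """InChIKey generation through the IUPAC InChI library (via RDKit)."""

    name = "real"

    def __init__(self):
        from rdkit import RDLogger
        from rdkit.Chem import inchi as _inchi

        RDLogger.DisableLog("rdApp.*")
        self._to_key = _inchi.InchiToInchiKey

    def key_from_inchi(self, std_inchi: str) -> str:
        key = self._to_key(std_inchi)
        if not key or len(key) != INCHIKEY_LENGTH:
            raise KeyGenerationError(f"cannot generate InChIKey from {std_inchi[:60]!r}")
        return key


class MockKeyBackend:
    """Deterministic stand-in key generator for chemistry-free logic tests.

    Produces syntactically valid 27-character keys (14- and 10-letter
    blocks, hyphen-separated, trailing ``-N``) from a SHA-256 of the
    InChI string.  Keys agree between calls and processes but are NOT the
    IUPAC hash; never mix mock keys with real ones in one store.
    """

    name = "mock"

    def key_from_inchi(self, std_inchi: str) -> str:
        if not std_inchi.startswith(STANDARD_PREFIX):
            raise KeyGenerationError(f"not a Standard InChI: {std_inchi[:60]!r}")
        digest = hashlib.sha256(std_inchi.encode("utf-8")).hexdigest()
        letters = [chr(ord("A") + int(digest[i : i + 2], 16) % 26) for i in range(0, 48, 2)]
        block1 = "".join(letters[:14])
        block2 = "".join(letters[14:22]) + "SA"
        return f"{block1}-{block2}-N"


def get_backend(name: str) -> InChIKeyBackend:
    """Resolve a backend by its config name ('real' or 'mock')."""
    if name == "real":
        return RDKitBackend()
    if name == "mock":
        return MockKeyBackend()
    raise ValueError(f"unknown InChIKey backend {name!r}")


def is_valid_inchikey(key: str) -> bool:
    """Syntactic check: 27 chars in the 14-10-1 block layout (hyphens after
    the 14th and 25th characters), all other characters uppercase letters."""
    if len(key) != INCHIKEY_LENGTH or key[14] != "-" or key[25] != "-":
        return False
    body = key[:14] + key[15:25] + key[26:]
    return body.isalpha() and body == body.upper()


def generate_inchikey(std_inchi: str, backend: InChIKeyBackend) -> str:
    """Compute the Standard InChIKey for ``std_inchi``.

    Only strings carrying the Standard prefix ``InChI=1S/`` are accepted;
    non-standard ``InChI=1/`` strings raise :class:`KeyGenerationError`
    with a distinguishing message, as the registry stores Standard InChIs
    exclusively.  Pure for a fixed backend.
    """
    inchi = std_inchi.strip()
    if inchi.startswith(NONSTANDARD_PREFIX) and not inchi.startswith(STANDARD_PREFIX):
        raise KeyGenerationError("non-standard InChI (prefix 'InChI=1/'); only Standard InChI is supported")
    if not inchi.startswith(STANDARD_PREFIX):
        raise KeyGenerationError(f"not a Standard InChI: {inchi[:60]!r}")
    key = backend.key_from_inchi(inchi)
    if not is_valid_inchikey(key):
        raise KeyGenerationError(f"backend produced malformed key {key!r}")
    return key.upper()


def validate_record(
    rec: SourceRecord,
    source_provides_inchikey: bool = True,
    backend: Optional[InChIKeyBackend] = None,
) -> ValidationOutcome:
    """Apply filtering rules R1-R5 to one parsed dump record.

    Evaluation order is R4 (no id), R2 (no InChI), R5 (over-long InChI),
    R3 (key generation fails), R1 (key mismatch); the first violated rule
    is reported.  A record whose key column is empty but whose InChI is
    valid is accepted with the computed key and a comment noting the
    absence.  All failures are encoded as rejections, never exceptions.
    """
    backend = backend if backend is not None else RDKitBackend()

    src_id = (rec.src_compound_id or "").strip()
    inchi = (rec.std_inchi or "").strip()
    provided_key = (rec.std_inchikey or "").strip().upper()

    if not src_id:
        return ValidationOutcome(False, "R4")
    if not inchi:
        return ValidationOutcome(False, "R2")
    if len(inchi) > MAX_INCHI_LENGTH:
        return ValidationOutcome(False, "R5")
    try:
        computed = generate_inchikey(inchi, backend)
    except KeyGenerationError as exc:
        return ValidationOutcome(False, "R3", comment=str(exc))
    if not provided_key:
        comment = None
        if source_provides_inchikey:
            comment = "source omitted the InChIKey; key computed during load"
        return ValidationOutcome(True, computed_inchikey=computed, comment=comment)
    if provided_key != computed:
        return ValidationOutcome(False, "R1")
    return ValidationOutcome(True, computed_inchikey=computed)
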