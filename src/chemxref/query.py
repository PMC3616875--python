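"""Cross-reference queries over the registry.

All query routes answer the same underlying question — "which identifiers
in which sources point at the same Standard InChI?" — anchored either on
a (src_compound_id, src_id) pair, on an InChI/InChIKey, or on a whole
source.  Two modes exist everywhere:

* ``all``     — anchor on every structure the query id was ever assigned
  to and return current and obsolete assignment rows alike;
* ``current`` — anchor only on structures the id is *currently* assigned
  to and return only current rows.  A query id whose assignments are all
  obsolete therefore returns nothing in this mode.

Row order is fixed at (uci, src_id, src_compound_id) so output is
reproducible; structural columns are repeated on every row so callers can
cluster multi-structure results by sorting on them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

from .errors import InChIKeyFormatError, UnsupportedUrlsError
from .inchi import is_valid_inchikey
from .registry import CURRENT, Registry, Source

MATCHROW_FIELDS = (
    "src_compound_id",
    "src_id",
    "source_name",
    "status",
    "uci",
    "std_inchi",
    "std_inchikey",
)


@dataclass(frozen=True)
class MatchRow:
    """One result row: an assignment joined with its source and structure."""

    src_compound_id: str
    src_id: int
    source_name: str
    status: str
    uci: int
    std_inchi: str
    std_inchikey: str

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in MATCHROW_FIELDS}


_ROW_SQL = """
SELECT x.SRC_COMPOUND_ID, x.SRC_ID, s.NAME, x.ASSIGNMENT, x.UCI,
       t.STANDARDINCHI, t.STANDARDINCHIKEY
FROM UC_XREF x
JOIN UC_SOURCES s ON s.SRC_ID = x.SRC_ID
JOIN UC_STRUCTURES t ON t.UCI = x.UCI
"""
_ROW_ORDER = " ORDER BY x.UCI, x.SRC_ID, x.SRC_COMPOUND_ID"


def _rows_for_ucis(
    registry: Registry,
    ucis: set[int],
    mode: str,
    target_src_id: Optional[int],
) -> list[MatchRow]:
    if not ucis:
        return []
    placeholders = ",".join("?" for _ in ucis)
    sql = _ROW_SQL + f"WHERE x.UCI IN ({placeholders})"
    params: list = sorted(ucis)
    if mode == "current":
        sql += " AND x.ASSIGNMENT = ?"
        params.append(CURRENT)
    if target_src_id is not None:
        sql += " AND x.SRC_ID = ?"
        params.append(target_src_id)
    sql += _ROW_ORDER
    return [MatchRow(*r) for r in registry.connection.execute(sql, params).fetchall()]


def _check_mode(mode: str) -> None:
    if mode not in ("all", "current"):
        raise ValueError(f"mode must be 'all' or 'current', got {mode!r}")


def lookup(
    registry: Registry,
    src_compound_id: str,
    src_id: int,
    mode: str = "all",
    target_src_id: Optional[int] = None,
) -> list[MatchRow]:
    """Find all identifiers structurally equivalent to the query identifier.

    Resolves the query id's structure set (current assignments only in
    ``current`` mode; all assignments in ``all`` mode), then returns the
    assignment rows for those structures across every source — including
    the query row itself.  ``target_src_id`` restricts the output to one
    source.  An unknown id yields an empty list; an unregistered
    ``src_id`` raises ``NotFoundError`` (distinct from no matches).
    """
    _check_mode(mode)
    registry.get_source(src_id)
    if target_src_id is not None:
        registry.get_source(target_src_id)
    sql = "SELECT UCI FROM UC_XREF WHERE SRC_COMPOUND_ID=? AND SRC_ID=?"
    params: list = [src_compound_id.strip(), src_id]
    if mode == "current":
        sql += " AND ASSIGNMENT=?"
        params.append(CURRENT)
    ucis = {r[0] for r in registry.connection.execute(sql, params)}
    return _rows_for_ucis(registry, ucis, mode, target_src_id)


def lookup_as_urls(
    registry: Registry,
    src_compound_id: str,
    src_id: int,
    target_src_id: int,
) -> list[str]:
    """Current-mode matches in the target source, rendered as full URLs
    (base URL + src_compound_id).  Raises if the target publishes no
    compound-specific base URL."""
    target = registry.get_source(target_src_id)
    if not target.supports_urls:
        raise UnsupportedUrlsError(
            f"source {target.name!r} (src_id {target_src_id}) has no base URL"
        )
    rows = lookup(registry, src_compound_id, src_id, mode="current", target_src_id=target_src_id)
    return [target.base_url + row.src_compound_id for row in rows]


def search_structure(
    registry: Registry,
    key: str,
    key_type: str = "inchikey",
    mode: str = "all",
) -> list[MatchRow]:
    """Find every assignment of the structure given by an exact Standard
    InChI or InChIKey; empty list if the structure is unregistered.
    A syntactically malformed InChIKey raises
    :class:`~chemxref.errors.InChIKeyFormatError`."""
    _check_mode(mode)
    if key_type == "inchikey" and not is_valid_inchikey(key.strip().upper()):
        raise InChIKeyFormatError(
            f"{key!r} is not a 27-character hyphenated Standard InChIKey"
        )
    structure = registry.find_structure(key, key_type)
    if structure is None:
        return []
    return _rows_for_ucis(registry, {structure.uci}, mode, None)


def whole_source_mapping(
    registry: Registry,
    from_src_id: int,
    to_src_id: int,
    mode: str = "current",
) -> list[tuple[str, str]]:
    """Complete identifier mapping between two sources, joined on shared
    structures.  ``current`` mode joins only current assignments on both
    sides; pairs are deduplicated and sorted."""
    _check_mode(mode)
    registry.get_source(from_src_id)
    registry.get_source(to_src_id)
    sql = (
        "SELECT DISTINCT a.SRC_COMPOUND_ID, b.SRC_COMPOUND_ID"
        " FROM UC_XREF a JOIN UC_XREF b ON a.UCI = b.UCI"
        " WHERE a.SRC_ID=? AND b.SRC_ID=?"
    )
    params: list = [from_src_id, to_src_id]
    if mode == "current":
        sql += " AND a.ASSIGNMENT=? AND b.ASSIGNMENT=?"
        params += [CURRENT, CURRENT]
    pairs = registry.connection.execute(sql, params).fetchall()
    return sorted((a, b) for a, b in pairs)


def list_sources(registry: Registry) -> list[Source]:
    """All registered sources in src_id order."""
    return registry.list_sources()


def rows_to_tsv(rows: list[MatchRow], header: bool = True) -> str:
    lines = ["\t".join(MATCHROW_FIELDS)] if header else []
    for row in rows:
        lines.append("\t".join(str(getattr(row, f)) for f in MATCHROW_FIELDS))
    return "\n".join(lines) + ("\n" if lines else "")


def rows_to_json(rows: list[MatchRow]) -> str:
    return json.dumps([r.to_dict() for r in rows], indent=2)
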