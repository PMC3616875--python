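"""The four-table relational registry and its immutability contracts.

The store is a single-file SQLite database with tables named after the
schema they mirror:

* ``UC_STRUCTURES`` — one immutable row per distinct Standard InChI,
  keyed by an integer UCI allocated in registration order.
* ``UC_SOURCES``   — registered identifier namespaces.
* ``UC_XREF``      — (src_compound_id, src_id, UCI) assignments, flagged
  ``current`` or ``obsolete``; rows are appended, never rewritten except
  for the status flag and the last-release-current marker.
* ``UC_RELEASE``   — one row per load event, with per-rule reject counts.

Immutability is enforced in the database itself: triggers abort any
UPDATE or DELETE on ``UC_STRUCTURES`` and any rewrite of ``UC_XREF`` key
columns.  Deletes on ``UC_XREF`` are blocked unless the store is inside a
rollback, which is the single sanctioned way to restore a pre-load
snapshot (and even then structures persist).
"""

from __future__ import annotations

import datetime as _dt
import json
import sqlite3
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from .errors import ConflictError, NotFoundError, StoreIntegrityError
from .inchi import is_valid_inchikey

CURRENT = "current"
OBSOLETE = "obsolete"

_SCHEMA = """
CREATE TABLE UC_STRUCTURES (
    UCI              INTEGER PRIMARY KEY,
    STANDARDINCHI    TEXT NOT NULL UNIQUE,
    STANDARDINCHIKEY TEXT NOT NULL,
    FIRST_RELEASE_U  INTEGER NOT NULL
);
CREATE INDEX idx_structures_key ON UC_STRUCTURES (STANDARDINCHIKEY);

CREATE TABLE UC_SOURCES (
    SRC_ID      INTEGER PRIMARY KEY,
    NAME        TEXT NOT NULL UNIQUE,
    DESCRIPTION TEXT NOT NULL DEFAULT '',
    BASE_URL    TEXT
);

CREATE TABLE UC_XREF (
    SRC_COMPOUND_ID TEXT NOT NULL,
    SRC_ID          INTEGER NOT NULL REFERENCES UC_SOURCES (SRC_ID),
    UCI             INTEGER NOT NULL REFERENCES UC_STRUCTURES (UCI),
    ASSIGNMENT      TEXT NOT NULL CHECK (ASSIGNMENT IN ('current', 'obsolete')),
    LAST_REL_U_CUR  INTEGER,
    PRIMARY KEY (SRC_COMPOUND_ID, SRC_ID, UCI),
    CHECK ((ASSIGNMENT = 'obsolete') = (LAST_REL_U_CUR IS NOT NULL))
);
CREATE INDEX idx_xref_uci ON UC_XREF (UCI);
CREATE INDEX idx_xref_src ON UC_XREF (SRC_ID, ASSIGNMENT);

CREATE TABLE UC_RELEASE (
    RELEASE_U     INTEGER NOT NULL,
    SRC_ID        INTEGER NOT NULL REFERENCES UC_SOURCES (SRC_ID),
    VERSION_LABEL TEXT NOT NULL,
    LOAD_DATE     TEXT NOT NULL,
    N_LOADED      INTEGER NOT NULL,
    N_REJECTED    TEXT NOT NULL,
    ROLLED_BACK   INTEGER NOT NULL DEFAULT 0,
    PRIMARY KEY (RELEASE_U, SRC_ID)
);

-- audit of per-release UC_XREF changes; consulted only by rollback
CREATE TABLE UC_AUDIT (
    RELEASE_U           INTEGER NOT NULL,
    SRC_COMPOUND_ID     TEXT NOT NULL,
    SRC_ID              INTEGER NOT NULL,
    UCI                 INTEGER NOT NULL,
    CHANGE              TEXT NOT NULL CHECK (CHANGE IN ('inserted', 'to_current', 'to_obsolete')),
    PREV_LAST_REL_U_CUR INTEGER
);

-- release-level comments (dedup notes, computed-key notes, ...)
CREATE TABLE UC_COMMENTS (
    RELEASE_U INTEGER NOT NULL,
    SRC_ID    INTEGER NOT NULL,
    LINE_NO   INTEGER,
    COMMENT   TEXT NOT NULL
);

CREATE TABLE UC_META (KEY TEXT PRIMARY KEY, VALUE TEXT NOT NULL);

-- single-row latch that authorizes UC_XREF deletes during a rollback
CREATE TABLE UC_GUARD (ID INTEGER PRIMARY KEY CHECK (ID = 1), ROLLBACK_OK INTEGER NOT NULL);
INSERT INTO UC_GUARD VALUES (1, 0);

CREATE TRIGGER trg_structures_no_update BEFORE UPDATE ON UC_STRUCTURES
BEGIN SELECT RAISE(ABORT, 'UC_STRUCTURES rows are immutable'); END;
CREATE TRIGGER trg_structures_no_delete BEFORE DELETE ON UC_STRUCTURES
BEGIN SELECT RAISE(ABORT, 'UC_STRUCTURES rows are never deleted'); END;

CREATE TRIGGER trg_xref_key_frozen BEFORE UPDATE ON UC_XREF
WHEN NEW.SRC_COMPOUND_ID != OLD.SRC_COMPOUND_ID
  OR NEW.SRC_ID != OLD.SRC_ID OR NEW.UCI != OLD.UCI
BEGIN SELECT RAISE(ABORT, 'UC_XREF key columns are immutable'); END;

CREATE TRIGGER trg_xref_no_delete BEFORE DELETE ON UC_XREF
WHEN (SELECT ROLLBACK_OK FROM UC_GUARD) = 0
BEGIN SELECT RAISE(ABORT, 'UC_XREF rows are only removed by rollback'); END;
"""


@dataclass(frozen=True)
class Structure:
    uci: int
    std_inchi: str
    std_inchikey: str
    first_release_u: int


@dataclass(frozen=True)
class Source:
    src_id: int
    name: str
    description: str = ""
    base_url: Optional[str] = None

    @property
    def supports_urls(self) -> bool:
        return self.base_url is not None


@dataclass(frozen=True)
class Release:
    release_u: int
    src_id: int
    version_label: str
    load_date: str
    n_loaded: int
    n_rejected_by_rule: dict = field(default_factory=dict)
    rolled_back: bool = False


@dataclass(frozen=True)
class Assignment:
    src_compound_id: str
    src_id: int
    uci: int
    status: str
    last_release_u_current: Optional[int] = None


class Registry:
    """Handle on one registry store (a SQLite file or ``:memory:``)."""

    def __init__(self, path: str | Path = ":memory:", create: bool = True):
        self._path = str(path)
        # autocommit connection; atomicity comes from explicit transaction()
        self._conn = sqlite3.connect(self._path, isolation_level=None)
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._txn_depth = 0
        if not self._initialized():
            if not create:
                raise NotFoundError(f"no registry store at {self._path}")
            self._conn.executescript(_SCHEMA)
            self._conn.commit()

    # -- lifecycle ---------------------------------------------------------

    def _initialized(self) -> bool:
        row = self._conn.execute(
            "SELECT 1 FROM sqlite_master WHERE type='table' AND name='UC_STRUCTURES'"
        ).fetchone()
        return row is not None

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "Registry":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @contextmanager
    def transaction(self) -> Iterator[sqlite3.Connection]:
        """All-or-nothing scope; loads and rollbacks run inside one.
        Nested uses join the outermost transaction."""
        if self._txn_depth == 0:
            self._conn.execute("BEGIN")
        self._txn_depth += 1
        try:
            yield self._conn
        except BaseException:
            self._txn_depth -= 1
            if self._txn_depth == 0:
                self._conn.execute("ROLLBACK")
            raise
        else:
            self._txn_depth -= 1
            if self._txn_depth == 0:
                self._conn.execute("COMMIT")

    def set_meta(self, key: str, value: str) -> None:
        with self.transaction() as conn:
            conn.execute("INSERT OR REPLACE INTO UC_META VALUES (?, ?)", (key, value))

    def get_meta(self, key: str) -> Optional[str]:
        row = self._conn.execute("SELECT VALUE FROM UC_META WHERE KEY=?", (key,)).fetchone()
        return row[0] if row else None

    # -- structures --------------------------------------------------------

    def register_structure(self, std_inchi: str, std_inchikey: str, release_u: int) -> int:
        """Return the UCI for ``std_inchi``, allocating the next one if new.

        Idempotent: the same InChI always resolves to the same UCI, and an
        existing (UCI, InChI) row is never touched.  A key inconsistent
        with the stored key for the same InChI is an integrity error —
        such records must have been filtered upstream.
        """
        inchi = std_inchi.strip()
        key = std_inchikey.strip().upper()
        if not is_valid_inchikey(key):
            raise StoreIntegrityError(f"malformed InChIKey {std_inchikey!r}")
        row = self._conn.execute(
            "SELECT UCI, STANDARDINCHIKEY FROM UC_STRUCTURES WHERE STANDARDINCHI=?", (inchi,)
        ).fetchone()
        if row is not None:
            if row[1] != key:
                raise StoreIntegrityError(
                    f"InChIKey {key} conflicts with stored key {row[1]} for UCI {row[0]}"
                )
            return row[0]
        cur = self._conn.execute(
            "INSERT INTO UC_STRUCTURES (STANDARDINCHI, STANDARDINCHIKEY, FIRST_RELEASE_U)"
            " VALUES (?, ?, ?)",
            (inchi, key, release_u),
        )
        return cur.lastrowid

    def get_structure(self, uci: int) -> Structure:
        row = self._conn.execute(
            "SELECT UCI, STANDARDINCHI, STANDARDINCHIKEY, FIRST_RELEASE_U"
            " FROM UC_STRUCTURES WHERE UCI=?",
            (uci,),
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no structure with UCI {uci}")
        return Structure(*row)

    def find_structure(self, key: str, key_type: str) -> Optional[Structure]:
        """Exact lookup by 'inchi' or 'inchikey'; None if unregistered."""
        if key_type == "inchi":
            clause, value = "STANDARDINCHI=?", key.strip()
        elif key_type == "inchikey":
            clause, value = "STANDARDINCHIKEY=?", key.strip().upper()
        else:
            raise ValueError(f"key_type must be 'inchi' or 'inchikey', got {key_type!r}")
        row = self._conn.execute(
            f"SELECT UCI, STANDARDINCHI, STANDARDINCHIKEY, FIRST_RELEASE_U"
            f" FROM UC_STRUCTURES WHERE {clause}",
            (value,),
        ).fetchone()
        return Structure(*row) if row else None

    def count_structures(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM UC_STRUCTURES").fetchone()[0]

    # -- sources -----------------------------------------------------------

    def add_source(self, name: str, base_url: Optional[str] = None, description: str = "") -> int:
        """Register an identifier namespace; src_ids are allocated 1, 2, ..."""
        try:
            with self.transaction() as conn:
                cur = conn.execute(
                    "INSERT INTO UC_SOURCES (NAME, DESCRIPTION, BASE_URL) VALUES (?, ?, ?)",
                    (name, description, base_url),
                )
                return cur.lastrowid
        except sqlite3.IntegrityError:
            raise ConflictError(f"source name {name!r} already registered") from None

    def get_source(self, src_id: int) -> Source:
        row = self._conn.execute(
            "SELECT SRC_ID, NAME, DESCRIPTION, BASE_URL FROM UC_SOURCES WHERE SRC_ID=?",
            (src_id,),
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no source with src_id {src_id}")
        return Source(*row)

    def get_source_by_name(self, name: str) -> Source:
        row = self._conn.execute(
            "SELECT SRC_ID, NAME, DESCRIPTION, BASE_URL FROM UC_SOURCES WHERE NAME=?",
            (name,),
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no source named {name!r}")
        return Source(*row)

    def list_sources(self) -> list[Source]:
        rows = self._conn.execute(
            "SELECT SRC_ID, NAME, DESCRIPTION, BASE_URL FROM UC_SOURCES ORDER BY SRC_ID"
        ).fetchall()
        return [Source(*r) for r in rows]

    # -- releases ----------------------------------------------------------

    def next_release_u(self) -> int:
        row = self._conn.execute("SELECT COALESCE(MAX(RELEASE_U), 0) FROM UC_RELEASE").fetchone()
        return row[0] + 1

    def latest_release_u(self, src_id: int, include_rolled_back: bool = False) -> Optional[int]:
        """Most recent release_u of one source; None before its first load."""
        sql = "SELECT MAX(RELEASE_U) FROM UC_RELEASE WHERE SRC_ID=?"
        if not include_rolled_back:
            sql += " AND ROLLED_BACK=0"
        return self._conn.execute(sql, (src_id,)).fetchone()[0]

    def get_release(self, release_u: int) -> Release:
        row = self._conn.execute(
            "SELECT RELEASE_U, SRC_ID, VERSION_LABEL, LOAD_DATE, N_LOADED, N_REJECTED,"
            " ROLLED_BACK FROM UC_RELEASE WHERE RELEASE_U=?",
            (release_u,),
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no release with release_u {release_u}")
        return Release(row[0], row[1], row[2], row[3], row[4], json.loads(row[5]), bool(row[6]))

    def list_releases(self, src_id: Optional[int] = None) -> list[Release]:
        sql = (
            "SELECT RELEASE_U, SRC_ID, VERSION_LABEL, LOAD_DATE, N_LOADED, N_REJECTED,"
            " ROLLED_BACK FROM UC_RELEASE"
        )
        params: tuple = ()
        if src_id is not None:
            sql += " WHERE SRC_ID=?"
            params = (src_id,)
        rows = self._conn.execute(sql + " ORDER BY RELEASE_U", params).fetchall()
        return [Release(r[0], r[1], r[2], r[3], r[4], json.loads(r[5]), bool(r[6])) for r in rows]

    def _insert_release(
        self,
        release_u: int,
        src_id: int,
        version_label: str,
        n_loaded: int,
        n_rejected_by_rule: dict,
        load_date: Optional[str] = None,
    ) -> None:
        self._conn.execute(
            "INSERT INTO UC_RELEASE (RELEASE_U, SRC_ID, VERSION_LABEL, LOAD_DATE,"
            " N_LOADED, N_REJECTED) VALUES (?, ?, ?, ?, ?, ?)",
            (
                release_u,
                src_id,
                version_label,
                load_date or _dt.date.today().isoformat(),
                n_loaded,
                json.dumps(n_rejected_by_rule),
            ),
        )

    # -- assignments -------------------------------------------------------

    def get_assignments(
        self,
        src_id: Optional[int] = None,
        status: Optional[str] = None,
        uci: Optional[int] = None,
    ) -> list[Assignment]:
        sql = "SELECT SRC_COMPOUND_ID, SRC_ID, UCI, ASSIGNMENT, LAST_REL_U_CUR FROM UC_XREF"
        clauses, params = [], []
        for clause, value in (("SRC_ID=?", src_id), ("ASSIGNMENT=?", status), ("UCI=?", uci)):
            if value is not None:
                clauses.append(clause)
                params.append(value)
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        sql += " ORDER BY UCI, SRC_ID, SRC_COMPOUND_ID"
        return [Assignment(*r) for r in self._conn.execute(sql, params).fetchall()]

    def count_assignments(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM UC_XREF").fetchone()[0]

    def assignment_state(self) -> dict[tuple[str, int, int], tuple[str, Optional[int]]]:
        """Full UC_XREF snapshot keyed by the composite primary key; used by
        oracle-equivalence and rollback tests."""
        return {
            (r[0], r[1], r[2]): (r[3], r[4])
            for r in self._conn.execute(
                "SELECT SRC_COMPOUND_ID, SRC_ID, UCI, ASSIGNMENT, LAST_REL_U_CUR FROM UC_XREF"
            )
        }

    @property
    def connection(self) -> sqlite3.Connection:
        return self._conn
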