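"""Dump parsing and the release load / rollback algorithm.

A release load is one transaction that

1. allocates the next global ``release_u``,
2. filters the parsed records through rules R1-R5,
3. registers any new structures (immutably, first come first UCI),
4. reconciles the source's assignments with the accepted set:
   new pairs are inserted as *current*; pairs that were *obsolete* and
   re-appear flip back to *current*; pairs that were *current* but are
   absent from this release flip to *obsolete* and remember, in
   ``last_release_u_current``, the source's own previous release — the
   last occasion the assignment was current,
5. records the release row with per-rule reject counts and comments.

Only the most recent non-rolled-back release of a source can be rolled
back; rollback restores the exact pre-load assignment snapshot (including
removing rows the release inserted) but never deletes structures.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .errors import DumpParseError, EmptyReleaseError, NotFoundError, UnsupportedRollbackError
from .inchi import RULES, InChIKeyBackend, SourceRecord, validate_record
from .registry import CURRENT, OBSOLETE, Registry

HEADER_FIRST_FIELD = "src_compound_id"


@dataclass
class LoadReport:
    """Summary of one release load (or, for rollback, its inverse)."""

    release_u: int
    src_id: int
    version_label: str
    n_parsed: int = 0
    n_accepted: int = 0
    n_rejected_by_rule: dict[str, int] = field(default_factory=dict)
    n_new_structures: int = 0
    n_new_assignments: int = 0
    n_to_obsolete: int = 0
    n_to_current: int = 0
    comments: list[tuple[Optional[int], str]] = field(default_factory=list)
    rolled_back: bool = False

    def __post_init__(self):
        for rule in RULES:
            self.n_rejected_by_rule.setdefault(rule, 0)

    @property
    def n_rejected(self) -> int:
        return sum(self.n_rejected_by_rule.values())

    def to_dict(self) -> dict:
        return {
            "release_u": self.release_u,
            "src_id": self.src_id,
            "version_label": self.version_label,
            "n_parsed": self.n_parsed,
            "n_accepted": self.n_accepted,
            "n_rejected_by_rule": dict(self.n_rejected_by_rule),
            "n_new_structures": self.n_new_structures,
            "n_new_assignments": self.n_new_assignments,
            "n_to_obsolete": self.n_to_obsolete,
            "n_to_current": self.n_to_current,
            "comments": [list(c) for c in self.comments],
            "rolled_back": self.rolled_back,
        }


class ParsedDump(list):
    """A list of :class:`SourceRecord` that also carries parse-time comments
    (one per deduplicated line), so they can flow into the load report."""

    def __init__(self, records=(), comments=()):
        super().__init__(records)
        self.comments: list[tuple[int, str]] = list(comments)


def parse_source_dump(source: Union[str, Path, io.TextIOBase]) -> ParsedDump:
    """Parse a three-column TSV dump into :class:`SourceRecord` rows.

    Columns are ``src_compound_id``, ``standardinchi``, ``standardinchikey``.
    An optional single header line is detected by the literal first field
    ``src_compound_id`` (case-insensitive).  Exact duplicate lines are kept
    once, remembered as a dedup comment on the record; a line with the
    wrong column count raises :class:`DumpParseError` naming the line.
    ``.gz`` paths are transparently decompressed.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise DumpParseError(f"dump file not found: {path}")
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt", encoding="utf-8") as fh:
            return _parse_lines(fh.read().splitlines())
    return _parse_lines(source.read().splitlines())


def _parse_lines(lines: Sequence[str]) -> ParsedDump:
    records: list[SourceRecord] = []
    seen: dict[str, int] = {}
    comments: list[tuple[int, str]] = []
    start = 0
    if lines and lines[0].split("\t")[0].strip().lower() == HEADER_FIRST_FIELD:
        start = 1
    for idx in range(start, len(lines)):
        line_no = idx + 1
        raw = lines[idx]
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != 3:
            raise DumpParseError(
                f"line {line_no}: expected 3 tab-separated columns, found {len(fields)}",
                line_no=line_no,
            )
        if raw in seen:
            comments.append((line_no, f"duplicate of line {seen[raw]}; kept once"))
            continue
        seen[raw] = line_no
        records.append(
            SourceRecord(
                src_compound_id=fields[0].strip(),
                std_inchi=fields[1].strip() or None,
                std_inchikey=fields[2].strip() or None,
                line_no=line_no,
            )
        )
    return ParsedDump(records, comments)


def load_release(
    registry: Registry,
    src_id: int,
    records: Sequence[SourceRecord],
    version_label: str,
    backend: InChIKeyBackend,
    *,
    source_provides_inchikey: bool = True,
    allow_empty: bool = False,
    load_date: Optional[str] = None,
) -> LoadReport:
    """Load one release of one source; transactional (all or nothing).

    A release whose accepted set is empty would obsolete every assignment
    of the source — typically a truncated download — and is refused unless
    ``allow_empty`` is set.
    """
    registry.get_source(src_id)  # raises NotFoundError for unknown sources

    accepted: list[tuple[SourceRecord, str]] = []  # (record, inchikey)
    report_comments: list[tuple[Optional[int], str]] = list(getattr(records, "comments", []))
    rejected = {rule: 0 for rule in RULES}
    for rec in records:
        outcome = validate_record(rec, source_provides_inchikey, backend)
        if outcome.accepted:
            accepted.append((rec, outcome.computed_inchikey))
            if outcome.comment:
                report_comments.append((rec.line_no, outcome.comment))
        else:
            rejected[outcome.rule_violated] += 1
            detail = f": {outcome.comment}" if outcome.comment else ""
            report_comments.append(
                (rec.line_no, f"rejected ({outcome.rule_violated}){detail}")
            )

    if not accepted and not allow_empty:
        raise EmptyReleaseError(
            f"release {version_label!r} of source {src_id} has no accepted records; "
            "pass allow_empty=True to load it anyway (this obsoletes the whole source)"
        )

    with registry.transaction() as conn:
        release_u = registry.next_release_u()
        prev_release_u = registry.latest_release_u(src_id)
        report = LoadReport(
            release_u=release_u,
            src_id=src_id,
            version_label=version_label,
            n_parsed=len(records),
            n_accepted=len(accepted),
            n_rejected_by_rule=rejected,
            comments=report_comments,
        )

        # register structures and collect the accepted (id, uci) pair set
        pair_set: set[tuple[str, int]] = set()
        for rec, key in accepted:
            before = registry.count_structures()
            uci = registry.register_structure(rec.std_inchi, key, release_u)
            if registry.count_structures() > before:
                report.n_new_structures += 1
            pair_set.add((rec.src_compound_id.strip(), uci))

        existing = {
            (a.src_compound_id, a.uci): a
            for a in registry.get_assignments(src_id=src_id)
        }

        for cid, uci in sorted(pair_set):
            prior = existing.get((cid, uci))
            if prior is None:
                conn.execute(
                    "INSERT INTO UC_XREF (SRC_COMPOUND_ID, SRC_ID, UCI, ASSIGNMENT)"
                    " VALUES (?, ?, ?, ?)",
                    (cid, src_id, uci, CURRENT),
                )
                conn.execute(
                    "INSERT INTO UC_AUDIT VALUES (?, ?, ?, ?, 'inserted', NULL)",
                    (release_u, cid, src_id, uci),
                )
                report.n_new_assignments += 1
            elif prior.status == OBSOLETE:
                conn.execute(
                    "UPDATE UC_XREF SET ASSIGNMENT=?, LAST_REL_U_CUR=NULL"
                    " WHERE SRC_COMPOUND_ID=? AND SRC_ID=? AND UCI=?",
                    (CURRENT, cid, src_id, uci),
                )
                conn.execute(
                    "INSERT INTO UC_AUDIT VALUES (?, ?, ?, ?, 'to_current', ?)",
                    (release_u, cid, src_id, uci, prior.last_release_u_current),
                )
                report.n_to_current += 1

        for (cid, uci), prior in existing.items():
            if prior.status == CURRENT and (cid, uci) not in pair_set:
                conn.execute(
                    "UPDATE UC_XREF SET ASSIGNMENT=?, LAST_REL_U_CUR=?"
                    " WHERE SRC_COMPOUND_ID=? AND SRC_ID=? AND UCI=?",
                    (OBSOLETE, prev_release_u, cid, src_id, uci),
                )
                conn.execute(
                    "INSERT INTO UC_AUDIT VALUES (?, ?, ?, ?, 'to_obsolete', NULL)",
                    (release_u, cid, src_id, uci),
                )
                report.n_to_obsolete += 1

        registry._insert_release(
            release_u, src_id, version_label, report.n_accepted, rejected, load_date
        )
        for line_no, text in report_comments:
            conn.execute(
                "INSERT INTO UC_COMMENTS VALUES (?, ?, ?, ?)",
                (release_u, src_id, line_no, text),
            )
    return report


def load_dump(
    registry: Registry,
    src_id: int,
    path: Union[str, Path],
    version_label: str,
    backend: InChIKeyBackend,
    **kwargs,
) -> LoadReport:
    """Convenience wrapper: parse a dump file and load it as a release."""
    return load_release(registry, src_id, parse_source_dump(path), version_label, backend, **kwargs)


def rollback_release(registry: Registry, release_u: int) -> LoadReport:
    """Undo the most recent load of a source, restoring the pre-load
    assignment snapshot.

    Assignments inserted by the release are removed and flipped statuses
    restored; structures the release registered stay in the store forever
    (they still resolve by InChI, merely without current assignments).
    The release row is kept, marked rolled back.
    """
    release = registry.get_release(release_u)
    if release.rolled_back:
        raise UnsupportedRollbackError(f"release {release_u} is already rolled back")
    latest = registry.latest_release_u(release.src_id)
    if latest != release_u:
        raise UnsupportedRollbackError(
            f"release {release_u} is not the latest load of source {release.src_id}"
            f" (latest is {latest}); only the latest release can be rolled back"
        )
    inverse = LoadReport(
        release_u=release_u,
        src_id=release.src_id,
        version_label=release.version_label,
        rolled_back=True,
    )
    with registry.transaction() as conn:
        rows = conn.execute(
            "SELECT SRC_COMPOUND_ID, SRC_ID, UCI, CHANGE, PREV_LAST_REL_U_CUR"
            " FROM UC_AUDIT WHERE RELEASE_U=?",
            (release_u,),
        ).fetchall()
        conn.execute("UPDATE UC_GUARD SET ROLLBACK_OK=1 WHERE ID=1")
        try:
            for cid, src, uci, change, prev_last in rows:
                if change == "inserted":
                    conn.execute(
                        "DELETE FROM UC_XREF WHERE SRC_COMPOUND_ID=? AND SRC_ID=? AND UCI=?",
                        (cid, src, uci),
                    )
                    inverse.n_new_assignments += 1
                elif change == "to_current":
                    conn.execute(
                        "UPDATE UC_XREF SET ASSIGNMENT=?, LAST_REL_U_CUR=?"
                        " WHERE SRC_COMPOUND_ID=? AND SRC_ID=? AND UCI=?",
                        (OBSOLETE, prev_last, cid, src, uci),
                    )
                    inverse.n_to_current += 1
                else:  # to_obsolete
                    conn.execute(
                        "UPDATE UC_XREF SET ASSIGNMENT=?, LAST_REL_U_CUR=NULL"
                        " WHERE SRC_COMPOUND_ID=? AND SRC_ID=? AND UCI=?",
                        (CURRENT, cid, src, uci),
                    )
                    inverse.n_to_obsolete += 1
        finally:
            conn.execute("UPDATE UC_GUARD SET ROLLBACK_OK=0 WHERE ID=1")
        conn.execute("DELETE FROM UC_AUDIT WHERE RELEASE_U=?", (release_u,))
        conn.execute("UPDATE UC_RELEASE SET ROLLED_BACK=1 WHERE RELEASE_U=?", (release_u,))
    return inverse
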