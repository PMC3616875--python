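"""Dump parsing and release load / rollback semantics."""

import io

import pytest

from chemxref import (
    DumpParseError,
    EmptyReleaseError,
    NotFoundError,
    SourceRecord,
    UnsupportedRollbackError,
    load_release,
    parse_source_dump,
    rollback_release,
)
from chemxref.registry import CURRENT, OBSOLETE

WATER = "InChI=1S/H2O/h1H2"
METHANE = "InChI=1S/CH4/h1H4"
ETHANOL = "InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3"


def dump(*rows, header=True):
    lines = ["src_compound_id\tstandardinchi\tstandardinchikey"] if header else []
    lines += ["\t".join(r) for r in rows]
    return io.StringIO("\n".join(lines) + "\n")


def recs(*pairs):
    return [SourceRecord(cid, inchi, None, i + 1) for i, (cid, inchi) in enumerate(pairs)]


class TestParsing:
    def test_line_numbers_without_header(self):
        out = parse_source_dump(dump(("A", WATER, ""), ("B", METHANE, ""), header=False))
        assert [(r.src_compound_id, r.line_no) for r in out] == [("A", 1), ("B", 2)]

    def test_header_detected_case_insensitively(self):
        text = io.StringIO("SRC_COMPOUND_ID\tx\ty\nA\t" + WATER + "\t\n")
        out = parse_source_dump(text)
        assert [(r.src_compound_id, r.line_no) for r in out] == [("A", 2)]

    def test_wrong_column_count_names_the_line(self):
        with pytest.raises(DumpParseError) as err:
            parse_source_dump(io.StringIO("A\t" + WATER + "\t\nB\t" + METHANE + "\n"))
        assert err.value.line_no == 2
        assert "line 2" in str(err.value)

    def test_exact_duplicate_lines_kept_once_with_comment(self):
        out = parse_source_dump(dump(("A", WATER, ""), ("A", WATER, "")))
        assert len(out) == 1
        assert len(out.comments) == 1 and "duplicate" in out.comments[0][1]

    def test_empty_fields_become_none(self):
        (record,) = parse_source_dump(dump(("A", "", "")))
        assert record.std_inchi is None and record.std_inchikey is None

    def test_gzipped_dump_round_trips(self, tmp_path):
        import gzip

        path = tmp_path / "d.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("A\t" + WATER + "\t\n")
        assert len(parse_source_dump(path)) == 1

    def test_missing_file_is_parse_error(self, tmp_path):
        with pytest.raises(DumpParseError):
            parse_source_dump(tmp_path / "absent.tsv")


class TestLoadRelease:
    def test_fresh_source_all_current(self, registry, mock_backend):
        src = registry.add_source("s")
        report = load_release(
            registry, src, recs(("A", WATER), ("B", METHANE), ("C", ETHANOL)), "v1", mock_backend
        )
        assert report.release_u == 1
        assert report.n_accepted == report.n_new_assignments == 3
        assert report.n_new_structures == 3
        assert report.n_to_obsolete == report.n_to_current == 0
        assert all(a.status == CURRENT for a in registry.get_assignments())

    def test_report_counters_are_conserved(self, registry, mock_backend):
        src = registry.add_source("s")
        records = recs(("A", WATER)) + [
            SourceRecord("", WATER, None, 10),  # R4
            SourceRecord("B", None, None, 11),  # R2
        ]
        report = load_release(registry, src, records, "v1", mock_backend)
        assert report.n_parsed == 3
        assert report.n_parsed == report.n_accepted + report.n_rejected
        assert report.n_rejected_by_rule["R4"] == 1
        assert report.n_rejected_by_rule["R2"] == 1

    def test_omitted_assignment_becomes_obsolete_with_marker(self, registry, mock_backend):
        src = registry.add_source("s")
        load_release(registry, src, recs(("A", WATER), ("B", METHANE)), "v1", mock_backend)
        load_release(registry, src, recs(("A", WATER)), "v2", mock_backend)
        state = registry.assignment_state()
        assert state[("B", src, 2)] == (OBSOLETE, 1)  # last current in release_u 1
        assert state[("A", src, 1)] == (CURRENT, None)

    def test_reappearing_assignment_flips_back_to_current(self, registry, mock_backend):
        src = registry.add_source("s")
        load_release(registry, src, recs(("A", WATER), ("B", METHANE)), "v1", mock_backend)
        load_release(registry, src, recs(("A", WATER)), "v2", mock_backend)
        report = load_release(registry, src, recs(("A", WATER), ("B", METHANE)), "v3", mock_backend)
        assert report.n_to_current == 1 and report.n_new_assignments == 0
        assert registry.assignment_state()[("B", src, 2)] == (CURRENT, None)

    def test_second_obsolescence_overwrites_first_marker(self, registry, mock_backend):
        # the simple lifecycle model keeps only the most recent last-current release
        src = registry.add_source("s")
        load_release(registry, src, recs(("A", WATER), ("B", METHANE)), "v1", mock_backend)  # ru 1
        load_release(registry, src, recs(("A", WATER)), "v2", mock_backend)  # ru 2: B obsolete (1)
        load_release(registry, src, recs(("A", WATER), ("B", METHANE)), "v3", mock_backend)  # ru 3
        load_release(registry, src, recs(("A", WATER)), "v4", mock_backend)  # ru 4: B obsolete again
        assert registry.assignment_state()[("B", src, 2)] == (OBSOLETE, 3)

    def test_obsolete_marker_uses_sources_own_previous_release(self, registry, mock_backend):
        a = registry.add_source("a")
        b = registry.add_source("b")
        load_release(registry, a, recs(("A", WATER)), "v1", mock_backend)  # ru 1
        load_release(registry, b, recs(("X", METHANE)), "v1", mock_backend)  # ru 2
        load_release(registry, a, recs(("B", ETHANOL)), "v2", mock_backend)  # ru 3: A obsolete
        # marker is release_u 1 (source a's prior release), not the global latest
        assert registry.assignment_state()[("A", a, 1)] == (OBSOLETE, 1)

    def test_reload_of_same_dump_is_a_no_op(self, registry, mock_backend):
        src = registry.add_source("s")
        records = recs(("A", WATER), ("B", METHANE))
        load_release(registry, src, records, "v1", mock_backend)
        before = registry.assignment_state()
        report = load_release(registry, src, records, "v1-again", mock_backend)
        assert (report.n_to_obsolete, report.n_to_current, report.n_new_assignments) == (0, 0, 0)
        assert registry.assignment_state() == before

    def test_multimapped_id_loads_parallel_current_assignments(self, registry, mock_backend):
        src = registry.add_source("s")
        load_release(registry, src, recs(("A", WATER), ("A", METHANE)), "v1", mock_backend)
        rows = registry.get_assignments(src_id=src)
        assert len(rows) == 2 and all(r.status == CURRENT for r in rows)
        assert {r.uci for r in rows} == {1, 2}

    def test_unregistered_source_is_not_found(self, registry, mock_backend):
        with pytest.raises(NotFoundError):
            load_release(registry, 42, recs(("A", WATER)), "v1", mock_backend)

    def test_empty_accepted_set_guarded(self, registry, mock_backend):
        src = registry.add_source("s")
        load_release(registry, src, recs(("A", WATER)), "v1", mock_backend)
        with pytest.raises(EmptyReleaseError):
            load_release(registry, src, [], "v2", mock_backend)
        # nothing was persisted by the refused load
        assert registry.latest_release_u(src) == 1
        report = load_release(registry, src, [], "v2", mock_backend, allow_empty=True)
        assert report.n_to_obsolete == 1

    def test_rejected_records_do_not_register_structures(self, registry, mock_backend):
        src = registry.add_source("s")
        records = [SourceRecord("A", "InChI=1S/" + "C" * 2000, None, 1)]  # R5
        load_release(registry, src, records, "v1", mock_backend, allow_empty=True)
        assert registry.count_structures() == 0

    def test_release_rows_retain_rejection_counts(self, registry, mock_backend):
        src = registry.add_source("s")
        records = recs(("A", WATER)) + [SourceRecord("B", "bad", None, 2)]
        load_release(registry, src, records, "v1", mock_backend)
        release = registry.get_release(1)
        assert release.n_rejected_by_rule["R3"] == 1
        assert release.n_loaded == 1


class TestRollback:
    def test_rollback_restores_pre_load_snapshot(self, registry, mock_backend):
        src = registry.add_source("s")
        load_release(registry, src, recs(("A", WATER), ("B", METHANE)), "v1", mock_backend)
        before = registry.assignment_state()
        load_release(registry, src, recs(("A", WATER), ("C", ETHANOL)), "v2", mock_backend)
        assert registry.assignment_state() != before
        rollback_release(registry, 2)
        assert registry.assignment_state() == before
        assert registry.get_release(2).rolled_back

    def test_rollback_keeps_structures(self, registry, mock_backend):
        src = registry.add_source("s")
        load_release(registry, src, recs(("A", WATER)), "v1", mock_backend)
        load_release(registry, src, recs(("A", WATER), ("B", METHANE)), "v2", mock_backend)
        rollback_release(registry, 2)
        assert registry.find_structure(METHANE, "inchi") is not None

    def test_only_latest_release_of_source_reversible(self, registry, mock_backend):
        src = registry.add_source("s")
        load_release(registry, src, recs(("A", WATER)), "v1", mock_backend)
        load_release(registry, src, recs(("B", METHANE)), "v2", mock_backend)
        with pytest.raises(UnsupportedRollbackError):
            rollback_release(registry, 1)

    def test_double_rollback_refused(self, registry, mock_backend):
        src = registry.add_source("s")
        load_release(registry, src, recs(("A", WATER)), "v1", mock_backend)
        rollback_release(registry, 1)
        with pytest.raises(UnsupportedRollbackError):
            rollback_release(registry, 1)

    def test_next_load_after_rollback_ignores_rolled_back_release(self, registry, mock_backend):
        src = registry.add_source("s")
        load_release(registry, src, recs(("A", WATER)), "v1", mock_backend)  # ru 1
        load_release(registry, src, recs(("A", WATER), ("B", METHANE)), "v2", mock_backend)  # ru 2
        rollback_release(registry, 2)
        load_release(registry, src, recs(("B", METHANE)), "v3", mock_backend)  # ru 3
        # A's last-current marker points at release 1; release 2 never "happened"
        assert registry.assignment_state()[("A", src, 1)] == (OBSOLETE, 1)
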