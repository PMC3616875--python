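"""Synthetic multi-source, multi-release dump histories plus a replay oracle.

Real registries are fed by many sources whose identifier sets churn from
release to release: records drop out, new ones appear, dropped ones come
back, several identifiers share one structure and one identifier can map
to several structures.  This module generates such histories from a small
parametric model so every loader and query behaviour is testable without
any downloads, and provides :func:`oracle_state` — a brute-force replay
that recomputes the expected final assignment state with plain set
operations, independently of the incremental loader.

The structure pool draws from a packaged list of real Standard
InChI/InChIKey pairs (small molecules, keys computed once with the IUPAC
InChI algorithm); beyond the pool size it synthesizes syntactically valid
pseudo-InChIs with deterministic mock keys, for logic tests that need no
chemistry.

Churn model: every candidate record is present in a source's first
release; afterwards, per release, a present record drops with probability
``p_drop`` and a dropped one reappears with ``p_reappear`` (independent
Bernoulli draws — the simplest model producing every transition type).
A reserve of late-appearing records enters with probability ``p_add`` per
release, attached to structures the source already covers.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .inchi import InChIKeyBackend, MockKeyBackend
from .registry import Registry

PDBE_BASE_URL = "http://www.ebi.ac.uk/pdbe-srv/pdbechem/chemicalCompound/show/"


@dataclass(frozen=True)
class UniverseSpec:
    """Parameters of a synthetic multi-source universe."""

    n_sources: int = 3
    n_structures: int = 200
    n_releases_per_source: int = 5
    churn_rates: tuple[float, float, float] = (0.15, 0.25, 0.4)  # p_drop, p_add, p_reappear
    p_shared_structure: float = 0.5
    p_multimap: float = 0.1
    seed: int = 0

    def __post_init__(self):
        assert self.n_sources >= 1 and self.n_structures >= 1
        assert self.n_releases_per_source >= 1
        assert all(0.0 <= p <= 1.0 for p in self.churn_rates)
        assert 0.0 <= self.p_shared_structure <= 1.0
        assert 0.0 <= self.p_multimap <= 1.0


@dataclass
class DumpRelease:
    """One generated dump: rows of (src_compound_id, inchi, inchikey)."""

    source_index: int  # 1-based position within the history
    source_name: str
    release_index: int  # 1-based within the source
    version_label: str
    rows: list[tuple[str, str, str]]

    @property
    def text(self) -> str:
        lines = ["src_compound_id\tstandardinchi\tstandardinchikey"]
        lines += ["\t".join(r) for r in self.rows]
        return "\n".join(lines) + "\n"

    @property
    def pairs(self) -> set[tuple[str, str]]:
        """Accepted (src_compound_id, std_inchi) pairs, assuming clean rows."""
        return {(cid, inchi) for cid, inchi, _ in self.rows}


@dataclass
class History:
    """Sources plus their releases in global load order."""

    sources: list[tuple[str, Optional[str]]]  # (name, base_url)
    releases: list[DumpRelease] = field(default_factory=list)

    def releases_of(self, source_index: int) -> list[DumpRelease]:
        return [r for r in self.releases if r.source_index == source_index]


def load_fixture_pool() -> list[tuple[str, str, str]]:
    """The packaged (name, std_inchi, std_inchikey) pool of real molecules."""
    text = resources.files("chemxref.data").joinpath("structure_pool.tsv").read_text("utf-8")
    rows = [line.split("\t") for line in text.strip().splitlines()[1:]]
    return [(n, i, k) for n, i, k in rows]


def _pseudo_inchi(i: int) -> str:
    # distinct, syntactically Standard-prefixed formula strings
    c, h, o = 4 + i % 40, 2 + (i * 7) % 60, i % 9
    return f"InChI=1S/C{c}H{h}O{o}X{i}/c1-2/h1H"


def make_structure_pool(
    n: int, seed: int, backend: Optional[InChIKeyBackend] = None
) -> list[tuple[str, str]]:
    """Return ``n`` distinct (std_inchi, std_inchikey) pairs, deterministically.

    The first entries are drawn (seeded, without replacement) from the
    packaged real-molecule pool with their true IUPAC keys; demand beyond
    the pool is met with synthetic pseudo-InChIs keyed by the mock
    backend.  Passing ``backend`` recomputes every key with it, so a
    fully mock-keyed (or fully real-keyed) pool of any size is available.
    """
    fixture = load_fixture_pool()
    rng = random.Random(seed)
    order = list(range(len(fixture)))
    rng.shuffle(order)
    mock = MockKeyBackend()
    pairs: list[tuple[str, str]] = []
    for j in range(n):
        if j < len(fixture):
            _, inchi, key = fixture[order[j]]
        else:
            inchi = _pseudo_inchi(j - len(fixture))
            key = mock.key_from_inchi(inchi)
        if backend is not None:
            key = backend.key_from_inchi(inchi)
        pairs.append((inchi, key))
    return pairs


def make_history(
    spec: UniverseSpec, backend: Optional[InChIKeyBackend] = None
) -> History:
    """Generate a full dump history for ``spec``; identical seeds give
    byte-identical dump texts."""
    rng = random.Random(spec.seed)
    pool = make_structure_pool(spec.n_structures, spec.seed, backend)

    # structure coverage: one primary source each, plus a second with
    # probability p_shared_structure (needs >= 2 sources)
    coverage: list[list[int]] = [[] for _ in range(spec.n_sources + 1)]  # 1-based
    for s_idx in range(spec.n_structures):
        primary = rng.randrange(1, spec.n_sources + 1)
        coverage[primary].append(s_idx)
        if spec.n_sources >= 2 and rng.random() < spec.p_shared_structure:
            other = rng.randrange(1, spec.n_sources)
            if other >= primary:
                other += 1
            coverage[other].append(s_idx)

    p_drop, p_add, p_reappear = spec.churn_rates
    sources = [(f"SRC{i}", None) for i in range(1, spec.n_sources + 1)]
    per_source_releases: list[list[DumpRelease]] = []

    for src in range(1, spec.n_sources + 1):
        name = sources[src - 1][0]
        # candidate records: one id per covered structure, some multimapped
        records: list[tuple[str, int]] = []
        for seq, s_idx in enumerate(coverage[src], start=1):
            cid = f"{name}C{seq:05d}"
            records.append((cid, s_idx))
            if rng.random() < spec.p_multimap and len(coverage[src]) > 1:
                extra = rng.choice(coverage[src])
                if extra != s_idx:
                    records.append((cid, extra))
        # reserve of late-appearing ids over already-covered structures
        n_future = max(1, len(coverage[src]) // 5)
        future: list[tuple[str, int]] = []
        if coverage[src]:
            for seq in range(1, n_future + 1):
                future.append((f"{name}N{seq:05d}", rng.choice(coverage[src])))

        state = {rec: "present" for rec in records}
        state.update({rec: "unborn" for rec in future})
        releases = []
        for rel in range(1, spec.n_releases_per_source + 1):
            if rel > 1:
                for rec in list(state):
                    st, u = state[rec], rng.random()
                    if st == "present" and u < p_drop:
                        state[rec] = "dropped"
                    elif st == "dropped" and u < p_reappear:
                        state[rec] = "present"
                    elif st == "unborn" and u < p_add:
                        state[rec] = "present"
            rows = [
                (cid, pool[s_idx][0], pool[s_idx][1])
                for (cid, s_idx) in records + future
                if state[(cid, s_idx)] == "present"
            ]
            releases.append(DumpRelease(src, name, rel, f"v{rel}", rows))
        per_source_releases.append(releases)

    # interleave: all sources' release 1, then release 2, ... (round-robin)
    history = History(sources=sources)
    for rel in range(spec.n_releases_per_source):
        for src in range(spec.n_sources):
            history.releases.append(per_source_releases[src][rel])
    return history


def inject_corruption(release: DumpRelease) -> DumpRelease:
    """Append exactly one violating row per filtering rule (R1-R5) to a
    dump, for filter tests.  Rows are crafted so rule precedence blames
    each on its intended rule."""
    mock = MockKeyBackend()
    good_inchi = "InChI=1S/CH4/h1H4"
    bad_rows = [
        ("BAD_R1", good_inchi, "A" * 14 + "-" + "A" * 10 + "-N"),  # key mismatch
        ("BAD_R2", "", mock.key_from_inchi(good_inchi)),  # no InChI
        ("BAD_R3", "InChI=1/C2H6O/c1-2-3/h3H,2H2,1H3", ""),  # non-standard prefix
        ("", good_inchi, ""),  # no id -> R4
        ("BAD_R5", "InChI=1S/" + "C" * 2000, ""),  # over-long
    ]
    return DumpRelease(
        release.source_index,
        release.source_name,
        release.release_index,
        release.version_label,
        release.rows + bad_rows,
    )


def oracle_state(history: History) -> dict[tuple[str, int, str], tuple[str, Optional[int]]]:
    """Brute-force replay: expected final assignment state of a history.

    Keys are (src_compound_id, source_index, std_inchi); values are
    (status, last_release_u_current).  Computed with plain set operations:
    a pair is *current* iff it is in the source's latest release; every
    other pair ever seen is *obsolete*, with ``last_release_u_current``
    the greatest release_u (global 1-based load position) of a release of
    that source containing the pair.
    """
    state: dict[tuple[str, int, str], tuple[str, Optional[int]]] = {}
    by_source: dict[int, list[tuple[int, DumpRelease]]] = {}
    for pos, rel in enumerate(history.releases, start=1):
        by_source.setdefault(rel.source_index, []).append((pos, rel))
    for src, rels in by_source.items():
        seen_in: dict[tuple[str, str], list[int]] = {}
        for release_u, rel in rels:
            for pair in rel.pairs:
                seen_in.setdefault(pair, []).append(release_u)
        latest_pairs = rels[-1][1].pairs
        for (cid, inchi), appearances in seen_in.items():
            if (cid, inchi) in latest_pairs:
                state[(cid, src, inchi)] = ("current", None)
            else:
                state[(cid, src, inchi)] = ("obsolete", max(appearances))
    return state


def load_history(
    registry: Registry,
    history: History,
    backend: InChIKeyBackend,
    allow_empty: bool = True,
) -> dict[int, int]:
    """Register the history's sources and load every release in order.

    Returns the mapping source_index -> allocated src_id (identical when
    loading into a fresh store).
    """
    from .loader import load_release, parse_source_dump
    import io

    src_ids: dict[int, int] = {}
    for idx, (name, base_url) in enumerate(history.sources, start=1):
        src_ids[idx] = registry.add_source(name, base_url=base_url)
    for rel in history.releases:
        records = parse_source_dump(io.StringIO(rel.text))
        load_release(
            registry,
            src_ids[rel.source_index],
            records,
            rel.version_label,
            backend,
            allow_empty=allow_empty,
        )
    return src_ids


def registry_state_as_oracle_keys(
    registry: Registry,
) -> dict[tuple[str, int, str], tuple[str, Optional[int]]]:
    """Registry assignment snapshot re-keyed by (id, src_id, std_inchi) so
    it is directly comparable with :func:`oracle_state` output."""
    out = {}
    for (cid, src_id, uci), (status, last) in registry.assignment_state().items():
        inchi = registry.get_structure(uci).std_inchi
        out[(cid, src_id, inchi)] = (status, last)
    return out


def write_history(history: History, directory: str | Path) -> Path:
    """Write each release as a TSV dump plus a JSON manifest describing
    source names, base URLs and load order; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for pos, rel in enumerate(history.releases, start=1):
        fname = f"{rel.source_name}_r{rel.release_index}.tsv"
        (directory / fname).write_text(rel.text, encoding="utf-8")
        entries.append(
            {
                "load_order": pos,
                "source_index": rel.source_index,
                "source_name": rel.source_name,
                "release_index": rel.release_index,
                "version_label": rel.version_label,
                "path": fname,
            }
        )
    manifest = {
        "sources": [{"name": n, "base_url": u} for n, u in history.sources],
        "releases": entries,
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest_path


def diazepam_fixture() -> History:
    """The worked three-source scenario used throughout the docs and tests.

    Source 1 ("ChEMBL") carries CHEMBL12, assigned to diazepam, in every
    release.  Source 2 ("DrugBank") maps both DB00829 and DB07699 to the
    same structure in its first release but drops DB07699 in its second,
    making that assignment obsolete with the first DrugBank release as
    its last-current marker.  Source 3 ("PDBe") publishes compound DIZ
    (a different structure) and a base URL, so URL construction is
    exercised.  Load order: ChEMBL r1, DrugBank r1, DrugBank r2, PDBe r1
    (release_u 1..4 in a fresh store).
    """
    by_name = {name: (inchi, key) for name, inchi, key in load_fixture_pool()}
    diaz_inchi, diaz_key = by_name["diazepam"]
    other_inchi, other_key = by_name["oxazepam"]
    sources = [("ChEMBL", None), ("DrugBank", None), ("PDBe", PDBE_BASE_URL)]
    releases = [
        DumpRelease(1, "ChEMBL", 1, "chembl_14", [("CHEMBL12", diaz_inchi, diaz_key)]),
        DumpRelease(
            2,
            "DrugBank",
            1,
            "db_3.0",
            [("DB00829", diaz_inchi, diaz_key), ("DB07699", diaz_inchi, diaz_key)],
        ),
        DumpRelease(2, "DrugBank", 2, "db_3.1", [("DB00829", diaz_inchi, diaz_key)]),
        DumpRelease(3, "PDBe", 1, "pdbe_2013w1", [("DIZ", other_inchi, other_key)]),
    ]
    return History(sources=sources, releases=releases)
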