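# chemxref

An embeddable chemical-structure cross-referencing and identifier-tracking
engine, for data managers who need to maintain links between compound
databases (bioactivity resources, drug databases, structural archives, …)
without adopting a shared identifier system.

## The problem and the model

Every compound database mints its own identifiers (`CHEMBL12`, `DB00829`,
`DIZ`, …). Linking such resources pairwise does not scale and breaks as
each source revises its releases. `chemxref` instead normalizes every
deposited record onto its **Standard InChI** — the IUPAC canonical
structure string generated with no user-selectable options — and treats
InChI equality as chemical equivalence. The registry holds four tables:

* `UC_STRUCTURES` — one immutable row per distinct Standard InChI, keyed
  by a permanent integer **UCI**; rows are never updated or deleted.
* `UC_SOURCES` — registered identifier namespaces (`src_id`, name,
  optional base URL for building compound page links).
* `UC_XREF` — assignments `(src_compound_id, src_id, UCI)`, each flagged
  **current** or **obsolete**. Assignments are append-only: when a new
  release of a source omits a previously present record the assignment
  flips to obsolete (remembering the last release in which it was
  current); if it reappears later it flips back.
* `UC_RELEASE` — one row per load event, with the per-rule counts of
  records rejected by the filtering rules.

Incoming dumps are three-column TSV (`src_compound_id`, Standard InChI,
Standard InChIKey). A record is refused if the provided key mismatches
the computed one, the InChI or the identifier is missing, a key cannot be
generated, or the InChI exceeds 2000 characters (the operational
definition of "small molecule" here). Cross-source links are never stored:
they are implied by shared UCIs, so loading one source instantly updates
its mappings to every other source.

## Worked example

The packaged three-source scenario: ChEMBL assigns `CHEMBL12` to
diazepam; DrugBank's first release maps both `DB00829` and `DB07699` to
the same structure but its second release drops `DB07699`; PDBe publishes
`DIZ` (a different structure) with a base URL.

```python
from chemxref import Registry, RDKitBackend, lookup
from chemxref.synthetic import diazepam_fixture, load_history

registry = Registry("store.db")
load_history(registry, diazepam_fixture(), RDKitBackend())

for row in lookup(registry, "CHEMBL12", 1, mode="all"):
    print(row.src_compound_id, row.source_name, row.status, row.uci)
```

prints

```
CHEMBL12 ChEMBL current 1
DB00829 DrugBank current 1
DB07699 DrugBank obsolete 1
```

— every identifier ever assigned to the query compound's structure,
with its lifecycle status. Restricting to current DrugBank rows
(`mode="current"`, `target_src_id=2`) returns exactly `DB00829`;
`lookup_as_urls(registry, "DIZ", 3, 3)` returns the full PDBe compound
URL; `whole_source_mapping(registry, 1, 2)` yields the complete
ChEMBL→DrugBank identifier table `[("CHEMBL12", "DB00829")]`.

The same operations are available from the shell:

```sh
chemxref init --store store.db
chemxref add-source --store store.db ChEMBL
chemxref load --store store.db ChEMBL chembl_dump.tsv chembl_14
chemxref query --store store.db CHEMBL12 1 --current --target 2
chemxref map --store store.db 1 2 --out mapping.tsv.gz
```

## Synthetic histories

`chemxref.synthetic` generates multi-source, multi-release dump histories
with controlled identifier churn (drop / add / reappear), structure
sharing across sources and many-to-many mappings, plus `oracle_state` —
a brute-force replay that recomputes the expected final assignment state
with plain set operations, used to validate the incremental loader.
The structure pool ships ≥ 150 real Standard InChI/InChIKey pairs.

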