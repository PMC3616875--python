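# Methods

## Normalization model

`chemxref` defines chemical identity by byte-exact equality of Standard
InChI strings (after stripping surrounding whitespace); InChIKeys are
upper-cased before comparison and storage. This is a deliberate
trade-off: Standard InChI collapses tautomers and ionization states that
some sources distinguish, so several source identifiers may legitimately
share one UCI, and one identifier may map to several UCIs when a source
revises a structure. The registry supports both directions of
many-to-many mapping as ordinary data rather than as errors. No Molfiles
or SMILES are ever stored; conversion of other representations into
Standard InChI is an upstream, pluggable concern (any callable producing
the three-column dump format can feed the loader).

## Identifier lifecycle

Assignments are append-only. The lifecycle model is intentionally
shallow: one status flag plus one marker, `last_release_u_current`,
holding the source's own release in which an obsolete assignment last
appeared. If an assignment cycles obsolete → current → obsolete, only the
most recent last-current release survives; the earlier history is
deliberately not modelled (a full event history would need a different
schema and has no driving use case here). The marker always refers to a
release of the owning source, not the globally latest release.

`release_u` is a single global counter shared by all sources; the
composite `(release_u, src_id)` key is still recorded on release rows.
The alternative — per-source release counters — would make
`last_release_u_current` ambiguous as a foreign key. UCIs and src_ids
are consecutive integers in registration order; they are local to one
store and not portable across independently built stores.

## Filtering rules

Five record-level rules protect the registry: key/InChI mismatch (R1),
missing InChI (R2), key generation failure (R3), missing identifier
(R4), and InChI length > 2000 characters (R5, a strict inequality —
length 2000 loads, 2001 does not — which operationally defines "small
molecule" for the registry). Evaluation order is R4 → R2 → R5 → R3 → R1:
cheapest checks first, and exactly one rule is blamed per rejected
record so per-release reject counts are unambiguous. A record with a
valid InChI but an empty key column is accepted with the computed key
and a comment noting the omission. Strings with the legacy `InChI=1/`
prefix are rejected under R3 with a distinguishing comment: only the
Standard form is a valid normalization key.

R5 counts the full string including the `InChI=1S/` prefix; the cutoff
is a property of the stored string, so the prefix belongs to the length.

## Key generation backends

InChIKey computation is an injectable interface. The production backend
wraps the IUPAC InChI library as shipped with RDKit. A deterministic
mock backend (SHA-256 of the InChI folded into the 14-10-1 letter-block
layout) exists so loader and query logic can be tested at scale without
chemistry; mock keys are never mixed with real ones in a store, and the
backend choice is recorded in store metadata at initialization. The
packaged structure pool (152 small molecules: common drugs, natural
products, and homologous series) carries keys computed once with the
real backend, so integration tests exercise the true algorithm offline.

Key-format validation accepts exactly 27 characters in the 14-10-1
block layout — hyphens after the 14th and 25th characters, all other
characters uppercase letters — which is the shape real InChIKeys have
(e.g. `XLYOFNOQVPJJNP-UHFFFAOYSA-N`).

## Loading semantics

A release load is transactional: filtering, structure registration,
assignment reconciliation and release bookkeeping either all commit or
none do. Reconciliation is pure set logic on accepted
`(src_compound_id, UCI)` pairs versus the source's existing assignments.
A release whose accepted set is empty is refused unless explicitly
allowed: obsoleting an entire source is almost always a truncated
download, not an intent. Exact duplicate dump lines are collapsed to one
record with a comment; conflicting rows within one release (same
identifier, different structures) load as parallel current assignments.

Rollback is restricted to the most recent non-rolled-back release of a
source and replays that release's change audit in reverse: rows the
release inserted are removed, flipped statuses and markers restored.
Structures are exempt — a UCI, once allocated, resolves forever, even if
no assignment references it. Store-level triggers enforce this: updates
and deletes on `UC_STRUCTURES` abort unconditionally, and `UC_XREF`
deletes abort unless a rollback latch is set inside the rollback
transaction.

## Query semantics

All query routes reduce to: resolve the anchor to a set of UCIs, return
assignment rows for those UCIs. In `current` mode the anchor uses only
structures the query identifier is *currently* assigned to and only
current rows are returned — an identifier whose assignments are all
obsolete therefore anchors nothing and returns empty. In `all` mode the
anchor includes the identifier's historical structures and obsolete rows
appear, so "what did this identifier used to point at" stays answerable.
Row order is fixed at `(uci, src_id, src_compound_id)` for reproducible
output; structural columns repeat on every row so multi-anchor results
can be clustered by sorting on them. Whole-source mappings are the
deduplicated sorted join of two sources' assignments on UCI.

## Synthetic universe generator

`UniverseSpec` defaults describe the regime the engine is designed for
and are the conditions under which the properties are verified: 3
sources, 200 structures, 5 releases per source, churn probabilities
(drop 0.15, add 0.25, reappear 0.4) per record per release, structure
sharing probability 0.5, multimap probability 0.1. Churn is independent
Bernoulli per record per release — the simplest model that produces
every lifecycle transition (new, dropped, reappeared, re-dropped).
Every candidate record is present in a source's first release; a reserve
of late-appearing identifiers (20 % of the initial count) enters with
the add probability, attached to structures the source already covers.
Releases are loaded round-robin across sources so the global release
counter interleaves, which is what makes the last-current marker
semantics non-trivial to get right.

What the generator does *not* emulate: chemically correlated churn
(real sources drop whole compound classes at once), realistic identifier
formats, structure revisions that move an identifier between similar
structures, or source-specific dump quirks. Passing the oracle
equivalence property therefore demonstrates the bookkeeping is correct
under arbitrary set-level churn, not that any particular real source
parses cleanly.

The replay oracle is intentionally naive: a pair is current iff it is in
the source's latest dump; everything else ever seen is obsolete with the
greatest containing release as its marker. It shares no code with the
incremental loader beyond the dump representation.

## Problem sizes and numerical choices

Tests and the acceptance script use 3-source × 5-release universes with
80–200 structures and 8–20 seeds, sizes at which the brute-force oracle
(quadratic joins, full-state comparisons) stays exact and the whole
suite runs in seconds. There is no floating-point anywhere in the core:
all comparisons are exact string/integer equality, so no tolerances
apply. Sequential allocation breaks all ties (first registration wins
the next UCI; dump row order decides nothing else since reconciliation
is set-based).

## Known limitations

* No connectivity-layer (stereo-insensitive) search: queries match the
  full InChIKey or InChI exactly.
* No similarity or substructure search; the data model stores no
  structure graphs, by design.
* Lifecycle history is single-depth, as described above.
* Provenance is not modelled: a source that mirrors another's compounds
  produces "circular" links, which are the consumer's concern to filter.
  Sub-sets of a source can simply be registered as separate sources.
* The store is a single-writer embedded database; there is no
  replication or concurrent-load support.
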