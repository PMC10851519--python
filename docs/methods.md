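# Methods

## Catalog schema and the relatedness vocabulary

Each ontology is described by one record with six sections mirroring the
curation spreadsheet: general information, references, modelling and
availability, domain classification, characteristics, and comments. The
machine-readable schema is published with the package
(`ontocat/data/record_schema.json`); `validate_record` enforces it and
returns violation messages rather than raising, so ingestion can report
all problems of a workbook at once.

The domain classification rates an ontology against exactly 14 subdomains
of catalysis research, grouped into catalysis fields (Biocatalysis,
Heterogeneous/Homogeneous catalysis, Photocatalysis, Electrocatalysis),
modelling fields (chemical substance / material / process modelling) and
data fields (synthesis, operando, performance, characterisation, heat-
transport-kinetic, and process-design-energy-cost data). Two schema
choices are deliberate:

* **"Process design, energy and cost data" is one subdomain**, not two.
  The spreadsheet layout prints a separator inside the phrase, but the
  domain arithmetic throughout the workflow assumes 14 domains; the merged
  reading is the only consistent one.
* **"Top level ontology" is a boolean flag**, not a 15th subdomain: it
  states what an ontology *is*, not which domain it covers, and top-level
  alignment is separately recorded in the modelling section.

Relatedness is a four-level ordinal vocabulary, `missing <
related:broader < related:narrower < contained`, mapped to ranks 0–3.
The two intermediate levels are curator judgements with no operational
definition; the package stores and orders them but never interprets or
derives them from ontology content. Cumulative tallies count records with
rank ≥ 1 ("at least related:broader"), ≥ 2 ("at least related:narrower")
and = 3 ("contained"); cumulativity (`contained ≤ narrower ≤ broader`) is
a structural invariant, tested property-style.

Variant spellings found in curated sources ("heterogenous",
"modeling", "characterization") are normalised to one canonical form at
ingest and accepted as aliases.

## Ingestion and JSON export

The workbook dialect is fixed and documented by this package (the
original curation spreadsheets are repository-specific): two-column
key/value rows grouped under the six section headers, which must each
appear exactly once per sheet, in any order. A CSV dialect (one file per
ontology, same rows) is supported so that no spreadsheet engine is needed
for text-only pipelines. Multi-valued cells split on ";" with whitespace
trimming. An empty cell is *absent* (`None`/empty list), never an empty
string; a present-but-blank classification cell is read as an explicit
`missing`. A fully blank sheet carries no record and is skipped.

Export follows a packaged JSON blueprint that fixes key order and null
placeholders; output is byte-deterministic (no timestamps), and
`workbook → records → JSON → catalog` round-trips to equal records.
Filenames derive from the acronym restricted to alphanumerics, dash and
underscore.

## Lexicon extraction

Ontology documents are parsed natively with rdflib in Turtle or RDF/XML
(auto-detected by trying parsers, with the file extension as a hint);
no external conversion step is needed, and lexicons are
serialization-invariant by construction. Named classes are subjects
declared `owl:Class` or `rdfs:Class` with an IRI; anonymous class
expressions (restrictions, blank nodes) are excluded, deprecated classes
included — no content filter is applied.

Per class the lexicon records: the IRI; the "name" (IRI fragment after
`#`, else the last `/` segment); all `rdfs:label`, `skos:prefLabel` and
`skos:altLabel` values with language tags stripped, whitespace trimmed,
empty strings dropped and duplicates collapsed (sorted for determinism);
and a definition taken from the first available of the IAO definition
annotation (`IAO_0000115`), `skos:definition`, `rdfs:comment`. Absent
annotation kinds are explicit *none* markers and never participate in
matching. `prefLabel` is read from the SKOS namespace, which is where
that property exists.

Entity counts (classes, object/data/annotation properties, named
individuals) are computed from the loaded document only; imports are
recorded as metadata, not fetched, and axiom/declaration totals are
treated as curated metadata rather than recomputed. Whether class totals
should include imported classes is therefore resolved as: they count the
loaded document, nothing else.

The corpus builder parses each ontology exactly once and reuses the
lexicons for all pairwise comparisons; a source that fails to parse is
skipped with a recorded reason instead of aborting the corpus (only an
empty corpus is an error).

## Pair mapping

Mapping a pair (A, B) is two-staged:

1. **IRI identity.** One row per IRI in both lexicons; these classes are
   excluded, per side, from stage 2. Self-mapping therefore yields
   exactly the class count — the semantics of the matrix diagonal.
2. **Cross-annotation lexical matching.** Over the remaining classes,
   (a, b) match if any annotation value of a equals any annotation value
   of b, across all field combinations of {name, `rdfs:label`,
   `skos:prefLabel`, `skos:altLabel`}. Equality is exact string equality
   after the lexicon's normalisation — the conservative reading of
   "similar entries" — case-sensitive by default with an opt-in
   case-insensitive mode.

Decisions where the design was genuinely open:

* **Multiplicity.** Many-to-many lexical matches are all emitted, one row
  per class pair, and `count` counts distinct class pairs (a label shared
  by 2 classes in A and 3 in B contributes 6). The per-pair table makes
  the multiplicity visible for manual review.
* **Rationale selection.** When several field combinations match one
  pair, the reported rationale is the first in priority order name >
  `rdfs:label` > `skos:prefLabel` > `skos:altLabel` on each side; the
  remaining combinations are kept in an auxiliary `extra_fields` note.
  The fixed order exists purely for determinism.
* **Ordering.** IRI rows sort by IRI; lexical rows by the (IRI-a, IRI-b)
  pair; ties in the matched value resolve to the lexicographically
  smallest value. All outputs are byte-stable.

The matrix computes each unordered pair once; symmetry and the
class-count diagonal are invariants. Concept-list matching treats each
user term as a one-field pseudo-class, collapses duplicates, and ranks
ontologies by hit count (ties by acronym).

## Reporting

Markdown pages contain the six sections in canonical order with absent
values rendered as an em dash; pair pages list numbered rows, IRI matches
first, with five data columns (IRI and rationale per side, definition of
the second class — an empty cell, not a *none* marker, when unavailable).
Pair page filenames put the two sanitized acronyms in ascending order
(`A__B.md`) so symmetric pairs share one file; self-pairs are computed
for the diagonal but never emitted as pages. The readme index contains
the ontology listing, per-domain clusters (an explicit "none" row when no
ontology exceeds `missing`), the aggregate radar and the matrix with
per-cell links; link integrity over the generated tree is tested.

Radar plots fix the axis order to the 14 subdomains grouped 5 catalysis
/ 3 modelling / 6 data fields (axis labels coloured blue/purple/black,
cumulative traces red/yellow/green; both configurable). Every image gets
a TSV sidecar with the exact axis/value series; tests and downstream
checks target the sidecar, because image bytes are a property of the
plotting backend, not of the data.

## Synthetic fixtures

The generator's role is to make every stage testable offline with known
ground truth, not to imitate any real ontology's content.

* **Ontology pairs** are built from an overlap blueprint: class counts
  per side, a number of shared IRIs, and shared lexical values each with
  an annotation field and multiplicity per side. Shared values are
  planted only on classes *outside* the shared-IRI set and on distinct
  carrier classes, so the expected mapped-pair count has the closed form
  `n_shared_iris + Σ multiplicity_a × multiplicity_b` with no exclusion
  interactions. Every other class receives a unique noise label, and
  side-specific IRI namespaces prevent accidental local-name collisions.
  An adversarial mode additionally plants the shared values on the
  IRI-matched classes of both sides; IRI precedence must leave the count
  unchanged. Documents are emitted as deterministic Turtle and RDF/XML
  text built directly from the class list — the same seed yields
  byte-identical files — and sizes default to ≤ ~20 classes per side,
  which is enough to exercise every matching rule while keeping the full
  oracle suite (100 seeded blueprints, each checked against both the
  closed form and an exhaustive double-loop oracle) to seconds.
* **Workbooks** contain n sheets of schema-valid, seeded-random metadata
  with the expected records returned for round-trip comparison.
* **The screening list** is a packaged transcription of the 30 candidate
  ontologies with the 7 exclusion flags (accessibility or relevance
  problems), leaving 23 in the metadata collection; of those, OntoCAPE
  is recorded as unloadable for class mapping, leaving 22 mapping
  participants.

What the fixtures do *not* emulate: real ontologies' scale (thousands of
classes), punctuation/casing variance in labels, multilingual labels
beyond tags that are stripped, OWL constructs other than class
declarations and annotations, and import closures. Passing tests
therefore demonstrate the correctness of the counting and matching rules
and the determinism of the pipeline — not recall/precision of the
lexical heuristic on real ontologies, which depends on curation quality
and drifts with ontology releases. For the same reason absolute pair
counts between real ontologies are version-dependent and are out of scope
for the offline checks.

## Numerical and degenerate-input choices

No floating-point arithmetic is involved anywhere in the core (all
quantities are counts and ranks). Degenerate inputs are defined, not
errors: an empty catalog yields all-zero tallies; a document with no
classes yields an empty lexicon (warning); a singleton corpus yields a
1×1 matrix; a concept list that is entirely blank is the one input
error. Duplicate acronyms are rejected at catalog construction.
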