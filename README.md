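# ontocat

Ontology metadata cataloguing, domain-relatedness classification and
lightweight pairwise class mapping, built for research-data management in
catalysis.

Research data in catalysis is diverse — from synthesis and operando
measurements to process modelling — and no single ontology covers it.
Portals such as EBI OLS or BioPortal help *find* ontologies but do not say
*which subdomains of catalysis research* an ontology actually covers, nor
how two candidate ontologies overlap. `ontocat` implements a complete
workflow for answering both questions:

1. **Catalog.** Curated metadata for each ontology across six sections
   (general information, references, modelling and availability, domain
   classification, characteristics, comments), ingested from a spreadsheet
   workbook (one sheet per ontology) or a directory of CSV files, validated
   against a published JSON schema and exported as one JSON document per
   ontology.
2. **Classification.** Each ontology is rated against 14 subdomains of
   catalysis research (5 catalysis fields, 3 modelling fields, 6 data
   fields) on an ordinal vocabulary

   ```
   missing < related:broader < related:narrower < contained
   ```

   Cumulative tallies per subdomain ("at least related:broader", "at least
   related:narrower", "contained") feed radar plots and per-domain tables.
3. **Mapping.** A two-stage, "lightweight" class aligner. For every
   ontology a lexicon of per-class handles is extracted once (IRI, IRI
   local name, `rdfs:label`, `skos:prefLabel`, `skos:altLabel`,
   definition) and consolidated into a corpus. For a pair (A, B):

   * classes sharing an IRI are identical — matched first and excluded
     from the second stage;
   * remaining classes match if *any* lexical handle of one exactly equals
     *any* handle of the other, cross-field (a string that is an
     `rdfs:label` in A may be a `skos:altLabel` in B).

   The mapped-pair counts for all pairs form a symmetric matrix with each
   ontology's class count on the diagonal. The same lexical rule ranks
   ontologies against a user's own plain-text concept list.
4. **Documentation.** Deterministic Markdown output: one page per
   ontology, per-pair mapping tables (IRI matches first, then lexical
   matches, with the rationale on each side and the second class's
   definition), a README index with per-domain tables and a clickable
   mapping matrix, plus radar plots (PNG with a TSV sidecar holding the
   exact plotted series).

A seeded fixture generator produces synthetic ontology pairs with a known
overlap (`expected = shared IRIs + Σ multiplicity_a × multiplicity_b` over
planted shared labels) and synthetic metadata workbooks, so the entire
workflow is testable offline.

## Worked example

Generate a synthetic ontology pair with 4 shared IRIs plus one shared
lexical value, and map it:

```python
from rdflib import Graph
from ontocat.fixtures import OverlapSpec, SharedLabel, generate_ontology_pair
from ontocat.lexicon import build_lexicon
from ontocat.mapper import map_pair

spec = OverlapSpec(
    n_classes_a=10, n_classes_b=12, n_shared_iris=4,
    shared_labels=(SharedLabel("Shape", field_a="rdfs:label",
                               field_b="skos:altLabel"),),
    seed=42,
)
pair = generate_ontology_pair(spec)
ga = Graph(); ga.parse(data=pair.ttl_a, format="turtle")
gb = Graph(); gb.parse(data=pair.ttl_b, format="turtle")
mapping = map_pair(build_lexicon("A", ga), build_lexicon("B", gb))
print("mapped pairs:", mapping.count)
for row in mapping.rows:
    print(row.iri_a, row.rationale_a, "->", row.iri_b, row.rationale_b)
```

prints

```
mapped pairs: 5
http://example.org/shared#S_0 IRI -> http://example.org/shared#S_0 IRI
http://example.org/shared#S_1 IRI -> http://example.org/shared#S_1 IRI
http://example.org/shared#S_2 IRI -> http://example.org/shared#S_2 IRI
http://example.org/shared#S_3 IRI -> http://example.org/shared#S_3 IRI
http://example.org/a#A_0 rdfs:label -> http://example.org/b#B_0 skos:altLabel
```

The count is 5 = 4 IRI-identity matches + 1 cross-field lexical match
(the value "Shape" is an `rdfs:label` in A and a `skos:altLabel` in B);
the IRI stage always precedes, and excludes its classes from, the lexical
stage.

## Command line

```bash
ontocat ingest --workbook metadata.xlsx --out json/           # workbook -> JSON
ontocat metrics --ontology onto.ttl                           # entity counts
ontocat map --catalog ontologies/ --pair AFO BAO --out maps/  # one pair
ontocat map-all --catalog ontologies/ --out maps/             # matrix + pages
ontocat match-concepts --terms concepts.txt --catalog ontologies/
ontocat render --catalog json/ --mappings ontologies/ --out site/
ontocat make-fixtures --seed 1 --out fixtures/
```

## Scope

Relatedness levels are curated inputs: the tool stores, orders,
aggregates and renders them but never derives them from ontology content.
The mapper is deliberately lexical-only — no definition-text similarity,
no graph-based alignment, no confidence scores — and its output is meant
for user-controlled review.
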