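"""Lightweight pairwise class mapping between ontology lexicons.

Two classes are mapped if they share the same IRI (direct identity), or —
failing that — if any lexical handle of one exactly equals any lexical
handle of the other, across the four annotation fields *name*,
``rdfs:label``, ``skos:prefLabel`` and ``skos:altLabel``.  Matching is
cross-field on purpose: a string recorded as an ``rdfs:label`` in one
ontology may be a ``skos:altLabel`` in another.

IRI matches take precedence: a class matched by IRI is excluded from the
lexical stage on its side, so the two stages never report the same class
twice.  Lexical matches are many-to-many — every matching class *pair* is
reported, and a pair mapping's ``count`` counts distinct class pairs.
Comparison is exact string equality after the lexicon's trimming and
language-tag stripping; case-sensitive by default.

This is deliberately a first-pass, "lightweight" aligner: no definition
text similarity, no graph structure, no confidence scores.  Its output is
meant for user-controlled review.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Iterable

from .lexicon import ANNOTATION_FIELDS, LexiconEntry, OntologyLexicon

__all__ = [
    "IRI_RATIONALE",
    "MatchRow",
    "PairMapping",
    "MappingMatrix",
    "ConceptHits",
    "match_by_iri",
    "match_by_annotation",
    "map_pair",
    "map_all_pairs",
    "build_matrix",
    "match_concept_list",
]

#: Rationale token for identity matches.
IRI_RATIONALE = "IRI"


@dataclass(frozen=True)
class MatchRow:
    """One mapped class pair with the rationale on each side.

    ``rationale_a``/``rationale_b`` are ``"IRI"`` for identity matches, or
    the annotation field names for lexical matches.  When several field
    combinations match the same class pair, the highest-priority one is
    recorded here and the remainder in ``extra_fields``.
    """

    iri_a: str
    rationale_a: str
    iri_b: str
    rationale_b: str
    matched_value: str
    definition_b: str | None = None
    extra_fields: tuple[tuple[str, str], ...] = ()

    @property
    def is_iri_match(self) -> bool:
        return self.rationale_a == IRI_RATIONALE


@dataclass
class PairMapping:
    """All match rows for one ontology pair; IRI rows first."""

    acronym_a: str
    acronym_b: str
    rows: list[MatchRow] = field(default_factory=list)

    @property
    def count(self) -> int:
        """Number of distinct mapped class pairs."""
        return len({(row.iri_a, row.iri_b) for row in self.rows})

    @property
    def iri_rows(self) -> list[MatchRow]:
        return [r for r in self.rows if r.is_iri_match]

    @property
    def lexical_rows(self) -> list[MatchRow]:
        return [r for r in self.rows if not r.is_iri_match]

    def swapped(self) -> "PairMapping":
        """The same mapping with the two sides exchanged."""
        return PairMapping(
            acronym_a=self.acronym_b,
            acronym_b=self.acronym_a,
            rows=[
                MatchRow(
                    iri_a=r.iri_b,
                    rationale_a=r.rationale_b,
                    iri_b=r.iri_a,
                    rationale_b=r.rationale_a,
                    matched_value=r.matched_value,
                    definition_b=None,
                    extra_fields=tuple((fb, fa) for fa, fb in r.extra_fields),
                )
                for r in self.rows
            ],
        )


def match_by_iri(
    lex_a: OntologyLexicon, lex_b: OntologyLexicon
) -> tuple[list[MatchRow], set[str], set[str]]:
    """Identity stage: one row per IRI shared by both lexicons.

    Returns the rows (IRI ascending) and the matched IRI set for each side;
    these sets seed the exclusion of the lexical stage.
    """
    shared = sorted(lex_a.iris & lex_b.iris)
    rows = [
        MatchRow(
            iri_a=iri,
            rationale_a=IRI_RATIONALE,
            iri_b=iri,
            rationale_b=IRI_RATIONALE,
            matched_value=iri,
            definition_b=lex_b[iri].definition,
        )
        for iri in shared
    ]
    return rows, set(shared), set(shared)


def _value_index(
    entries: Iterable[LexiconEntry], case_sensitive: bool
) -> dict[str, set[str]]:
    """Inverted index annotation value -> IRIs carrying it."""
    index: dict[str, set[str]] = {}
    for entry in entries:
        for value in entry.all_values():
            if not case_sensitive:
                value = value.casefold()
            index.setdefault(value, set()).add(entry.iri)
    return index


def _pair_rationale(
    entry_a: LexiconEntry, entry_b: LexiconEntry, case_sensitive: bool
) -> tuple[tuple[str, str, str], list[tuple[str, str]]] | None:
    """Find matching field combinations for one class pair.

    Returns ``((field_a, field_b, value), extra_combinations)`` for the
    highest-priority combination (priority order name > rdfs:label >
    skos:prefLabel > skos:altLabel on each side), or None if no values
    coincide.
    """
    norm = (lambda v: v) if case_sensitive else str.casefold
    combos: list[tuple[str, str, str]] = []
    for fld_a in ANNOTATION_FIELDS:
        values_a = {norm(v): v for v in entry_a.values_for(fld_a)}
        if not values_a:
            continue
        for fld_b in ANNOTATION_FIELDS:
            common = set(values_a) & {norm(v) for v in entry_b.values_for(fld_b)}
            if common:
                combos.append((fld_a, fld_b, values_a[min(common)]))
    if not combos:
        return None
    first = combos[0]
    return first, [(fa, fb) for fa, fb, _ in combos[1:]]


def match_by_annotation(
    lex_a: OntologyLexicon,
    lex_b: OntologyLexicon,
    excluded_a: set[str] | None = None,
    excluded_b: set[str] | None = None,
    case_sensitive: bool = True,
) -> list[MatchRow]:
    """Lexical stage: cross-annotation exact matching on the remainder.

    Classes in the excluded sets (normally the IRI-stage matches) never
    appear.  Every matching class pair yields one row; absent annotation
    kinds (*none* markers) match nothing.  Rows are ordered by the pair of
    IRIs.
    """
    excluded_a = excluded_a or set()
    excluded_b = excluded_b or set()
    candidates_a = [e for e in lex_a if e.iri not in excluded_a]
    candidates_b = [e for e in lex_b if e.iri not in excluded_b]
    index_b = _value_index(candidates_b, case_sensitive)

    norm = (lambda v: v) if case_sensitive else str.casefold
    rows: list[MatchRow] = []
    for entry_a in candidates_a:
        partner_iris: set[str] = set()
        for value in entry_a.all_values():
            partner_iris.update(index_b.get(norm(value), ()))
        for iri_b in sorted(partner_iris):
            entry_b = lex_b[iri_b]
            found = _pair_rationale(entry_a, entry_b, case_sensitive)
            if found is None:  # pragma: no cover - index guarantees a hit
                continue
            (fld_a, fld_b, value), extra = found
            rows.append(
                MatchRow(
                    iri_a=entry_a.iri,
                    rationale_a=fld_a,
                    iri_b=iri_b,
                    rationale_b=fld_b,
                    matched_value=value,
                    definition_b=entry_b.definition,
                    extra_fields=tuple(extra),
                )
            )
    rows.sort(key=lambda r: (r.iri_a, r.iri_b))
    return rows


def map_pair(
    lex_a: OntologyLexicon,
    lex_b: OntologyLexicon,
    case_sensitive: bool = True,
) -> PairMapping:
    """Full two-stage mapping of one ontology pair.

    IRI rows come first (IRI ascending), then lexical rows (pair
    lexicographic).  Mapping a lexicon against itself matches every class
    by IRI, so the self-count equals the class count — the diagonal
    semantics of the all-pairs matrix.
    """
    iri_rows, matched_a, matched_b = match_by_iri(lex_a, lex_b)
    lexical_rows = match_by_annotation(
        lex_a, lex_b, matched_a, matched_b, case_sensitive
    )
    return PairMapping(
        acronym_a=lex_a.acronym,
        acronym_b=lex_b.acronym,
        rows=iri_rows + lexical_rows,
    )


@dataclass
class MappingMatrix:
    """Symmetric all-pairs count table with class totals on the diagonal."""

    acronyms: list[str]
    counts: dict[frozenset, int] = field(default_factory=dict)
    diagonal: dict[str, int] = field(default_factory=dict)

    def cell(self, acronym_a: str, acronym_b: str) -> int:
        if acronym_a == acronym_b:
            return self.diagonal[acronym_a]
        return self.counts[frozenset((acronym_a, acronym_b))]

    def to_dataframe(self):
        """The matrix as a pandas DataFrame (acronym-indexed, symmetric)."""
        import pandas as pd

        data = {
            a: [self.cell(a, b) for b in self.acronyms] for a in self.acronyms
        }
        return pd.DataFrame(data, index=self.acronyms, columns=self.acronyms)


def map_all_pairs(
    corpus: Mapping[str, OntologyLexicon], case_sensitive: bool = True
) -> dict[tuple[str, str], PairMapping]:
    """Compute every unordered off-diagonal pair once (keys sorted)."""
    acronyms = sorted(corpus)
    return {
        (a, b): map_pair(corpus[a], corpus[b], case_sensitive)
        for a, b in itertools.combinations(acronyms, 2)
    }


def build_matrix(
    corpus: Mapping[str, OntologyLexicon],
    pair_mappings: Mapping[tuple[str, str], PairMapping] | None = None,
    case_sensitive: bool = True,
) -> MappingMatrix:
    """All-pairs mapping matrix over a corpus.

    The diagonal holds each ontology's class count (equivalently the
    self-mapping count); off-diagonal cells the pair mapping counts.
    Precomputed pair mappings can be passed to avoid recomputation.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    if pair_mappings is None:
        pair_mappings = map_all_pairs(corpus, case_sensitive)
    acronyms = sorted(corpus)
    return MappingMatrix(
        acronyms=acronyms,
        counts={
            frozenset(key): pm.count for key, pm in pair_mappings.items()
        },
        diagonal={a: corpus[a].class_count for a in acronyms},
    )


@dataclass
class ConceptHits:
    """Lexical hits of a user concept list against one ontology."""

    acronym: str
    hit_count: int
    rows: list[MatchRow] = field(default_factory=list)


def match_concept_list(
    terms: Iterable[str],
    corpus: Mapping[str, OntologyLexicon],
    case_sensitive: bool = True,
) -> list[ConceptHits]:
    """Match plain-text concepts against every lexicon in the corpus.

    Each term acts as a single-field pseudo-class and is compared by the
    lexical rule; blank terms are dropped and duplicates collapse before
    matching.  Results are ranked by hit count descending, ties broken by
    acronym.
    """
    cleaned = sorted({t.strip() for t in terms if t and t.strip()})
    if not cleaned:
        raise ValueError("no non-blank concepts provided")
    norm = (lambda v: v) if case_sensitive else str.casefold

    results: list[ConceptHits] = []
    for acronym in sorted(corpus):
        lexicon = corpus[acronym]
        index = _value_index(lexicon.entries, case_sensitive)
        rows: list[MatchRow] = []
        for term in cleaned:
            for iri in sorted(index.get(norm(term), ())):
                entry = lexicon[iri]
                fld = next(
                    f
                    for f in ANNOTATION_FIELDS
                    if any(norm(v) == norm(term) for v in entry.values_for(f))
                )
                rows.append(
                    MatchRow(
                        iri_a=f"concept:{term}",
                        rationale_a="concept",
                        iri_b=iri,
                        rationale_b=fld,
                        matched_value=term,
                        definition_b=entry.definition,
                    )
                )
        results.append(ConceptHits(acronym=acronym, hit_count=len(rows), rows=rows))
    results.sort(key=lambda h: (-h.hit_count, h.acronym))
    return results
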