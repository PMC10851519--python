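"""Per-class annotation lexicons extracted from ontology documents.

For every ontology the mapper needs the set of named classes and, for each
class, the lexical handles under which it may be known: the IRI local name
("name"), ``rdfs:label``, ``skos:prefLabel`` and ``skos:altLabel`` values,
plus a textual definition where available.  These bundles form one
:class:`OntologyLexicon` per ontology; the lexicons for all catalog members
are consolidated into a corpus ("overarching dictionary") that is built
once and reused for every pairwise comparison, so each ontology document is
parsed exactly once.

Turtle and OWL (RDF/XML) serializations are read natively; semantically
identical documents yield identical lexicons regardless of serialization.
Language tags are stripped and values whitespace-trimmed before they enter
matching; annotation kinds with no values are explicit *none* markers
(empty lists / ``None``) — an empty string never enters a lexicon.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from rdflib import Graph, RDF, RDFS, OWL, URIRef
from rdflib.namespace import SKOS

__all__ = [
    "NONE_MARKER",
    "LexiconEntry",
    "OntologyLexicon",
    "Corpus",
    "EntityCounts",
    "load_graph",
    "load_ontology_classes",
    "extract_lexicon_entry",
    "build_lexicon",
    "build_corpus",
    "compute_entity_counts",
]

logger = logging.getLogger(__name__)

#: Serialized placeholder for an absent annotation kind.
NONE_MARKER = "none"

IAO_DEFINITION = URIRef("http://purl.obolibrary.org/obo/IAO_0000115")

#: Annotation fields in rationale-priority order.
ANNOTATION_FIELDS: tuple[str, ...] = (
    "name",
    "rdfs:label",
    "skos:prefLabel",
    "skos:altLabel",
)


class FormatError(ValueError):
    """The document could not be parsed in any supported serialization."""


def _guess_formats(source: str | Path, format_hint: str | None) -> list[str]:
    if format_hint in ("ttl", "turtle"):
        return ["turtle"]
    if format_hint in ("owl", "owl-xml", "xml", "rdf-xml"):
        return ["xml"]
    suffix = Path(str(source)).suffix.lower()
    if suffix == ".ttl":
        return ["turtle", "xml"]
    if suffix in (".owl", ".rdf", ".xml"):
        return ["xml", "turtle"]
    return ["turtle", "xml"]


def load_graph(source: str | Path, format_hint: str | None = None) -> Graph:
    """Parse an ontology document into an RDF graph.

    ``format_hint`` may be ``"ttl"``, ``"owl-xml"`` or ``None``/"auto"
    (try Turtle then RDF/XML, guided by the file extension).
    """
    if format_hint == "auto":
        format_hint = None
    errors: list[str] = []
    for fmt in _guess_formats(source, format_hint):
        graph = Graph()
        try:
            graph.parse(str(source), format=fmt)
            return graph
        except Exception as exc:  # rdflib raises many parser-specific types
            errors.append(f"{fmt}: {exc}")
    raise FormatError(
        f"could not parse {source} in any supported serialization "
        f"({'; '.join(errors)})"
    )


def _named_classes(graph: Graph) -> set[URIRef]:
    """IRIs of all named (non-anonymous) class declarations in the graph."""
    classes: set[URIRef] = set()
    for class_type in (OWL.Class, RDFS.Class):
        for subject in graph.subjects(RDF.type, class_type):
            if isinstance(subject, URIRef):
                classes.add(subject)
    return classes


def load_ontology_classes(
    source: str | Path | Graph, format_hint: str | None = None
) -> set[str]:
    """Return the IRIs of all named classes declared in an ontology.

    Anonymous class expressions (blank nodes such as restrictions) are
    excluded; deprecated classes are included — no content filter is
    applied.  A document declaring no classes yields an empty set (with a
    warning), not an error.
    """
    graph = source if isinstance(source, Graph) else load_graph(source, format_hint)
    classes = {str(iri) for iri in _named_classes(graph)}
    if not classes:
        logger.warning("no named classes found in %s", source)
    return classes


def local_name(iri: str) -> str:
    """IRI fragment after '#', else the segment after the final '/'."""
    if "#" in iri:
        return iri.rsplit("#", 1)[1]
    return iri.rstrip("/").rsplit("/", 1)[-1]


@dataclass(frozen=True)
class LexiconEntry:
    """Annotation bundle for one named class."""

    iri: str
    local_name: str
    labels: tuple[str, ...] = ()
    pref_labels: tuple[str, ...] = ()
    alt_labels: tuple[str, ...] = ()
    definition: str | None = None

    def values_for(self, fld: str) -> tuple[str, ...]:
        """Annotation values for one field of :data:`ANNOTATION_FIELDS`."""
        if fld == "name":
            return (self.local_name,) if self.local_name else ()
        if fld == "rdfs:label":
            return self.labels
        if fld == "skos:prefLabel":
            return self.pref_labels
        if fld == "skos:altLabel":
            return self.alt_labels
        raise KeyError(fld)

    def all_values(self) -> set[str]:
        out: set[str] = set()
        for fld in ANNOTATION_FIELDS:
            out.update(self.values_for(fld))
        return out

    def to_dict(self) -> dict[str, object]:
        """Dictionary form with explicit none markers for absent kinds."""
        return {
            "iri": self.iri,
            "name": self.local_name or NONE_MARKER,
            "rdfs:label": list(self.labels) or NONE_MARKER,
            "skos:prefLabel": list(self.pref_labels) or NONE_MARKER,
            "skos:altLabel": list(self.alt_labels) or NONE_MARKER,
            "definition": self.definition if self.definition else NONE_MARKER,
        }


def _clean_values(graph: Graph, subject: URIRef, prop: URIRef) -> tuple[str, ...]:
    """Collect literal values: strip language tags, trim, drop empties, dedupe."""
    seen: set[str] = set()
    for obj in graph.objects(subject, prop):
        text = str(obj).strip()
        if text:
            seen.add(text)
    return tuple(sorted(seen))


def extract_lexicon_entry(class_iri: str | URIRef, graph: Graph) -> LexiconEntry:
    """Build the annotation bundle for one class of a parsed ontology.

    The definition is taken from the first non-empty of the IAO definition
    property, ``skos:definition``, then ``rdfs:comment``.
    """
    subject = URIRef(str(class_iri))
    definition: str | None = None
    for prop in (IAO_DEFINITION, SKOS.definition, RDFS.comment):
        values = _clean_values(graph, subject, prop)
        if values:
            definition = values[0]
            break
    return LexiconEntry(
        iri=str(class_iri),
        local_name=local_name(str(class_iri)),
        labels=_clean_values(graph, subject, RDFS.label),
        pref_labels=_clean_values(graph, subject, SKOS.prefLabel),
        alt_labels=_clean_values(graph, subject, SKOS.altLabel),
        definition=definition,
    )


@dataclass
class OntologyLexicon:
    """All class annotation bundles of one ontology, sorted by IRI."""

    acronym: str
    source: str = ""
    entries: list[LexiconEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.iri)
        iris = [e.iri for e in self.entries]
        if len(set(iris)) != len(iris):
            raise ValueError(f"duplicate IRIs in lexicon {self.acronym!r}")
        self._by_iri = {e.iri: e for e in self.entries}

    @property
    def class_count(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, iri: str) -> LexiconEntry:
        return self._by_iri[iri]

    def __contains__(self, iri: str) -> bool:
        return iri in self._by_iri

    @property
    def iris(self) -> set[str]:
        return set(self._by_iri)


def build_lexicon(
    acronym: str, source: str | Path | Graph, format_hint: str | None = None
) -> OntologyLexicon:
    """Parse one ontology document and extract its full lexicon."""
    graph = source if isinstance(source, Graph) else load_graph(source, format_hint)
    entries = [
        extract_lexicon_entry(iri, graph) for iri in _named_classes(graph)
    ]
    return OntologyLexicon(
        acronym=acronym,
        source="" if isinstance(source, Graph) else str(source),
        entries=entries,
    )


class Corpus(Mapping):
    """Consolidated per-ontology lexicons, plus skip records for failures.

    Behaves as a mapping ``acronym -> OntologyLexicon``; ontologies whose
    source failed to load are listed in :attr:`skipped` with the reason.
    """

    def __init__(
        self,
        lexicons: dict[str, OntologyLexicon] | None = None,
        skipped: dict[str, str] | None = None,
    ) -> None:
        self.lexicons: dict[str, OntologyLexicon] = dict(lexicons or {})
        self.skipped: dict[str, str] = dict(skipped or {})

    def __getitem__(self, acronym: str) -> OntologyLexicon:
        return self.lexicons[acronym]

    def __iter__(self) -> Iterator[str]:
        return iter(self.lexicons)

    def __len__(self) -> int:
        return len(self.lexicons)


def build_corpus(
    sources: Mapping[str, str | Path | Graph],
    format_hints: Mapping[str, str] | None = None,
) -> Corpus:
    """Build the corpus of lexicons, one parse per ontology.

    Sources that fail to load are skipped with a recorded reason rather
    than aborting the whole corpus; if *every* source fails, that is an
    error.
    """
    format_hints = format_hints or {}
    corpus = Corpus()
    for acronym in sorted(sources):
        try:
            corpus.lexicons[acronym] = build_lexicon(
                acronym, sources[acronym], format_hints.get(acronym)
            )
        except Exception as exc:
            logger.warning("skipping %s: %s", acronym, exc)
            corpus.skipped[acronym] = str(exc)
    if sources and not corpus.lexicons:
        raise FormatError(
            "no ontology source could be loaded: "
            + "; ".join(f"{k}: {v}" for k, v in corpus.skipped.items())
        )
    return corpus


@dataclass(frozen=True)
class EntityCounts:
    class_count: int
    object_property_count: int
    data_property_count: int
    annotation_property_count: int
    individual_count: int


def compute_entity_counts(
    source: str | Path | Graph, format_hint: str | None = None
) -> EntityCounts:
    """Counts of declared named entities per kind (all >= 0).

    Counts cover the loaded document only; imported ontologies are not
    fetched.  The result is serialization-invariant.
    """
    graph = source if isinstance(source, Graph) else load_graph(source, format_hint)

    def count(entity_type: URIRef) -> int:
        return sum(
            1
            for s in graph.subjects(RDF.type, entity_type)
            if isinstance(s, URIRef)
        )

    return EntityCounts(
        class_count=len(_named_classes(graph)),
        object_property_count=count(OWL.ObjectProperty),
        data_property_count=count(OWL.DatatypeProperty),
        annotation_property_count=count(OWL.AnnotationProperty),
        individual_count=count(OWL.NamedIndividual),
    )
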