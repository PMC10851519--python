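"""Shared fixtures and the independent brute-force mapping oracle."""

from __future__ import annotations

import pytest

from ontocat.catalog import (
    DomainClassification,
    GeneralInfo,
    OntologyRecord,
    Relatedness,
    SUBDOMAINS,
)
from ontocat.lexicon import LexiconEntry, OntologyLexicon


def brute_force_pair_count(lex_a: OntologyLexicon, lex_b: OntologyLexicon) -> int:
    """Exhaustive double-loop oracle for the mapped-pair count.

    Recomputes the two-stage rule from the raw entry fields, independently
    of the mapper implementation: shared IRIs first, then — over classes
    not matched by IRI — every pair whose annotation value sets intersect.
    """

    def values(entry: LexiconEntry) -> set[str]:
        out = {entry.local_name}
        out.update(entry.labels)
        out.update(entry.pref_labels)
        out.update(entry.alt_labels)
        out.discard("")
        return out

    shared = {e.iri for e in lex_a} & {e.iri for e in lex_b}
    count = len(shared)
    for entry_a in lex_a:
        if entry_a.iri in shared:
            continue
        for entry_b in lex_b:
            if entry_b.iri in shared:
                continue
            if values(entry_a) & values(entry_b):
                count += 1
    return count


def make_lexicon(acronym: str, classes: dict[str, dict]) -> OntologyLexicon:
    """Build a lexicon directly from ``{iri: {field: values, ...}}``.

    Recognised keys per class: ``labels``, ``pref_labels``, ``alt_labels``
    (lists) and ``definition`` (string).
    """
    entries = []
    for iri, spec in classes.items():
        local = iri.rsplit("#", 1)[1] if "#" in iri else iri.rsplit("/", 1)[-1]
        entries.append(
            LexiconEntry(
                iri=iri,
                local_name=local,
                labels=tuple(spec.get("labels", ())),
                pref_labels=tuple(spec.get("pref_labels", ())),
                alt_labels=tuple(spec.get("alt_labels", ())),
                definition=spec.get("definition"),
            )
        )
    return OntologyLexicon(acronym=acronym, entries=entries)


def make_record(
    acronym: str,
    levels: dict[str, Relatedness | str] | None = None,
    **kwargs,
) -> OntologyRecord:
    """A schema-conforming record with all subdomains missing by default."""
    relatedness: dict[str, Relatedness] = {
        name: Relatedness.MISSING for name in SUBDOMAINS
    }
    for name, level in (levels or {}).items():
        relatedness[name] = (
            level if isinstance(level, Relatedness) else Relatedness(level)
        )
    return OntologyRecord(
        general=GeneralInfo(name=f"{acronym} ontology", acronym=acronym),
        classification=DomainClassification(relatedness=relatedness),
        **kwargs,
    )


@pytest.fixture
def simple_lexicon_pair() -> tuple[OntologyLexicon, OntologyLexicon]:
    """Hand-built pair: 2 shared IRIs plus one cross-field label match."""
    lex_a = make_lexicon(
        "A",
        {
            "http://ex.org/shared#S1": {},
            "http://ex.org/shared#S2": {},
            "http://ex.org/a#C3": {"labels": ["Shape"]},
            "http://ex.org/a#Lone": {"labels": ["only-in-a"]},
        },
    )
    lex_b = make_lexicon(
        "B",
        {
            "http://ex.org/shared#S1": {},
            "http://ex.org/shared#S2": {"definition": "shared class two"},
            "http://ex.org/b#X1": {
                "alt_labels": ["Shape"],
                "definition": "a form or contour",
            },
            "http://ex.org/b#X2": {"labels": ["only-in-b"]},
        },
    )
    return lex_a, lex_b
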