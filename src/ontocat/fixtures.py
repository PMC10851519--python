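"""Synthetic test data: ontology pairs with controlled overlap, metadata
workbooks, and the transcribed screening list.

The ontology-pair generator plants a known amount of overlap between two
small ontologies — ``n_shared_iris`` classes with identical IRIs, plus
shared lexical values with chosen annotation fields and multiplicities on
classes *outside* the shared-IRI set — so the expected mapping count has a
closed form::

    expected = n_shared_iris + sum(multiplicity_a * multiplicity_b)

An adversarial mode additionally plants shared lexical values on the
IRI-matched classes; because IRI matches exclude those classes from the
lexical stage, the expected count must not change.

Documents are emitted as deterministic Turtle and OWL (RDF/XML) text built
directly from the class list, so the same seed always yields byte-identical
files in both serializations.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from pathlib import Path

from .catalog import (
    Characteristics,
    DomainClassification,
    GeneralInfo,
    Modeling,
    OntologyRecord,
    References,
    Relatedness,
    SUBDOMAINS,
)
from .ingest import FIELD_LAYOUT, LIST_SEPARATOR, SECTION_HEADERS, TOP_LEVEL_LABEL

__all__ = [
    "SharedLabel",
    "OverlapSpec",
    "GeneratedPair",
    "generate_ontology_pair",
    "random_overlap_spec",
    "generate_workbook_fixture",
    "ScreeningEntry",
    "table2_screening_list",
]

LEXICAL_FIELDS = ("name", "rdfs:label", "skos:prefLabel", "skos:altLabel")

_TTL_PREAMBLE = """\
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix skos: <http://www.w3.org/2004/02/skos/core#> .

"""

_XML_HEADER = """\
<?xml version="1.0" encoding="utf-8"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:owl="http://www.w3.org/2002/07/owl#"
         xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"
         xmlns:skos="http://www.w3.org/2004/02/skos/core#">
"""

_FIELD_TO_TTL = {
    "rdfs:label": "rdfs:label",
    "skos:prefLabel": "skos:prefLabel",
    "skos:altLabel": "skos:altLabel",
}
_FIELD_TO_XML = {
    "rdfs:label": "rdfs:label",
    "skos:prefLabel": "skos:prefLabel",
    "skos:altLabel": "skos:altLabel",
}


@dataclass(frozen=True)
class SharedLabel:
    """One lexical value planted in both ontologies of a pair."""

    value: str
    field_a: str = "rdfs:label"
    field_b: str = "rdfs:label"
    multiplicity_a: int = 1
    multiplicity_b: int = 1


@dataclass(frozen=True)
class OverlapSpec:
    """Blueprint for a synthetic ontology pair with known overlap."""

    n_classes_a: int
    n_classes_b: int
    n_shared_iris: int = 0
    shared_labels: tuple[SharedLabel, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_shared_iris > min(self.n_classes_a, self.n_classes_b):
            raise ValueError("n_shared_iris exceeds a side's class count")
        if self.n_shared_iris < 0 or self.n_classes_a < 0 or self.n_classes_b < 0:
            raise ValueError("negative sizes are infeasible")
        need_a = sum(s.multiplicity_a for s in self.shared_labels)
        need_b = sum(s.multiplicity_b for s in self.shared_labels)
        if need_a > self.n_classes_a - self.n_shared_iris:
            raise ValueError("not enough non-shared classes in A for label carriers")
        if need_b > self.n_classes_b - self.n_shared_iris:
            raise ValueError("not enough non-shared classes in B for label carriers")
        values = [s.value for s in self.shared_labels]
        if len(set(values)) != len(values):
            raise ValueError("shared label values must be distinct")
        for shared in self.shared_labels:
            if shared.field_a not in LEXICAL_FIELDS or shared.field_b not in LEXICAL_FIELDS:
                raise ValueError(f"unknown annotation field in {shared}")
            if shared.multiplicity_a < 1 or shared.multiplicity_b < 1:
                raise ValueError("multiplicities must be >= 1")

    @property
    def expected_count(self) -> int:
        """Closed-form mapped-pair count for documents built from this spec."""
        return self.n_shared_iris + sum(
            s.multiplicity_a * s.multiplicity_b for s in self.shared_labels
        )


@dataclass
class _ClassSpec:
    iri: str
    annotations: list[tuple[str, str]] = field(default_factory=list)
    definition: str | None = None


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _xml_escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )


def _to_ttl(classes: list[_ClassSpec]) -> str:
    chunks = [_TTL_PREAMBLE]
    for cls in classes:
        lines = [f"<{cls.iri}> a owl:Class"]
        for fld, value in cls.annotations:
            lines.append(f"    {_FIELD_TO_TTL[fld]} \"{_escape(value)}\"")
        if cls.definition:
            lines.append(f"    skos:definition \"{_escape(cls.definition)}\"")
        chunks.append(" ;\n".join(lines) + " .\n\n")
    return "".join(chunks)


def _to_owl_xml(classes: list[_ClassSpec]) -> str:
    chunks = [_XML_HEADER]
    for cls in classes:
        chunks.append(f'  <owl:Class rdf:about="{cls.iri}">\n')
        for fld, value in cls.annotations:
            tag = _FIELD_TO_XML[fld]
            chunks.append(f"    <{tag}>{_xml_escape(value)}</{tag}>\n")
        if cls.definition:
            chunks.append(
                f"    <skos:definition>{_xml_escape(cls.definition)}"
                "</skos:definition>\n"
            )
        chunks.append("  </owl:Class>\n")
    chunks.append("</rdf:RDF>\n")
    return "".join(chunks)


@dataclass
class GeneratedPair:
    """Two synthetic ontology documents plus their expected mapping summary."""

    spec: OverlapSpec
    ttl_a: str
    owl_a: str
    ttl_b: str
    owl_b: str
    expected_count: int
    shared_iris: tuple[str, ...]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write all four documents; filenames record the spec seed."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        seed = self.spec.seed
        paths = {
            "ttl_a": out_dir / f"onto_a_seed{seed}.ttl",
            "owl_a": out_dir / f"onto_a_seed{seed}.owl",
            "ttl_b": out_dir / f"onto_b_seed{seed}.ttl",
            "owl_b": out_dir / f"onto_b_seed{seed}.owl",
        }
        for key, path in paths.items():
            path.write_text(getattr(self, key), encoding="utf-8")
        return paths


def _build_side(
    side: str,
    n_classes: int,
    n_shared: int,
    shared_iris: list[str],
    labels: list[tuple[str, str, int]],  # (value, field, multiplicity)
    rng: random.Random,
    adversarial_values: list[str],
) -> list[_ClassSpec]:
    ns = f"http://example.org/{side}#"
    classes: list[_ClassSpec] = []
    for iri in shared_iris:
        cls = _ClassSpec(iri=iri)
        # adversarial: plant shared lexical values on IRI-matched classes;
        # the IRI stage must keep them out of the lexical stage
        for value in adversarial_values:
            cls.annotations.append(("rdfs:label", value))
        classes.append(cls)

    unique: list[_ClassSpec] = []
    name_carrier = 0
    for i in range(n_classes - n_shared):
        unique.append(_ClassSpec(iri=f"{ns}{side.upper()}_{i}"))
    pointer = 0
    for value, fld, multiplicity in labels:
        for _ in range(multiplicity):
            carrier = unique[pointer]
            pointer += 1
            if fld == "name":
                # a "name" is the IRI local part; give the carrier an IRI
                # whose local name is the shared value (namespaces differ
                # per carrier so multiplicity > 1 stays feasible)
                name_carrier += 1
                carrier.iri = f"http://example.org/{side}/n{name_carrier}#{value}"
            else:
                carrier.annotations.append((fld, value))
    # per-class noise label, unique per side, never colliding across sides
    for i, cls in enumerate(unique):
        noise = "".join(rng.choices(string.ascii_lowercase, k=8))
        cls.annotations.append(("rdfs:label", f"noise-{side}-{i}-{noise}"))
    classes.extend(unique)
    if side == "b":
        for cls in classes:
            cls.definition = f"Synthetic definition of <{cls.iri}>."
    return classes


def generate_ontology_pair(
    spec: OverlapSpec, adversarial: bool = False
) -> GeneratedPair:
    """Build a synthetic ontology pair realizing an overlap blueprint.

    With ``adversarial=True`` every shared lexical value is additionally
    planted as an ``rdfs:label`` on the IRI-shared classes of both sides;
    the expected mapping count is unchanged because those classes are
    matched (and excluded) by IRI first.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    shared_iris = [
        f"http://example.org/shared#S_{i}" for i in range(spec.n_shared_iris)
    ]
    adversarial_values = (
        [s.value for s in spec.shared_labels] if adversarial else []
    )
    classes_a = _build_side(
        "a",
        spec.n_classes_a,
        spec.n_shared_iris,
        shared_iris,
        [(s.value, s.field_a, s.multiplicity_a) for s in spec.shared_labels],
        rng,
        adversarial_values,
    )
    classes_b = _build_side(
        "b",
        spec.n_classes_b,
        spec.n_shared_iris,
        shared_iris,
        [(s.value, s.field_b, s.multiplicity_b) for s in spec.shared_labels],
        rng,
        adversarial_values,
    )
    return GeneratedPair(
        spec=spec,
        ttl_a=_to_ttl(classes_a),
        owl_a=_to_owl_xml(classes_a),
        ttl_b=_to_ttl(classes_b),
        owl_b=_to_owl_xml(classes_b),
        expected_count=spec.expected_count,
        shared_iris=tuple(shared_iris),
    )


def random_overlap_spec(seed: int, max_classes: int = 12) -> OverlapSpec:
    """A small random-but-feasible overlap blueprint for property tests."""
    rng = random.Random(seed)
    n_shared = rng.randint(0, 4)
    n_labels = rng.randint(0, 3)
    need = 2 * n_labels  # up to multiplicity 2 per side
    n_a = n_shared + need + rng.randint(0, max_classes - n_shared - need)
    n_b = n_shared + need + rng.randint(0, max_classes - n_shared - need)
    fields = list(LEXICAL_FIELDS)
    labels = tuple(
        SharedLabel(
            value=f"shared-{seed}-{i}",
            field_a=rng.choice(fields),
            field_b=rng.choice(fields),
            multiplicity_a=rng.randint(1, 2),
            multiplicity_b=rng.randint(1, 2),
        )
        for i in range(n_labels)
    )
    spec = OverlapSpec(
        n_classes_a=n_a,
        n_classes_b=n_b,
        n_shared_iris=n_shared,
        shared_labels=labels,
        seed=seed,
    )
    spec.validate()
    return spec


# --- metadata workbook fixtures -------------------------------------------

_ORG_KINDS = ("consortium", "single maintainer", "standards body", "project")
_LICENSES = ("CC-BY 4.0", "CC0", "MIT", "Apache-2.0")
_REASONERS = ((), ("HermiT",), ("HermiT", "FaCT++"), ("ELK",))
_LEVELS = tuple(m.value for m in Relatedness)


def _random_record(index: int, rng: random.Random) -> OntologyRecord:
    acronym = f"SYN{index}"
    classification = DomainClassification(
        relatedness={
            name: Relatedness(rng.choice(_LEVELS)) for name in SUBDOMAINS
        },
        top_level_ontology=rng.random() < 0.2,
    )
    n_classes = rng.randint(5, 500)
    return OntologyRecord(
        general=GeneralInfo(
            name=f"Synthetic Ontology {index}",
            alternative_names=[f"SynOnto{index}"] if rng.random() < 0.5 else [],
            acronym=acronym,
            creators=[f"Curator {rng.randint(1, 9)}"],
            issuing_organization=f"Synthetic Org {rng.randint(1, 5)}",
            organizational_structure=rng.choice(_ORG_KINDS),
        ),
        references=References(
            organization_url=f"https://example.org/org{index}",
            persistent_uri=f"https://example.org/onto/{acronym.lower()}.ttl",
            documentation_url=(
                f"https://example.org/docs/{acronym.lower()}"
                if rng.random() < 0.7
                else None
            ),
            version_directory_url=None,
            additional_links=[],
        ),
        modeling=Modeling(
            formats=rng.choice((["ttl"], ["owl"], ["ttl", "owl"])),
            inference_degree=rng.choice(("inferred", "non-inferred")),
            license=rng.choice(_LICENSES),
            working_reasoners=list(rng.choice(_REASONERS)),
            shortest_reasoning_time=(
                f"{rng.randint(1, 120)} s" if rng.random() < 0.5 else None
            ),
            top_level_alignment=rng.choice(("BFO", "none", "EMMO")),
            imports=[],
            prefixes=["rdfs", "skos"],
            class_annotation_types=["rdfs:label", "skos:altLabel"],
        ),
        classification=classification,
        characteristics=Characteristics(
            axiom_count=n_classes * rng.randint(3, 8),
            logical_axiom_count=n_classes * rng.randint(1, 3),
            declaration_count=n_classes + rng.randint(0, 50),
            class_count=n_classes,
            object_property_count=rng.randint(0, 40),
            data_property_count=rng.randint(0, 20),
            individual_count=rng.randint(0, 30),
            annotation_property_count=rng.randint(0, 15),
        ),
        comments=f"Synthetic fixture record {index}." if rng.random() < 0.5 else "",
    )


def _record_rows(record: OntologyRecord) -> list[tuple[str, str]]:
    """Serialize a record to workbook key/value rows (section layout)."""
    rows: list[tuple[str, str]] = []
    section_attr = {
        "General information": record.general,
        "References": record.references,
        "Ontology modeling and availability": record.modeling,
        "Ontology characteristics": record.characteristics,
    }
    for header in SECTION_HEADERS:
        rows.append((header, ""))
        if header == "Classification":
            for name in SUBDOMAINS:
                rows.append((name, record.classification.relatedness[name].value))
            rows.append(
                (
                    TOP_LEVEL_LABEL,
                    "yes" if record.classification.top_level_ontology else "no",
                )
            )
            continue
        if header == "Comments":
            rows.append(("Remarks", record.comments or ""))
            continue
        section = section_attr[header]
        for label, fname, kind in FIELD_LAYOUT[header]:
            value = getattr(section, fname)
            if kind == "list":
                cell = f"{LIST_SEPARATOR} ".join(value)
            elif value is None:
                cell = ""
            else:
                cell = str(value)
            rows.append((label, cell))
    return rows


def generate_workbook_fixture(
    n: int, seed: int, out_path: str | Path, dialect: str = "xlsx"
) -> list[OntologyRecord]:
    """Write a synthetic metadata workbook with ``n`` ontology sheets.

    Returns the expected records for round-trip comparison.  ``dialect``
    is ``"xlsx"`` (one sheet per ontology) or ``"csv"`` (``out_path`` is a
    directory of per-ontology CSV files).  The same seed always produces
    the same workbook.
    """
    rng = random.Random(seed)
    records = [_random_record(i, rng) for i in range(n)]
    out_path = Path(out_path)
    if dialect == "xlsx":
        from openpyxl import Workbook

        workbook = Workbook()
        if records:  # a workbook needs >= 1 sheet; a blank one means "empty"
            workbook.remove(workbook.active)
        for record in records:
            sheet = workbook.create_sheet(title=record.acronym)
            for key, value in _record_rows(record):
                sheet.append([key, value if value else None])
        out_path.parent.mkdir(parents=True, exist_ok=True)
        workbook.save(out_path)
    elif dialect == "csv":
        import csv as _csv

        out_path.mkdir(parents=True, exist_ok=True)
        for record in records:
            with (out_path / f"{record.acronym}.csv").open(
                "w", newline="", encoding="utf-8"
            ) as handle:
                writer = _csv.writer(handle)
                writer.writerows(_record_rows(record))
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    return records


# --- screening list --------------------------------------------------------


@dataclass(frozen=True)
class ScreeningEntry:
    """One ontology considered during screening; ``excluded`` marks the
    entries dropped before metadata collection."""

    acronym: str
    excluded: bool = False


#: The 30 screened ontologies; 7 were excluded for accessibility or
#: relevance problems, leaving 23 in the metadata collection.
_SCREENING: tuple[tuple[str, bool], ...] = (
    ("AFO", False),
    ("BAO", False),
    ("BFO", False),
    ("CAO", False),
    ("ChEBI", False),
    ("CHEMINF", False),
    ("CHMO", False),
    ("CIF", False),
    ("DOLCE", True),
    ("EDAM", False),
    ("EMMO", False),
    ("ENVO", False),
    ("ISO 15926", True),
    ("ISO 15926-14", True),
    ("M3", False),
    ("M4I", False),
    ("MOP", False),
    ("MS", False),
    ("OBI", False),
    ("OFM", True),
    ("OM", False),
    ("OntoCAPE", False),
    ("OntoCompChem", True),
    ("OntoKin", True),
    ("OSMO", False),
    ("PIMS-II", True),
    ("REX", False),
    ("RXNO", False),
    ("SBO", False),
    ("VIMMP", False),
)

#: Retained ontology that could not be loaded for class mapping (modular,
#: deprecated design), so it does not participate in the pairwise mapping.
MAPPING_UNLOADABLE: tuple[str, ...] = ("OntoCAPE",)


def table2_screening_list() -> list[ScreeningEntry]:
    """The screening list: 30 candidate ontologies with exclusion flags."""
    return [ScreeningEntry(acronym=a, excluded=x) for a, x in _SCREENING]


def retained_acronyms() -> list[str]:
    """Acronyms kept for metadata collection (exclusion flags removed)."""
    return [e.acronym for e in table2_screening_list() if not e.excluded]


def mapping_participants() -> list[str]:
    """Retained ontologies that can be loaded for pairwise class mapping."""
    return [a for a in retained_acronyms() if a not in MAPPING_UNLOADABLE]
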