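"""Workbook ingestion and JSON serialization of ontology records.

The curated metadata lives in a workbook with one sheet per ontology (or,
equivalently, a directory of per-ontology CSV files).  Every sheet is a
two-column key/value layout grouped under the six section headers; the exact
labels accepted are listed in :data:`FIELD_LAYOUT`.  Multi-valued cells use
"; " as separator.  An empty cell means *absent* — never an empty string.

Records are exported to one JSON document per ontology, following the key
order of the packaged blueprint template, and can be re-loaded into a
:class:`~ontocat.catalog.Catalog`.  The pipeline is round-trip safe and
byte-deterministic (no timestamps are embedded).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterator

from .catalog import (
    Catalog,
    Characteristics,
    DomainClassification,
    GeneralInfo,
    Modeling,
    OntologyRecord,
    References,
    Relatedness,
    SUBDOMAINS,
    normalize_subdomain,
    sanitize_acronym,
    validate_record,
)

__all__ = [
    "DialectError",
    "CatalogError",
    "IngestReport",
    "SECTION_HEADERS",
    "read_metadata_workbook",
    "export_record_json",
    "load_catalog",
    "load_template",
    "record_to_dict",
    "record_from_dict",
]

logger = logging.getLogger(__name__)

LIST_SEPARATOR = ";"


class DialectError(ValueError):
    """The workbook does not follow the expected sheet layout."""


class CatalogError(ValueError):
    """Catalog-level constraint violated (e.g. duplicate acronyms)."""


#: The six section headers, in canonical order.  Each must appear exactly
#: once per sheet (any order is accepted on read).
SECTION_HEADERS: tuple[str, ...] = (
    "General information",
    "References",
    "Ontology modeling and availability",
    "Classification",
    "Ontology characteristics",
    "Comments",
)

# label -> (section attribute, field, kind); kind in
# {text, list, int}.  Classification rows are handled separately.
FIELD_LAYOUT: dict[str, list[tuple[str, str, str]]] = {
    "General information": [
        ("Ontology name", "name", "text"),
        ("Alternative names", "alternative_names", "list"),
        ("Ontology acronym", "acronym", "text"),
        ("Creator(s)", "creators", "list"),
        ("Issuing organization", "issuing_organization", "text"),
        ("Organizational structure", "organizational_structure", "text"),
    ],
    "References": [
        ("Organizational website", "organization_url", "text"),
        ("Persistent URI", "persistent_uri", "text"),
        ("Documentation", "documentation_url", "text"),
        ("Version directory", "version_directory_url", "text"),
        ("Additional links", "additional_links", "list"),
    ],
    "Ontology modeling and availability": [
        ("Formats", "formats", "list"),
        ("Degree of inference and composition", "inference_degree", "text"),
        ("License", "license", "text"),
        ("Working reasoners", "working_reasoners", "list"),
        ("Shortest reasoning time", "shortest_reasoning_time", "text"),
        ("Top level alignment", "top_level_alignment", "text"),
        ("Imports", "imports", "list"),
        ("Prefixes", "prefixes", "list"),
        ("Class annotation types", "class_annotation_types", "list"),
    ],
    "Ontology characteristics": [
        ("Axioms", "axiom_count", "int"),
        ("Logical axiom count", "logical_axiom_count", "int"),
        ("Declaration axioms count", "declaration_count", "int"),
        ("Class count", "class_count", "int"),
        ("Object property count", "object_property_count", "int"),
        ("Data property count", "data_property_count", "int"),
        ("Individual count", "individual_count", "int"),
        ("Annotation property count", "annotation_property_count", "int"),
    ],
    "Comments": [
        ("Remarks", "comments", "text"),
    ],
}

_SECTION_ATTR = {
    "General information": "general",
    "References": "references",
    "Ontology modeling and availability": "modeling",
    "Ontology characteristics": "characteristics",
}

TOP_LEVEL_LABEL = "Top level ontology"

_TRUTHY = {"yes", "true", "1", "x"}
_FALSY = {"no", "false", "0", ""}


def _cell_text(value: Any) -> str | None:
    """Normalise a raw cell value; blank cells become None (absent)."""
    if value is None:
        return None
    if isinstance(value, float) and value.is_integer():
        value = int(value)
    text = str(value).strip()
    return text or None


def _split_list(value: str | None) -> list[str]:
    if value is None:
        return []
    return [part.strip() for part in value.split(LIST_SEPARATOR) if part.strip()]


def _parse_bool(value: str | None, where: str) -> bool:
    if value is None:
        return False
    lowered = value.strip().lower()
    if lowered in _TRUTHY:
        return True
    if lowered in _FALSY:
        return False
    raise DialectError(f"{where}: cannot interpret {value!r} as yes/no")


def _record_from_rows(
    sheet: str, rows: list[tuple[str | None, Any]]
) -> OntologyRecord:
    """Build a record from one sheet's key/value rows."""
    sections: dict[str, list[tuple[str, Any]]] = {}
    current: str | None = None
    for raw_key, raw_value in rows:
        key = _cell_text(raw_key)
        if key is None:
            continue
        if key in SECTION_HEADERS:
            if key in sections:
                raise DialectError(
                    f"sheet {sheet!r}: section header {key!r} appears twice"
                )
            sections[key] = []
            current = key
            continue
        if current is None:
            raise DialectError(
                f"sheet {sheet!r}: row {key!r} appears before any section header"
            )
        sections[current].append((key, raw_value))

    missing = [h for h in SECTION_HEADERS if h not in sections]
    if missing:
        raise DialectError(
            f"sheet {sheet!r}: missing section header(s): " + ", ".join(missing)
        )

    record = OntologyRecord(classification=DomainClassification())
    for header, attr in _SECTION_ATTR.items():
        layout = {label: (fname, kind) for label, fname, kind in FIELD_LAYOUT[header]}
        target = getattr(record, attr)
        for key, raw_value in sections[header]:
            if key not in layout:
                raise DialectError(
                    f"sheet {sheet!r}, section {header!r}: unknown field {key!r}"
                )
            fname, kind = layout[key]
            text = _cell_text(raw_value)
            if kind == "list":
                setattr(target, fname, _split_list(text))
            elif kind == "int":
                if text is None:
                    setattr(target, fname, None)
                else:
                    try:
                        setattr(target, fname, int(text))
                    except ValueError:
                        # leave invalid content for validate_record to flag
                        setattr(target, fname, text)  # type: ignore[arg-type]
            else:
                setattr(target, fname, text if text is not None else
                        ("" if fname == "acronym" or fname == "name" else None))
    # general.name/acronym are plain strings, not optional
    if record.general.name is None:  # pragma: no cover - normalised above
        record.general.name = ""

    for key, raw_value in sections["Classification"]:
        text = _cell_text(raw_value)
        if key == TOP_LEVEL_LABEL:
            record.classification.top_level_ontology = _parse_bool(
                text, f"sheet {sheet!r}: {TOP_LEVEL_LABEL}"
            )
            continue
        try:
            subdomain = normalize_subdomain(key)
        except KeyError:
            raise DialectError(
                f"sheet {sheet!r}, section 'Classification': "
                f"unknown subdomain {key!r}"
            ) from None
        # a present-but-blank cell is an explicit "missing"
        level = text if text is not None else Relatedness.MISSING.value
        try:
            record.classification.relatedness[subdomain] = Relatedness(level)
        except ValueError:
            record.classification.relatedness[subdomain] = level  # type: ignore[assignment]

    comments = dict(
        (k, _cell_text(v)) for k, v in sections["Comments"]
    ).get("Remarks")
    record.comments = comments or ""
    return record


@dataclass
class IngestReport:
    """Records parsed from a workbook plus any validation violations.

    Iterating the report yields the records, so it can be used wherever a
    record list is expected; ``violations`` maps acronym (or sheet name) to
    the messages produced by :func:`~ontocat.catalog.validate_record`.
    """

    records: list[OntologyRecord] = field(default_factory=list)
    violations: dict[str, list[str]] = field(default_factory=dict)

    def __iter__(self) -> Iterator[OntologyRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ok(self) -> bool:
        return not self.violations


def _sheets_from_xlsx(path: Path) -> list[tuple[str, list[tuple[Any, Any]]]]:
    from openpyxl import load_workbook

    workbook = load_workbook(path, read_only=True, data_only=True)
    sheets = []
    for sheet in workbook.worksheets:
        rows = [
            (row[0] if row else None, row[1] if len(row) > 1 else None)
            for row in sheet.iter_rows(values_only=True)
        ]
        sheets.append((sheet.title, rows))
    workbook.close()
    return sheets


def _sheets_from_csv_dir(path: Path) -> list[tuple[str, list[tuple[Any, Any]]]]:
    sheets = []
    for csv_path in sorted(path.glob("*.csv")):
        with csv_path.open(newline="", encoding="utf-8") as handle:
            rows = [
                (row[0] if row else None, row[1] if len(row) > 1 else None)
                for row in csv.reader(handle)
            ]
        sheets.append((csv_path.stem, rows))
    return sheets


def read_metadata_workbook(
    path: str | Path, dialect: str = "auto"
) -> IngestReport:
    """Read the metadata workbook into validated ontology records.

    Parameters
    ----------
    path
        Either an ``.xlsx`` workbook with one sheet per ontology, or a
        directory of per-ontology ``.csv`` files with the same two-column
        layout.
    dialect
        ``"xlsx"``, ``"csv"`` or ``"auto"`` (decide from the path).

    Raises
    ------
    DialectError
        If a sheet violates the layout (missing/duplicate section header,
        unknown field label).
    CatalogError
        If two sheets declare the same acronym.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "csv" if path.is_dir() else "xlsx"
    if dialect == "xlsx":
        sheets = _sheets_from_xlsx(path)
    elif dialect == "csv":
        sheets = _sheets_from_csv_dir(path)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    report = IngestReport()
    seen: dict[str, str] = {}
    for sheet_name, rows in sheets:
        if all(_cell_text(k) is None and _cell_text(v) is None for k, v in rows):
            continue  # fully blank sheet carries no record
        record = _record_from_rows(sheet_name, rows)
        acronym = record.acronym or sheet_name
        if record.acronym in seen:
            raise CatalogError(
                f"duplicate acronym {record.acronym!r} "
                f"(sheets {seen[record.acronym]!r} and {sheet_name!r})"
            )
        if record.acronym:
            seen[record.acronym] = sheet_name
        messages = validate_record(record)
        if messages:
            report.violations[acronym] = messages
        report.records.append(record)
    return report


def load_template() -> dict[str, Any]:
    """The packaged JSON blueprint defining document structure and key order."""
    with resources.files("ontocat.data").joinpath(
        "record_template.json"
    ).open(encoding="utf-8") as handle:
        return json.load(handle)


def record_to_dict(
    record: OntologyRecord, template: dict[str, Any] | None = None
) -> dict[str, Any]:
    """Serialize a record to a plain dict following the template's key order.

    Absent scalar values are emitted as explicit ``null`` placeholders;
    multi-valued fields as (possibly empty) lists.
    """
    template = template or load_template()

    def _value(section: Any, fname: str, default: Any) -> Any:
        value = getattr(section, fname)
        if isinstance(value, Relatedness):
            return value.value
        if isinstance(default, list):
            return list(value)
        return value

    doc: dict[str, Any] = {}
    for attr in ("general", "references", "modeling"):
        section = getattr(record, attr)
        doc[attr] = {
            fname: _value(section, fname, default)
            for fname, default in template[attr].items()
        }
    doc["classification"] = {
        "relatedness": {
            name: str(record.classification.relatedness.get(name, ""))
            for name in SUBDOMAINS
        },
        "top_level_ontology": record.classification.top_level_ontology,
    }
    doc["characteristics"] = {
        fname: getattr(record.characteristics, fname)
        for fname in template["characteristics"]
    }
    doc["comments"] = record.comments or None
    return doc


def record_from_dict(doc: dict[str, Any]) -> OntologyRecord:
    """Inverse of :func:`record_to_dict`."""
    general = GeneralInfo(**{
        **doc.get("general", {}),
        "name": doc.get("general", {}).get("name") or "",
        "acronym": doc.get("general", {}).get("acronym") or "",
    })
    references = References(**doc.get("references", {}))
    modeling = Modeling(**doc.get("modeling", {}))
    cls_doc = doc.get("classification", {})
    classification = DomainClassification(
        relatedness={
            name: Relatedness(level)
            for name, level in cls_doc.get("relatedness", {}).items()
        },
        top_level_ontology=bool(cls_doc.get("top_level_ontology", False)),
    )
    characteristics = Characteristics(**doc.get("characteristics", {}))
    return OntologyRecord(
        general=general,
        references=references,
        modeling=modeling,
        classification=classification,
        characteristics=characteristics,
        comments=doc.get("comments") or "",
    )


def export_record_json(
    record: OntologyRecord,
    template: dict[str, Any] | None = None,
    out_dir: str | Path = ".",
) -> Path:
    """Write one JSON document for a record; returns the written path.

    The file is named after the sanitized acronym; output bytes are stable
    across runs for identical input.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = sanitize_acronym(record.acronym)
    if not stem:
        raise ValueError(
            f"acronym {record.acronym!r} sanitizes to an empty filename"
        )
    path = out_dir / f"{stem}.json"
    doc = record_to_dict(record, template)
    path.write_text(
        json.dumps(doc, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )
    return path


def load_catalog(json_dir: str | Path) -> Catalog:
    """Load a directory of exported JSON documents into a catalog.

    Duplicate acronyms are rejected; malformed JSON raises a parse error
    naming the offending file.  An empty directory yields an empty catalog
    (with a logged warning).
    """
    json_dir = Path(json_dir)
    records: list[OntologyRecord] = []
    paths = sorted(json_dir.glob("*.json"))
    if not paths:
        logger.warning("no JSON documents found in %s", json_dir)
    for path in paths:
        try:
            doc = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed JSON in {path}: {exc}") from exc
        records.append(record_from_dict(doc))
    return Catalog(records=records)
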