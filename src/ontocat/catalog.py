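"""Metadata schema for the ontology catalog.

The catalog describes each ontology with six curated metadata sections
(general information, references, modelling and availability, domain
classification, characteristics, comments) and classifies it against the
fourteen subdomains of the catalysis-research data value chain.  Relatedness
of an ontology to a subdomain is expressed on a four-level ordinal
vocabulary::

    missing < related:broader < related:narrower < contained

``contained`` means the subdomain's concepts are substantially represented
in the ontology; ``missing`` means close to no concepts are.  The two
``related:*`` levels are intermediate curator judgements; this module stores
and orders them but assigns them no operational semantics.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping
from urllib.parse import urlparse

__all__ = [
    "Relatedness",
    "SUBDOMAINS",
    "SUBDOMAIN_GROUPS",
    "subdomain_names",
    "normalize_subdomain",
    "DomainClassification",
    "GeneralInfo",
    "References",
    "Modeling",
    "Characteristics",
    "OntologyRecord",
    "Catalog",
    "relatedness_rank",
    "validate_record",
    "cumulative_domain_counts",
    "DomainCounts",
]


class Relatedness(str, enum.Enum):
    """Four-level ordinal vocabulary for subdomain coverage."""

    MISSING = "missing"
    RELATED_BROADER = "related:broader"
    RELATED_NARROWER = "related:narrower"
    CONTAINED = "contained"

    def __str__(self) -> str:  # keep serialized form identical to the value
        return self.value


_RANK: dict[Relatedness, int] = {
    Relatedness.MISSING: 0,
    Relatedness.RELATED_BROADER: 1,
    Relatedness.RELATED_NARROWER: 2,
    Relatedness.CONTAINED: 3,
}


def relatedness_rank(level: Relatedness | str) -> int:
    """Ordinal rank of a relatedness level (missing=0 ... contained=3).

    Raises ``ValueError`` for strings outside the four-term vocabulary.
    """
    if not isinstance(level, Relatedness):
        level = Relatedness(level)  # ValueError on unknown vocabulary
    return _RANK[level]


# The 14 subdomains, grouped as on the aggregate radar plot: specific fields
# of catalysis, modelling-oriented fields, then general catalytic data fields.
SUBDOMAIN_GROUPS: tuple[tuple[str, tuple[str, ...]], ...] = (
    (
        "catalysis-field",
        (
            "Biocatalysis",
            "Heterogeneous catalysis",
            "Homogeneous catalysis",
            "Photocatalysis",
            "Electrocatalysis",
        ),
    ),
    (
        "modelling-field",
        (
            "Chemical substance modelling",
            "Material modelling",
            "Process modelling",
        ),
    ),
    (
        "data-field",
        (
            "Synthesis data",
            "Operando data",
            "Performance data",
            "Characterisation data",
            "Heat, transport and kinetic data",
            "Process design, energy and cost data",
        ),
    ),
)

#: Ordered names of the 14 subdomains.
SUBDOMAINS: tuple[str, ...] = tuple(
    name for _, names in SUBDOMAIN_GROUPS for name in names
)

#: Map subdomain name -> group tag.
SUBDOMAIN_GROUP_OF: dict[str, str] = {
    name: group for group, names in SUBDOMAIN_GROUPS for name in names
}

# Accepted alias spellings (normalised at ingest).  Curated sources use both
# "heterogenous" and "heterogeneous", and both "modeling" and "modelling".
_ALIASES: dict[str, str] = {
    "heterogenous catalysis": "Heterogeneous catalysis",
    "homogenous catalysis": "Homogeneous catalysis",
    "chemical substance modeling": "Chemical substance modelling",
    "material modeling": "Material modelling",
    "process modeling": "Process modelling",
    "characterization data": "Characterisation data",
}
_CANONICAL_LOWER: dict[str, str] = {name.lower(): name for name in SUBDOMAINS}


def subdomain_names() -> tuple[str, ...]:
    """The canonical, ordered tuple of the 14 subdomain names."""
    return SUBDOMAINS


def normalize_subdomain(name: str) -> str:
    """Map a (possibly alias-spelled) subdomain name to its canonical form.

    Raises ``KeyError`` if the name is not a subdomain under any accepted
    spelling.
    """
    key = " ".join(name.split()).lower()
    if key in _CANONICAL_LOWER:
        return _CANONICAL_LOWER[key]
    if key in _ALIASES:
        return _ALIASES[key]
    raise KeyError(f"unknown subdomain: {name!r}")


@dataclass
class DomainClassification:
    """Relatedness of one ontology to each of the 14 subdomains.

    ``top_level_ontology`` flags a domain-independent foundational ontology;
    it is deliberately not a 15th subdomain.
    """

    relatedness: dict[str, Relatedness] = field(default_factory=dict)
    top_level_ontology: bool = False

    @classmethod
    def all_missing(cls, top_level_ontology: bool = False) -> "DomainClassification":
        return cls(
            relatedness={name: Relatedness.MISSING for name in SUBDOMAINS},
            top_level_ontology=top_level_ontology,
        )

    def rank(self, subdomain: str) -> int:
        return relatedness_rank(self.relatedness[subdomain])


@dataclass
class GeneralInfo:
    name: str = ""
    alternative_names: list[str] = field(default_factory=list)
    acronym: str = ""
    creators: list[str] = field(default_factory=list)
    issuing_organization: str = ""
    organizational_structure: str = ""


@dataclass
class References:
    organization_url: str | None = None
    persistent_uri: str | None = None
    documentation_url: str | None = None
    version_directory_url: str | None = None
    additional_links: list[str] = field(default_factory=list)


@dataclass
class Modeling:
    formats: list[str] = field(default_factory=list)
    inference_degree: str | None = None
    license: str | None = None
    working_reasoners: list[str] = field(default_factory=list)
    shortest_reasoning_time: str | None = None
    top_level_alignment: str | None = None
    imports: list[str] = field(default_factory=list)
    prefixes: list[str] = field(default_factory=list)
    class_annotation_types: list[str] = field(default_factory=list)


#: Entity-count fields recorded in the characteristics section, in the order
#: they are documented.
CHARACTERISTIC_FIELDS: tuple[str, ...] = (
    "axiom_count",
    "logical_axiom_count",
    "declaration_count",
    "class_count",
    "object_property_count",
    "data_property_count",
    "individual_count",
    "annotation_property_count",
)


@dataclass
class Characteristics:
    axiom_count: int | None = None
    logical_axiom_count: int | None = None
    declaration_count: int | None = None
    class_count: int | None = None
    object_property_count: int | None = None
    data_property_count: int | None = None
    individual_count: int | None = None
    annotation_property_count: int | None = None


@dataclass
class OntologyRecord:
    """One ontology's curated metadata across the six catalog sections."""

    general: GeneralInfo = field(default_factory=GeneralInfo)
    references: References = field(default_factory=References)
    modeling: Modeling = field(default_factory=Modeling)
    classification: DomainClassification = field(
        default_factory=DomainClassification.all_missing
    )
    characteristics: Characteristics = field(default_factory=Characteristics)
    comments: str = ""

    @property
    def acronym(self) -> str:
        return self.general.acronym


_ACRONYM_SANITIZE = re.compile(r"[^A-Za-z0-9_-]+")


def sanitize_acronym(acronym: str) -> str:
    """Filesystem-safe form of an acronym (alphanumerics, dash, underscore)."""
    return _ACRONYM_SANITIZE.sub("_", acronym.strip()).strip("_")


def _is_absolute_uri(value: str) -> bool:
    parsed = urlparse(value)
    return bool(parsed.scheme) and bool(parsed.netloc or parsed.path)


def validate_record(record: OntologyRecord) -> list[str]:
    """Check one record against the schema invariants.

    Returns an empty list for a conforming record; otherwise one message per
    violation, each naming the section and field concerned.  Validation is
    pure: the record is never modified and no exception is raised for
    content problems.
    """
    violations: list[str] = []

    if not record.general.acronym or not record.general.acronym.strip():
        violations.append("general/acronym: must be non-empty")

    for fname in ("persistent_uri", "organization_url", "documentation_url",
                  "version_directory_url"):
        value = getattr(record.references, fname)
        if value is not None and not _is_absolute_uri(value):
            violations.append(
                f"references/{fname}: not a valid absolute URI: {value!r}"
            )

    seen = set(record.classification.relatedness)
    for name in SUBDOMAINS:
        if name not in seen:
            violations.append(f"classification/{name}: subdomain missing")
    for name in sorted(seen - set(SUBDOMAINS)):
        violations.append(f"classification/{name}: not a known subdomain")
    for name, level in record.classification.relatedness.items():
        if not isinstance(level, Relatedness):
            try:
                Relatedness(level)
            except ValueError:
                violations.append(
                    f"classification/{name}: invalid relatedness value "
                    f"{level!r} (admissible: "
                    + ", ".join(m.value for m in Relatedness)
                    + ")"
                )

    for fname in CHARACTERISTIC_FIELDS:
        value = getattr(record.characteristics, fname)
        if value is None:
            continue
        if not isinstance(value, int) or isinstance(value, bool) or value < 0:
            violations.append(
                f"characteristics/{fname}: must be a non-negative integer, "
                f"got {value!r}"
            )

    return violations


@dataclass
class Catalog:
    """The validated set of ontology records, optionally with lexicons."""

    records: list[OntologyRecord] = field(default_factory=list)
    lexicons: dict[str, object] | None = None

    def __post_init__(self) -> None:
        acronyms = [r.acronym for r in self.records]
        dupes = {a for a in acronyms if acronyms.count(a) > 1}
        if dupes:
            raise ValueError(
                "duplicate acronyms in catalog: " + ", ".join(sorted(dupes))
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, acronym: str) -> OntologyRecord:
        for record in self.records:
            if record.acronym == acronym:
                return record
        raise KeyError(acronym)

    @property
    def acronyms(self) -> list[str]:
        return [r.acronym for r in self.records]


@dataclass(frozen=True)
class DomainCounts:
    """Cumulative ontology counts for one subdomain."""

    n_at_least_broader: int
    n_at_least_narrower: int
    n_contained: int


def cumulative_domain_counts(
    catalog: Catalog | Iterable[OntologyRecord],
) -> dict[str, DomainCounts]:
    """Per-subdomain cumulative tallies over a catalog.

    For every subdomain the triple counts the records whose relatedness is at
    least ``related:broader``, at least ``related:narrower``, and exactly
    ``contained``.  By rank monotonicity
    ``n_contained <= n_at_least_narrower <= n_at_least_broader`` always
    holds.  An empty catalog yields all-zero triples.
    """
    records = list(catalog)
    counts: dict[str, DomainCounts] = {}
    for name in SUBDOMAINS:
        ranks = [r.classification.rank(name) for r in records]
        counts[name] = DomainCounts(
            n_at_least_broader=sum(1 for k in ranks if k >= 1),
            n_at_least_narrower=sum(1 for k in ranks if k >= 2),
            n_contained=sum(1 for k in ranks if k >= 3),
        )
    return counts
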