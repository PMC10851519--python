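"""Human-readable documentation layer: Markdown pages and radar plots.

Everything here is derived purely from catalog records and pair mappings,
and is byte-stable across runs: no timestamps, fixed key order, fixed axis
order.  Radar images come with a TSV sidecar holding the exact axis/value
series — downstream checks target the sidecar, since plot image bytes
depend on the rendering backend.

Layout written by :func:`render_site` under the output directory::

    README.md                      index: listing, domain tables, matrix
    ontologies/<ACRO>.md           one page per ontology
    mappings/<A>__<B>.md           one page per unordered pair (A < B)
    plots/<ACRO>_radar.png|.tsv    per-ontology radar
    plots/overview_radar.png|.tsv  aggregate radar (three cumulative traces)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .catalog import (
    Catalog,
    DomainCounts,
    OntologyRecord,
    Relatedness,
    SUBDOMAIN_GROUP_OF,
    SUBDOMAINS,
    cumulative_domain_counts,
    relatedness_rank,
    sanitize_acronym,
)
from .ingest import FIELD_LAYOUT, SECTION_HEADERS, TOP_LEVEL_LABEL
from .mapper import MappingMatrix, PairMapping

__all__ = [
    "RadarSeries",
    "ABSENT",
    "render_ontology_page",
    "render_pair_table",
    "render_readme",
    "render_radar",
    "ontology_radar_series",
    "aggregate_radar_series",
    "pair_page_name",
    "render_site",
]

#: Placeholder for absent values in rendered tables.
ABSENT = "—"  # em dash

#: Axis-group colours on the aggregate radar (catalysis / modelling / data).
GROUP_COLORS = {
    "catalysis-field": "tab:blue",
    "modelling-field": "purple",
    "data-field": "black",
}
#: Trace colours for the cumulative series.
TRACE_COLORS = {
    "at-least-broader": "tab:red",
    "at-least-narrower": "gold",
    "contained": "tab:green",
}


@dataclass
class RadarSeries:
    """Values over the 14 subdomain axes, one or more named traces."""

    axes: tuple[str, ...] = field(default_factory=lambda: SUBDOMAINS)
    traces: dict[str, list[float]] = field(default_factory=dict)
    title: str = ""

    def __post_init__(self) -> None:
        if len(self.axes) != len(SUBDOMAINS):
            raise ValueError("radar series must span all subdomain axes")
        for name, values in self.traces.items():
            if len(values) != len(self.axes):
                raise ValueError(
                    f"trace {name!r}: {len(values)} values for "
                    f"{len(self.axes)} axes"
                )


def ontology_radar_series(record: OntologyRecord) -> RadarSeries:
    """Single-trace series: the ontology's relatedness rank per subdomain."""
    return RadarSeries(
        traces={
            "relatedness": [
                float(record.classification.rank(name)) for name in SUBDOMAINS
            ]
        },
        title=record.acronym,
    )


def aggregate_radar_series(
    catalog: Catalog, counts: Mapping[str, DomainCounts] | None = None
) -> RadarSeries:
    """Three-trace series with the catalog's cumulative counts per subdomain."""
    counts = counts or cumulative_domain_counts(catalog)
    return RadarSeries(
        traces={
            "at-least-broader": [
                float(counts[n].n_at_least_broader) for n in SUBDOMAINS
            ],
            "at-least-narrower": [
                float(counts[n].n_at_least_narrower) for n in SUBDOMAINS
            ],
            "contained": [float(counts[n].n_contained) for n in SUBDOMAINS],
        },
        title="Ontologies per domain of catalysis research",
    )


def render_radar(series: RadarSeries, out_path: str | Path) -> tuple[Path, Path]:
    """Write the radar image and its TSV sidecar; returns both paths.

    The sidecar has one row per axis (axis, group, then one column per
    trace) and is the canonical, byte-stable record of what was plotted.
    """
    import math

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)

    n = len(series.axes)
    angles = [2 * math.pi * i / n for i in range(n)]
    fig, ax = plt.subplots(subplot_kw={"polar": True}, figsize=(7, 7))
    for name, values in series.traces.items():
        closed_angles = angles + angles[:1]
        closed_values = list(values) + [values[0]]
        color = TRACE_COLORS.get(name)
        ax.plot(closed_angles, closed_values, label=name, color=color)
        ax.fill(closed_angles, closed_values, alpha=0.1, color=color)
    ax.set_xticks(angles)
    ax.set_xticklabels(series.axes, fontsize=7)
    for label, axis_name in zip(ax.get_xticklabels(), series.axes):
        label.set_color(GROUP_COLORS[SUBDOMAIN_GROUP_OF[axis_name]])
    if series.title:
        ax.set_title(series.title)
    if len(series.traces) > 1:
        ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    fig.savefig(out_path, bbox_inches="tight", dpi=120)
    plt.close(fig)

    sidecar = out_path.with_suffix(".tsv")
    trace_names = list(series.traces)
    lines = ["\t".join(["axis", "group"] + trace_names)]
    for i, axis_name in enumerate(series.axes):
        row = [axis_name, SUBDOMAIN_GROUP_OF[axis_name]]
        row += [_format_number(series.traces[t][i]) for t in trace_names]
        lines.append("\t".join(row))
    sidecar.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out_path, sidecar


def _format_number(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(value)


def _link(url: str | None) -> str:
    return f"<{url}>" if url else ABSENT


def _text(value: str | None) -> str:
    return value if value else ABSENT


def _items(values: Sequence[str]) -> str:
    return "; ".join(values) if values else ABSENT


def render_ontology_page(
    record: OntologyRecord, radar_path: str | Path | None = None
) -> str:
    """Markdown page for one ontology: all six sections plus its radar."""
    g, ref, mod = record.general, record.references, record.modeling
    lines: list[str] = [f"# {g.acronym or g.name}", ""]
    if g.name and g.acronym:
        lines += [f"*{g.name}*", ""]
    if radar_path is not None:
        lines += [f"![Domain radar plot for {g.acronym}]({radar_path})", ""]

    lines += ["## General information", ""]
    lines += _kv_table(
        [
            ("Ontology name", _text(g.name)),
            ("Alternative names", _items(g.alternative_names)),
            ("Ontology acronym", _text(g.acronym)),
            ("Creator(s)", _items(g.creators)),
            ("Issuing organization", _text(g.issuing_organization)),
            ("Organizational structure", _text(g.organizational_structure)),
        ]
    )
    lines += ["", "## References", ""]
    lines += _kv_table(
        [
            ("Organizational website", _link(ref.organization_url)),
            ("Persistent URI", _link(ref.persistent_uri)),
            ("Documentation", _link(ref.documentation_url)),
            ("Version directory", _link(ref.version_directory_url)),
            (
                "Additional links",
                "; ".join(f"<{u}>" for u in ref.additional_links) or ABSENT,
            ),
        ]
    )
    lines += ["", "## Ontology modeling and availability", ""]
    lines += _kv_table(
        [
            ("Formats", _items(mod.formats)),
            ("Degree of inference and composition", _text(mod.inference_degree)),
            ("License", _text(mod.license)),
            ("Working reasoners", _items(mod.working_reasoners)),
            ("Shortest reasoning time", _text(mod.shortest_reasoning_time)),
            ("Top level alignment", _text(mod.top_level_alignment)),
            ("Imports", _items(mod.imports)),
            ("Prefixes", _items(mod.prefixes)),
            ("Class annotation types", _items(mod.class_annotation_types)),
        ]
    )
    lines += ["", "## Classification", ""]
    cls_rows = [
        (name, str(record.classification.relatedness[name]))
        for name in SUBDOMAINS
        if name in record.classification.relatedness
    ]
    cls_rows.append(
        (TOP_LEVEL_LABEL, "yes" if record.classification.top_level_ontology else "no")
    )
    lines += _kv_table(cls_rows, headers=("Subdomain", "Relatedness"))
    lines += ["", "## Ontology characteristics", ""]
    char_rows = []
    for label, fname, _kind in FIELD_LAYOUT["Ontology characteristics"]:
        value = getattr(record.characteristics, fname)
        char_rows.append((label, str(value) if value is not None else ABSENT))
    lines += _kv_table(char_rows, headers=("Metric", "Value"))
    lines += ["", "## Comments", "", record.comments or ABSENT, ""]
    return "\n".join(lines)


def _kv_table(
    rows: Sequence[tuple[str, str]], headers: tuple[str, str] = ("Field", "Value")
) -> list[str]:
    out = [f"| {headers[0]} | {headers[1]} |", "| --- | --- |"]
    out += [f"| {key} | {value} |" for key, value in rows]
    return out


def pair_page_name(acronym_a: str, acronym_b: str) -> str:
    """Canonical pair page filename: acronyms in ascending order."""
    first, second = sorted(
        (sanitize_acronym(acronym_a), sanitize_acronym(acronym_b))
    )
    return f"{first}__{second}.md"


def render_pair_table(pair: PairMapping) -> str:
    """Markdown detail table for one ontology pair.

    Numbered rows, IRI-identity matches first, then lexical matches; five
    data columns: class IRI and rationale for each side, then the textual
    definition of the second ontology's class (empty where unavailable).
    """
    lines = [
        f"# Class mapping: {pair.acronym_a} – {pair.acronym_b}",
        "",
        f"{pair.count} mapped class pair(s).",
        "",
    ]
    if not pair.rows:
        lines += ["*No mappings found.*", ""]
        return "\n".join(lines)
    lines += [
        f"| # | IRI ({pair.acronym_a}) | Rationale ({pair.acronym_a}) "
        f"| IRI ({pair.acronym_b}) | Rationale ({pair.acronym_b}) "
        f"| Definition ({pair.acronym_b}) |",
        "| --- | --- | --- | --- | --- | --- |",
    ]
    ordered = pair.iri_rows + pair.lexical_rows
    for i, row in enumerate(ordered):
        definition = row.definition_b or ""
        definition = definition.replace("|", "\\|").replace("\n", " ")
        lines.append(
            f"| {i} | [{row.iri_a}]({row.iri_a}) | {row.rationale_a} "
            f"| [{row.iri_b}]({row.iri_b}) | {row.rationale_b} "
            f"| {definition} |"
        )
    lines.append("")
    return "\n".join(lines)


def render_readme(
    catalog: Catalog,
    matrix: MappingMatrix | None = None,
    page_dir: str = "ontologies",
    mapping_dir: str = "mappings",
    plot_dir: str = "plots",
) -> str:
    """Markdown index: listing, domain tables, aggregate radar, matrix.

    Links are relative to the output root, pointing at the files written by
    :func:`render_site`.
    """
    lines = [
        "# Ontology catalog for catalysis research",
        "",
        "Curated metadata, domain classification and pairwise class",
        "mappings for the ontologies below.",
        "",
        "## Ontologies",
        "",
        "| Acronym | Name |",
        "| --- | --- |",
    ]
    for record in sorted(catalog, key=lambda r: r.acronym):
        stem = sanitize_acronym(record.acronym)
        lines.append(
            f"| [{record.acronym}]({page_dir}/{stem}.md) "
            f"| {_text(record.general.name)} |"
        )
    lines += [
        "",
        "## Domain coverage",
        "",
        f"![Ontologies per domain]({plot_dir}/overview_radar.png)",
        "",
    ]
    for name in SUBDOMAINS:
        lines += [f"### {name}", ""]
        clusters: dict[str, list[str]] = {
            m.value: [] for m in Relatedness if m is not Relatedness.MISSING
        }
        for record in sorted(catalog, key=lambda r: r.acronym):
            level = record.classification.relatedness.get(name)
            if level is None:
                continue
            if relatedness_rank(level) > 0:
                clusters[str(level)].append(record.acronym)
        lines += ["| Relatedness | Ontologies |", "| --- | --- |"]
        any_row = False
        for level in ("contained", "related:narrower", "related:broader"):
            members = clusters[level]
            if members:
                any_row = True
                linked = ", ".join(
                    f"[{a}]({page_dir}/{sanitize_acronym(a)}.md)" for a in members
                )
                lines.append(f"| {level} | {linked} |")
        if not any_row:
            lines.append("| none | — |")
        lines.append("")

    if matrix is not None:
        lines += [
            "## Class mappings",
            "",
            "Mapped class pairs per ontology pair; the diagonal lists each",
            "ontology's total class count.",
            "",
            "| | " + " | ".join(matrix.acronyms) + " |",
            "| --- |" + " --- |" * len(matrix.acronyms),
        ]
        for a in matrix.acronyms:
            cells = []
            for b in matrix.acronyms:
                value = matrix.cell(a, b)
                if a == b:
                    cells.append(f"**{value}**")
                else:
                    cells.append(
                        f"[{value}]({mapping_dir}/{pair_page_name(a, b)})"
                    )
            lines.append(f"| **{a}** | " + " | ".join(cells) + " |")
        lines.append("")
    return "\n".join(lines)


def render_site(
    catalog: Catalog,
    out_dir: str | Path,
    pair_mappings: Mapping[tuple[str, str], PairMapping] | None = None,
    matrix: MappingMatrix | None = None,
) -> Path:
    """Write the full documentation tree; returns the README path.

    Per-ontology pages and radars are always written; mapping pages and
    the matrix section only when pair mappings are provided.  Self-pairs
    are never emitted as pages.
    """
    out_dir = Path(out_dir)
    (out_dir / "ontologies").mkdir(parents=True, exist_ok=True)
    (out_dir / "plots").mkdir(exist_ok=True)

    for record in catalog:
        stem = sanitize_acronym(record.acronym)
        render_radar(
            ontology_radar_series(record), out_dir / "plots" / f"{stem}_radar.png"
        )
        page = render_ontology_page(
            record, radar_path=f"../plots/{stem}_radar.png"
        )
        (out_dir / "ontologies" / f"{stem}.md").write_text(page, encoding="utf-8")

    render_radar(
        aggregate_radar_series(catalog), out_dir / "plots" / "overview_radar.png"
    )

    if pair_mappings:
        (out_dir / "mappings").mkdir(exist_ok=True)
        for (a, b), pm in sorted(pair_mappings.items()):
            if a == b:
                continue
            name = pair_page_name(a, b)
            (out_dir / "mappings" / name).write_text(
                render_pair_table(pm), encoding="utf-8"
            )

    readme_path = out_dir / "README.md"
    readme_path.write_text(render_readme(catalog, matrix), encoding="utf-8")
    return readme_path
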