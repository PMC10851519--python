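"""Workbook ingestion, JSON export and catalog round-tripping."""

from __future__ import annotations

import json

import pytest
from openpyxl import load_workbook

from ontocat.catalog import Relatedness
from ontocat.fixtures import generate_workbook_fixture
from ontocat.ingest import (
    CatalogError,
    DialectError,
    export_record_json,
    load_catalog,
    load_template,
    read_metadata_workbook,
    record_from_dict,
    record_to_dict,
)

from conftest import make_record


@pytest.fixture(params=["xlsx", "csv"])
def workbook_with_records(request, tmp_path):
    target = tmp_path / ("wb.xlsx" if request.param == "xlsx" else "csvdir")
    expected = generate_workbook_fixture(3, seed=11, out_path=target,
                                         dialect=request.param)
    return target, expected


class TestReadMetadataWorkbook:
    def test_fixture_workbook_round_trips(self, workbook_with_records):
        path, expected = workbook_with_records
        report = read_metadata_workbook(path)
        assert report.ok
        assert report.records == expected
        assert [r.acronym for r in report] == [r.acronym for r in expected]

    def test_missing_section_header_names_the_sheet(self, tmp_path):
        path = tmp_path / "wb.xlsx"
        generate_workbook_fixture(1, seed=1, out_path=path)
        workbook = load_workbook(path)
        sheet = workbook.active
        for row in sheet.iter_rows():
            if row[0].value == "References":
                row[0].value = None
        workbook.save(path)
        with pytest.raises(DialectError, match="SYN0.*References"):
            read_metadata_workbook(path)

    def test_blank_reasoner_cell_yields_empty_list(self, tmp_path):
        # no working reasoner found is a permitted, meaningful state
        path = tmp_path / "wb.xlsx"
        generate_workbook_fixture(1, seed=2, out_path=path)
        workbook = load_workbook(path)
        sheet = workbook.active
        for row in sheet.iter_rows():
            if row[0].value == "Working reasoners":
                row[1].value = None
        workbook.save(path)
        report = read_metadata_workbook(path)
        assert report.records[0].modeling.working_reasoners == []

    def test_blank_cells_become_absent_not_empty_string(self, tmp_path):
        path = tmp_path / "wb.xlsx"
        generate_workbook_fixture(1, seed=3, out_path=path)
        workbook = load_workbook(path)
        sheet = workbook.active
        for row in sheet.iter_rows():
            if row[0].value in ("License", "Axioms"):
                row[1].value = None
        workbook.save(path)
        record = read_metadata_workbook(path).records[0]
        assert record.modeling.license is None
        assert record.characteristics.axiom_count is None

    def test_duplicate_acronym_rejected(self, tmp_path):
        path = tmp_path / "wb.xlsx"
        generate_workbook_fixture(1, seed=4, out_path=path)
        workbook = load_workbook(path)
        source = workbook.active
        copy = workbook.copy_worksheet(source)
        copy.title = "SYN0-copy"
        workbook.save(path)
        with pytest.raises(CatalogError, match="SYN0"):
            read_metadata_workbook(path)

    def test_unknown_field_label_is_a_dialect_error(self, tmp_path):
        path = tmp_path / "wb.xlsx"
        generate_workbook_fixture(1, seed=9, out_path=path)
        workbook = load_workbook(path)
        sheet = workbook.active
        for row in sheet.iter_rows():
            if row[0].value == "License":
                row[0].value = "Favourite colour"
        workbook.save(path)
        with pytest.raises(DialectError, match="Favourite colour"):
            read_metadata_workbook(path)


class TestJsonExport:
    def test_file_named_after_acronym_with_six_sections(self, tmp_path):
        record = make_record("AFO")
        path = export_record_json(record, out_dir=tmp_path)
        assert path.name == "AFO.json"
        doc = json.loads(path.read_text())
        assert list(doc) == [
            "general",
            "references",
            "modeling",
            "classification",
            "characteristics",
            "comments",
        ]

    def test_acronym_is_sanitized_for_filenames(self, tmp_path):
        record = make_record("ISO 15926-14")
        path = export_record_json(record, out_dir=tmp_path)
        assert path.name == "ISO_15926-14.json"

    def test_unsanitizable_acronym_is_an_error(self, tmp_path):
        record = make_record("OK")
        record.general.acronym = "///"
        with pytest.raises(ValueError, match="sanitizes"):
            export_record_json(record, out_dir=tmp_path)

    def test_absent_values_become_explicit_null(self, tmp_path):
        record = make_record("AFO")
        assert record.modeling.shortest_reasoning_time is None
        doc = json.loads(
            export_record_json(record, out_dir=tmp_path).read_text()
        )
        assert "shortest_reasoning_time" in doc["modeling"]
        assert doc["modeling"]["shortest_reasoning_time"] is None

    def test_export_is_byte_deterministic(self, tmp_path):
        record = make_record("AFO", {"Biocatalysis": "contained"})
        first = export_record_json(record, out_dir=tmp_path / "a").read_bytes()
        second = export_record_json(record, out_dir=tmp_path / "b").read_bytes()
        assert first == second

    def test_dict_round_trip_preserves_every_field(self):
        record = make_record("BAO", {"Operando data": "related:narrower"})
        record.modeling.working_reasoners = ["HermiT", "FaCT++"]
        record.characteristics.class_count = 7512
        assert record_from_dict(record_to_dict(record)) == record

    def test_template_covers_every_record_field(self):
        template = load_template()
        record = make_record("X")
        doc = record_to_dict(record, template)
        for section in ("general", "references", "modeling", "characteristics"):
            assert set(doc[section]) == set(template[section])
        assert len(doc["classification"]["relatedness"]) == 14


class TestLoadCatalog:
    def test_directory_of_exports_loads_back(self, tmp_path):
        records = [make_record(a) for a in ("AFO", "BAO", "BFO")]
        for record in records:
            export_record_json(record, out_dir=tmp_path)
        catalog = load_catalog(tmp_path)
        assert sorted(catalog.acronyms) == ["AFO", "BAO", "BFO"]

    def test_duplicate_acronyms_across_files_rejected(self, tmp_path):
        record = make_record("BAO")
        path = export_record_json(record, out_dir=tmp_path)
        (tmp_path / "BAO2.json").write_text(path.read_text())
        with pytest.raises(ValueError, match="duplicate"):
            load_catalog(tmp_path)

    def test_empty_directory_gives_empty_catalog(self, tmp_path):
        assert len(load_catalog(tmp_path)) == 0

    def test_malformed_json_names_the_file(self, tmp_path):
        (tmp_path / "bad.json").write_text("{not json")
        with pytest.raises(ValueError, match="bad.json"):
            load_catalog(tmp_path)


def test_full_round_trip_workbook_to_catalog(tmp_path):
    expected = generate_workbook_fixture(
        4, seed=42, out_path=tmp_path / "wb.xlsx"
    )
    report = read_metadata_workbook(tmp_path / "wb.xlsx")
    for record in report:
        export_record_json(record, out_dir=tmp_path / "json")
    catalog = load_catalog(tmp_path / "json")
    assert sorted(catalog.records, key=lambda r: r.acronym) == sorted(
        expected, key=lambda r: r.acronym
    )
    # classification levels survive as the enum type
    assert all(
        isinstance(level, Relatedness)
        for record in catalog
        for level in record.classification.relatedness.values()
    )
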