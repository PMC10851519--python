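"""Two-stage pair mapping, all-pairs matrix and concept-list matching."""

from __future__ import annotations

import pytest

from ontocat.fixtures import OverlapSpec, SharedLabel, generate_ontology_pair
from ontocat.lexicon import build_lexicon
from ontocat.mapper import (
    IRI_RATIONALE,
    build_matrix,
    map_all_pairs,
    map_pair,
    match_by_annotation,
    match_by_iri,
    match_concept_list,
)

from conftest import brute_force_pair_count, make_lexicon


def lexicons_from_spec(spec, tmp_path, adversarial=False):
    pair = generate_ontology_pair(spec, adversarial=adversarial)
    paths = pair.write(tmp_path)
    return (
        build_lexicon("A", paths["ttl_a"]),
        build_lexicon("B", paths["ttl_b"]),
    )


class TestMatchByIri:
    def test_self_comparison_matches_everything(self, simple_lexicon_pair):
        lex_a, _ = simple_lexicon_pair
        rows, matched_a, matched_b = match_by_iri(lex_a, lex_a)
        assert len(rows) == lex_a.class_count
        assert matched_a == matched_b == lex_a.iris
        # nothing is left for the lexical stage
        assert match_by_annotation(lex_a, lex_a, matched_a, matched_b) == []

    def test_disjoint_iri_spaces_match_nothing(self):
        lex_a = make_lexicon("A", {"http://ex.org/a#C1": {}})
        lex_b = make_lexicon("B", {"http://ex.org/b#C1x": {}})
        rows, matched_a, matched_b = match_by_iri(lex_a, lex_b)
        assert rows == [] and matched_a == set() and matched_b == set()

    def test_shared_iris_give_one_row_each(self, tmp_path):
        spec = OverlapSpec(n_classes_a=10, n_classes_b=12, n_shared_iris=4, seed=1)
        lex_a, lex_b = lexicons_from_spec(spec, tmp_path)
        rows, _, _ = match_by_iri(lex_a, lex_b)
        assert len(rows) == 4
        assert all(r.rationale_a == r.rationale_b == IRI_RATIONALE for r in rows)
        assert [r.iri_a for r in rows] == sorted(r.iri_a for r in rows)


class TestMatchByAnnotation:
    def test_label_matches_alt_label_across_fields(self, simple_lexicon_pair):
        lex_a, lex_b = simple_lexicon_pair
        _, matched_a, matched_b = match_by_iri(lex_a, lex_b)
        rows = match_by_annotation(lex_a, lex_b, matched_a, matched_b)
        assert len(rows) == 1
        row = rows[0]
        assert (row.rationale_a, row.rationale_b) == ("rdfs:label", "skos:altLabel")
        assert row.matched_value == "Shape"
        assert row.definition_b == "a form or contour"

    def test_alt_label_matches_label_with_swapped_rationales(self):
        lex_a = make_lexicon(
            "A", {"http://ex.org/a#T": {"alt_labels": ["time"]}}
        )
        lex_b = make_lexicon("B", {"http://ex.org/b#U": {"labels": ["time"]}})
        rows = match_by_annotation(lex_a, lex_b)
        assert len(rows) == 1
        assert (rows[0].rationale_a, rows[0].rationale_b) == (
            "skos:altLabel",
            "rdfs:label",
        )

    def test_shared_value_cross_product_counts_class_pairs(self):
        lex_a = make_lexicon(
            "A",
            {
                f"http://ex.org/a#C{i}": {"labels": ["shared"]}
                for i in range(2)
            },
        )
        lex_b = make_lexicon(
            "B",
            {
                f"http://ex.org/b#D{i}": {"pref_labels": ["shared"]}
                for i in range(3)
            },
        )
        rows = match_by_annotation(lex_a, lex_b)
        assert len(rows) == 6  # full 2 x 3 cross product

    def test_matching_is_case_sensitive_by_default(self):
        lex_a = make_lexicon("A", {"http://ex.org/a#C": {"labels": ["Shape"]}})
        lex_b = make_lexicon("B", {"http://ex.org/b#D": {"labels": ["shape"]}})
        assert match_by_annotation(lex_a, lex_b) == []
        insensitive = match_by_annotation(lex_a, lex_b, case_sensitive=False)
        assert len(insensitive) == 1

    def test_field_priority_selects_rationale_and_keeps_rest(self):
        # both label and prefLabel coincide; rdfs:label wins on each side,
        # the lower-priority combinations are kept as extras
        lex_a = make_lexicon(
            "A",
            {"http://ex.org/a#C": {"labels": ["v"], "pref_labels": ["v"]}},
        )
        lex_b = make_lexicon(
            "B",
            {"http://ex.org/b#D": {"labels": ["v"], "pref_labels": ["v"]}},
        )
        rows = match_by_annotation(lex_a, lex_b)
        assert len(rows) == 1
        assert (rows[0].rationale_a, rows[0].rationale_b) == (
            "rdfs:label",
            "rdfs:label",
        )
        assert ("skos:prefLabel", "skos:prefLabel") in rows[0].extra_fields


class TestMapPair:
    def test_count_combines_iri_and_lexical_stages(self, tmp_path):
        spec = OverlapSpec(
            n_classes_a=10,
            n_classes_b=12,
            n_shared_iris=4,
            shared_labels=(
                SharedLabel("one"),
                SharedLabel("two", field_a="skos:prefLabel"),
                SharedLabel("three", field_b="skos:altLabel"),
            ),
            seed=2,
        )
        lex_a, lex_b = lexicons_from_spec(spec, tmp_path)
        mapping = map_pair(lex_a, lex_b)
        assert mapping.count == 4 + 3
        assert len(mapping.iri_rows) == 4
        assert len(mapping.lexical_rows) == 3

    def test_self_pair_count_equals_class_count(self, simple_lexicon_pair):
        lex_a, _ = simple_lexicon_pair
        assert map_pair(lex_a, lex_a).count == lex_a.class_count

    def test_symmetry_under_side_swap(self, tmp_path):
        spec = OverlapSpec(
            n_classes_a=8,
            n_classes_b=11,
            n_shared_iris=2,
            shared_labels=(SharedLabel("x", multiplicity_b=2),),
            seed=3,
        )
        lex_a, lex_b = lexicons_from_spec(spec, tmp_path)
        forward = map_pair(lex_a, lex_b)
        backward = map_pair(lex_b, lex_a)
        assert forward.count == backward.count
        assert {(r.iri_a, r.iri_b) for r in forward.rows} == {
            (r.iri_b, r.iri_a) for r in backward.rows
        }

    def test_iri_matched_classes_never_reappear_lexically(self, tmp_path):
        spec = OverlapSpec(
            n_classes_a=9,
            n_classes_b=9,
            n_shared_iris=3,
            shared_labels=(SharedLabel("y"),),
            seed=4,
        )
        lex_a, lex_b = lexicons_from_spec(spec, tmp_path, adversarial=True)
        mapping = map_pair(lex_a, lex_b)
        iri_side_a = {r.iri_a for r in mapping.iri_rows}
        iri_side_b = {r.iri_b for r in mapping.iri_rows}
        assert iri_side_a.isdisjoint(r.iri_a for r in mapping.lexical_rows)
        assert iri_side_b.isdisjoint(r.iri_b for r in mapping.lexical_rows)

    def test_rows_ordered_iri_first_then_pair_lexicographic(self, tmp_path):
        spec = OverlapSpec(
            n_classes_a=7,
            n_classes_b=7,
            n_shared_iris=2,
            shared_labels=(SharedLabel("z", multiplicity_a=2),),
            seed=5,
        )
        lex_a, lex_b = lexicons_from_spec(spec, tmp_path)
        mapping = map_pair(lex_a, lex_b)
        assert mapping.rows[: len(mapping.iri_rows)] == mapping.iri_rows
        lexical = mapping.lexical_rows
        assert [(r.iri_a, r.iri_b) for r in lexical] == sorted(
            (r.iri_a, r.iri_b) for r in lexical
        )

    def test_fresh_class_never_decreases_count(self, simple_lexicon_pair):
        lex_a, lex_b = simple_lexicon_pair
        before = map_pair(lex_a, lex_b).count
        grown = make_lexicon(
            "A2",
            {
                **{e.iri: {"labels": list(e.labels),
                           "pref_labels": list(e.pref_labels),
                           "alt_labels": list(e.alt_labels)}
                   for e in lex_a},
                "http://ex.org/a#Fresh": {"labels": ["totally-new-label"]},
            },
        )
        assert map_pair(grown, lex_b).count >= before

    def test_agrees_with_brute_force_oracle(self, tmp_path):
        spec = OverlapSpec(
            n_classes_a=12,
            n_classes_b=10,
            n_shared_iris=3,
            shared_labels=(
                SharedLabel("p", multiplicity_a=2, multiplicity_b=2),
            ),
            seed=6,
        )
        lex_a, lex_b = lexicons_from_spec(spec, tmp_path)
        assert map_pair(lex_a, lex_b).count == brute_force_pair_count(
            lex_a, lex_b
        )


class TestMappingMatrix:
    @pytest.fixture
    def corpus(self, tmp_path):
        lexicons = {}
        for i in range(3):
            spec = OverlapSpec(
                n_classes_a=5 + i,
                n_classes_b=6,
                n_shared_iris=2,
                shared_labels=(SharedLabel(f"m{i}"),),
                seed=30 + i,
            )
            paths = generate_ontology_pair(spec).write(tmp_path / str(i))
            lexicons[f"L{i}A"] = build_lexicon(f"L{i}A", paths["ttl_a"])
        return lexicons

    def test_symmetric_with_class_counts_on_diagonal(self, corpus):
        matrix = build_matrix(corpus)
        for a in matrix.acronyms:
            assert matrix.cell(a, a) == corpus[a].class_count
            for b in matrix.acronyms:
                assert matrix.cell(a, b) == matrix.cell(b, a)

    def test_each_pair_computed_once(self, corpus):
        pairs = map_all_pairs(corpus)
        assert len(pairs) == 3  # C(3, 2)
        assert all(a < b for a, b in pairs)

    def test_singleton_corpus_gives_1x1_matrix(self, corpus):
        acronym = next(iter(corpus))
        matrix = build_matrix({acronym: corpus[acronym]})
        assert matrix.acronyms == [acronym]
        assert matrix.cell(acronym, acronym) == corpus[acronym].class_count

    def test_order_invariance(self, corpus):
        reversed_corpus = dict(reversed(list(corpus.items())))
        m1 = build_matrix(corpus)
        m2 = build_matrix(reversed_corpus)
        for a in m1.acronyms:
            for b in m1.acronyms:
                assert m1.cell(a, b) == m2.cell(a, b)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_matrix({})


class TestMatchConceptList:
    @pytest.fixture
    def corpus(self):
        return {
            "CAT": make_lexicon(
                "CAT",
                {
                    "http://ex.org/cat#C1": {"labels": ["Catalyst"]},
                    "http://ex.org/cat#C2": {"alt_labels": ["reactor"]},
                },
            ),
            "EMPTY": make_lexicon("EMPTY", {"http://ex.org/e#E1": {}}),
        }

    def test_labelled_ontology_ranked_first(self, corpus):
        results = match_concept_list(["Catalyst"], corpus)
        assert results[0].acronym == "CAT"
        assert results[0].hit_count == 1
        assert results[0].rows[0].rationale_b == "rdfs:label"

    def test_no_hits_gives_zero_counts_in_acronym_order(self, corpus):
        results = match_concept_list(["nonexistent-concept"], corpus)
        assert [(r.acronym, r.hit_count) for r in results] == [
            ("CAT", 0),
            ("EMPTY", 0),
        ]

    def test_duplicate_and_padded_terms_collapse(self, corpus):
        once = match_concept_list(["Catalyst"], corpus)
        thrice = match_concept_list(
            ["Catalyst", " Catalyst ", "Catalyst"], corpus
        )
        assert [(r.acronym, r.hit_count) for r in once] == [
            (r.acronym, r.hit_count) for r in thrice
        ]

    def test_all_blank_terms_is_an_input_error(self, corpus):
        with pytest.raises(ValueError):
            match_concept_list(["", "   "], corpus)
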