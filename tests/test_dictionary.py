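"""MRCONSO parsing, longest-match scanning, and prediction merging."""

import random

import pytest

from conftest import span
from oracles import brute_force_match
from nestner.dictionary import (
    ConceptMap,
    ConceptRow,
    TypedDictionary,
    match_terms,
    merge_predictions,
    parse_mrconso,
)


def rrf_row(cui, term, lang="ENG"):
    cols = [""] * 18
    cols[0], cols[1], cols[14] = cui, lang, term
    return "|".join(cols)


ANATOMY_MAP = ConceptMap(rows=[ConceptRow("ANATOMY", "C1268086", "A1.2")])


class TestConceptMap:
    def test_rejects_bad_cui(self):
        with pytest.raises(ValueError, match="concept identifier"):
            ConceptMap(rows=[ConceptRow("ANATOMY", "X123")])

    def test_rejects_unknown_type(self):
        with pytest.raises(ValueError, match="entity type"):
            ConceptMap(rows=[ConceptRow("GENE", "C123")])

    def test_from_csv_with_header(self):
        cm = ConceptMap.from_csv(
            "entity_type,concept_id,semantic_group\n"
            "ANATOMY,C1268086,A1.2 Anatomical structure\n"
            "CHEM,C0220806,A1.4.1 Chemical\n"
        )
        assert cm.cui_to_type() == {"C1268086": {"ANATOMY"}, "C0220806": {"CHEM"}}


class TestParseMrconso:
    def test_direct_filter(self):
        rrf = "\n".join(
            [
                rrf_row("C1268086", "Body structure"),
                rrf_row("C1268086", "serum"),
                rrf_row("C9999999", "unrelated"),
            ]
        )
        d = parse_mrconso(rrf, ANATOMY_MAP)
        assert {"body structure", "serum"} <= d.get("ANATOMY")
        assert "unrelated" not in d.get("ANATOMY")

    def test_empty_content_warns_for_all_types(self, caplog):
        with caplog.at_level("WARNING"):
            d = parse_mrconso("", ANATOMY_MAP)
        assert all(not d.get(t) for t in d.terms)
        assert caplog.text.count("is empty") == 8

    def test_non_english_rows_excluded(self):
        d = parse_mrconso(rrf_row("C1268086", "struktura tela", lang="RUS"), ANATOMY_MAP)
        assert d.get("ANATOMY") == set()

    def test_descendant_closure(self):
        # parent C1268086 -> child C0000001 -> grandchild C0000002
        rrf = "\n".join(
            [rrf_row("C0000001", "child term"), rrf_row("C0000002", "grandchild term")]
        )
        relations = "C1268086|C0000001\nC0000001|C0000002\n"
        without = parse_mrconso(rrf, ANATOMY_MAP)
        assert without.get("ANATOMY") == set()
        with_rel = parse_mrconso(rrf, ANATOMY_MAP, relations)
        assert with_rel.get("ANATOMY") == {"child term", "grandchild term"}

    def test_malformed_rows_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            d = parse_mrconso(
                "garbage-without-pipes\n" + rrf_row("C1268086", "serum"), ANATOMY_MAP
            )
        assert "serum" in d.get("ANATOMY")
        assert "malformed" in caplog.text

    def test_save_load_round_trip(self, tmp_path):
        d = parse_mrconso(rrf_row("C1268086", "Body Structure"), ANATOMY_MAP)
        d.save(tmp_path)
        back = TypedDictionary.load(tmp_path)
        assert back.get("ANATOMY") == {"body structure"}


def dict_of(**terms_by_type):
    return TypedDictionary(terms={k: set(v) for k, v in terms_by_type.items()})


class TestMatchTerms:
    def test_single_case_folded_match(self):
        spans = match_terms("Serum levels rose.", dict_of(ANATOMY=["serum"]))
        assert [(s.etype, s.start, s.end) for s in spans] == [("ANATOMY", 0, 5)]

    def test_longest_match_wins_within_type(self):
        spans = match_terms(
            "Serum levels rose.", dict_of(ANATOMY=["serum", "serum levels"])
        )
        assert [(s.start, s.end) for s in spans] == [(0, 12)]

    def test_word_boundary_required(self):
        assert match_terms("biserum", dict_of(ANATOMY=["serum"])) == []

    def test_minimum_length_threshold(self):
        assert match_terms("an ox ran", dict_of(ANATOMY=["ox"])) == []

    def test_cross_type_nesting_allowed(self):
        spans = match_terms(
            "serum level decrease", dict_of(ANATOMY=["serum"],
                                            FINDING=["serum level decrease"])
        )
        assert {(s.etype, s.start, s.end) for s in spans} == {
            ("ANATOMY", 0, 5),
            ("FINDING", 0, 20),
        }

    def test_insertion_order_irrelevant(self):
        terms = ["serum", "serum levels", "levels"]
        a = match_terms("Serum levels rose.", dict_of(ANATOMY=terms))
        b = match_terms("Serum levels rose.", dict_of(ANATOMY=list(reversed(terms))))
        assert [s.key() for s in a] == [s.key() for s in b]

    def test_oracle_equivalence_random_fixtures(self):
        rng = random.Random(99)
        words = ["serum", "liver", "flux", "gel", "acid", "ion", "overt", "beta"]
        for _ in range(40):
            text = " ".join(rng.choices(words + ["of", "at"], k=rng.randint(3, 20)))
            terms_by_type = {
                "ANATOMY": {
                    " ".join(rng.choices(words, k=rng.randint(1, 3)))
                    for _ in range(rng.randint(1, 8))
                },
                "CHEM": {rng.choice(words) for _ in range(rng.randint(1, 4))},
            }
            got = {
                s.key()
                for s in match_terms(text, TypedDictionary(terms=terms_by_type))
            }
            assert got == brute_force_match(text, terms_by_type)


class TestMerge:
    def test_plain_union_of_disjoint_sets(self):
        model = [span("DISO", 0, 5), span("CHEM", 10, 14), span("PHYS", 20, 24)]
        dic = [span("ANATOMY", 30, 35), span("DISO", 40, 45)]
        assert len(merge_predictions(model, dic)) == 5

    def test_identical_span_deduplicated(self):
        s = span("DISO", 0, 5)
        assert len(merge_predictions([s], [s])) == 1

    def test_model_precedence_same_type_overlap(self):
        model = [span("DISO", 10, 25)]
        dic = [span("DISO", 10, 20), span("CHEM", 12, 18)]
        merged = merge_predictions(model, dic)
        assert {(s.etype, s.start, s.end) for s in merged} == {
            ("DISO", 10, 25),
            ("CHEM", 12, 18),
        }

    def test_every_model_span_survives(self):
        rng = random.Random(5)
        for _ in range(30):
            model = [
                span(rng.choice(["DISO", "CHEM"]), s, s + rng.randint(1, 6))
                for s in rng.sample(range(100), rng.randint(0, 10))
            ]
            dic = [
                span(rng.choice(["DISO", "CHEM"]), s, s + rng.randint(1, 6))
                for s in rng.sample(range(100), rng.randint(0, 10))
            ]
            merged_keys = {s.key() for s in merge_predictions(model, dic)}
            assert {s.key() for s in model} <= merged_keys
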