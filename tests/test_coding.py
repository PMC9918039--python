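"""Coding rules (specific/compound/idiosyncratic) and frequency summaries."""

import random

import pytest

from symptom_overlap import (ItemRecord, InstrumentInfo,
                             classification_coverage, derive_matrix_from_items,
                             idiosyncratic_symptoms, instrument_summary,
                             n_symptoms_in_half, symptom_frequencies,
                             category_frequencies)
from symptom_overlap.errors import (CategoryError, DuplicateItemError,
                                    FlagError, InstrumentLookupError)

from conftest import make_matrix

CATS = {"Fatigue": "general", "Daytime sleepiness": "sleepiness",
        "Snoring": "respiratory", "A": "general", "B": "general"}


def item(inst, iid, *symptoms, na_reason=None):
    return ItemRecord(instrument=inst, item_id=iid,
                      mapped_symptoms=tuple(symptoms),
                      not_applicable=na_reason is not None,
                      reason=na_reason or "none")


class TestDeriveMatrix:
    def test_multi_symptom_item_codes_both_compound(self):
        # An item probing tiredness/fatigue and daytime sleepiness at once
        # renders both symptoms compound for that questionnaire.
        m = derive_matrix_from_items(
            [item("Q", "6", "Fatigue", "Daytime sleepiness")], CATS)
        assert m.codes.at["Fatigue", "Q"] == 2
        assert m.codes.at["Daytime sleepiness", "Q"] == 2

    def test_single_symptom_item_codes_specific(self):
        m = derive_matrix_from_items([item("Q", "10", "Snoring")], CATS)
        assert m.codes.at["Snoring", "Q"] == 1

    def test_specificity_takes_precedence_over_compound(self):
        # A appears both alone and inside a compound item -> specific;
        # B appears only in the compound item -> compound.
        m = derive_matrix_from_items(
            [item("Q", "1", "A", "B"), item("Q", "2", "A")], CATS)
        assert m.codes.at["A", "Q"] == 1
        assert m.codes.at["B", "Q"] == 2

    def test_not_applicable_items_excluded(self):
        m = derive_matrix_from_items(
            [item("Q", "1", "Snoring"), item("Q", "2", na_reason="lifestyle")],
            CATS)
        assert m.n_symptoms == 1

    def test_item_order_does_not_matter(self):
        items = [item("Q1", "1", "A", "B"), item("Q1", "2", "A"),
                 item("Q2", "1", "B"), item("Q2", "2", "Snoring", "Fatigue")]
        m1 = derive_matrix_from_items(items, CATS)
        rng = random.Random(7)
        for _ in range(10):
            shuffled = items[:]
            rng.shuffle(shuffled)
            m2 = derive_matrix_from_items(shuffled, CATS)
            assert m2.codes.sort_index().sort_index(axis=1).equals(
                m1.codes.sort_index().sort_index(axis=1))

    def test_uncategorized_symptom_rejected(self):
        with pytest.raises(CategoryError, match="Mystery"):
            derive_matrix_from_items([item("Q", "1", "Mystery")], CATS)

    def test_duplicate_item_id_rejected(self):
        with pytest.raises(DuplicateItemError, match="'1'"):
            derive_matrix_from_items(
                [item("Q", "1", "A"), item("Q", "1", "B")], CATS)

    def test_reference_columns_appended_and_flagged(self):
        ref = make_matrix([[1], [1]], symptoms=["A", "RefOnly"],
                          instruments=["ICSD"], reference=["ICSD"],
                          categories=["general", "general"])
        m = derive_matrix_from_items([item("Q", "1", "A")], CATS,
                                     reference_matrix=ref)
        assert m.references == ["ICSD"]
        assert m.codes.at["RefOnly", "ICSD"] == 1
        assert m.codes.at["RefOnly", "Q"] == 0


class TestItemRecordInvariants:
    def test_na_requires_empty_mapping(self):
        with pytest.raises(ValueError):
            ItemRecord("Q", "1", mapped_symptoms=("A",), not_applicable=True,
                       reason="lifestyle")

    def test_reason_requires_na(self):
        with pytest.raises(ValueError):
            ItemRecord("Q", "1", mapped_symptoms=("A",), reason="history")


class TestFrequencies:
    def test_counts_nonzero_codes_across_questionnaires(self):
        m = make_matrix([[1, 2, 0]])
        assert symptom_frequencies(m)["count"].tolist() == [2]

    def test_all_zero_matrix_counts_zero(self):
        m = make_matrix([[0, 0], [0, 0]])
        assert symptom_frequencies(m)["count"].tolist() == [0, 0]

    def test_reference_columns_ignored(self, tiny_matrix):
        freq = symptom_frequencies(tiny_matrix).set_index("symptom")["count"]
        # REF column codes never counted
        assert freq["initiating insomnia"] == 2
        assert freq["maintaining insomnia"] == 2
        assert freq["leg movement"] == 1

    def test_sorted_descending_with_alphabetical_ties(self):
        m = make_matrix([[1, 1], [0, 1], [1, 1]],
                        symptoms=["b", "c", "a"])
        assert symptom_frequencies(m)["symptom"].tolist() == ["a", "b", "c"]

    def test_total_equals_nonzero_cells(self, study_matrix):
        freq = symptom_frequencies(study_matrix)
        nonzero = int((study_matrix.codes[study_matrix.questionnaires] > 0)
                      .to_numpy().sum())
        assert int(freq["count"].sum()) == nonzero

    def test_category_view_is_category_major(self, tiny_matrix):
        df = category_frequencies(tiny_matrix)
        assert df["category"].tolist() == ["insomnia", "insomnia", "motor"]


class TestIdiosyncratic:
    def test_single_questionnaire_symptom_detected(self):
        m = make_matrix([[1, 0, 0], [1, 1, 0]])
        assert idiosyncratic_symptoms(m) == ["s0"]

    def test_two_questionnaire_symptom_excluded(self):
        m = make_matrix([[1, 2, 0]])
        assert idiosyncratic_symptoms(m) == []

    def test_reference_presence_does_not_disqualify(self):
        # present in one questionnaire and one reference list -> idiosyncratic
        m = make_matrix([[1, 0, 1]], instruments=["A", "B", "REF"],
                        reference=["REF"])
        assert idiosyncratic_symptoms(m) == ["s0"]


@pytest.mark.parametrize("at_least,expected", [(True, 2), (False, 1)])
def test_half_count_switch(at_least, expected):
    # 4 questionnaires: counts 4, 2, 1 -> >=2: two symptoms; ==2: one.
    m = make_matrix([[1, 1, 1, 1], [1, 1, 0, 0], [1, 0, 0, 0]])
    assert n_symptoms_in_half(m, at_least=at_least) == expected


class TestInstrumentSummary:
    def test_counts_specific_and_compound(self):
        m = make_matrix([[1], [1], [2]], instruments=["Q"])
        (s,) = instrument_summary(m, [InstrumentInfo("Q", 10)])
        assert (s.n_specific, s.n_compound, s.n_total) == (2, 1, 3)

    def test_all_zero_instrument(self):
        m = make_matrix([[0, 1]], instruments=["Q", "R"])
        s = instrument_summary(m, [InstrumentInfo("Q", 5),
                                   InstrumentInfo("R", 5)])[0]
        assert (s.n_specific, s.n_compound, s.n_total) == (0, 0, 0)

    def test_conservation_specific_plus_compound(self, study_matrix):
        meta = [InstrumentInfo(q, 1) for q in study_matrix.questionnaires]
        for s in instrument_summary(study_matrix, meta):
            nonzero = int((study_matrix.codes[s.instrument] > 0).sum())
            assert s.n_total == nonzero

    def test_missing_metadata_rejected(self):
        m = make_matrix([[1, 1]])
        with pytest.raises(InstrumentLookupError, match="I1"):
            instrument_summary(m, [InstrumentInfo("I0", 3)])


class TestCoverage:
    def test_reference_equal_to_questionnaire_fully_covered(self):
        m = make_matrix([[1, 1], [1, 1], [0, 0]],
                        instruments=["Q", "REF"], reference=["REF"])
        rep = classification_coverage(m, "REF")
        assert rep.n_found == rep.n_reference_symptoms == 2
        assert rep.found_fraction == 1.0
        assert rep.missing_from_questionnaires == ()

    def test_counts_are_conserved_and_extras_reported(self):
        # REF lists s0,s1; questionnaires probe s0,s2 -> found 1, missing s1,
        # extra s2 (absent from every reference column).
        m = make_matrix([[1, 0, 1], [0, 0, 1], [1, 1, 0]],
                        instruments=["Q1", "Q2", "REF"], reference=["REF"])
        rep = classification_coverage(m, "REF")
        assert rep.n_reference_symptoms == 2
        assert rep.n_found == 1
        assert rep.missing_from_questionnaires == ("s1",)
        assert rep.extra_beyond_reference == ("s2",)
        assert rep.n_found + len(rep.missing_from_questionnaires) == \
            rep.n_reference_symptoms

    def test_union_of_two_references(self):
        m = make_matrix([[1, 1, 0], [1, 0, 1], [1, 0, 0]],
                        instruments=["Q", "R1", "R2"],
                        reference=["R1", "R2"])
        rep = classification_coverage(m, ["R1", "R2"])
        assert rep.n_reference_symptoms == 2       # union of s0, s1
        assert rep.n_found == 2

    def test_unflagged_reference_rejected(self, tiny_matrix):
        with pytest.raises(FlagError, match="'A'"):
            classification_coverage(tiny_matrix, "A")
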