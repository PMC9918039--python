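"""Jaccard pairwise overlap: oracle equivalence, invariants, strength bands."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from symptom_overlap import (category_means, category_overlap,
                             interpret_strength, jaccard_pair,
                             pairwise_matrix)
from symptom_overlap.errors import (InstrumentLookupError,
                                    InsufficientInstrumentsError,
                                    SymptomOverlapError)

from conftest import coding_matrices, make_matrix


def naive_jaccard(m, a, b):
    """Independent oracle: explicit symptom sets, intersection over union."""
    sa, sb = m.symptom_set(a), m.symptom_set(b)
    union = sa | sb
    if not union:
        return None
    return len(sa & sb) / len(union)


class TestJaccardPair:
    def test_identical_presence_gives_one(self):
        m = make_matrix([[1, 2], [2, 1], [1, 1]])
        assert jaccard_pair(m, "I0", "I1").index == 1.0

    def test_disjoint_presence_gives_zero(self):
        m = make_matrix([[1, 0], [0, 2]])
        assert jaccard_pair(m, "I0", "I1").index == 0.0

    def test_worked_counts_example(self):
        # a probes {A,B,D}, b probes {A,C,D}: s=2, u1=1, u2=1 -> 0.5
        m = make_matrix([[1, 1], [1, 0], [0, 1], [1, 1]],
                        symptoms=list("ABCD"), instruments=["a", "b"])
        p = jaccard_pair(m, "a", "b")
        assert (p.s, p.u1, p.u2) == (2, 1, 1)
        assert p.index == 0.5

    def test_empty_union_is_undefined(self):
        m = make_matrix([[0, 0], [1, 1]])
        p = jaccard_pair(m, "I0", "I1")
        # restricted to nothing shared the pair is fine; force empty vectors
        m2 = make_matrix([[0, 0]])
        q = jaccard_pair(m2, "I0", "I1")
        assert not q.defined and math.isnan(q.index)
        assert p.defined

    def test_unknown_instrument_rejected(self, tiny_matrix):
        with pytest.raises(InstrumentLookupError):
            jaccard_pair(tiny_matrix, "A", "nope")

    @given(m=coding_matrices())
    def test_matches_set_oracle_and_symmetry(self, m):
        for a, b in itertools.combinations(m.instruments, 2):
            p = jaccard_pair(m, a, b)
            q = jaccard_pair(m, b, a)
            assert (p.s, p.u1, p.u2) == (q.s, q.u2, q.u1)
            expected = naive_jaccard(m, a, b)
            if expected is None:
                assert not p.defined
            else:
                assert p.index == expected
                assert 0.0 <= p.index <= 1.0


class TestMonotonicity:
    def test_adding_shared_symptom_never_decreases(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            codes = rng.integers(0, 3, size=(rng.integers(1, 10), 2))
            m = make_matrix(codes)
            before = jaccard_pair(m, "I0", "I1")
            grown = make_matrix(np.vstack([codes, [1, 1]]))
            after = jaccard_pair(grown, "I0", "I1")
            if before.defined:
                assert after.index >= before.index
            assert after.defined

    def test_adding_unique_symptom_never_increases(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            codes = rng.integers(0, 3, size=(rng.integers(1, 10), 2))
            m = make_matrix(codes)
            before = jaccard_pair(m, "I0", "I1")
            grown = make_matrix(np.vstack([codes, [1, 0]]))
            after = jaccard_pair(grown, "I0", "I1")
            if before.defined:
                assert after.index <= before.index


@given(m=coding_matrices())
def test_permutation_invariance(m):
    om = pairwise_matrix(m)
    rng = np.random.default_rng(0)
    sym_perm = rng.permutation(m.n_symptoms)
    inst_perm = rng.permutation(m.instruments)
    shuffled = make_matrix(m.codes.iloc[sym_perm][inst_perm].to_numpy(),
                           symptoms=[m.symptoms[i] for i in sym_perm],
                           instruments=list(inst_perm),
                           categories=m.categories.iloc[sym_perm].tolist())
    om2 = pairwise_matrix(shuffled)
    for a, b in itertools.combinations(m.instruments, 2):
        va, vb = om.values.at[a, b], om2.values.at[a, b]
        assert (math.isnan(va) and math.isnan(vb)) or va == vb


class TestPairwiseMatrix:
    def test_two_instruments_means_collapse(self):
        m = make_matrix([[1, 1], [1, 0]])
        om = pairwise_matrix(m)
        j = om.values.at["I0", "I1"]
        assert om.per_instrument_mean.tolist() == [j, j]
        assert om.grand_mean == j

    def test_diagonal_is_unit_for_nonempty_instruments(self, study_matrix):
        om = pairwise_matrix(study_matrix)
        for i in om.instruments:
            assert om.values.at[i, i] == 1.0

    def test_reference_columns_excluded_from_means(self, tiny_matrix):
        om = pairwise_matrix(tiny_matrix)
        manual = np.mean([om.values.at["A", "B"], om.values.at["A", "C"],
                          om.values.at["B", "C"]])
        assert om.grand_mean == pytest.approx(manual)
        # per-instrument means average questionnaire peers only
        assert om.per_instrument_mean["A"] == pytest.approx(
            np.mean([om.values.at["A", "B"], om.values.at["A", "C"]]))
        # the reference still gets a mean against questionnaires
        assert not math.isnan(om.per_instrument_mean["REF"])

    def test_include_reference_false_drops_columns(self, tiny_matrix):
        om = pairwise_matrix(tiny_matrix, include_reference=False)
        assert om.instruments == ["A", "B", "C"]

    def test_aggregation_identity_when_all_defined(self, study_matrix):
        om = pairwise_matrix(study_matrix)
        assert not om.undefined_pairs
        assert om.grand_mean == pytest.approx(om.mean_of_instrument_means)

    def test_fewer_than_two_questionnaires_rejected(self):
        m = make_matrix([[1, 1]], instruments=["Q", "REF"], reference=["REF"])
        with pytest.raises(InsufficientInstrumentsError):
            pairwise_matrix(m)


class TestCategoryOverlap:
    def test_identical_restricted_vectors_mean_one(self):
        m = make_matrix([[1, 1], [2, 2], [1, 0]],
                        categories=["insomnia", "insomnia", "motor"])
        om = category_overlap(m, "insomnia")
        assert om.grand_mean == 1.0

    def test_one_empty_restriction_uses_unique_counts(self):
        # Third instrument probes nothing in the category: its pairs have
        # s=0 against any nonempty peer -> index 0, not undefined.
        m = make_matrix([[1, 1, 0], [0, 1, 0], [1, 1, 1]],
                        categories=["c", "c", "other"])
        om = category_overlap(m, "c")
        assert om.values.at["I0", "I2"] == 0.0
        assert om.values.at["I1", "I2"] == 0.0
        assert om.values.at["I0", "I1"] == 0.5
        assert not om.undefined_pairs

    def test_both_empty_restriction_is_undefined_and_excluded(self):
        # only I0 probes the category: the I1-I2 pair has an empty union
        m = make_matrix([[1, 0, 0], [0, 1, 1]], categories=["c", "other"])
        om = category_overlap(m, "c")
        assert om.undefined_pairs == [("I1", "I2")]
        # mean over remaining defined pairs only (both are 0 against I0)
        assert om.grand_mean == pytest.approx(0.0)

    def test_unknown_category_rejected(self, tiny_matrix):
        with pytest.raises(SymptomOverlapError, match="nope"):
            category_overlap(tiny_matrix, "nope")

    def test_category_means_one_row_per_category(self, tiny_matrix):
        df = category_means(tiny_matrix)
        assert df["category"].tolist() == ["insomnia", "motor"]


class TestStrengthBands:
    @pytest.mark.parametrize("value,label", [
        (0.0, "very weak"), (0.19, "very weak"),
        (0.20, "weak"), (0.39, "weak"),
        (0.40, "moderate"), (0.44, "moderate"), (0.59, "moderate"),
        (0.60, "strong"), (0.79, "strong"),
        (0.80, "very strong"), (1.0, "very strong"),
    ])
    def test_banding(self, value, label):
        assert interpret_strength(value) == label

    @pytest.mark.parametrize("bad", [-0.01, 1.01, math.nan])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(SymptomOverlapError):
            interpret_strength(bad)
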