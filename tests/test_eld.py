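import numpy as np
import pandas as pd
import pytest

from alloexpr.de import DETable
from alloexpr.eld import (
    A_EQ_C,
    A_GT_C,
    A_LT_C,
    AMBIGUOUS,
    CATEGORY_OF_TRIPLE,
    CONSERVED,
    PATTERN_OF_ROMAN,
    ROMANS,
    T_EQ_A,
    T_EQ_C,
    T_GT_A,
    T_GT_C,
    T_LT_A,
    T_LT_C,
    all_triples,
    classify_individual,
    classify_triple,
    pair_level_matrix,
    pattern_summary,
)
from alloexpr.io import ConfigError
from conftest import make_counts, make_pairs, make_sheet


def test_classification_is_total_and_partitions_triples():
    seen = [classify_triple(*t) for t in all_triples()]
    assert len(seen) == 27
    # all 12 romans plus CONSERVED appear exactly once; the rest are ambiguous
    for roman in ROMANS:
        assert seen.count(roman) == 1
    assert seen.count(CONSERVED) == 1
    assert seen.count(AMBIGUOUS) == 14


def test_group_membership_constraints_hold_for_every_triple():
    # ELD-A: total equal to A, different from C, parents different; etc.
    for triple in all_triples():
        d_ac, d_ta, d_tc = triple
        pattern = PATTERN_OF_ROMAN[classify_triple(*triple)]
        if pattern == "ELD_A":
            assert d_ta == T_EQ_A and d_tc != T_EQ_C and d_ac != A_EQ_C
        elif pattern == "ELD_C":
            assert d_tc == T_EQ_C and d_ta != T_EQ_A and d_ac != A_EQ_C
        elif pattern == "TRANS_UP":
            assert d_ta == T_GT_A and d_tc == T_GT_C
        elif pattern == "TRANS_DOWN":
            assert d_ta == T_LT_A and d_tc == T_LT_C
        elif pattern == "ADDITIVE":
            assert (d_ac, d_ta, d_tc) in {
                (A_LT_C, T_GT_A, T_LT_C),
                (A_GT_C, T_LT_A, T_GT_C),
            }
        elif pattern == CONSERVED:
            assert triple == (A_EQ_C, T_EQ_A, T_EQ_C)


@pytest.mark.parametrize(
    "triple, roman",
    [
        ((A_LT_C, T_EQ_A, T_LT_C), "IV"),    # dominance toward the A parent
        ((A_EQ_C, T_EQ_A, T_EQ_C), CONSERVED),
        ((A_EQ_C, T_GT_A, T_GT_C), "V"),     # transgressive up
        ((A_LT_C, T_GT_A, T_EQ_C), "II"),    # dominance toward the C parent
        ((A_LT_C, T_EQ_A, T_EQ_C), AMBIGUOUS),  # total equal to both, parents differ
    ],
)
def test_canonical_category_examples(triple, roman):
    assert classify_triple(*triple) == roman


def test_pair_level_matrix_projection_and_sum():
    sheet = make_sheet(n_individuals=1)
    n = 2
    # columns: PA x3, PC x3, AACC1 x3
    counts = np.array(
        [
            [5, 5, 5, 9, 9, 9, 5, 6, 7],     # gA0
            [1, 1, 1, 8, 8, 8, 2, 2, 2],     # gA1
            [3, 3, 3, 7, 7, 7, 7, 7, 7],     # gC0
            [2, 2, 2, 6, 6, 6, 10, 10, 10],  # gC1
        ]
    )
    cm = make_counts(counts, sheet, n)
    pm = pair_level_matrix(cm, make_pairs(n), sheet)
    assert pm.gene_ids == ["p0", "p1"]
    # parent A sample takes the A copy, parent C the C copy, polyploid the sum
    assert pm.counts[0].tolist() == [5, 5, 5, 7, 7, 7, 12, 13, 14]
    assert pm.counts[1].tolist() == [1, 1, 1, 6, 6, 6, 12, 12, 12]


def test_pair_level_matrix_missing_gene_is_an_error():
    sheet = make_sheet(n_individuals=1)
    cm = make_counts(np.ones((2, 9), dtype=int), sheet, 1)
    with pytest.raises(ConfigError):
        pair_level_matrix(cm, make_pairs(2), sheet)


def de_stub(calls: dict[str, str]) -> DETable:
    ids = list(calls)
    return DETable(
        pd.DataFrame(
            {
                "unit_id": ids,
                "mean_A": 1.0,
                "mean_B": 1.0,
                "log2fc": 0.0,
                "pvalue": 1.0,
                "qvalue": 1.0,
                "call": [calls[i] for i in ids],
            }
        )
    )


def test_classify_individual_assembles_triples():
    # pair p0: all NS -> conserved; p1: A<C, T>A, T=C -> II (ELD toward C)
    de_ac = de_stub({"p0": "NS", "p1": "UP_B"})
    de_ta = de_stub({"p0": "NS", "p1": "UP_B"})
    de_tc = de_stub({"p0": "NS", "p1": "NS"})
    out = classify_individual(de_ta, de_tc, de_ac, "AACC1").set_index("pair_id")
    assert out.loc["p0", "roman"] == CONSERVED
    assert out.loc["p1", "roman"] == "II"
    assert out.loc["p1", "pattern"] == "ELD_C"


def test_classify_individual_requires_matching_ids():
    with pytest.raises(ConfigError):
        classify_individual(
            de_stub({"p0": "NS"}), de_stub({"p1": "NS"}), de_stub({"p0": "NS"}), "x"
        )


def test_pattern_summary_counts_and_denominator():
    assign = pd.DataFrame(
        {
            "pair_id": [f"p{i}" for i in range(5)],
            "roman": ["I", "XII", "IV", CONSERVED, AMBIGUOUS],
            "pattern": ["ADDITIVE", "ADDITIVE", "ELD_A", CONSERVED, AMBIGUOUS],
        }
    )
    summary = pattern_summary(assign, denominator=100)
    patterns = summary[summary["level"] == "pattern"].set_index("label")
    assert patterns.loc["ADDITIVE", "count"] == 2
    assert patterns.loc["ADDITIVE", "fraction"] == pytest.approx(0.02)
    cats = summary[summary["level"] == "category"]
    assert cats["count"].sum() == 5  # partition: every pair counted once
    empty = pattern_summary(assign.iloc[:0], denominator=100)
    assert (empty["count"] == 0).all()


def test_planted_eld_recovery_on_small_cohort(small_sim):
    from alloexpr.eld import classify_eld

    sim = small_sim
    truth = sim.truth.set_index("pair_id")
    out = classify_eld(sim.counts, sim.pairs, sim.sheet, "AACC1").set_index("pair_id")
    planted = truth.index[truth["planted_class"] == "ELD_A"]
    recall = (out.loc[planted, "pattern"] == "ELD_A").mean()
    assert recall >= 0.9
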