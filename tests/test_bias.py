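import itertools

import numpy as np
import pandas as pd
import pytest

from alloexpr.bias import (
    A_BIAS,
    BIAS_LOST,
    BIAS_REVERSED,
    BIAS_STATES,
    C_BIAS,
    NO_BIAS,
    NOVEL_BIAS_A,
    NOVEL_BIAS_C,
    PARENTAL_CONDITION,
    TRANSITIONS,
    bias_summary,
    classify_transition,
    hybrid_bias,
    parental_bias,
    transition_table,
)
from alloexpr.io import CountMatrix, HomoeologPairTable
from conftest import make_counts, make_pairs, make_sheet


def test_transition_mapping_is_total_on_all_nine_combinations():
    outcomes = {
        (p, h): classify_transition(p, h)
        for p, h in itertools.product(BIAS_STATES, repeat=2)
    }
    assert len(outcomes) == 9
    assert set(outcomes.values()) == set(TRANSITIONS)
    assert outcomes[(A_BIAS, A_BIAS)] == PARENTAL_CONDITION
    assert outcomes[(NO_BIAS, NO_BIAS)] == PARENTAL_CONDITION
    assert outcomes[(C_BIAS, NO_BIAS)] == BIAS_LOST
    assert outcomes[(NO_BIAS, A_BIAS)] == NOVEL_BIAS_A
    assert outcomes[(NO_BIAS, C_BIAS)] == NOVEL_BIAS_C
    assert outcomes[(A_BIAS, C_BIAS)] == BIAS_REVERSED


def test_summary_on_full_enumeration():
    combos = list(itertools.product(BIAS_STATES, repeat=2))
    parent = pd.Series([p for p, _ in combos], index=[f"p{i}" for i in range(9)])
    hybrid = pd.Series([h for _, h in combos], index=[f"p{i}" for i in range(9)])
    trans = transition_table(parent, hybrid)
    summary = bias_summary(trans).set_index("label")
    assert summary.loc[PARENTAL_CONDITION, "count"] == 3
    assert summary.loc[BIAS_LOST, "count"] == 2
    assert summary.loc[NOVEL_BIAS_A, "count"] == 1
    assert summary.loc[NOVEL_BIAS_C, "count"] == 1
    assert summary.loc[BIAS_REVERSED, "count"] == 2
    trans_rows = summary[summary["level"] == "transition"]
    assert trans_rows["fraction"].sum() == pytest.approx(1.0)
    collapsed = bias_summary(trans, collapse_novel=True).set_index("label")
    assert collapsed.loc["NOVEL_BIAS", "count"] == 2


def test_all_no_bias_is_pure_parental_condition():
    idx = [f"p{i}" for i in range(4)]
    states = pd.Series([NO_BIAS] * 4, index=idx)
    trans = transition_table(states, states)
    assert (trans["transition"] == PARENTAL_CONDITION).all()


def test_symmetric_counts_give_no_bias_and_strong_split_is_called():
    sheet = make_sheet(n_individuals=1)
    n = 40
    rng = np.random.default_rng(1)
    counts = rng.poisson(200, size=(2 * n, 9))
    counts[n:, 6:9] = counts[:n, 6:9]  # polyploid C copy == A copy
    cm = make_counts(counts, sheet, n)
    pairs = make_pairs(n)
    _, states = hybrid_bias(cm, pairs, sheet, "AACC1", size_factors=np.ones(9))
    assert (states == NO_BIAS).all()


def test_single_pair_strong_c_bias_example():
    # A copy (0,0,0) vs C copy (100,120,90) within the polyploid
    sheet = make_sheet(n_individuals=1)
    counts = np.zeros((2, 9), dtype=int)
    counts[0, 6:9] = [0, 0, 0]
    counts[1, 6:9] = [100, 120, 90]
    counts[0, 0:3] = 50  # keep parents expressed so size factors exist
    counts[1, 3:6] = 50
    cm = make_counts(counts, sheet, 1)
    _, states = hybrid_bias(cm, make_pairs(1), sheet, "AACC1", size_factors=np.ones(9))
    assert states.iloc[0] == C_BIAS


def test_alpha_zero_means_all_no_bias(small_sim):
    _, states = parental_bias(
        small_sim.counts, small_sim.pairs, small_sim.sheet, alpha=1e-300
    )
    assert (states == NO_BIAS).all()


def _swap_subgenomes(cm: CountMatrix, pairs: HomoeologPairTable, sheet):
    """Relabel every A gene as C and vice versa, swapping parents too."""
    n = len(pairs)
    swapped_counts = cm.counts.copy()
    cols_pa = cm.sample_cols(sheet.samples_of("PARENT_A"))
    cols_pc = cm.sample_cols(sheet.samples_of("PARENT_C"))
    # move parental expression onto the other parent's columns
    swapped_counts[:, cols_pa], swapped_counts[:, cols_pc] = (
        cm.counts[:, cols_pc], cm.counts[:, cols_pa],
    )
    # swap the rows of the two copies
    swapped_counts = np.vstack([swapped_counts[n:], swapped_counts[:n]])
    cm2 = CountMatrix(
        gene_ids=cm.gene_ids, subgenome=cm.subgenome,
        sample_ids=cm.sample_ids, counts=swapped_counts,
    )
    return cm2


def test_relabeling_symmetry(small_sim):
    """Swapping the subgenome labels swaps A/C bias states everywhere."""
    sim = small_sim
    _, parent1 = parental_bias(sim.counts, sim.pairs, sim.sheet)
    _, hybrid1 = hybrid_bias(sim.counts, sim.pairs, sim.sheet, "AACC1")
    cm2 = _swap_subgenomes(sim.counts, sim.pairs, sim.sheet)
    _, parent2 = parental_bias(cm2, sim.pairs, sim.sheet)
    _, hybrid2 = hybrid_bias(cm2, sim.pairs, sim.sheet, "AACC1")
    swap = {A_BIAS: C_BIAS, C_BIAS: A_BIAS, NO_BIAS: NO_BIAS}
    assert (parent2 == parent1.map(swap)).all()
    assert (hybrid2 == hybrid1.map(swap)).all()
    t1 = transition_table(parent1, hybrid1)["transition"].value_counts()
    t2 = transition_table(parent2, hybrid2)["transition"].value_counts()
    for unchanged in (PARENTAL_CONDITION, BIAS_LOST, BIAS_REVERSED):
        assert t1.get(unchanged, 0) == t2.get(unchanged, 0)
    assert t1.get(NOVEL_BIAS_A, 0) == t2.get(NOVEL_BIAS_C, 0)
    assert t1.get(NOVEL_BIAS_C, 0) == t2.get(NOVEL_BIAS_A, 0)


def test_planted_bias_recovery(small_sim):
    truth = small_sim.truth.set_index("pair_id")
    _, parent_states = parental_bias(small_sim.counts, small_sim.pairs, small_sim.sheet)
    planted_a = truth.index[truth["parent_bias"] == A_BIAS]
    assert (parent_states.loc[planted_a] == A_BIAS).mean() >= 0.9
    _, hybrid_states = hybrid_bias(small_sim.counts, small_sim.pairs, small_sim.sheet, "AACC1")
    planted_c = truth.index[truth["hybrid_bias"] == C_BIAS]
    assert (hybrid_states.loc[planted_c] == C_BIAS).mean() >= 0.9
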