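"""Homoeolog expression bias and its transitions from parents to polyploid.

Bias is a per-pair ternary state: A_BIAS (A-copy significantly higher),
C_BIAS, or NO_BIAS. In the parents the A-copy lives in parent A and the
C-copy in parent C, so the parental state comes from comparing parent-A
replicates of the A gene with parent-C replicates of the C gene. In a
polyploid both copies are measured in the same replicate, so the two groups
share each replicate's size factor and the comparison is within-sample.

Crossing the parental and hybrid states yields five transition patterns:
the parental condition is retained, a pre-existing bias is lost, a novel
bias appears (toward A or toward C), or the bias direction is reversed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .de import DETable, de_table, size_factors_median_of_ratios
from .io import ConfigError, CountMatrix, HomoeologPairTable, SampleSheet, PARENT_A, PARENT_C, POLYPLOID

A_BIAS = "A_BIAS"
C_BIAS = "C_BIAS"
NO_BIAS = "NO_BIAS"
BIAS_STATES = (A_BIAS, NO_BIAS, C_BIAS)

PARENTAL_CONDITION = "PARENTAL_CONDITION"
BIAS_LOST = "BIAS_LOST"
NOVEL_BIAS_A = "NOVEL_BIAS_A"
NOVEL_BIAS_C = "NOVEL_BIAS_C"
BIAS_REVERSED = "BIAS_REVERSED"
TRANSITIONS = (PARENTAL_CONDITION, BIAS_LOST, NOVEL_BIAS_A, NOVEL_BIAS_C, BIAS_REVERSED)


def _pair_gene_rows(counts: CountMatrix, pairs: HomoeologPairTable) -> tuple[np.ndarray, np.ndarray]:
    df = pairs.frame
    try:
        rows_a = np.array([counts.gene_row(g) for g in df["gene_A"]], dtype=np.intp)
        rows_c = np.array([counts.gene_row(g) for g in df["gene_C"]], dtype=np.intp)
    except KeyError as exc:
        raise ConfigError(f"pair references a gene missing from counts: {exc}") from None
    return rows_a, rows_c


def _states_from_table(table: DETable, alpha: float) -> pd.Series:
    """Group1 = A copy, group2 = C copy: UP_B means the C copy is higher."""
    frame = table.frame
    sig = frame["qvalue"] < alpha
    state = np.where(
        sig & (frame["log2fc"] > 0), C_BIAS, np.where(sig & (frame["log2fc"] < 0), A_BIAS, NO_BIAS)
    )
    return pd.Series(state, index=frame["unit_id"], name="state")


def parental_bias(
    counts: CountMatrix,
    pairs: HomoeologPairTable,
    sheet: SampleSheet,
    alpha: float = 0.05,
    size_factors: np.ndarray | None = None,
) -> tuple[DETable, pd.Series]:
    """Per-pair bias state in the parental generation (A copy vs C copy)."""
    rows_a, rows_c = _pair_gene_rows(counts, pairs)
    cols_pa = counts.sample_cols(sheet.samples_of(PARENT_A))
    cols_pc = counts.sample_cols(sheet.samples_of(PARENT_C))
    if size_factors is None:
        from .eld import pair_level_matrix

        size_factors = size_factors_median_of_ratios(pair_level_matrix(counts, pairs, sheet))
    table = de_table(
        pairs.pair_ids,
        counts.counts[np.ix_(rows_a, cols_pa)],
        counts.counts[np.ix_(rows_c, cols_pc)],
        size_factors[cols_pa],
        size_factors[cols_pc],
        alpha=alpha,
    )
    return table, _states_from_table(table, alpha)


def hybrid_bias(
    counts: CountMatrix,
    pairs: HomoeologPairTable,
    sheet: SampleSheet,
    individual: str,
    alpha: float = 0.05,
    size_factors: np.ndarray | None = None,
) -> tuple[DETable, pd.Series]:
    """Per-pair bias state within one polyploid individual.

    The A-copy and C-copy counts of each replicate form the two groups and
    share that replicate's size factor, so library depth cancels and the
    comparison is a within-sample homoeolog ratio test.
    """
    rows_a, rows_c = _pair_gene_rows(counts, pairs)
    cols_t = counts.sample_cols(sheet.samples_of(POLYPLOID, individual))
    if size_factors is None:
        from .eld import pair_level_matrix

        size_factors = size_factors_median_of_ratios(pair_level_matrix(counts, pairs, sheet))
    sf = size_factors[cols_t]
    table = de_table(
        pairs.pair_ids,
        counts.counts[np.ix_(rows_a, cols_t)],
        counts.counts[np.ix_(rows_c, cols_t)],
        sf,
        sf,
        alpha=alpha,
    )
    return table, _states_from_table(table, alpha)


def classify_transition(parent: str, hybrid: str) -> str:
    """Total mapping of (parental state, hybrid state) to a transition pattern."""
    if parent == hybrid:
        return PARENTAL_CONDITION
    if hybrid == NO_BIAS:
        return BIAS_LOST
    if parent == NO_BIAS:
        return NOVEL_BIAS_A if hybrid == A_BIAS else NOVEL_BIAS_C
    return BIAS_REVERSED


def transition_table(parent_states: pd.Series, hybrid_states: pd.Series) -> pd.DataFrame:
    if not parent_states.index.equals(hybrid_states.index):
        raise ConfigError("parental and hybrid bias states cover different pairs")
    trans = [classify_transition(p, h) for p, h in zip(parent_states, hybrid_states)]
    return pd.DataFrame(
        {
            "pair_id": parent_states.index,
            "parent_state": parent_states.to_numpy(),
            "hybrid_state": hybrid_states.to_numpy(),
            "transition": trans,
        }
    )


def bias_summary(
    transitions: pd.DataFrame, collapse_novel: bool = False
) -> pd.DataFrame:
    """Per-pattern counts/fractions plus hybrid A/C bias totals.

    ``collapse_novel`` merges NOVEL_BIAS_A and NOVEL_BIAS_C into one
    NOVEL_BIAS pattern for reporting.
    """
    n = len(transitions)
    counts = transitions["transition"].value_counts()
    rows = []
    if collapse_novel:
        labels = [PARENTAL_CONDITION, BIAS_LOST, "NOVEL_BIAS", BIAS_REVERSED]
        merged = counts.copy()
        merged["NOVEL_BIAS"] = counts.get(NOVEL_BIAS_A, 0) + counts.get(NOVEL_BIAS_C, 0)
        counts = merged
    else:
        labels = list(TRANSITIONS)
    for lab in labels:
        c = int(counts.get(lab, 0))
        rows.append({"level": "transition", "label": lab, "count": c,
                     "fraction": c / n if n else 0.0})
    hybrid = transitions["hybrid_state"].value_counts()
    for lab in (A_BIAS, C_BIAS, NO_BIAS):
        c = int(hybrid.get(lab, 0))
        rows.append({"level": "hybrid_state", "label": lab, "count": c,
                     "fraction": c / n if n else 0.0})
    return pd.DataFrame(rows)
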