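"""Twelve-category expression-level-dominance classification.

For each homoeolog pair and each allopolyploid individual, three two-group
comparisons are made at the pair level: parent A vs parent C, polyploid
total (A-copy + C-copy) vs parent A, and polyploid total vs parent C. The
resulting ternary triple (each comparison being lower / equal / higher) is
binned into one of twelve roman categories or CONSERVED (all three equal);
triples that fit no category (e.g. the total equal to both parents while the
parents differ) are AMBIGUOUS.

Category groups:

* additive          — I, XII        (total strictly between differing parents)
* ELD toward A      — IV, IX        (total equal to parent A, different from C)
* ELD toward C      — II, XI        (total equal to parent C, different from A)
* transgressive up  — V, VI, VIII   (total above both parents)
* transgressive down— III, VII, X   (total below both parents)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .de import NS, UP_A, UP_B, DETable, de_table, size_factors_median_of_ratios
from .io import ConfigError, CountMatrix, HomoeologPairTable, SampleSheet, PARENT_A, PARENT_C, POLYPLOID

# ternary relation symbols
A_LT_C, A_EQ_C, A_GT_C = "A<C", "A=C", "A>C"
T_LT_A, T_EQ_A, T_GT_A = "T<A", "T=A", "T>A"
T_LT_C, T_EQ_C, T_GT_C = "T<C", "T=C", "T>C"

ADDITIVE = "ADDITIVE"
ELD_A = "ELD_A"
ELD_C = "ELD_C"
TRANS_UP = "TRANS_UP"
TRANS_DOWN = "TRANS_DOWN"
CONSERVED = "CONSERVED"
AMBIGUOUS = "AMBIGUOUS"

ROMANS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII")

#: canonical triple -> roman category table
CATEGORY_OF_TRIPLE: dict[tuple[str, str, str], str] = {
    (A_EQ_C, T_EQ_A, T_EQ_C): CONSERVED,
    # additive: total strictly between differing parents
    (A_LT_C, T_GT_A, T_LT_C): "I",
    (A_GT_C, T_LT_A, T_GT_C): "XII",
    # expression-level dominance toward parent A
    (A_LT_C, T_EQ_A, T_LT_C): "IV",
    (A_GT_C, T_EQ_A, T_GT_C): "IX",
    # expression-level dominance toward parent C
    (A_LT_C, T_GT_A, T_EQ_C): "II",
    (A_GT_C, T_LT_A, T_EQ_C): "XI",
    # transgressive up
    (A_EQ_C, T_GT_A, T_GT_C): "V",
    (A_LT_C, T_GT_A, T_GT_C): "VI",
    (A_GT_C, T_GT_A, T_GT_C): "VIII",
    # transgressive down
    (A_EQ_C, T_LT_A, T_LT_C): "VII",
    (A_LT_C, T_LT_A, T_LT_C): "III",
    (A_GT_C, T_LT_A, T_LT_C): "X",
}

PATTERN_OF_ROMAN: dict[str, str] = {
    "I": ADDITIVE,
    "XII": ADDITIVE,
    "IV": ELD_A,
    "IX": ELD_A,
    "II": ELD_C,
    "XI": ELD_C,
    "V": TRANS_UP,
    "VI": TRANS_UP,
    "VIII": TRANS_UP,
    "III": TRANS_DOWN,
    "VII": TRANS_DOWN,
    "X": TRANS_DOWN,
    CONSERVED: CONSERVED,
    AMBIGUOUS: AMBIGUOUS,
}

PATTERNS = (ADDITIVE, ELD_A, ELD_C, TRANS_UP, TRANS_DOWN, CONSERVED, AMBIGUOUS)


def classify_triple(d_ac: str, d_ta: str, d_tc: str) -> str:
    """Map one ternary triple to its roman category (total on all 27 triples)."""
    return CATEGORY_OF_TRIPLE.get((d_ac, d_ta, d_tc), AMBIGUOUS)


def all_triples() -> list[tuple[str, str, str]]:
    """Enumerate all 27 ternary triples."""
    return [
        (ac, ta, tc)
        for ac in (A_LT_C, A_EQ_C, A_GT_C)
        for ta in (T_LT_A, T_EQ_A, T_GT_A)
        for tc in (T_LT_C, T_EQ_C, T_GT_C)
    ]


def pair_level_matrix(
    counts: CountMatrix, pairs: HomoeologPairTable, sheet: SampleSheet
) -> CountMatrix:
    """Collapse gene-level counts to homoeolog-pair rows.

    Parent-A samples take the A-copy counts, parent-C samples the C-copy
    counts, and polyploid samples the pair total (A-copy + C-copy), so that
    every downstream comparison sees the quantity the classification is
    defined on.
    """
    df = pairs.frame
    try:
        rows_a = np.array([counts.gene_row(g) for g in df["gene_A"]], dtype=np.intp)
        rows_c = np.array([counts.gene_row(g) for g in df["gene_C"]], dtype=np.intp)
    except KeyError as exc:
        raise ConfigError(f"pair references a gene missing from counts: {exc}") from None
    n_pairs = len(df)
    mat = np.zeros((n_pairs, counts.n_samples), dtype=np.int64)
    geno = counts_sample_genotypes(counts, sheet)
    a_counts = counts.counts[rows_a] if n_pairs else np.zeros((0, counts.n_samples), dtype=np.int64)
    c_counts = counts.counts[rows_c] if n_pairs else np.zeros((0, counts.n_samples), dtype=np.int64)
    for j, g in enumerate(geno):
        if g == PARENT_A:
            mat[:, j] = a_counts[:, j]
        elif g == PARENT_C:
            mat[:, j] = c_counts[:, j]
        else:
            mat[:, j] = a_counts[:, j] + c_counts[:, j]
    return CountMatrix(
        gene_ids=list(df["pair_id"]),
        subgenome=np.array(["AC"] * n_pairs, dtype=object),
        sample_ids=list(counts.sample_ids),
        counts=mat,
    )


def counts_sample_genotypes(counts: CountMatrix, sheet: SampleSheet) -> list[str]:
    lookup = dict(zip(sheet.frame["sample_id"], sheet.frame["genotype"]))
    try:
        return [lookup[s] for s in counts.sample_ids]
    except KeyError as exc:
        raise ConfigError(f"sample missing from sheet: {exc}") from None


def ternary_from_call(call: str, lt: str, eq: str, gt: str) -> str:
    """Translate a DE call (group2 vs group1) into a ternary relation symbol."""
    if call == UP_B:
        return gt
    if call == UP_A:
        return lt
    if call == NS:
        return eq
    raise ValueError(f"unknown DE call {call!r}")


def classify_individual(
    de_ta: DETable,
    de_tc: DETable,
    de_ac: DETable,
    individual: str,
) -> pd.DataFrame:
    """Assemble ternary triples from three DE tables and bin every pair.

    All three tables must cover identical pair ids; contrasts are oriented
    parent -> polyploid total (and parent A -> parent C).
    """
    ids = list(de_ac.frame["unit_id"])
    for tbl, name in ((de_ta, "T vs A"), (de_tc, "T vs C")):
        if list(tbl.frame["unit_id"]) != ids:
            raise ConfigError(f"pair ids of {name} table do not match A vs C table")
    d_ac = [ternary_from_call(c, A_GT_C, A_EQ_C, A_LT_C) for c in de_ac.frame["call"]]
    d_ta = [ternary_from_call(c, T_LT_A, T_EQ_A, T_GT_A) for c in de_ta.frame["call"]]
    d_tc = [ternary_from_call(c, T_LT_C, T_EQ_C, T_GT_C) for c in de_tc.frame["call"]]
    roman = [classify_triple(a, t1, t2) for a, t1, t2 in zip(d_ac, d_ta, d_tc)]
    return pd.DataFrame(
        {
            "pair_id": ids,
            "individual": individual,
            "d_AC": d_ac,
            "d_TA": d_ta,
            "d_TC": d_tc,
            "roman": roman,
            "pattern": [PATTERN_OF_ROMAN[r] for r in roman],
        }
    )


def classify_eld(
    counts: CountMatrix,
    pairs: HomoeologPairTable,
    sheet: SampleSheet,
    individual: str,
    alpha: float = 0.05,
    pair_matrix: CountMatrix | None = None,
    size_factors: np.ndarray | None = None,
    de_ac: DETable | None = None,
) -> pd.DataFrame:
    """End-to-end classification of one polyploid individual.

    The pair matrix, its size factors and the parent-vs-parent DE table can
    be passed in when classifying several individuals against the same
    parents (they are individual-independent).
    """
    pm = pair_matrix if pair_matrix is not None else pair_level_matrix(counts, pairs, sheet)
    sf = size_factors if size_factors is not None else size_factors_median_of_ratios(pm)
    cols_a = pm.sample_cols(sheet.samples_of(PARENT_A))
    cols_c = pm.sample_cols(sheet.samples_of(PARENT_C))
    cols_t = pm.sample_cols(sheet.samples_of(POLYPLOID, individual))
    ids = pm.gene_ids
    if de_ac is None:
        de_ac = de_table(ids, pm.counts[:, cols_a], pm.counts[:, cols_c], sf[cols_a], sf[cols_c], alpha)
    de_ta = de_table(ids, pm.counts[:, cols_a], pm.counts[:, cols_t], sf[cols_a], sf[cols_t], alpha)
    de_tc = de_table(ids, pm.counts[:, cols_c], pm.counts[:, cols_t], sf[cols_c], sf[cols_t], alpha)
    return classify_individual(de_ta, de_tc, de_ac, individual)


def pattern_summary(assignments: pd.DataFrame, denominator: int) -> pd.DataFrame:
    """Counts and fractions per roman category and per combined pattern.

    Fractions use the full homoeolog-pair count as denominator, so summaries
    from subsets remain comparable across individuals.
    """
    rows = []
    labels = list(ROMANS) + [CONSERVED, AMBIGUOUS]
    roman_counts = assignments["roman"].value_counts() if len(assignments) else pd.Series(dtype=int)
    for lab in labels:
        c = int(roman_counts.get(lab, 0))
        rows.append({"level": "category", "label": lab, "count": c,
                     "fraction": c / denominator if denominator else 0.0})
    pat_counts = assignments["pattern"].value_counts() if len(assignments) else pd.Series(dtype=int)
    for lab in PATTERNS:
        c = int(pat_counts.get(lab, 0))
        rows.append({"level": "pattern", "label": lab, "count": c,
                     "fraction": c / denominator if denominator else 0.0})
    return pd.DataFrame(rows)
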