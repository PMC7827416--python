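"""Gene activation (novel expression) and silencing calls.

Rules operate per homoeolog per polyploid individual on raw counts and CPM:

* **novel** — both parental species show zero reads for the pair in every
  replicate, yet the polyploid shows more than ``cpm_threshold`` (default 10)
  counts per million for the focal homoeolog in every replicate.
* **silenced** — the parent carrying the focal homoeolog shows more than
  ``cpm_threshold`` CPM in every replicate, yet the polyploid shows zero
  counts for that homoeolog in every replicate.

Per-subgenome evaluation yields the NOVEL_AA / NOVEL_CC and SILENCE_AA /
SILENCE_CC splits; the subgenome asymmetry of the counts is assessed with a
two-proportion chi-square test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .de import cpm
from .io import ConfigError, CountMatrix, HomoeologPairTable, SampleSheet, PARENT_A, PARENT_C, POLYPLOID

SILENCED = "SILENCED"
NOVEL = "NOVEL"
NEITHER = "NEITHER"

CPM_THRESHOLD = 10.0


def _above_threshold(cpm_vals: np.ndarray, threshold: float, mode: str) -> np.ndarray:
    """Row mask: CPM rule over replicates ('all' per-replicate, or 'pooled')."""
    if mode == "all":
        return (cpm_vals > threshold).all(axis=1)
    if mode == "pooled":
        return cpm_vals.mean(axis=1) > threshold
    raise ConfigError(f"unknown replicate mode {mode!r}")


def call_novel(
    parent_a_counts: np.ndarray,
    parent_c_counts: np.ndarray,
    poly_cpm: np.ndarray,
    cpm_threshold: float = CPM_THRESHOLD,
    mode: str = "all",
) -> bool:
    """Novel expression for one homoeolog of one pair in one individual.

    True iff every parental replicate of both parents has zero raw counts
    for the pair and every polyploid replicate exceeds the CPM threshold for
    the focal homoeolog.
    """
    parents_zero = (np.asarray(parent_a_counts) == 0).all() and (
        np.asarray(parent_c_counts) == 0
    ).all()
    poly_high = bool(
        _above_threshold(np.atleast_2d(np.asarray(poly_cpm, dtype=float)), cpm_threshold, mode)[0]
    )
    return bool(parents_zero and poly_high)


def call_silenced(
    parent_cpm: np.ndarray,
    poly_counts: np.ndarray,
    cpm_threshold: float = CPM_THRESHOLD,
    mode: str = "all",
) -> bool:
    """Silencing for one homoeolog: parent above threshold, polyploid at zero.

    ``parent_cpm`` holds the corresponding parent's per-replicate CPM for
    the homoeolog; ``poly_counts`` the polyploid's raw counts for it.
    """
    parent_high = bool(
        _above_threshold(np.atleast_2d(np.asarray(parent_cpm, dtype=float)), cpm_threshold, mode)[0]
    )
    poly_zero = (np.asarray(poly_counts) == 0).all()
    return bool(parent_high and poly_zero)


def silencing_calls(
    counts: CountMatrix,
    pairs: HomoeologPairTable,
    sheet: SampleSheet,
    individual: str,
    cpm_threshold: float = CPM_THRESHOLD,
    mode: str = "all",
    require_both_parents: bool = False,
) -> pd.DataFrame:
    """Vectorized novel/silencing calls for every homoeolog of one individual.

    Returns one row per (pair, subgenome) with a status in
    {SILENCED, NOVEL, NEITHER}. ``require_both_parents`` additionally demands
    the other parent's homoeolog above threshold for silencing calls.
    """
    df = pairs.frame
    try:
        rows_a = np.array([counts.gene_row(g) for g in df["gene_A"]], dtype=np.intp)
        rows_c = np.array([counts.gene_row(g) for g in df["gene_C"]], dtype=np.intp)
    except KeyError as exc:
        raise ConfigError(f"pair references a gene missing from counts: {exc}") from None
    cols_pa = counts.sample_cols(sheet.samples_of(PARENT_A))
    cols_pc = counts.sample_cols(sheet.samples_of(PARENT_C))
    cols_t = counts.sample_cols(sheet.samples_of(POLYPLOID, individual))

    cpm_all = cpm(counts)
    raw = counts.counts

    pa_counts = raw[np.ix_(rows_a, cols_pa)]
    pc_counts = raw[np.ix_(rows_c, cols_pc)]
    pa_cpm = cpm_all[np.ix_(rows_a, cols_pa)]
    pc_cpm = cpm_all[np.ix_(rows_c, cols_pc)]
    ta_counts = raw[np.ix_(rows_a, cols_t)]
    tc_counts = raw[np.ix_(rows_c, cols_t)]
    ta_cpm = cpm_all[np.ix_(rows_a, cols_t)]
    tc_cpm = cpm_all[np.ix_(rows_c, cols_t)]

    parents_zero = (pa_counts == 0).all(axis=1) & (pc_counts == 0).all(axis=1)
    novel_a = parents_zero & _above_threshold(ta_cpm, cpm_threshold, mode)
    novel_c = parents_zero & _above_threshold(tc_cpm, cpm_threshold, mode)

    parent_a_high = _above_threshold(pa_cpm, cpm_threshold, mode)
    parent_c_high = _above_threshold(pc_cpm, cpm_threshold, mode)
    sil_a_req = parent_a_high & parent_c_high if require_both_parents else parent_a_high
    sil_c_req = parent_a_high & parent_c_high if require_both_parents else parent_c_high
    silenced_a = sil_a_req & (ta_counts == 0).all(axis=1)
    silenced_c = sil_c_req & (tc_counts == 0).all(axis=1)

    def status(novel: np.ndarray, silenced: np.ndarray) -> np.ndarray:
        return np.where(novel, NOVEL, np.where(silenced, SILENCED, NEITHER))

    out_a = pd.DataFrame(
        {
            "pair_id": df["pair_id"],
            "gene_id": df["gene_A"],
            "subgenome": "A",
            "individual": individual,
            "status": status(novel_a, silenced_a),
        }
    )
    out_c = pd.DataFrame(
        {
            "pair_id": df["pair_id"],
            "gene_id": df["gene_C"],
            "subgenome": "C",
            "individual": individual,
            "status": status(novel_c, silenced_c),
        }
    )
    return pd.concat([out_a, out_c], ignore_index=True)


def silencing_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """NOVEL/SILENCED counts per subgenome per individual, with totals."""
    rows = []
    for individual, sub in calls.groupby("individual", sort=True):
        counts = sub.groupby(["status", "subgenome"]).size()
        for status in (NOVEL, SILENCED):
            for sg in ("A", "C"):
                rows.append(
                    {
                        "individual": individual,
                        "metric": f"{'NOVEL' if status == NOVEL else 'SILENCE'}_{sg}{sg}",
                        "count": int(counts.get((status, sg), 0)),
                    }
                )
    return pd.DataFrame(rows)


def subgenome_asymmetry_test(count_a: int, count_c: int, n_pairs: int) -> float:
    """Two-proportion chi-square p-value for an A vs C count asymmetry."""
    table = np.array([[count_a, n_pairs - count_a], [count_c, n_pairs - count_c]])
    if table[:, 0].sum() == 0:
        return 1.0
    return float(chi2_contingency(table, correction=True)[1])
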