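"""Mid-parent value construction and non-additive expression testing.

The mid-parent value (MPV) is the average of the two parents' expression;
a pair is non-additively expressed in a polyploid when its total expression
deviates significantly from MPV. MPV is realized as in-silico pseudo-
replicates: parent-A replicate i is paired with parent-C replicate i (by
replicate index), their size-factor-normalized pair counts are averaged with
equal weight (the AACC constitution contributes each genome once) and
rounded half-up back to an integer pseudo-count with size factor 1, so the
same NB machinery tests polyploid totals against MPV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DETable, de_table, estimate_dispersion, size_factors_median_of_ratios
from .io import ConfigError, CountMatrix, SampleSheet, PARENT_A, PARENT_C, POLYPLOID


@dataclass
class MPVSamples:
    """Mid-parent pseudo-replicates over homoeolog pairs."""

    pair_ids: list[str]
    pseudo_sample_ids: list[str]
    counts: np.ndarray          # pairs x pseudo-replicates, integer
    source_replicates: list[tuple[str, str]]  # (parent A sample, parent C sample)

    @property
    def size_factors(self) -> np.ndarray:
        return np.ones(self.counts.shape[1])


def build_mpv(
    pair_matrix: CountMatrix,
    sheet: SampleSheet,
    size_factors: np.ndarray,
) -> MPVSamples:
    """Construct MPV pseudo-replicates from index-paired parental replicates.

    mpv_i = round_half_up((countA_i / sfA_i + countC_i / sfC_i) / 2); the
    parents must have equal replicate counts.
    """
    samples_a = sheet.samples_of(PARENT_A)
    samples_c = sheet.samples_of(PARENT_C)
    if len(samples_a) != len(samples_c):
        raise ConfigError(
            f"MPV needs equal parental replicate numbers "
            f"({len(samples_a)} vs {len(samples_c)})"
        )
    cols_a = pair_matrix.sample_cols(samples_a)
    cols_c = pair_matrix.sample_cols(samples_c)
    norm_a = pair_matrix.counts[:, cols_a] / size_factors[cols_a]
    norm_c = pair_matrix.counts[:, cols_c] / size_factors[cols_c]
    mpv = np.floor((norm_a + norm_c) / 2.0 + 0.5).astype(np.int64)  # half-up
    return MPVSamples(
        pair_ids=list(pair_matrix.gene_ids),
        pseudo_sample_ids=[f"MPV_rep{i + 1}" for i in range(len(samples_a))],
        counts=mpv,
        source_replicates=list(zip(samples_a, samples_c)),
    )


def test_nonadditive(
    pair_matrix: CountMatrix,
    sheet: SampleSheet,
    individual: str,
    alpha: float = 0.05,
    size_factors: np.ndarray | None = None,
    mpv: MPVSamples | None = None,
) -> tuple[DETable, float]:
    """Test each pair's polyploid total against MPV; return table and fraction.

    Non-additive iff q < alpha; the fraction is over all pairs in the table.
    """
    sf = size_factors if size_factors is not None else size_factors_median_of_ratios(pair_matrix)
    if mpv is None:
        mpv = build_mpv(pair_matrix, sheet, sf)
    cols_t = pair_matrix.sample_cols(sheet.samples_of(POLYPLOID, individual))
    table = de_table(
        pair_matrix.gene_ids,
        mpv.counts,
        pair_matrix.counts[:, cols_t],
        mpv.size_factors,
        sf[cols_t],
        alpha=alpha,
    )
    flagged = table.frame["qvalue"] < alpha
    fraction = float(flagged.mean()) if len(table.frame) else 0.0
    out = table.frame.copy()
    out["nonadditive"] = flagged
    return DETable(out), fraction
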