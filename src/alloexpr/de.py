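"""Normalization and two-group negative-binomial differential expression.

The engine is a conditional NB exact test: for each unit (gene or homoeolog
pair) the total count K over both groups is held fixed and the probability of
every split (a, K - a) is computed under the null model in which both groups
share one concentration, group means are proportional to their summed size
factors, and counts are negative-binomial with variance mu + alpha * mu^2.
The two-sided p-value is the total probability of all splits no more probable
than the observed one (minimum-likelihood method). At dispersion 0 the NB
degenerates to Poisson and the conditional distribution is exactly
Binomial(K, S2 / (S1 + S2)) — this analytic limit anchors the test suite.

Normalization is median-of-ratios (per-sample size factors whose geometric
mean is 1); dispersion is method-of-moments per unit with a nearest-neighbour
trend floor; multiple testing uses the Benjamini-Hochberg step-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, ndtr

from .io import ConfigError, CountMatrix, SampleSheet

UP_A = "UP_A"
UP_B = "UP_B"
NS = "NS"

#: above this conditional total the exact enumeration switches to a normal
#: approximation of the conditional distribution
EXACT_MAX_TOTAL = 10_000

#: pseudocount added to normalized group means for log2 fold changes
PSEUDOCOUNT = 1.0


# ---------------------------------------------------------------------------
# normalization


def size_factors_median_of_ratios(counts: np.ndarray | CountMatrix) -> np.ndarray:
    """DESeq-style median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample j the factor is the median over all-positive genes of
    ``counts[g, j] / geometric_mean_g(counts[g, :])``.

    Raises
    ------
    ConfigError
        If no gene has positive counts in every sample (CPM normalization is
        the fallback for such degenerate matrices).
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    positive = np.all(mat > 0, axis=1)
    if not positive.any():
        raise ConfigError(
            "no gene with positive counts in every sample; "
            "median-of-ratios is undefined — use CPM normalization instead"
        )
    sub = mat[positive].astype(float)
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    factors = np.median(ratios, axis=0)
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def cpm(counts: np.ndarray | CountMatrix) -> np.ndarray:
    """Counts per million: ``count * 1e6 / column_sum``."""
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    totals = mat.sum(axis=0, dtype=float)
    if np.any(totals <= 0):
        raise ConfigError("zero-total sample: CPM undefined")
    return mat * 1e6 / totals


def fpkm(counts: CountMatrix) -> np.ndarray:
    """Fragments per kilobase per million mapped reads.

    ``count * 1e9 / (length_bp * column_sum)``; requires gene lengths.
    """
    if counts.gene_lengths is None:
        raise ConfigError("FPKM requires gene lengths")
    totals = counts.counts.sum(axis=0, dtype=float)
    if np.any(totals <= 0):
        raise ConfigError("zero-total sample: FPKM undefined")
    return counts.counts * 1e9 / (counts.gene_lengths[:, None] * totals)


# ---------------------------------------------------------------------------
# dispersion


def estimate_dispersion(
    group1: np.ndarray,
    group2: np.ndarray,
    sf1: np.ndarray,
    sf2: np.ndarray,
    n_neighbors: int = 50,
) -> np.ndarray:
    """Per-unit NB dispersion by method of moments with a trend floor.

    Counts are normalized by size factors; the within-group variances are
    pooled and the raw estimate is ``max(0, (pooled_var - mean) / mean^2)``.
    Each unit's final dispersion is the maximum of its own raw estimate and
    the median raw estimate of its ``n_neighbors`` nearest units by mean
    normalized expression (a deterministic guard against the severe
    underestimation that 3-replicate moment estimates are prone to).
    """
    group1 = np.atleast_2d(np.asarray(group1, dtype=float))
    group2 = np.atleast_2d(np.asarray(group2, dtype=float))
    n1, n2 = group1.shape[1], group2.shape[1]
    if n1 < 2 and n2 < 2:
        raise ConfigError("dispersion estimation needs >= 2 replicates in a group")
    norm1 = group1 / np.asarray(sf1, dtype=float)
    norm2 = group2 / np.asarray(sf2, dtype=float)
    mean = np.concatenate([norm1, norm2], axis=1).mean(axis=1)
    num = 0.0
    den = 0
    if n1 >= 2:
        num = num + (n1 - 1) * norm1.var(axis=1, ddof=1)
        den += n1 - 1
    if n2 >= 2:
        num = num + (n2 - 1) * norm2.var(axis=1, ddof=1)
        den += n2 - 1
    pooled_var = num / den
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mean > 0, (pooled_var - mean) / np.maximum(mean, 1e-300) ** 2, 0.0)
    raw = np.maximum(raw, 0.0)
    order = np.argsort(mean, kind="stable")
    window = min(n_neighbors + 1, len(raw))
    trend_sorted = (
        pd.Series(raw[order]).rolling(window, center=True, min_periods=1).median().to_numpy()
    )
    trend = np.empty_like(raw)
    trend[order] = trend_sorted
    return np.maximum(raw, trend)


# ---------------------------------------------------------------------------
# the exact test


_LOG_FACT = np.zeros(1)  # cached gammaln(k + 1), grown on demand


def _log_factorials(n: int) -> np.ndarray:
    """gammaln(k+1) for k = 0..n, cached across calls."""
    global _LOG_FACT
    if len(_LOG_FACT) <= n:
        _LOG_FACT = gammaln(np.arange(max(n + 1, 2 * len(_LOG_FACT))) + 1.0)
    return _LOG_FACT[: n + 1]


def _nb_logpmf(a: np.ndarray, log_fact: np.ndarray, mu: float, var: float) -> np.ndarray:
    """Log pmf of NB parameterized by mean and variance (Poisson if var<=mu).

    ``log_fact`` must hold gammaln(a+1) for the same ``a``.
    """
    a = np.asarray(a, dtype=float)
    if mu == 0:
        return np.where(a == 0, 0.0, -np.inf)
    if var <= mu:  # Poisson limit
        return a * np.log(mu) - mu - log_fact
    r = mu * mu / (var - mu)
    logp = np.log(r) - np.log(r + mu)
    log1mp = np.log(mu) - np.log(r + mu)
    return gammaln(a + r) - gammaln(r) - log_fact + r * logp + a * log1mp


def nb_exact_test(
    k1: np.ndarray,
    k2: np.ndarray,
    sf1: np.ndarray,
    sf2: np.ndarray,
    dispersion: float,
) -> float:
    """Two-sided conditional NB exact test p-value for one unit.

    ``k1``/``k2`` are per-replicate raw counts of the two groups and
    ``sf1``/``sf2`` their size factors. Conditions on the grand total K and
    sums the probabilities of all splits no more probable than the observed
    one. K = 0 returns p = 1 by convention; totals above
    ``EXACT_MAX_TOTAL`` use a normal approximation to the conditional law.
    """
    k1 = np.asarray(k1)
    k2 = np.asarray(k2)
    ka, kb = int(k1.sum()), int(k2.sum())
    K = ka + kb
    if K == 0:
        return 1.0
    sf1 = np.asarray(sf1, dtype=float)
    sf2 = np.asarray(sf2, dtype=float)
    s1, s2 = sf1.sum(), sf2.sum()
    q0 = K / (s1 + s2)
    mu1, mu2 = q0 * s1, q0 * s2
    # variance of a group sum of independent NB replicates
    var1 = mu1 + dispersion * q0 * q0 * float(np.sum(sf1 * sf1))
    var2 = mu2 + dispersion * q0 * q0 * float(np.sum(sf2 * sf2))
    if K > EXACT_MAX_TOTAL:
        sigma2 = var1 * var2 / (var1 + var2)
        z = (ka - mu1) / np.sqrt(sigma2)
        return float(min(1.0, 2.0 * ndtr(-abs(z))))
    a = np.arange(K + 1)
    lf = _log_factorials(K)
    logp = _nb_logpmf(a, lf, mu1, var1) + _nb_logpmf(K - a, lf[::-1], mu2, var2)
    logp -= logsumexp(logp)
    obs = logp[ka]
    keep = logp <= obs + 1e-8  # tolerance keeps equiprobable mirror splits
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def log2_fold_change(
    k1: np.ndarray, k2: np.ndarray, sf1: np.ndarray, sf2: np.ndarray
) -> float:
    """log2((mean2 + 1)/(mean1 + 1)) on size-factor-normalized means."""
    m1 = float(np.mean(np.asarray(k1, dtype=float) / np.asarray(sf1, dtype=float)))
    m2 = float(np.mean(np.asarray(k2, dtype=float) / np.asarray(sf2, dtype=float)))
    return float(np.log2((m2 + PSEUDOCOUNT) / (m1 + PSEUDOCOUNT)))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# full DE table


@dataclass
class DETable:
    """Per-unit DE results for one two-group contrast."""

    frame: pd.DataFrame  # unit_id, mean_A, mean_B, log2fc, pvalue, qvalue, call

    def calls(self) -> pd.Series:
        return self.frame.set_index("unit_id")["call"]


def de_table(
    unit_ids: list[str],
    group1: np.ndarray,
    group2: np.ndarray,
    sf1: np.ndarray,
    sf2: np.ndarray,
    alpha: float = 0.05,
    dispersion: np.ndarray | None = None,
) -> DETable:
    """Run the NB exact test for every unit and BH-adjust across units.

    ``group1``/``group2`` are units x replicates count arrays. When
    ``dispersion`` is None it is estimated by :func:`estimate_dispersion`.
    Calls: UP_B if q < alpha and log2fc > 0, UP_A if q < alpha and
    log2fc < 0, otherwise NS (strict threshold: q exactly at alpha is NS).
    """
    group1 = np.atleast_2d(np.asarray(group1))
    group2 = np.atleast_2d(np.asarray(group2))
    n = group1.shape[0]
    if group2.shape[0] != n or len(unit_ids) != n:
        raise ConfigError("unit dimension mismatch between groups")
    sf1 = np.asarray(sf1, dtype=float)
    sf2 = np.asarray(sf2, dtype=float)
    if dispersion is None:
        dispersion = estimate_dispersion(group1, group2, sf1, sf2)
    else:
        dispersion = np.broadcast_to(np.asarray(dispersion, dtype=float), (n,))
    norm1 = group1 / sf1
    norm2 = group2 / sf2
    mean_a = norm1.mean(axis=1)
    mean_b = norm2.mean(axis=1)
    log2fc = np.log2((mean_b + PSEUDOCOUNT) / (mean_a + PSEUDOCOUNT))
    pvals = np.empty(n)
    for i in range(n):
        pvals[i] = nb_exact_test(group1[i], group2[i], sf1, sf2, float(dispersion[i]))
    qvals = bh_adjust(pvals)
    sig = qvals < alpha
    call = np.where(sig & (log2fc > 0), UP_B, np.where(sig & (log2fc < 0), UP_A, NS))
    return DETable(
        pd.DataFrame(
            {
                "unit_id": unit_ids,
                "mean_A": mean_a,
                "mean_B": mean_b,
                "log2fc": log2fc,
                "pvalue": pvals,
                "qvalue": qvals,
                "call": call,
            }
        )
    )


def _resolve_group(sheet: SampleSheet, selector: str) -> list[str]:
    """Group selector: 'PARENT_A', 'PARENT_C', or 'POLYPLOID/<individual>'."""
    if "/" in selector:
        genotype, individual = selector.split("/", 1)
    else:
        genotype, individual = selector, ""
    return sheet.samples_of(genotype, individual)


def call_de(
    counts: CountMatrix,
    sheet: SampleSheet,
    contrast: tuple[str, str] | str,
    alpha: float = 0.05,
    size_factors: np.ndarray | None = None,
) -> DETable:
    """Gene-level DE between two groups named by sample-sheet selectors.

    ``contrast`` is a (group1, group2) pair such as
    ``("PARENT_A", "POLYPLOID/AACC1")`` or the string form
    ``"PARENT_A:POLYPLOID/AACC1"``. Size factors default to median-of-ratios
    over the full matrix.
    """
    if isinstance(contrast, str):
        g1_spec, g2_spec = contrast.split(":", 1)
    else:
        g1_spec, g2_spec = contrast
    samples1 = _resolve_group(sheet, g1_spec)
    samples2 = _resolve_group(sheet, g2_spec)
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(counts)
    cols1 = counts.sample_cols(samples1)
    cols2 = counts.sample_cols(samples2)
    return de_table(
        counts.gene_ids,
        counts.counts[:, cols1],
        counts.counts[:, cols2],
        size_factors[cols1],
        size_factors[cols2],
        alpha=alpha,
    )
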