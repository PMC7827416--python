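"""Synthetic allopolyploid cohort generator with planted expression classes.

The generator emulates the study design every analysis in this package is
written for: two diploid parents (AA and CC) and eight allopolyploid
individuals, three biological replicates each, ~25,000 homoeolog pairs,
negative-binomial counts (variance = mu + dispersion * mu^2, dispersion
shared across genes by the generator — estimators must not assume this) and
per-sample library-size variation.

Each pair is assigned one planted class which fixes the parental means, the
polyploid pair-total mean and the homoeolog split:

* CONSERVED          — all three expression levels equal.
* ADDITIVE           — parents differ by ``effect_log2fc``; the total sits at
                       the parental midpoint (categories I/XII).
* ELD_A / ELD_C      — parents differ; the total matches parent A / parent C.
* TRANS_UP / TRANS_DOWN — the total exceeds / falls below both parents by
                       ``effect_log2fc``.
* NONADDITIVE_ONLY   — parents differ by twice the effect; the total sits at
                       the *geometric* midpoint, i.e. inside the parental
                       range (additive category) but far from the arithmetic
                       mid-parent value.
* SILENCED_A / SILENCED_C — the focal parental homoeolog is highly expressed
                       (CPM far above the silencing threshold) while the
                       polyploid copy is exactly zero.
* NOVEL              — both parents are exactly zero; one polyploid homoeolog
                       is highly expressed.

Silenced/novel "high" means are set to 10x the CPM-threshold-equivalent
count and the corresponding draws are left-truncated at 2x the threshold
count, so the threshold rules are satisfied by construction rather than by
boundary luck. Zeros are exact (mean zero).

Homoeolog bias: a configurable fraction of transgressive pairs is planted
with unequal parents (parental bias); each parentally biased pair keeps its
biased homoeolog split in the polyploid with probability
``bias_preservation`` (else the split is 50:50 and the bias is lost).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bias import A_BIAS, C_BIAS, NO_BIAS, classify_transition
from .io import CountMatrix, HomoeologPairTable, SampleSheet, TraitMatrix, PARENT_A, PARENT_C, POLYPLOID

CLASSES = (
    "CONSERVED",
    "ADDITIVE",
    "ELD_A",
    "ELD_C",
    "TRANS_UP",
    "TRANS_DOWN",
    "NONADDITIVE_ONLY",
    "SILENCED_A",
    "SILENCED_C",
    "NOVEL",
)

#: default planted proportions, shaped after the magnitudes reported for
#: resynthesized B. napus: a conserved majority, ELD toward A about three
#: times ELD toward C, transgressive up above transgressive down, silencing
#: around a percent per subgenome with an A/C asymmetry, novel expression
#: split evenly between subgenomes.
DEFAULT_PROPORTIONS: dict[str, float] = {
    "CONSERVED": 0.43,
    "ADDITIVE": 0.13,
    "ELD_A": 0.15,
    "ELD_C": 0.05,
    "TRANS_UP": 0.10,
    "TRANS_DOWN": 0.04,
    "NONADDITIVE_ONLY": 0.06,
    "SILENCED_A": 0.01,
    "SILENCED_C": 0.015,
    "NOVEL": 0.015,
}


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort."""

    n_pairs: int = 25_000
    n_individuals: int = 8
    replicates: int = 3
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    #: log-normal baseline expression: median exp(meanlog), floored at
    #: baseline_min so every planted effect rides on a well-measured gene
    baseline_meanlog: float = float(np.log(500.0))
    baseline_sdlog: float = 0.6
    baseline_min: float = 200.0
    effect_log2fc: float = 4.0
    dispersion: float = 0.05
    #: per-sample depth factors; None draws log-uniform from [0.5, 2]
    library_sizes: np.ndarray | None = None
    parental_bias_fraction: float = 0.3
    bias_preservation: float = 0.7
    cpm_threshold: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        unknown = set(self.class_proportions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")
        if min(self.class_proportions.values()) < 0:
            raise ValueError("negative class proportion")
        for name in ("n_pairs", "n_individuals", "replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion < 0 or self.effect_log2fc < 0:
            raise ValueError("dispersion and effect_log2fc must be >= 0")


@dataclass
class SimResult:
    counts: CountMatrix
    sheet: SampleSheet
    pairs: HomoeologPairTable
    truth: pd.DataFrame


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with variance mu + dispersion * mu^2 (Poisson at dispersion 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean).astype(np.int64)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    n = 1.0 / dispersion
    p = n / (n + mean[pos])
    out[pos] = rng.negative_binomial(n, p)
    return out


def simulate(config: SimConfig) -> SimResult:
    """Generate the synthetic cohort and its truth table.

    Fully reproducible: all randomness flows from ``config.seed`` through one
    PCG64 generator.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    P = config.n_pairs
    reps = config.replicates
    e = 2.0 ** config.effect_log2fc

    # ---- cohort layout -------------------------------------------------
    individuals = [f"AACC{i + 1}" for i in range(config.n_individuals)]
    sheet_rows = []
    sample_ids: list[str] = []
    for r in range(1, reps + 1):
        sample_ids.append(f"PA_r{r}")
        sheet_rows.append({"sample_id": f"PA_r{r}", "genotype": PARENT_A, "individual": "", "replicate": r})
    for r in range(1, reps + 1):
        sample_ids.append(f"PC_r{r}")
        sheet_rows.append({"sample_id": f"PC_r{r}", "genotype": PARENT_C, "individual": "", "replicate": r})
    for ind in individuals:
        for r in range(1, reps + 1):
            sample_ids.append(f"{ind}_r{r}")
            sheet_rows.append({"sample_id": f"{ind}_r{r}", "genotype": POLYPLOID, "individual": ind, "replicate": r})
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    S = len(sample_ids)

    if config.library_sizes is None:
        lib = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=S))
    else:
        lib = np.asarray(config.library_sizes, dtype=float)
        if lib.shape != (S,):
            raise ValueError(f"library_sizes must have length {S}")

    # ---- per-pair class and baseline ----------------------------------
    labels = list(config.class_proportions)
    probs = np.array([config.class_proportions[k] for k in labels])
    cls = rng.choice(len(labels), size=P, p=probs)
    planted = np.array(labels, dtype=object)[cls]
    base = np.maximum(
        rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, size=P),
        config.baseline_min,
    )
    # direction coin: True means parent A is the lower parent where the
    # class has unequal parents
    a_low = rng.random(P) < 0.5
    trans_biased = rng.random(P) < config.parental_bias_fraction
    keep_bias = rng.random(P) < config.bias_preservation
    novel_on_a = rng.random(P) < 0.5

    mu_a = np.zeros(P)   # A-copy mean in parent A
    mu_c = np.zeros(P)   # C-copy mean in parent C
    total = np.zeros(P)  # polyploid pair-total mean
    frac_a = np.full(P, 0.5)  # polyploid A-copy share of the total
    nonadditive = np.zeros(P, dtype=bool)
    high_parent_a = np.zeros(P, dtype=bool)  # silenced-A focal parent copies
    high_parent_c = np.zeros(P, dtype=bool)
    high_poly_a = np.zeros(P, dtype=bool)    # novel focal polyploid copies
    high_poly_c = np.zeros(P, dtype=bool)

    for i in range(P):
        b = base[i]
        c = planted[i]
        lo, hi = (b, b * e)
        if c == "CONSERVED":
            mu_a[i] = mu_c[i] = b
            total[i] = b
        elif c == "ADDITIVE":
            mu_a[i], mu_c[i] = (lo, hi) if a_low[i] else (hi, lo)
            total[i] = (mu_a[i] + mu_c[i]) / 2.0
        elif c == "ELD_A":
            mu_a[i], mu_c[i] = (lo, hi) if a_low[i] else (hi, lo)
            total[i] = mu_a[i]
            nonadditive[i] = True
        elif c == "ELD_C":
            mu_a[i], mu_c[i] = (lo, hi) if a_low[i] else (hi, lo)
            total[i] = mu_c[i]
            nonadditive[i] = True
        elif c == "TRANS_UP":
            if trans_biased[i]:
                mu_a[i], mu_c[i] = (lo, hi) if a_low[i] else (hi, lo)
            else:
                mu_a[i] = mu_c[i] = b
            total[i] = max(mu_a[i], mu_c[i]) * e
            nonadditive[i] = True
        elif c == "TRANS_DOWN":
            if trans_biased[i]:
                mu_a[i], mu_c[i] = (b * e, b * e * e) if a_low[i] else (b * e * e, b * e)
            else:
                mu_a[i] = mu_c[i] = b * e
            total[i] = min(mu_a[i], mu_c[i]) / e
            nonadditive[i] = True
        elif c == "NONADDITIVE_ONLY":
            mu_a[i], mu_c[i] = (b, b * e * e) if a_low[i] else (b * e * e, b)
            total[i] = b * e  # geometric midpoint: inside the range, far from MPV
            nonadditive[i] = True
        elif c == "SILENCED_A":
            high_parent_a[i] = True
            mu_c[i] = b
            total[i] = b
            frac_a[i] = 0.0
            nonadditive[i] = True
        elif c == "SILENCED_C":
            high_parent_c[i] = True
            mu_a[i] = b
            total[i] = b
            frac_a[i] = 1.0
            nonadditive[i] = True
        elif c == "NOVEL":
            if novel_on_a[i]:
                high_poly_a[i] = True
                frac_a[i] = 1.0
            else:
                high_poly_c[i] = True
                frac_a[i] = 0.0
            nonadditive[i] = True

    # homoeolog split in the polyploid for ordinary classes: proportional to
    # the parental means when the planted bias is preserved, else 50:50
    ordinary = ~(high_parent_a | high_parent_c | high_poly_a | high_poly_c)
    parents_unequal = ordinary & (mu_a != mu_c)
    prop = np.divide(mu_a, mu_a + mu_c, out=np.full(P, 0.5), where=(mu_a + mu_c) > 0)
    use_prop = parents_unequal & keep_bias
    frac_a[use_prop] = prop[use_prop]

    # ---- silenced/novel "high" means with guaranteed CPM margin --------
    cc = 10.0 * config.cpm_threshold / 1e6  # high mean = 10x threshold count
    s0_pa = mu_a[~high_parent_a].sum()
    s0_pc = mu_c[~high_parent_c].sum()
    n_sa, n_sc = int(high_parent_a.sum()), int(high_parent_c.sum())
    m_sil_a = cc * s0_pa / max(1e-12, 1.0 - cc * n_sa) if n_sa else 0.0
    m_sil_c = cc * s0_pc / max(1e-12, 1.0 - cc * n_sc) if n_sc else 0.0
    mu_a[high_parent_a] = m_sil_a
    mu_c[high_parent_c] = m_sil_c
    n_nov = int((high_poly_a | high_poly_c).sum())
    s0_t = total[~(high_poly_a | high_poly_c)].sum()
    m_nov = cc * s0_t / max(1e-12, 1.0 - cc * n_nov) if n_nov else 0.0
    total[high_poly_a | high_poly_c] = m_nov

    # ---- expected library totals and truncation floors -----------------
    exp_total_pa = mu_a.sum()
    exp_total_pc = mu_c.sum()
    exp_total_poly = total.sum()
    thr = config.cpm_threshold / 1e6

    at = total * frac_a
    ct = total * (1.0 - frac_a)

    # ---- draw counts ---------------------------------------------------
    gene_a_ids = [f"gA{i:06d}" for i in range(P)]
    gene_c_ids = [f"gC{i:06d}" for i in range(P)]
    counts = np.zeros((2 * P, S), dtype=np.int64)
    genotypes = [r["genotype"] for r in sheet_rows]
    for j in range(S):
        g = genotypes[j]
        if g == PARENT_A:
            mean_col = np.concatenate([mu_a, np.zeros(P)])
        elif g == PARENT_C:
            mean_col = np.concatenate([np.zeros(P), mu_c])
        else:
            mean_col = np.concatenate([at, ct])
        col = _nb_draw(rng, mean_col * lib[j], config.dispersion)
        # left-truncate the planted high homoeologs at 2x the threshold
        # count so the CPM rules hold by construction
        if g == PARENT_A and n_sa:
            floor = int(np.floor(2.0 * thr * exp_total_pa * lib[j])) + 1
            rows = np.where(high_parent_a)[0]
            col[rows] = np.maximum(col[rows], floor)
        elif g == PARENT_C and n_sc:
            floor = int(np.floor(2.0 * thr * exp_total_pc * lib[j])) + 1
            rows = P + np.where(high_parent_c)[0]
            col[rows] = np.maximum(col[rows], floor)
        elif g == POLYPLOID and n_nov:
            floor = int(np.floor(2.0 * thr * exp_total_poly * lib[j])) + 1
            rows_a_hi = np.where(high_poly_a)[0]
            rows_c_hi = P + np.where(high_poly_c)[0]
            col[rows_a_hi] = np.maximum(col[rows_a_hi], floor)
            col[rows_c_hi] = np.maximum(col[rows_c_hi], floor)
        counts[:, j] = col

    lengths = rng.integers(500, 5000, size=2 * P)
    cm = CountMatrix(
        gene_ids=gene_a_ids + gene_c_ids,
        subgenome=np.array(["A"] * P + ["C"] * P, dtype=object),
        sample_ids=sample_ids,
        counts=counts,
        gene_lengths=lengths,
    )

    pair_ids = [f"pair{i:06d}" for i in range(P)]
    pairs = HomoeologPairTable(
        pd.DataFrame(
            {
                "pair_id": pair_ids,
                "gene_A": gene_a_ids,
                "gene_C": gene_c_ids,
                "identity_pct": 95.0,
                "evalue": 1e-50,
            }
        )
    )

    # ---- truth table ---------------------------------------------------
    parent_bias = np.where(
        mu_a > mu_c, A_BIAS, np.where(mu_c > mu_a, C_BIAS, NO_BIAS)
    ).astype(object)
    hybrid_bias = np.where(
        at > ct, A_BIAS, np.where(ct > at, C_BIAS, NO_BIAS)
    ).astype(object)
    transition = [classify_transition(p, h) for p, h in zip(parent_bias, hybrid_bias)]
    truth = pd.DataFrame(
        {
            "pair_id": pair_ids,
            "planted_class": planted,
            "mu_parent_A": mu_a,
            "mu_parent_C": mu_c,
            "mu_total": total,
            "frac_A": frac_a,
            "parent_bias": parent_bias,
            "hybrid_bias": hybrid_bias,
            "transition": transition,
            "nonadditive": nonadditive,
            "silenced_A": high_parent_a,
            "silenced_C": high_parent_c,
            "novel_A": high_poly_a,
            "novel_C": high_poly_c,
        }
    )
    return SimResult(counts=cm, sheet=sheet, pairs=pairs, truth=truth)


def evaluate_recovery(
    truth_labels: pd.Series, predicted_labels: pd.Series
) -> pd.DataFrame:
    """Confusion counts with per-class recall and precision.

    Both series are indexed by pair id; the indices must coincide.
    """
    if set(truth_labels.index) != set(predicted_labels.index):
        raise ValueError("truth and prediction cover different pair ids")
    predicted = predicted_labels.reindex(truth_labels.index)
    classes = sorted(set(truth_labels) | set(predicted))
    rows = []
    for c in classes:
        planted = truth_labels == c
        called = predicted == c
        tp = int((planted & called).sum())
        n_planted = int(planted.sum())
        n_called = int(called.sum())
        rows.append(
            {
                "class": c,
                "planted": n_planted,
                "called": n_called,
                "recovered": tp,
                "recall": tp / n_planted if n_planted else 0.0,
                "precision": tp / n_called if n_called else 0.0,
            }
        )
    return pd.DataFrame(rows)


TRAIT_NAMES = (
    "flowering_time",
    "stalk_diameter",
    "plant_height",
    "fourth_leaf_length",
    "fourth_leaf_width",
    "petiole_length",
    "flower_size",
    "bud_size",
    "leaf_wings",
    "leaf_color",
    "leaf_shrinkage",
)


def simulate_traits(
    individuals: list[str],
    seed: int = 0,
    n_outliers: int = 2,
    grade_range: tuple[int, int] = (1, 5),
) -> TraitMatrix:
    """Synthetic ordinal trait grades (11 field traits, grades 1-5).

    Most individuals share a common grade profile with +/-1 jitter; the
    first ``n_outliers`` individuals get strongly shifted profiles, mimicking
    a segregating cohort in which a couple of plants diverge phenotypically.
    """
    rng = np.random.default_rng(seed)
    lo, hi = grade_range
    center = rng.integers(lo + 1, hi, size=len(TRAIT_NAMES))
    rows = {}
    for k, ind in enumerate(individuals):
        jitter = rng.integers(-1, 2, size=len(TRAIT_NAMES))
        shift = (hi - lo) // 2 + 1 if k < n_outliers else 0
        sign = 1 if k % 2 == 0 else -1
        rows[ind] = np.clip(center + jitter + sign * shift, lo, hi)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(TRAIT_NAMES))
    frame.index.name = "individual"
    return TraitMatrix(frame)
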