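# Methods

## Statistical model

All comparisons are two-group tests on replicated counts under a
negative-binomial model with variance $\mu + \alpha\mu^2$. Rather than a
Wald or likelihood-ratio GLM test, we use a **conditional exact test**: for
one unit (gene or homoeolog pair) with group counts $k_1, k_2$ and size
factors $s_1, s_2$, condition on the grand total $K = \sum k_1 + \sum k_2$,
set the common concentration $q_0 = K / (S_1 + S_2)$ with $S_g = \sum_j
s_{gj}$, and model the group sums as independent NBs with means $q_0 S_g$
and variances $q_0 S_g + \alpha q_0^2 \sum_j s_{gj}^2$. The two-sided
p-value is the total conditional probability of all splits $(a, K-a)$ whose
probability does not exceed that of the observed split (minimum-likelihood
method). Properties that anchor the tests:

* at $\alpha = 0$ the NBs degenerate to Poissons and the conditional law is
  exactly $\mathrm{Binomial}(K,\, S_2/(S_1+S_2))$ — verified exhaustively
  for all $K \le 50$;
* $K = 0$ returns $p = 1$, and identical groups return $p = 1$;
* for $K > 10{,}000$ the enumeration switches to a normal approximation of
  the conditional law (mean $q_0 S_1$, variance
  $\sigma_1^2\sigma_2^2/(\sigma_1^2+\sigma_2^2)$); at that scale the
  discrete enumeration and the Gaussian agree to well within the decision
  threshold.

Under a 10,000-gene Poisson null the empirical type-I error at nominal 0.05
is ≈ 0.044–0.046 (slightly conservative from discreteness), and BH leaves a
q < 0.05 fraction of zero.

**Normalization.** Median-of-ratios size factors (per sample, the median
over all-positive genes of count / per-gene geometric mean), rescaled to
geometric mean 1. CPM ($10^6 \cdot$ count / column sum) backs the
activation/silencing rules; FPKM ($10^9 \cdot$ count / (length × column
sum)) is available when gene lengths are supplied.

**Dispersion.** Per unit, method of moments on size-factor-normalized
counts: within-group variances are pooled and
$\hat\alpha = \max(0, (\mathrm{Var} - \bar\mu)/\bar\mu^2)$. Because a
3-replicate moment estimate is extremely noisy, each unit's final value is
$\max(\hat\alpha_{\text{own}}, \text{trend})$, the trend being the median
raw estimate of the 50 nearest units by mean expression. This floor is
deliberately conservative: it protects the equality calls (T = parent) that
the dominance classification depends on, at a small cost in power for
borderline fold changes.

**Multiple testing.** In-house BH step-up,
$q_{(i)} = \min_{j \ge i} p_{(j)} m / j$ capped at 1; DE iff $q < 0.05$
(strict). Cross-checked elementwise against brute force and statsmodels.

## Classification

The three ternary DE outcomes (A vs C, total vs A, total vs C) have 27
combinations; 13 are nameable (CONSERVED plus categories I–XII, grouped as
additive I/XII, dominance-toward-A IV/IX, dominance-toward-C II/XI,
transgressive-up V/VI/VIII, transgressive-down III/VII/X) and the remaining
14 (e.g. total equal to both parents while the parents differ) are reported
as AMBIGUOUS rather than forced into a bin. The within-group roman
numbering is fixed by a canonical table; all downstream statistics depend
only on the groups. The polyploid expression entering these comparisons is
the homoeolog-pair total $A_t + C_t$, the standard construction for
expression-level dominance; no ploidy/dosage correction is applied.

The mid-parent value is realized as pseudo-replicates: parent-A replicate
$i$ is paired with parent-C replicate $i$ (by replicate index),
$\mathrm{MPV}_i = \mathrm{round}_{1/2\uparrow}((k_{Ai}/s_{Ai} +
k_{Ci}/s_{Ci})/2)$ with size factor 1, so the same NB machinery tests the
polyploid total against MPV. The replicate pairing is arbitrary; because
replicates are exchangeable the choice only perturbs the pseudo-replicate
noise, not its mean, but results with strongly unbalanced parental
replicate quality would be sensitive to it.

Homoeolog bias in the polyploid compares $A_t$ with $C_t$ within each
replicate, both groups sharing that replicate's size factor, so depth
cancels; the parental state compares the A copy in parent A with the C
copy in parent C using the pair-level size factors. Gene-length differences
between homoeologs are ignored by default (counts compared directly); this
is a documented caveat, not a correction. Crossing parental and hybrid
states yields five transition patterns (kept / lost / novel-toward-A /
novel-toward-C / reversed); a `collapse_novel` option merges the two novel
directions for reporting.

Activation and silencing use raw-count-zero and CPM rules evaluated per
homoeolog per individual: novel iff both parents have zero reads in every
replicate and the focal homoeolog exceeds 10 CPM in every polyploid
replicate; silenced iff the corresponding parent exceeds 10 CPM in every
replicate and the polyploid has zero counts for that homoeolog. "All
replicates" is the strictest consistent reading of the rule and is the
default; a pooled-mean mode is available. Evaluating the silencing
threshold on the corresponding parent only (rather than both parents)
matches the per-subgenome SILENCE_AA / SILENCE_CC accounting; a
`require_both_parents` switch provides the stricter variant. The A-vs-C
asymmetry of silencing counts is assessed with a two-proportion chi-square.

## Synthetic cohort

The generator emulates the study design: 2 parental genotypes and 8
polyploid individuals × 3 replicates, 25,000 homoeolog pairs, NB counts
with a shared dispersion of 0.05 (estimators must not and do not assume the
sharing), and per-sample depth factors drawn log-uniformly from [0.5, 2].
Baselines are log-normal (median 500, σ_log 0.6) floored at 200 so every
planted effect rides on a well-measured gene; the planted effect is 16-fold
(log2 = 4). Class proportions default to magnitudes shaped after the real
cohort this design mimics: conserved majority (43%), additive 13%,
dominance toward A three times dominance toward C (15% vs 5%),
transgressive up above down (10% vs 4%), sub-percent silencing per
subgenome with an A/C asymmetry, and ~1.5% novel expression split evenly.

Constructions per class fix $(\mu_A, \mu_C, T)$ and the homoeolog split:
additive pairs sit at the arithmetic midpoint of 16-fold-different parents;
dominance classes pin $T$ to one parent; transgressive classes place $T$
16-fold beyond the more extreme parent; the "non-additive only" class puts
$T$ at the geometric midpoint of 256-fold-different parents (inside the
parental range — category I/XII — yet 8-fold from the arithmetic MPV).
A configurable fraction of transgressive pairs carries unequal parents
(planting parental homoeolog bias without touching class identity), and
each parentally biased pair keeps a proportional homoeolog split in the
polyploid with probability `bias_preservation` (default 0.7), else splits
50:50 and loses the bias. Silenced/novel "high" homoeologs get means of 10×
the CPM-threshold-equivalent count with draws left-truncated at 2× the
threshold count, and their zeros are exact, so the threshold rules are
recoverable by construction rather than by boundary luck.

What the generator does **not** model: homoeolog read mis-assignment,
mappability and gene-length biases between subgenomes, outlier replicates,
correlated genes, and un-paired genes outside the homoeolog table. Passing
recovery tests therefore demonstrates the correctness and calibration of
the statistical machinery under the declared model, not robustness to
alignment artifacts in real data.

## Known limitations

Two recovery properties fall short of their idealized bounds at the default
calibration, for structural reasons:

* **Additive pairs** (~0.83–0.88 recall). An additive total sits at the
  parental midpoint, so its contrast against the higher parent is at most
  $(1+e)/2e \to 2$-fold no matter how large the parental effect $e$ is.
  With dispersion 0.05 and 3 replicates that test's conditional z is ≈ 3.3
  against a BH-effective critical value ≈ 2.3, i.e. ~85% power; missed
  pairs leak into the dominance classes. Only lower dispersion or more
  replicates would close this.
* **Conserved false positives** (~6–10% vs the ~4.5% expected from three
  BH-adjusted null tests). The planted class mix is asymmetric — more
  transgressive-up than -down, dominance skewed toward A, novel genes
  present only in polyploids — so more than half of all pairs are DE in
  some comparison and median-of-ratios size factors acquire a systematic
  ±5% composition bias (parents under-, polyploids over-estimated). Every
  null total-vs-parent test is thereby shifted by ~0.6σ. This is a faithful
  reproduction of a real failure mode of ratio-based normalization at high
  DE density, not a defect of the test itself.

Other limitations: one-to-one homoeolog pairing only (greedy best-bitscore,
no synteny); no GLM designs or covariates; MPV assumes equal parental
genome contribution (1:1 AACC); GO enrichment is out of scope — the set
reports export the gene lists that downstream enrichment would consume.

## Sizes and determinism

The bundled analysis scripts use 6,000 pairs × 8 individuals (~1 min);
`scripts/acceptance.py` uses the full 25,000 pairs × 2 individuals
(~2 min). All randomness flows through one seeded PCG64 generator;
`run_all` reruns are bit-identical, and the run manifest records the
package version, parameters, seed and input checksums.
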