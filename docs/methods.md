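# Methods

This note records the models, defaults and numerical choices behind
`mhcscreen`, and what the synthetic validation does and does not show.

## Signature scoring

**GSVA-style score.** For continuous (log2-TPM) data the per-gene,
cross-sample statistic is the Gaussian-kernel CDF estimate
`z_ij = mean_k Φ((x_ij − x_ik)/h_i)` with bandwidth `h_i = sd_i/4` (sample
standard deviation, ddof = 1); for counts, plain mid-ranks. Within each
sample, genes are ordered by decreasing statistic (ties broken by input
order) and a weighted Kolmogorov–Smirnov walk is taken: hit steps
proportional to `|z|^tau` (default `tau = 1`), miss steps uniform. The
enrichment score is `v+ − v−`, the difference of the maximum positive and
maximum negative deviations, each floored at zero — the "difference of
extremes" form, which keeps scores in (−1, 1) and near zero for sets with
no coherent rank signal. A gene with zero variance under the Gaussian
kernel falls back to the rank statistic with a warning. The choice of
kernel and `tau` is recorded in provenance; neither is treated as an
empirical fact about any external dataset.

**UCell score.** Within a unit (cell, sample, cell line), genes are ranked
by decreasing expression with mid-ranks for ties; ranks above `max_rank`
(default 1500) are clipped to `max_rank + 1`. With `n` set genes present
in the data and `R` their rank sum, `U = R − n(n+1)/2` and
`score = 1 − U/(n · max_rank)`, clipped to [0, 1]. Genes absent from the
matrix are ignored, so padding a set cannot change the score; `n >
max_rank` is an error because the score is undefined there. Cell-line
scores are z-normalized across the panel (population sd) before use.

**Spearman correlation** is Pearson on mid-ranks with the
t-approximation on `n − 2` degrees of freedom. Correlations within
1e−12 of ±1 are snapped to ±1 and reported with the smallest positive
double as p-value rather than 0, so downstream log transforms stay
finite.

## Survival models

Univariate Cox proportional hazards is maximized by Newton–Raphson with
step halving on the Efron-corrected partial likelihood (tie groups
precomputed, derivative evaluations vectorized). Convergence requires
|gradient| < 1e−9 or a step below 1e−10 within 50 iterations. Monotone
likelihood is detected by either |β| > 50 or a vanishing curvature
(−hessian < 1e−8) — the gradient alone is insufficient because the
partial likelihood flattens as β runs away — and is reported through the
`converged` flag, never as a silent estimate. Wald z gives the two-sided
p-value. The Kaplan–Meier estimator handles tied events jointly and
counts same-time censorings as at risk; the log-rank test uses the
hypergeometric variance over distinct event times.

**Prognostic score.** For each endpoint (OS, DSS, PFS, TTE by default)
and each horizon in {1, 3, 5, 10, ∞} years, follow-up beyond the horizon
is converted to censoring at the horizon (events exactly at the horizon
remain events) and a Cox model is fitted on z-scored continuous
expression (a median-dichotomized mode exists behind a config flag for
sensitivity analysis). Contributions are signed unit counts gated at
p < 0.05; the score is their sum, so |score| ≤ endpoints × horizons and
the construction is antisymmetric under negating the covariate. Cells
with fewer than 20 usable samples or 5 events are recorded as skipped
with contribution 0; if every cell is skipped the score is *unavailable*
(None), not 0. A gene is "risky in a cohort" when its score is ≤ −12,
and the pan-cohort criterion is strictly more than 3 risky cohorts.

A caveat worth stating explicitly: the five horizon fits of one endpoint
are nested truncations of the same data, so their z-statistics are
correlated roughly like Brownian motion at the event-count information
fractions (adjacent horizons at ρ ≈ 0.7–0.94). Under the null the score
is therefore a sum of four independent endpoint *blocks* whose nonzero
values cluster (±2 to ±5), not of twenty independent ±1 coins: measured
on null genes, the score has mean ≈ 0 and |score| ≤ 2 in about 87% of
genes — tighter concentration would require horizons with nearly
disjoint information, which the grid deliberately does not have (it
spans short- and long-term risk of the same cohort). The −12 screening
cutoff is far outside the null bulk either way (largest null |score|
observed in 500 draws: 7).

## Deconvolution

Fractions are estimated per sample by non-negative least squares against
the marker-signature columns, then renormalized to the simplex; the
residual norm is reported per sample. This replaces a ν-SVR deconvolver
deliberately: it is deterministic, exact on noiseless mixtures, and
scale-invariant per sample, which is all the downstream correlation
filter consumes. Log-scale input is exponentiated with a warning; a real
reference matrix (e.g. LM22) can be supplied as TSV in place of the
synthetic one.

## Enrichment statistics

Differential expression is a deliberately lightweight stand-in for a
count-model fit: genes with total count < 10 are flagged and untested;
counts are normalized by median-of-ratios size factors; Welch's t is
applied on log2(normalized + 1); log2FC is the difference of group means
on that scale; BH correction is step-up with monotonicity enforcement.
Its job is to produce a defensible ranking for preranked GSEA, not to
reproduce a negative-binomial GLM — dispersion shrinkage and count-level
inference are out of scope.

Preranked GSEA uses the signed extreme deviation of the weighted KS walk
(GSEA convention — intentionally different from the per-sample scoring
walk), a gene-label permutation null (`n_perm` random same-size sets),
signed-null NES normalization, and the permutation p-value
`(1 + #{same-sign null ≥ |ES|}) / (1 + #same-sign null)`, which is
bounded below by `1/(n_perm + 1)`. Fixed seeds make results
bit-reproducible. Over-representation is the upper-tail hypergeometric
probability, BH-corrected across pathways.

## Synthetic study conditions

The generator emulates the statistical structure the screen assumes, not
any particular dataset's marginals. Defaults (the study conditions used
throughout the tests):

| parameter | default | meaning |
|---|---|---|
| samples / cohort | 500 | TCGA-like cohort size |
| cohorts | 6 | first is the focal "BRCA" cohort |
| genes | 2000 | 8 signature + 25 planted + decoys |
| planted negative regulators | 25 | expression `μ − 0.8·a + N(0,1)` |
| dual-effectors | 5 | subset of planted; essential in the panel |
| latent activity `a` | N(0, 1) per sample | interferon-activity construct |
| signature loading | +1.0 | signature genes `μ + a + N(0,1)` |
| hazard β | 0.15 per planted gene, all endpoints | exponential PH linear predictor |
| baseline hazard | 0.15 / year | median survival ≈ 4.6 years at lp = 0 |
| censoring | 30% | independent exponential, rate solved numerically |
| fraction coupling | 0.7 | added to CD8 T / NK log-weights before renormalizing |
| cell lines | 40 | dependency ~N(−0.8, 0.1) for duals, ~N(0, 0.15) otherwise |

Survival times are exponential with hazard
`λ_j = λ0 · exp(Σ_g β_g (x_gj − μ_g))` over planted genes; the censoring
rate of an independent exponential censor is calibrated by solving
`E[μ_c/(μ_c + λ_j)] = target` with Brent's method. Immune fractions come
from a Dirichlet (tumor-dominant concentration) whose CD8 T and
activated-NK log-weights are tilted by `c·a_j` before renormalization,
keeping fractions on the simplex. Single-cell samples draw a tumor-cell
proportion uniformly on (0.05, 0.95); tumor cells carry a latent
centered on the sample-level activity, the MHC-I program rises with it
(Poisson rates `exp(0.5 + 0.7·m)`), and planted-gene expression is
zero-inflated with probability falling in the latent plus an extra
dropout factor, so "expressing" cells (count > 0, matching the binary
phrasing of the validation) have lower MHC-I scores. All randomness
flows from one seed through named `SeedSequence` sub-streams.

What the generator does **not** emulate: library-size artifacts, batch
effects, realistic expression marginals, gene–gene correlation beyond
the single latent factor, non-proportional hazards, or informative
censoring. Passing the recovery tests therefore shows the cascade's
logic and statistics are sound under its stated assumptions — it does
not certify performance on real cohorts, where effect sizes are smaller
and confounding is real. Effect sizes for the planted genes are
generator calibrations, not estimates from any dataset.

## Boundary semantics and degenerate inputs

Threshold comparisons follow the printed wording literally: the
signature-correlation bound (≤ −0.15) is inclusive; the prognostic
(< −12), TIL (< −0.1), dependency (< −0.5) and risky-cohort (> 3)
comparisons are strict. Duplicate gene rows collapse by mean with a
warning; duplicate sample ids are hard errors. An empty stratum in the
expressing/non-expressing comparison raises a dedicated degenerate-case
error rather than returning 0. Times load in days or years and are
stored in years (÷365.25). The cell-line dependency aggregate across
lines is the median (the distribution, not a named aggregator, is what
the upstream analysis displays; the choice is flagged in provenance).

## Problem sizes used in validation

The default recovery experiment runs the full cascade at the study
conditions above for five seeds (~16 s per seed on one core; Cox fits
are only run for correlation-filter survivors, matching the cascade
order). Null calibrations use 500 prognostic-score draws, 1,000
log-rank simulations at n = 100, 1,000 random BH vectors, and 500 GSEA
permutation replicates at a 100-gene universe with 200 permutations
each.
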