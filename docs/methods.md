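# Methods

`omicnet` implements an integrative transcriptome–metabolome analysis for a
crossed factorial field design — varieties × locations × developmental
stages with biological replicates — as a sequence of testable stages, and
ships a synthetic-data generator that plants recoverable ground truth for
every one of them. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic benchmarks do and do not
demonstrate.

## The analysis model

**Variability filter.** Transcripts are screened before differential
analysis by the coefficient of variation CV = SD/mean, computed per feature
across all samples on the *linear* scale (the CV of log-scale values is
ill-defined near zero; `cv_scale` is configurable). A two-component
univariate Gaussian mixture is fitted to the CV distribution by EM, and
features with posterior probability ≥ 0.5 of the high-CV component are
retained. The EM uses a median-split initialization plus four random
restarts (best log-likelihood wins), a convergence tolerance of 1e-8 on the
log-likelihood, and treats a component SD collapsing below 1e-6 × data SD as
a degenerate start. The per-iteration log-likelihood is asserted
non-decreasing. Metabolites are not filtered.

**Differential analysis.** Each feature's log2 abundance is fitted by the
full factorial linear model

    y = μ + variety + location + stage
        + variety:location + variety:stage + location:stage
        + variety:location:stage + ε

with sum-to-zero contrasts. Term sums of squares are Type III (the
residual-SS increase when the term's columns are removed from the full
model), which on balanced designs reduces exactly to the classical
orthogonal decomposition; with unequal replication (real designs often have
2–3 replicates per cell) Type III is the defensible choice and a warning is
logged. The fit is vectorized — the design matrix and the QR bases of the
full and each reduced model are computed once and applied to all features as
one matrix product — so 2,000 features × 108 samples fit in well under a
second. F = (SS/df)/(SS_res/df_res), p from the F distribution; a zero
residual with a non-zero effect SS reports p = 0, all-zero SS reports NaN
with a warning.

Per factor, p-values are Benjamini–Hochberg adjusted *across features*
(factors are not pooled, mirroring per-comparison DE reporting), and a
feature is called differential when adjusted p < 0.01 AND its fold change —
the maximum absolute difference of level means, each an unweighted average
of cell means over the other two factors — is at least 2 standard deviations
of that factor's all-feature fold-change distribution. The "k SD of fold
change" rule is population-level and per-factor; both the multiplier and the
per-factor choice are configurable. The FC filter can only remove calls,
never add them, so the empirical FDR of the final call set is bounded by the
BH level.

**Co-expression modules.** Unsigned weighted adjacency a_ij = |cor(x_i,
x_j)|^β with β = 7 for both omics layers (the scale-free-topology diagnostic
is computed — equal-width connectivity bins, signed R² of the log–log
frequency/connectivity regression — and the smallest power reaching R² ≥ 0.8
is suggested, falling back to 7). Topological overlap

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

is clustered by average linkage on 1 − TOM. The tree is cut at the midpoint
of a merge-height gap: the ~10 largest gaps are scored by the number of
clusters of at least `min_size` members the cut would produce, and the best
cut wins (ties go to the larger gap). A single global largest-gap rule is
fragile in both directions — clumps of near-duplicate features create
spurious gaps at low heights, and background-dominated trees push most
merges to heights near 1, which also defeats any fixed quantile cut — while
the gap-scoring rule is deterministic and recovers planted partitions
exactly; fixed-height and quantile cuts remain available as explicit
options. Clusters of ≥ `min_size` (defaults: 30 genes, 10 metabolites)
become modules named by decreasing size in the conventional colour order
(turquoise, blue, brown, …); everything else is grey and excluded
downstream.

Each module's eigengene is the first principal component (via SVD) of its
standardized member profiles, scaled to unit variance and oriented so the
mean member correlation is non-negative. Module membership kME(f, m) is the
Pearson correlation of feature f with eigengene m, with the usual two-sided
t-test p-value (t = r√(n−2)/√(1−r²), df = n−2). An optional eigengene-merge
step is deliberately not applied by default.

**Mutual-information networks.** Per gene module, MI is estimated for every
(curated regulator) × (module member) pair by the plug-in estimator on
equal-frequency rank bins: B bins per margin, MI = Σ p̂(i,j) ln p̂(i,j)/(p̂(i)
p̂(j)) in nats. The default B = max(2, ⌊√n/3⌋) keeps the estimator's
independence bias, approximately (B−1)²/2n nats, below 0.05 at practical
sample sizes. Because binning is rank-based, the null distribution of MI
depends only on (n, B); the significance threshold for a target tail
probability (the conventional network threshold is 1e-8) is calibrated by
permutation with an exponential fit to the top 5% of the null and
extrapolation along the fitted tail — a tail probability far below 1/n_perm
is thereby reachable, and the calibration itself is verified empirically at
the reachable 1e-3 level (fresh-null exceedance within 3× binomial SE at
n_perm = 1e5). Edges above threshold are pruned by the data processing
inequality: in every fully connected triplet the weakest edge is flagged
indirect when its MI < (1 − tolerance) × min(other two); tolerance defaults
to 0. Edges are undirected; "regulator" is a labeling from the curated list,
not a causal claim.

**Integration.** Two-way Pearson correlation: each metabolite against every
gene-module eigengene, and each (module-assigned) gene against every
metabolite-module eigengene, with the t-test p at df = n−2 and a raw
p < 0.01 significance rule (no multiple-testing correction by default — a BH
flag exists). Results are tabulated per (gene module, metabolite module)
pair with counts, sign consistency, and a reciprocal-support flag: the pair
is supported when at least one member metabolite is significant against the
gene eigengene *and* at least one member gene against the metabolite
eigengene.

**Prioritization.** Five p-value channels per gene: own-module kME p; raw
factorial-ANOVA p for location, variety and stage; and the minimum p over
metabolite-module eigengene correlations ("best-correlated metabolite
module"). Fisher's combined statistic X² = −2 Σ ln p_i is referred to
chi-square with df = 2k (k = channels present; genes missing a channel are
combined over the rest). Raw, not BH-adjusted, DE p-values are combined:
adjusted p-values are not uniform under the null, which Fisher's method
assumes (a flag switches to adjusted). The score is −log10(combined p),
computed from the chi-square *log* survival function so that extreme
evidence does not saturate at the floating-point underflow limit; ranks
break ties lexicographically by gene id. Caveats, documented rather than
corrected: the channels share data and are not independent (a Brown-style
correction is out of scope), and the channel-5 minimum is not recalibrated
for selection.

**Enrichment.** One-sided Fisher's exact test (hypergeometric upper tail)
of a selected feature set against each pathway set intersected with a
declared universe — the variance-filtered transcripts by default — with BH
FDR across sets and a 5% significance level.

**QC.** Feature-centered PCA of the samples with design annotations and
variance-explained fractions; component signs are fixed deterministically
(largest-magnitude score positive).

## The synthetic-data generator

The generator emulates the statistical structure this analysis assumes,
with one seeded RNG stream so identical configurations are bit-identical:

* A full crossing of 3 varieties × 3 locations × 6 ordered stages × 2
  replicates (n = 108) by default.
* Gene modules driven by latent eigengene profiles e_m = planted factor
  effects + N(0, 0.5²). Factor effects span 2.0 log2 units (a 4-fold change
  between extreme conditions — typical of strongly condition-dependent
  transcripts): a monotone trend across stages, ±half-span offsets of the
  extreme levels for variety/location. Each module responds to a fixed
  subset of factors (the first module to all three). Members load on their
  eigengene as μ_g + λ_g e_m + N(0, σ_g²) with λ_g = u_g σ_g √(r/(1−r))/sd(e_m),
  u_g ~ U(0.8, 1.2), which makes the expected pairwise member correlation
  equal the configured `within_module_cor` (0.8) regardless of each gene's
  noise level. A member's factor signal-to-noise is therefore bounded by the
  eigengene's own effect/noise ratio — the reason the defaults put the
  effect span at 4× the latent noise SD; with substantially weaker settings
  the planted truth stops being recoverable at adjusted p < 0.01, defeating
  the generator's purpose.
* A low-variability component: a configurable fraction (0.5) of genes get
  their residual SD shrunk ×0.2 (loadings shrink proportionally), producing
  the two-component CV mixture the filter stage is built for.
* Metabolite modules coupled to gene modules: linked latents are
  sign·standardized gene eigengene + N(0, σ_link) with σ_link chosen so the
  latent correlation equals `coupling_r` (0.8); signs alternate. Unlinked
  metabolite modules get independent latents with no factor effects.
* One planted regulator: first member of the all-factor module, loading
  multiplier 1.5 (the module hub), with 8 targets generated as
  4/(1+exp(−2z)) + N(0, 0.3) of the regulator's standardized profile — a
  monotone saturating dependence that mutual information detects strongly
  while linear correlation understates in the tails, with enough dynamic
  range to pass the 2-SD fold-change filter like a genuine strong responder.
* Ground truth (module membership, per-factor DE sets, couplings, regulator
  targets, the low-CV set) is emitted as JSON, the regulator list as text,
  and the planted modules as a GMT usable as enrichment truth.

What the generator does **not** emulate: batch and array effects, probe- or
peak-level measurement structure, missing values, heavy-tailed or count
noise, correlated replicates, and module overlap (each feature belongs to at
most one true module). Passing benchmarks therefore demonstrate that the
implementation recovers the structure it models — Gaussian, additive,
block-structured — not that it is robust to everything field data can do.

## Problem sizes and benchmarks

The study-scale configuration is 2,000 genes, 500 metabolites and 108
samples; the full pipeline (including MI threshold calibration at n_perm =
1e5) completes in a few seconds on one CPU, and the test suite exercises it
end-to-end twice to assert byte-identical reruns. Statistical benchmarks
use: 20 random balanced 2×2×2×2 datasets against a hat-matrix projection
oracle (agreement to relative 1e-8); 1,000 Gaussian null features for
per-term type-I calibration; 100 planted effects among 2,000 features for
DE sensitivity/FDR; 5 planted modules of 50 among 500 features for module
recovery (ARI ≥ 0.9); 10,000 simulated CVs for EM recovery; 50 Markov-chain
replicates for DPI; and 50 small-scale pipeline replicates for regulator
prioritization. Replicate counts and feature sizes were chosen to make the
binomial/ARI tolerances meaningful while keeping each check in seconds.

## Known limitations

* The static gap-scored tree cut has no concept of nested modules; deeply
  hierarchical structure would need a dynamic cut.
* Type-III ANOVA requires every design cell to be non-empty; missing cells
  are rejected rather than approximated.
* The MI threshold extrapolation assumes an exponential right tail; it is
  validated at 1e-3 and extrapolated three to five further decades to reach
  1e-8, which is conventional but unverifiable by permutation at desk scale.
* Fisher's combination treats dependent channels as independent; combined
  p-values are rankings, not calibrated error rates.
* Correlation-based integration detects linear association only, and no
  causal direction is implied anywhere.
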