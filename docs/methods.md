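# Methods

## Problem setting

A paired two-condition design: the same subjects measured before and
after an intervention (here, the motivating case is endurance
training), with a genes × samples log2 expression matrix, per-subject
phenotype measurements, and gene-set (pathway) annotations. The goal is
to find *network rewiring* — gene pairs and gene modules whose mutual
correlation differs between conditions — and to rank candidate
regulators by how strongly their neighborhood rewires and how well
their baseline expression predicts the phenotypic response.

## Differential co-expression model

Let `C1` and `C2` be gene–gene correlation matrices computed separately
in the two conditions (Pearson on log2 values by default; Spearman
available — the correlation method is a genuine free choice, Pearson
was picked as the conventional default for log-scale array data).

* **Adjacency.** `a_ij = (|C1_ij − C2_ij|/2)^β`, diagonal zero. The
  half-difference lies in [0, 1]; β (default 6, the customary soft
  threshold for unsigned networks) suppresses small, noise-level
  correlation changes. The adjacency is unsigned: a pair that moves
  from +0.8 to −0.8 and one that moves from −0.8 to +0.8 score the
  same, because the analysis targets the magnitude of rewiring.
* **Topological overlap.**
  `T_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)` with
  `k_i = Σ_u a_iu`, `T_ii = 1`. Two genes are similar when they share
  rewired neighbors even if their direct edge is noisy; this is what
  makes module detection robust at β = 6, where individual edges are
  heavily shrunk.
* **Module detection.** Average-linkage hierarchical clustering on
  `1 − T`, cut at an absolute dissimilarity height (default 0.99);
  clusters below `min_module_size` (default 10) are left unassigned
  (label 0). The original dynamic hybrid tree-cut algorithm is not
  reimplemented: no maintained Python port is pre-installed, its exact
  parameters are not recoverable for this pipeline, and on the
  separable structures the static cut must handle (strongly rewired
  modules against an unstructured background, whose dissimilarities
  concentrate near 1) the static cut is equivalent. The cut height is
  the sensitivity knob: lower values split more aggressively.

## Permutation filters

* **Gene-pair filter.** For every within-module pair the statistic is
  `|C1_ij − C2_ij|`. The null swaps each subject's pre/post labels
  independently (a paired-design condition permutation: under the null
  of no rewiring the two conditions are exchangeable within subject)
  and recomputes both correlation matrices. P-values use the +1
  correction, `p = (1 + #{null ≥ obs}) / (n_perm + 1)`, so they are
  never zero and never below `1/(n_perm+1)`; BH correction runs across
  all tested pairs and pairs with q > 1% are removed. Genes that lose
  every within-module edge are dropped from the module by default (a
  flag keeps them, since whether the original procedure removed genes
  or only edges is ambiguous).
* **Module dispersion.** For modules A, B the dispersion
  `d(A,B) = sqrt(mean over pairs ((C1_ij − C2_ij)/2)^2)`, with
  unordered within-module pairs when A = B. The null re-partitions the
  analyzed gene universe into random clusters with the observed module
  size multiset (default 1,000 draws) and recomputes d for every
  cluster pair. Because the null scale of d depends on the module
  sizes, each observed pair is compared only against null pairs with
  the same unordered size pair — and within-module values are never
  pooled with cross-module values even at equal sizes, as they are
  different statistics. A pooled null is available behind a flag.
  Module pairs at BH q ≤ 10% become edges of the module graph.

## Paired SAM

Per gene, `r` is the mean paired difference (post − pre), `s` its
standard error, and `d = r / (s + s0)`. The fudge factor s0 is chosen
by the classic heuristic: scan s0 over percentiles of {s}, bin genes by
s, and pick the s0 minimizing the coefficient of variation of the
median absolute deviation of d across bins ("median" and fixed-value
rules are also available). The null flips the sign of each subject's
difference independently (the exact paired-design permutation);
p-values are two-sided on |d| with the +1 correction, and significance
is BH q ≤ 5%. This is a deliberate simplification of the original SAM
delta-table machinery: the analysis only ever consumes an FDR
threshold, and BH is the correction used everywhere else in the
pipeline.

## Enrichment

* **ORA.** Upper-tail hypergeometric test of a gene list against each
  set, universe = genes actually present in the expression matrix (not
  the genome — testing against measured genes avoids detection bias).
  Sets with fewer than 5 in-universe members are skipped; BH across
  tested sets; enriched means q ≤ 10% (boundary inclusive).
* **Ranked GSEA.** Weighted Kolmogorov–Smirnov running sum: hits
  advance proportionally to |score|^w (w default 1; w = 0 gives the
  classical KS statistic), misses retreat by `1/(N − N_hit)`; ES is
  the extremum, the leading edge is the hits at or before a positive
  extremum (at or after a negative one); p permutes gene labels,
  two-sided on |ES|. Where the pipeline needs "pathways linked to a
  regulator" it defaults to ORA on the FDR-selected neighbor list;
  ranked GSEA is exposed for score-ranked analyses.

## Integration graph

Typed tripartite graph over regulator genes, gene sets, phenotypes.

* Regulator → pathway: ORA of the regulator's significantly rewired
  neighborhood (per-gene score `|C1_gr − C2_gr|`, same condition-swap
  null, BH, default FDR 10%).
* Regulator → phenotype: OLS of the per-subject phenotype change
  (post − pre; percent change behind a flag) on baseline (pre)
  expression; two-sided slope p; BH across the full
  regulator × phenotype grid (the minimal global-control reading;
  per-phenotype correction would be anti-conservative here).
* Duplicate edges keep the best q; degrees are ranked descending with
  deterministic tie-break by node name.

Seed networks: per-condition correlation of every gene with a seed
gene, exact t transform `t = r sqrt((n−2)/(1−r²))` with n−2 df (chosen
over Fisher-z for small-n accuracy), BH at 5%, then ORA of the
significant genes at 10%; the seed's degree is its number of enriched
sets.

## Synthetic data

The generator states a world in which every downstream claim can be
checked against planted truth:

* **Module genes** come from one latent factor per (module, condition,
  subject): `x = σ (sqrt(ρ) f + sqrt(1−ρ) ε) + μ_gene`, so the expected
  within-module correlation equals the target ρ exactly. Latent factors
  are independent across conditions, so pairing induces no
  cross-condition structure unless planted. Modules sharing a `group`
  reuse the factor and are therefore co-rewired (their cross-module
  correlations change together).
* **Negative ρ** is realized as a two-arm module (half the genes load
  `+sqrt(|ρ|)`, half `−sqrt(|ρ|)`): mutual negative correlation of all
  pairs is not realizable beyond two genes (the minimum is −1/(k−1)).
  A consequence worth knowing: under the default sign-flip rewiring
  (+0.85 pre → −0.85 post) the within-arm pairs genuinely do not
  rewire, and the pair filter correctly removes about half of each
  module's pairs.
* **Defaults** are the stated world of the validation suite: 2,000
  genes, 40 subjects (the scale of a typical paired training cohort),
  five rewired modules of 30 genes at ±0.85 — a strong-rewiring regime
  chosen to be unambiguous at β = 6, not an estimate of any real
  cohort's effect sizes, which are unknown. Background genes are i.i.d.
  normal with per-gene baseline means ~N(8, 1.5²) on the log2 scale and
  unit noise SD.
* **Hub regulator:** one gene correlated (ρ = 0.7) with a set of
  neighbor genes in each condition; the pre- and post-neighborhoods are
  disjoint gene sets, so the hub's neighborhood rewires while
  the neighbors themselves form no detectable module.
* **Phenotypes:** per-subject change = Σ coeff × baseline driver
  expression + N(0, σ²); pre values are independent baselines, post =
  pre + change. Drivers can be sampled or named explicitly (naming the
  hub reproduces the regulator–phenotype edge).
* **Gene sets:** exact copies of planted modules/neighborhoods plus
  decoys drawn from background genes only.

What the generator does **not** emulate: probe-level artifacts, batch
effects, heteroscedastic platform noise, correlated background
structure, missing values, or realistic (weak, graded) rewiring effect
sizes. A green recovery test therefore establishes that the pipeline's
logic and calibration are correct, not that any particular real cohort
would yield the same power.

## Numerical choices

* Permutation p-values always use the +1 correction; minimum attainable
  p is `1/(n_perm+1)`. Analyses that feed BH over many tests need
  n_perm large enough that the minimum p can survive correction
  (e.g. 999 for ~2,000 regulator tests at FDR 10%).
* Correlation matrices are symmetrized and clipped to [−1, 1];
  zero-variance genes are an error, not a silent NaN.
* Quantile normalization uses the row-mean-of-sorted-values target;
  ties receive the mean of the target slots they span (exact, not
  interpolated), which makes the transform idempotent on tie-free data.
* Voronoi domains are computed by shapely and clipped to the provided
  region boundary (the edge-effect treatment; capillaries on the
  boundary are included). logSD uses the natural log — any other base
  rescales it by a constant, recorded in the output metadata.
* BH is delegated to statsmodels; an independent brute-force step-up
  implementation serves as the test oracle.

## Known limitations

* The static tree cut cannot resolve nested or weakly separated
  modules the way the dynamic hybrid cut can; for weak-rewiring data,
  lower `cut_height` and β.
* The dispersion null assumes the module-size multiset is given; it
  does not account for the selection step that produced the modules
  (the same choice the original resampling procedure makes).
* Regulator scoring is one permutation run per regulator; scoring very
  many regulators is linear in that cost.
* GSEA p-values use gene-label permutation, not subject permutation,
  and so test set membership against the given ranking only.
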