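# Methods

This note documents the models and procedures phylosym implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions used throughout.

## QC filtering

The chain runs in a fixed order: per-sample abundance cut → taxon filter →
contaminant rules → depth floor. The order matters in two places and was
chosen deliberately: the depth floor runs last so it sees fully filtered
counts (in a typical dataset it then removes every negative control), and the
abundance cut runs first so that contaminant prevalence is judged on signal
above the noise floor.

* **Abundance cut** (`min_frac`, default 0.01): a cell is zeroed when its
  count is strictly below `min_frac` times its sample's total, with the total
  taken *before* any zeroing in this step. The rule is per-sample; a column
  is dropped only when it ends up empty everywhere. A cell at exactly the
  threshold survives.
* **Taxon filter**: mitochondrial, chloroplast and non-bacterial ASVs are
  dropped, with flags derived from SILVA-style lineage strings (mitochondria
  appear as a family inside Rickettsiales, chloroplasts as an order inside
  Cyanobacteria; bacterial means domain = Bacteria).
* **Contaminant rules** (`trace_frac` 0.01, `ubiquity_frac` 1.0): applied per
  sequencing run, since each run has its own negative controls and reagent
  batch. Within a run, an ASV found in a control is treated as a contaminant
  if it is unique to the controls, or if it also occurs in at least
  `ubiquity_frac` of the run's samples (a reagent signal spread run-wide);
  its counts are then zeroed across that run. An ASV found in a control but
  only in *some* samples is retained — the report notes whether its level in
  the control was below `trace_frac` relative abundance. A run without a
  control is skipped with a warning.
* **Depth floor** (`min_depth`, default 3,000 reads): samples below the floor
  are dropped; the inequality is strict, so a 3,000-read sample stays.

The chain is idempotent, never increases a count, and emits a step-by-step
`FilterReport` whose totals are internally consistent.

## Community statistics

All three tests operate on Bray–Curtis dissimilarities of row-normalized
abundances (`scipy` computes the distances; an all-zero sample is an error).

**PERMANOVA.** The pseudo-F follows the standard partition of the Gower-
centered matrix G = −½·J·D²·J. Model terms are dummy-coded factors (an
interaction is the cell-means coding of the label combination), orthogonalized
sequentially against everything before them, so multi-term models give
sequential (Type-I) sums of squares: SS(A), SS(B|A), SS(A:B|A,B) and the
residual add up to tr(G) exactly. p-values come from free permutation of
samples, or permutation within the levels of a blocking factor when `strata`
is given; a permuted F equal to the observed one counts toward the tail
(conservative), and all Monte-Carlo p-values use the plus-one correction
(1+hits)/(1+P), giving the attainable floor 1/(P+1). A single-factor
unblocked model whose number of distinct relabelings is at most the requested
permutation count switches to complete enumeration and reports an exact p
(the observed labeling counts as one arrangement). On univariate Euclidean
input the statistic reduces to the classical one-way ANOVA F; the test suite
checks this identity to 1e-9 and validates the multi-term decomposition
against vegan's `adonis2` on a frozen fixture.

**Beta-dispersion** embeds the distance matrix by principal coordinates,
keeping axes with negative eigenvalues as imaginary axes; a sample's distance
to its group centroid is sqrt(max(0, real-part distance² − imaginary-part
distance²)), and a one-way ANOVA on those distances gives the test. Centroids
(not spatial medians) are used. When every distance is numerically zero the
result is reported as a degenerate "no dispersion" outcome instead of an
undefined F.

**SIMPER**: for groups g, h, the contribution of taxon k is the mean over
cross-group pairs (i, j) of |x_ik − x_jk| / Σ_m(x_im + x_jm). Contributions
are non-negative and sum exactly to the mean between-group Bray–Curtis
dissimilarity (a decomposition identity the tests assert to 1e-9).
Permutation p-values (default 100 permutations) shuffle samples between the
two groups of each pair.

## Co-occurrence screen

Presence means any nonzero post-QC count in the genus-collapsed table; the
preceding 1 % rule has already removed trace signal, so no extra presence
threshold is applied. The screen conditions each pair the way the study
design demands: (i) a pair is tested only if both genera occur together in at
least one (sequencing run, host species) combination; (ii) the 2×2 cells
count only samples from combinations containing both genera; (iii) genera
seen in fewer than `min_genus_samples` (default 3) samples overall are
excluded — the "overall" reading is the plainer one, and the threshold is a
parameter. Two-sided p-values use the point-probability definition of
Fisher's exact test; the odds ratio is the sample odds ratio
n₁₁n₀₀/(n₁₀n₀₁), flagged undefined whenever a cell is zero. Pairs are judged
at α = 0.05 without multiplicity adjustment, matching how such screens are
usually reported; a Benjamini–Hochberg option exists but defaults off.
Per-run 2×2 tables are kept alongside the pooled table for inspection, since
the design does not dictate whether pooling happens before or after testing.

## Phylobiome trees

Queens are collapsed to species by summing raw counts (rarefaction needs
integers, and collapse-then-rarefy follows the stated order of operations).
Each iteration rarefies every eligible species row to `depth` reads with a
multivariate-hypergeometric draw (subsampling without replacement — a row at
exactly the depth passes through unchanged), computes Bray–Curtis, and builds
a UPGMA tree. UPGMA is implemented directly so its conventions are pinned:
node heights are half the merge dissimilarity, and tied merges are broken
lexicographically on the sorted leaf-name keys, making the tree deterministic;
scipy's average-linkage heights are cross-checked in the tests. The final
tree is the UPGMA tree of the element-wise *mean* of the iteration distance
matrices — the per-iteration trees only supply support values (the fraction
of iterations containing each exact leaf-set cluster). The mean-matrix
convention was chosen over, e.g., a majority-rule consensus because it is
stable, reproducible and uses all the distance information; with
deterministic rarefaction the two coincide and every support equals 1.
Species whose totals cannot reach the depth (common in single-genus trees)
are excluded and recorded, and rows are processed in sorted-name order so the
per-iteration random draws attach to species identity — the result is
invariant to input row order. Per-iteration streams are
`default_rng([seed, iteration])`, so any single iteration is independently
reproducible.

## Tree congruence

Clusters of a rooted tree are the leaf sets below internal non-root nodes,
excluding singletons and the full leaf set; multifurcating host trees are
accepted as-is, with no arbitrary resolution. Robinson–Foulds Cluster is half
the symmetric difference of the two cluster sets; Matching Cluster pads the
smaller cluster set with empty sets and solves the minimum-cost one-to-one
matching exactly (Hungarian algorithm), with pair cost the symmetric-
difference size. Both satisfy the metric axioms, verified exhaustively over
all 105 rooted binary 5-leaf topologies.

The null model draws leaf-labeled rooted binary topologies uniformly (each
new leaf inserted on an edge — including the root edge — chosen uniformly,
labels randomly permuted); a Yule/coalescent alternative (uniform random pair
joining) is available by flag. Observed and reference trees are pruned to
their shared leaf set first (logged, since it changes the null; fewer than 4
shared leaves is an error). The observed distance is compared against R
(default 1,000) random trees: small distances mean congruence, so
p = (1 + #{null ≤ observed})/(1 + R), and the normalized score divides the
observed distance by the null mean — a value near 1 means "no better than
random", values near 0 mean strong congruence.

## Synthetic data

The generator produces the *structure* of a two-run 16S queen survey, not
reads: a pure-birth ultrametric host tree (14 species in 5 clades by
default — clades are the monophyletic groups cut at the height where that
many lineages exist); heritable genera whose species-level presence evolves
along the tree under a two-state Markov process (gain/loss rates per unit
branch length), with per-queen carriage probabilities; environmental genera
occurring independently of the tree; pairwise presence associations planted
through a 2×2 copula with a specified odds multiplier (Plackett
construction, preserving the marginals); per-run log-normal batch factors on
genus abundance weights; fixed-fraction host mitochondrial (8 %),
chloroplast and eukaryotic reads; reagent contaminants placed in negative
controls and, for the "ubiquitous" kind, in every sample of a run at 3 %;
planted sub-1 % trace ASVs; and integer depths drawn uniformly from ranges
straddling the 3,000-read floor (controls and two designated samples fall
below it, as in the study design). Within a sample the present genera share
the non-fixed mass through a Dirichlet draw around their weights
(concentration 60 by default — mild overdispersion), each genus splits its
mass over its ASVs in fixed geometric proportions, and counts are one
multinomial draw at the sample's depth. The default scenario mirrors the
study qualitatively: a near-universal dominant genus (Wolbachia-like, 55 %
weight), a clade-restricted obligate genus (Liliensternia-like) negatively
associated with a widespread gut genus (Lactobacillus-like, positively
associated with the dominant genus), a sporadic genus (Spiroplasma-like),
several environmental genera and a ubiquitous low-level gut background so
every queen yields bacterial reads.

What the generator does *not* emulate: sequencing error, chimeras, copy-
number variation, compositional correlations beyond the planted pairs, or
taxonomy misclassification. Passing tests therefore demonstrate that the
*statistics* behave correctly on data with known structure — not that any
particular biological dataset satisfies the generator's assumptions.

All randomness flows from one master seed through named substreams
(`default_rng([seed, stage, ...])`), so stages are independently reproducible
and reruns are byte-identical.

## Calibration and recovery studies

`phylosym.calibration` packages the simulation studies used in the tests and
the reproduction script, at sizes chosen to run in seconds to minutes on one
core:

* **PERMANOVA type-I**: 500 replicates of unstructured Gaussian data
  (16 samples, two groups, 999 permutations); the p-values are checked
  against Uniform(0,1) by a Kolmogorov–Smirnov test.
* **Congruence type-I**: the observed tree is itself drawn from the null.
  The study is pooled over 50 random reference trees (10 observations each,
  999-tree nulls) at 20 leaves and uses the Matching Cluster metric: RFC at
  study size takes only a handful of distinct values, so its permutation p is
  far too discrete for a KS-against-continuous-uniform check to be
  informative, while MC is quasi-continuous; pooling over references averages
  out the remaining discreteness.
* **Co-occurrence false-positive rate**: 1,000 replicates of two independent
  50 %-prevalence genera in 150 samples. Fisher's exact test is conservative
  under discreteness, so the rate sits slightly below the nominal 5 %; the
  150-sample scale (about the size of a full queen survey) keeps the
  discreteness mild.
* **Phylosymbiosis recovery**: 100 replicates of the strong-vertical-
  transmission scenario — 48 single-ASV heritable lineages with gain = loss
  = 0.25 per unit branch length, full within-species carriage, no nuisance
  structure — at 14 species / 5 clades, phylobiome at 3,000 × 100 iterations,
  congruence against 1,000 random trees. The rate of p < 0.01 is reported per
  metric. The scenario was fixed by a small design sweep over lineage counts
  and rates; around 50 moderately-evolving binary characters is where
  average-linkage recovery of a 14-leaf tree becomes reliable.
* **Association recovery**: 100 replicates of one planted synergy (odds
  multiplier 15) and one antagonism (1/15) among 50 %-prevalence genera in 60
  samples, screened through the full conditioning pipeline; a recovery
  requires significance *and* the correct odds-ratio direction.

## Numerical conventions and limitations

Ties in permutation tests count toward the tail. Floating-point comparisons
in permutation tails use a 1e-12 slack; decomposition identities are asserted
at 1e-9. UPGMA tie-breaking is lexicographic; assignment problems are solved
exactly. Known limitations: PERMANOVA supports a single blocking factor (no
nested strata); nested model formulas (factor-within-factor) are not
implemented — fit the factors as separate models instead; tree distances
ignore branch lengths by construction (cluster-based metrics); and the exact-
enumeration path for PERMANOVA applies only to single-factor unblocked
models.
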