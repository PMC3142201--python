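# Methods

## Data model

The raw unit is a peptide-level abundance ratio: labeled over unlabeled
signal of one peptide pair, tagged with protein accession, condition and
replicate.  Ratios are analyzed on their original scale by default; a log2
transform is available (`log_transform`) and applied exactly once at load
time, since ratios are multiplicative by nature but the default mirrors the
established practice of testing the ratios directly.  Stored p-values are
never capped or rounded; "> 0.99"-style displays are left to formatting.

## Differential testing

For each protein all peptide ratios are pooled across replicates (replicate
identity is not modeled; with few biological replicates every peptide
measurement is treated as an independent observation of the protein) and
grouped by condition.  Conditions with fewer than two measurements cannot
contribute a variance estimate and are dropped from that protein's series;
a protein is testable when at least two conditions remain and N ≥ k + 2.
Untestable proteins are reported but excluded from every correction family.

Four tests run per protein: one-way fixed-effects ANOVA (sums of squares
computed directly, p from the F(k−1, N−k) distribution), Kruskal–Wallis
(tie-corrected, chi-square approximation), Shapiro–Wilk on within-group
residuals pooled across groups (the normality prerequisite concerns
deviations from group means, and pooling keeps the test defined at small
per-group n), and Fligner–Killeen for variance homogeneity.  Each test is
Holm-adjusted as its own family across proteins, matching result tables
that print adjusted p-values for all four columns.  Degenerate inputs are
resolved explicitly: zero within-group variance with distinct means gives
F = ∞, p = 0; all-identical values give H = 0, p = 1; identical spread
patterns give a Fligner statistic of 0, p = 1; residual ranges of zero give
NA.

Classification precedence (the rule sets overlap): `strict_significant`
(ANOVA significant, both assumption checks pass at the same α) >
`both_lenient` (ANOVA and KW significant, an assumption violated) >
`anova_only_assumptions_violated` > `kw_only` > `not_significant`.  A
missing assumption p-value blocks strictness — an unverifiable assumption
is treated as unmet.

Concordance between ANOVA and KW uses Spearman's ρ on *raw* p-values: Holm
adjustment is a monotone but heavily tied transform that would distort
ranks.  Box–whisker summaries use linear interpolation between order
statistics for the quartiles and whiskers at the most extreme observation
within 1.5·IQR; conventions differ between softwares, so this one is fixed
and tested.

## Profiles

Aggregation takes the arithmetic mean of all peptide ratios per protein and
condition (median and trimmed mean are offered, as all three are defensible
location estimates).  Cells with fewer than `min_support` (default 2)
measurements are flagged missing; the primary pipeline drops proteins with
any missing cell.  Opt-in imputation replaces up to a per-protein budget of
missing cells with the protein's mean over observed conditions and never
alters observed cells.

## Clustering

Distances: Euclidean, or 1 − r for centered/uncentered Pearson correlation
(the conventional similarity-to-distance conversion, order-preserving).
Hierarchical clustering uses Lance–Williams agglomeration; Ward linkage is
restricted to Euclidean input and its merge heights follow the standard
convention (square root of the variance-increase recurrence applied to
squared distances).  Cut labels are renumbered by first appearance.  The
merge-distance curve reports, for each k, the height of the merge producing
k clusters; the knee estimate is the k maximizing the second difference of
heights, a numerical proxy for the visual jump.

K-means runs Lloyd iterations from centers sampled uniformly from the data,
with the within-SS checked non-increasing and emptied clusters re-seeded
from distinct highest-cost points.  Because single-start Lloyd is
init-sensitive (it splits one of three well-separated blobs in roughly a
third of starts), the default keeps the best of `n_init = 10` starts by
objective; the reproducibility protocol overrides this to a single start,
because run-to-run initialization sensitivity is exactly what that protocol
measures.

Neural gas presents the data in shuffled order for 50 epochs and moves every
center toward each datum weighted by exp(−rank/λ), with ε annealed from 0.5
to 0.005 and λ from k/2 to 0.01 (the original formulation's schedule; all
exposed as parameters).  Fuzzy C-means uses fuzzifier m = 2, membership
u_ij ∝ (1/d²)^{1/(m−1)} normalized per datum, membership^m-weighted center
updates, convergence on center shift < 1e−5, and hardening by maximal
membership with ties to the lowest index.

## Validation

Rand and adjusted Rand indexes are computed from the contingency table; the
ARI's degenerate denominator (both partitions all-singletons or single-
cluster) returns 1 for identical partitions and 0 otherwise.  The
reproducibility protocol re-runs a seed-sensitive algorithm (default 25
repetitions at k = 20) under child seeds derived deterministically from the
master seed and collects all pairwise similarities (plain Rand by default,
as in the protocol it reproduces; the cross-algorithm matrix defaults to
adjusted Rand, which is chance-corrected and hence comparable across k).
Two algorithms are contrasted with a two-sided Mann–Whitney test on the
off-diagonal values — pairwise similarities are not independent samples, so
the p-value is approximate and flagged as such here.

Validity indexes over a k-sweep (one seeded clustering per k, child seed
derived from master seed, algorithm and k): Calinski–Harabasz
[B/(k−1)]/[W/(n−k)] (maximize); Index I ((1/k)(E1/Ek)Dk)^p with p = 2
(maximize); Davies–Bouldin with root-mean-squared member-to-centroid
dispersion, matching its error-sum-of-squares instance (minimize);
Krzanowski–Lai |DIFF(k)|/|DIFF(k+1)| with DIFF(k) = (k−1)^{2/p}W(k−1) −
k^{2/p}W(k), consuming the sweep's W sequence with W(1) supplied
analytically as the total sum of squares.  The Figure of Merit leaves one
condition out, clusters on the rest, and scores the root-mean-squared
deviation of the left-out column from cluster means, summed over left-out
conditions; the adjusted form divides by sqrt((n−k)/n).  Raw FOM is defined
and exactly zero at k = n (singletons); the adjusted form is NA there, its
divisor vanishing.  Per-k failures become NA and sweeps continue.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
desk scale: 5 conditions (time points) × 3 replicates, a configurable number
of peptide measurements per protein and condition (default 12 ≈ 4 peptides ×
3 replicates), baselines uniform in [0.8, 1.2] and Gaussian noise with SD
0.1 — about a 10% coefficient of variation, typical of well-behaved
isotope-pair quantification.  Regulated proteins (default 20%) receive a
condition-dependent mean shift of 0.5 shaped as a step, monotone ramp or
transient pulse, the patterns seen in stress/starvation time courses.
Assumption violations are planted disjointly: one condition's SD × 4
(heteroscedastic) or t(df = 3) residuals rescaled to unit variance
(heavy-tailed) — both strong enough to trip the corresponding checks at the
simulated sample sizes.  Missingness acts at the protein × condition level
(0 or 1 measurements, below the support minimum).  Contaminants draw ratios
as baseline × 2^N(0,3), producing both very high and very low values as a
label swap does, hence extreme pooled variance.  Non-positive draws
(vanishingly rare outside the heavy-tailed class) are redrawn.

What the generator does *not* emulate: peptide-specific effects (shared
ionization/digestion biases across conditions), intensity-dependent
variance, correlated missingness, or run-level batch structure.  Passing
tests therefore demonstrate correctness of the statistical machinery under
its stated assumptions, not robustness to every artifact of real LC-MS/MS
data.

## Problem sizes and numerical choices

The test suite exercises calibration at 10,000 null proteins (raw rejection
rates), family-wise error control at 20 × 500 null proteins, clustering
recovery on 60 profiles in 3 blobs at 10σ separation over 20 seeds, and the
reproducibility contrast on 150 overlapping-blob profiles with k = 20 and
25 repetitions per algorithm — sizes chosen so each property is measured
with sensible statistical resolution at interactive runtimes.  All
randomness flows from explicit seeds through `numpy.random.default_rng`;
child seeds are derived via CRC32 of (master seed, stage labels), keeping
every stage reproducible and independent.  Determinism is asserted in tests
at the byte level for file outputs.

## Known limitations

Treating each peptide ratio as an independent measurement inflates the
effective sample size when peptides share systematic biases; the resulting
p-values are best read comparatively, which is how the classification and
concordance layers use them.  The Mann–Whitney reproducibility p-value
inherits the pseudo-replication caveat above.  Two-way designs, FDR-style
correction and protein-level rollup before testing are out of scope.
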