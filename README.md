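# protquant

Statistical evaluation of stable-isotope quantitative proteomics experiments:
which proteins are differentially regulated across conditions, and which
groups of proteins are co-regulated?

Metabolic labeling (e.g. growing cells on <sup>15</sup>N medium) yields, for
every identified peptide pair, an abundance ratio of labeled to unlabeled
signal — a relative measurement of the parent protein's quantity.  A time
course or condition contrast then produces, per protein, a series of ratios
*x* = {x₁ … x_N} with condition assignments *t*.  `protquant` implements a
two-part evaluation strategy for such data, aimed at analysts of microbial
stress/starvation time courses and similar designs:

**Question 1 — differential regulation.**  Every peptide ratio is treated as
an independent measurement and each protein's series is submitted to a
one-way fixed-effects ANOVA, x_i = μ + τ_{t_i} + ε_i, alongside the
non-parametric Kruskal–Wallis rank-sum test.  The ANOVA's prerequisites are
checked explicitly — Shapiro–Wilk on pooled within-group residuals
(normality) and Fligner–Killeen across conditions (variance homogeneity) —
and all four test families are corrected for multiple testing with Holm's
step-down procedure to control the family-wise error rate.  A protein is
*strictly significant* when the adjusted ANOVA p-value is below α and
neither assumption check rejects.  Agreement between ANOVA and
Kruskal–Wallis is summarized by Spearman's rank correlation of the raw
p-value vectors, and box–whisker summaries support per-protein inspection.

**Question 2 — co-regulation.**  Peptide ratios are averaged to one value
per protein and condition (proteins need at least two measurements in every
condition; mean-imputation of sparse profiles is opt-in), and the resulting
profile matrix is clustered with a battery of algorithms: hierarchical
agglomeration (single, complete, average, Ward linkage; Euclidean or
correlation distances d = 1 − r), K-means, neural gas, and fuzzy C-means.
Because no ground truth exists in real experiments, the results are
validated computationally: repeated-run reproducibility scored with the Rand
index, cross-algorithm similarity with the adjusted Rand index, and
cluster-number selection via merge-distance knees, the Calinski–Harabasz
index, Index I, the Davies–Bouldin index, the Krzanowski–Lai index and the
leave-one-condition-out Figure of Merit.

A seeded synthetic-data generator emulates the relevant structure of real
isotope-ratio datasets (condition-dependent mean profiles, heteroscedastic
and heavy-tailed proteins, under-supported cells, label-swap contaminants)
with full ground truth, so every stage is testable without any download.

## Worked example

```bash
cat > config.yaml <<'YAML'
analysis:    {alpha: 0.05, k_min: 2, k_max: 10, seed: 17}
simulation:  {n_proteins: 200, frac_regulated: 0.25, effect_size: 0.5,
              frac_heteroscedastic: 0.1, frac_heavy_tailed: 0.1,
              missing_rate: 0.05, frac_contaminant: 0.02}
validation:  {reps: 25, k: 20}
YAML
protquant run --config config.yaml --outdir run
```

prints

```
pipeline complete (proteins_in=200, peptide_records=11555, proteins_testable=200,
proteins_strict_significant=48, proteins_clustered=164); 14 artifacts in run
```

and `run/summary.json` contains (excerpt):

```json
{
  "classification_counts": {"strict_significant": 48, "both_lenient": 1,
                            "not_significant": 151},
  "spearman_rho_anova_vs_kw": 0.9497,
  "selected_k_per_index": {"krzanowski_lai": 3, "index_i": 3,
                           "calinski_harabasz": 10, "davies_bouldin": 4},
  "merge_curve_knee": 3,
  "clustering_k": 3
}
```

Reading: of 200 simulated proteins (25% regulated with a mean ratio shift of
0.5 against a noise SD of 0.1), 48 pass the strict ANOVA criterion after
Holm correction and one more is significant under both tests while violating
an ANOVA assumption; the two tests' p-values agree strongly (ρ ≈ 0.95).  164
proteins carry at least two measurements in every condition and enter
clustering; the Krzanowski–Lai index, Index I and the merge-distance knee
all select the three profile shapes (step/ramp/pulse) the generator planted.
Stage artifacts (`protein_tests.tsv`, `profiles.tsv`, `labels_*.tsv`,
`index_curves.tsv`, `rand_matrix_*.tsv`, …) are plain TSV; `manifest.json`
records config, seeds and counts.  Each stage is also available as its own
subcommand (`simulate`, `test`, `aggregate`, `cluster`, `validate`).

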