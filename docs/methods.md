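# Methods

## Scope and data model

`genevista` computes and serves per-gene summary statistics for a
replicated expression matrix: genes in rows, biological samples in
columns named `<GROUP><replicate#>`. The replicate index is parsed as
the maximal trailing run of decimal digits in the header; everything
before it is the sample-group label. Values are assumed non-negative
and already normalised (FPKM, TPM, counts-per-million, microarray
intensities); the package performs no alignment, normalisation or
batch correction, and its default statistics are intentionally the
conceptually simplest choices rather than the most powerful ones for
any given design.

Annotations arrive as a long CSV with one row per (gene, GO term),
carrying an Entrez URL and a free-text description per gene. Expression
and annotation are joined on the gene symbol by case-sensitive exact
match; a case-insensitive fallback is deliberately not applied
(predictability over recall). Genes without annotation get empty
fields; annotation-only symbols are dropped with a logged count.
Conflicting descriptions for one symbol keep the first row (logged).
Empty expression cells are treated as missing and excluded from that
gene/group's replicate count; a gene left with fewer than two observed
replicates in any group is flagged `insufficient_replicates` and its
ANOVA/SEM entries are undefined rather than silently guessed.

## Statistical model

Fitting is moment-based and closed-form, vectorised over genes:

- **Group summaries.** Mean and SEM = s/√n per (gene, group), s the
  sample standard deviation (n−1 denominator).
- **One-way ANOVA** across all k groups on the values exactly as
  supplied: F = MS_between / MS_within with df (k−1, N−k), p from the
  upper tail of the F distribution. No internal log transform is
  applied — the supplied scale is the tested scale, which keeps every
  reported number traceable to the input file. Zero-variance
  degeneracies are resolved at the boundary instead of producing NaN:
  MS_within = 0 with MS_between = 0 gives p = 1; MS_within = 0 with
  MS_between > 0 gives p = 0 and a `degenerate` flag (constant-replicate
  genes are common in zero-inflated count data, and NaN would silently
  drop them from ranking).
- **Pairwise contrasts.** For each unordered group pair, a Welch
  unequal-variance t-test (Welch–Satterthwaite df) — a robust default
  for small replicate groups — and the log2 fold change of group means
  with a pseudocount ε added to numerator and denominator. ε defaults
  to 1 expression unit and is configurable; it exists to keep ratios
  finite for zero-count genes. Same degeneracy boundary rules as the
  ANOVA.
- **Multiple testing.** Benjamini–Hochberg step-up q-values, computed
  per family: the ANOVA over all genes is one family, each pairwise
  contrast over all genes another. BH was chosen as the standard,
  assumption-light FDR procedure. NaN p-values propagate to NaN q and do
  not count toward the family size. The implementation is local (the
  step-up formula is a few lines and must handle NaN); it is verified
  against `statsmodels.stats.multitest.multipletests` in the test suite,
  and the ANOVA/Welch machinery is likewise cross-checked against
  `scipy.stats.f_oneway` / `ttest_ind` and an exhaustive label-permutation
  oracle.

The fitted results persist as a wide CSV (per-group `avg_`/`sem_`,
`anova_F/p/q`, per-contrast `log2fc_A_vs_B`/`q_A_vs_B`) plus a JSON
sidecar holding ε, the group order, the contrast list and a SHA-256
content hash of the inputs; rebuilding with unchanged inputs is a cache
hit, and a hash mismatch triggers a logged recompute.

## Filters

Six composable, pure predicates. The three text criteria (symbol,
description, GO term) use case-insensitive substring matching —
browser-style search, not regex — and are OR-combined into one search
facet; the numeric criteria (expression window, fold change vs a
reference group, maximum ANOVA q) are each AND-combined with that facet.
The expression window tests the gene's **maximum group mean**, matching
the browsing question "is this gene expressed at this level anywhere?";
this is one of several defensible semantics (any-group, all-groups) and
is called out here because it changes survivor sets. The fold-change
criterion is two-sided: a gene survives if any non-reference group is at
least min_fold up **or** down versus the reference. Flagged genes are
excluded by the q filter (logged). Results are ordered by ANOVA q
ascending with alphabetical tie-break; this canonical order also defines
"the first fifty" rows of the heatmap.

## Visualizations

Every builder returns the figure **and** the exact plotted table, so
correctness is asserted on numbers, not pixels. Choices where the
design was open:

- Dot plots share one y-range across panels so levels compare across
  genes; at most 25 panels (filter first).
- Volcano: x is the stored contrast log2FC (never recomputed), y is
  −log10 q; q = 0 points are drawn 10 % above the largest finite y.
- Gene-comparison plot: d(g, s) = log2((mean_gs+ε)/(mean_ref,s+ε));
  similarity score = mean |d| across groups (Euclidean and
  correlation-distance alternatives are exposed); diverging
  red–yellow–blue colour scale symmetric over the observed |d| range.
- Heatmap pipeline order: truncate to the first `max_rows` (default 50)
  of the incoming order → optional log2(x+ε) → optional row/column
  z-scoring (sd = 0 yields an all-zero row/column) → optional
  hierarchical clustering with Euclidean distance and complete linkage
  (configurable); black-to-yellow colour scale over the displayed range.
- PCA: genes × groups matrix of log2(mean+ε), column-centred, no
  variance scaling, SVD. Sign is fixed deterministically: within each
  component the largest-magnitude loading is positive. Scores are U·S;
  % variance explained from the squared singular values.

## Synthetic data generator

The generator emulates exactly the structure the model assumes, with
known truth: per-gene log2 baseline b_g ~ Normal(μ0, τ); a fraction π
of genes get a +δ log2 shift in **one** randomly chosen group (the
simplest identifiable structure for a one-way design); replicates are
lognormal, 2^(b + shift + Normal(0, σ)), or negative-binomial with the
matching mean and var = m + φm² for count-like data. Defaults — 1000
genes, 4 groups, 3 replicates, π = 0.1, δ = 2, μ0 = 6, τ = 2, σ = 0.5,
φ = 0.1 — describe a moderately noisy FPKM-like experiment in which the
planted shift is 4 noise-sd. Each gene receives 1–6 GO-like terms from a
fixed vocabulary; DE genes additionally carry a designated
planted-pathway term so annotation filters are checkable against truth.
Everything derives from one integer seed; identical configs produce
byte-identical files.

What the simulation does **not** emulate: library-size differences,
batch structure, gene–gene correlation, realistic mean–dispersion
trends, multi-group effects. Passing recovery tests therefore
demonstrates the statistical machinery is correct under its own
assumptions, not that the default pipeline is optimal for real RNA-seq.

A consequence worth stating: because tests run on the raw scale while
the generator's noise is multiplicative, within-group variance grows
with the mean, and power at the default conditions is ≈ 0.6–0.7 at
q ≤ 0.05 (a log-scale ANOVA on the same data would be near 1). The
realized FDR stays well under the nominal 0.05 level's BH guarantee,
and power is monotone in effect size and replication; both are asserted
in the test suite at the sizes below. The log2FC bias check runs with
ε = 0: lognormal data contain no zeros, and a nonzero pseudocount
deliberately shrinks ratios at low expression, which would measure the
pseudocount rather than the estimator.

## Numerical and testing notes

- Problem sizes used by the test suite and acceptance script: 2000-gene
  simulations for calibration/FDR checks, 300–600 genes for power
  curves, 500 genes for the filter brute-force oracle, C(8,4) = 70
  exhaustive permutations for the ANOVA oracle. The whole suite runs in
  well under a minute on one CPU.
- Degenerate-input behaviour (all-zero genes, constant replicates,
  missing cells, single-replicate groups, empty annotation files) is
  specified above and unit-tested; errors name the offending gene or
  column.
- Known limitations: no count-model DE methods (negative-binomial GLMs),
  no batch correction, no GO-graph expansion of annotation terms
  (substring match only), and no claim of numerical parity with any
  other browser implementation beyond the documented statistics.
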