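# genevista

A scriptable browser for replicated gene-expression matrices (bulk
RNA-seq FPKM/counts or microarray intensities). Small labs that publish
genome-scale expression data need a way to let colleagues ask the two
questions biologists actually ask of such data — *how is my gene
expressed across samples?* and *which transcripts differ between two
samples?* — without shipping a spreadsheet. `genevista` provides the
computational core of such a resource as a Python library and CLI:
it ingests a wide-format expression CSV plus a gene-annotation CSV,
precomputes a per-gene statistics lookup table, filters transcripts by
symbol / description / GO term / expression level / fold change /
significance, and renders the standard visualizations (dot plots,
volcano plot, gene-comparison plot, heatmap, PCA), each with an
exportable data table.

## The statistics

For gene *g* with expression values *x<sub>gij</sub>* (group *i* of *k*,
replicate *j* of *n<sub>i</sub>*), the fitted lookup table holds:

- group mean *x̄<sub>gi</sub>* and SEM *s<sub>gi</sub>/√n<sub>i</sub>*
  (*s* the sample standard deviation, *n*−1 denominator);
- one-way fixed-effects ANOVA across all groups,
  *F = MS<sub>between</sub>/MS<sub>within</sub>* with df (*k*−1, *N*−*k*),
  testing whether any group differs;
- for every pair of groups (*a*, *b*): the log2 fold change
  log2((x̄<sub>ga</sub>+ε)/(x̄<sub>gb</sub>+ε)) with pseudocount ε
  (default 1 expression unit), and a Welch unequal-variance t-test with
  Welch–Satterthwaite degrees of freedom;
- q-values by Benjamini–Hochberg step-up,
  q<sub>(i)</sub> = min<sub>j≥i</sub> p<sub>(j)</sub>·m/j, one family per
  test (the ANOVA across genes; each pairwise contrast across genes).

Tests run on expression values exactly as supplied (no internal log
transform); upstream normalisation is the user's responsibility.

## Worked example

The package ships a built-in demo: a 23-gene GTEx excerpt with two
tissues (stomach, salivary gland) and three replicates each.

```python
from genevista import ExpressionProfileModel
from genevista.demo import load_demo_dataset

model = ExpressionProfileModel(load_demo_dataset())
results = model.fit()
print(results.summary())
```

```
Expression profile statistics
==============================================
Genes:                                      23
Sample groups:                               2
Pairwise contrasts:                          1
Fold-change pseudocount:                     1
ANOVA df:                               (1, 4)
Genes with ANOVA q <= 0.05:                  0
Flagged genes:                               0
==============================================
```

Two tissues give one contrast and ANOVA df (1, 4); with three replicates
per tissue and 23 genes, no gene reaches q ≤ 0.05 after BH correction —
expected at this tiny scale. Per-gene numbers:

```python
results.group_means.at["A1BG", "STOMACH"]      # 260.667
results.group_sems.at["A1BG", "STOMACH"]       # 13.872
results.log2fc("SALIVARY_GLAND", "STOMACH")["A2M"]   # 0.454
```

A1BG averages 260.7 ± 13.9 (SEM) in stomach; A2M is ~1.37-fold higher
in salivary gland (log2 ≈ 0.45). Filtering and plotting:

```python
from genevista import FilterQuery, apply_query, heatmap

hits = apply_query(model.dataset, results, FilterQuery(expr_range=(0, 0)))
hits.genes        # ['AA06', 'AADACL2'] — the all-zero transcripts
```

From the shell, the same pipeline (see `genevista --help`):

```sh
genevista simulate --genes 500 --groups 4 --seed 7 --out demo/
genevista build --config config.yaml
genevista query --config config.yaml --go "kinase" --max-q 0.05 \
    --plot heatmap --plot volcano
```

`build` writes the lookup table (`lookup_table.csv` + a JSON sidecar
with a content hash; unchanged inputs are a cache hit). `query` writes
`summary.csv` — one row per surviving transcript with description,
Entrez link, per-group mean/SEM, ANOVA F/p/q and all pairwise
log2FC/q — plus the requested figures as PNG with their data tables as
CSV. `simulate` generates synthetic expression/annotation/truth files
with planted differential expression for end-to-end testing.

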