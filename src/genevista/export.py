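"""Downloadable artifacts: the per-gene summary CSV with Entrez links."""

from __future__ import annotations

import pandas as pd

from .ingest import Dataset
from .model import ExpressionStatsResults


def summary_frame(stats: ExpressionStatsResults, survivors,
                  dataset: Dataset | None = None) -> pd.DataFrame:
    """One row per surviving gene, in the given order: symbol,
    description, Entrez URL (empty for unannotated genes), per-group mean
    and SEM, ANOVA F/p/q and every pairwise log2fc / q column."""
    dataset = dataset or stats.dataset
    survivors = list(survivors)
    unknown = [g for g in survivors if g not in stats.group_means.index]
    if unknown:
        raise KeyError(f"genes not in the statistics table: {unknown[:5]}")
    wide = stats.to_frame().loc[survivors]
    if dataset is not None:
        ann = dataset.annotations.reindex(survivors)
        meta = pd.DataFrame({
            "description": ann["description"].fillna(""),
            "entrez_link": ann["gene_link"].fillna(""),
        }, index=wide.index)
    else:
        meta = pd.DataFrame({"description": "", "entrez_link": ""},
                            index=wide.index)
    out = pd.concat([meta, wide], axis=1)
    out.index.name = "gene"
    return out


def write_summary_csv(stats: ExpressionStatsResults, survivors, path,
                      dataset: Dataset | None = None) -> None:
    """Write the summary table as CSV; numeric columns round-trip to full
    precision through ``pandas.read_csv``."""
    summary_frame(stats, survivors, dataset).to_csv(path)
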