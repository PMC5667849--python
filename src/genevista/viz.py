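"""Deterministic builders for the five standard views of a fitted dataset.

Every builder returns a :class:`FigureBundle`: the rendered matplotlib
figure together with the exact data table it was drawn from, so tests and
downstream analysis work on the numbers rather than on pixels.

Views: per-gene dot plots of group means with SEM error bars; a volcano
plot of one pairwise contrast; a gene-comparison ("difference") view of
log2 ratios against a reference transcript; an expression heatmap capped
at the first fifty transcripts; and a PCA of transcripts over sample
groups with loadings for the first two components.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap, Normalize
from scipy.cluster.hierarchy import leaves_list, linkage

from .model import ExpressionStatsResults

MAX_DOT_PANELS = 25

#: low expression black, high expression yellow
HEAT_CMAP = LinearSegmentedColormap.from_list("black_yellow", ["black", "yellow"])
#: diverging scale for difference plots: red (down) - yellow (none) - blue (up)
DIFF_CMAP = matplotlib.colormaps["RdYlBu"]


@dataclass
class FigureBundle:
    """A rendered figure plus the table of plotted values and the options
    that produced it."""

    figure: plt.Figure
    table: pd.DataFrame
    meta: dict

    def close(self) -> None:
        plt.close(self.figure)


def render_png(bundle: FigureBundle, path, dpi: int = 150,
               table_path=None) -> None:
    """Write the bundle's figure as a PNG (and optionally its table as CSV)."""
    if dpi <= 0:
        raise ValueError("dpi must be a positive integer")
    bundle.figure.savefig(path, dpi=dpi, format="png")
    if table_path is not None:
        bundle.table.to_csv(table_path, index=False)


def _check_genes(stats: ExpressionStatsResults, genes) -> list[str]:
    genes = list(genes)
    missing = [g for g in genes if g not in stats.group_means.index]
    if missing:
        raise KeyError(f"genes not in the statistics table: {missing[:5]}")
    return genes


def dot_plot(stats: ExpressionStatsResults, genes) -> FigureBundle:
    """One panel per gene: group means with +/- SEM error bars, all panels
    sharing one y-axis range so expression levels compare across genes."""
    genes = _check_genes(stats, genes)
    if not genes:
        raise ValueError("no genes to plot")
    if len(genes) > MAX_DOT_PANELS:
        raise ValueError(
            f"{len(genes)} genes exceed the {MAX_DOT_PANELS}-panel limit; "
            "filter the gene list first"
        )
    rows = []
    for g in genes:
        for grp in stats.groups:
            rows.append((g, grp, stats.group_means.at[g, grp],
                         stats.group_sems.at[g, grp]))
    table = pd.DataFrame(rows, columns=["gene", "group", "mean", "sem"])

    upper = (table["mean"] + table["sem"].fillna(0.0)).max()
    ymax = float(upper) * 1.05 if upper > 0 else 1.0
    ncol = min(len(genes), 5)
    nrow = int(np.ceil(len(genes) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.4 * ncol, 2.2 * nrow),
                             squeeze=False, sharey=True)
    x = np.arange(len(stats.groups))
    for ax, g in zip(axes.flat, genes):
        sub = table[table["gene"] == g]
        ax.errorbar(x, sub["mean"], yerr=sub["sem"].fillna(0.0),
                    fmt="o", capsize=3, ms=4)
        ax.set_title(g, fontsize=8)
        ax.set_xticks(x, stats.groups, rotation=90, fontsize=6)
        ax.set_ylim(0, ymax)
    for ax in axes.flat[len(genes):]:
        ax.set_visible(False)
    fig.tight_layout()
    return FigureBundle(fig, table, {"kind": "dot", "ymax": ymax,
                                     "genes": genes})


def volcano_plot(stats: ExpressionStatsResults, group_a: str,
                 group_b: str) -> FigureBundle:
    """Per-gene log2 fold change of ``group_a`` vs ``group_b`` against
    -log10 of the contrast q-value; q = 0 is drawn 10% above the largest
    finite point."""
    if group_a == group_b:
        raise ValueError("volcano plot needs two distinct groups")
    lfc = stats.log2fc(group_a, group_b)
    q = stats.pairwise_q(group_a, group_b)
    with np.errstate(divide="ignore"):
        y = -np.log10(q.to_numpy(float))
    finite = np.isfinite(y)
    ceiling = y[finite].max() * 1.1 if finite.any() and y[finite].max() > 0 else 1.0
    y = np.where(np.isinf(y), ceiling, y)
    table = pd.DataFrame({
        "gene": lfc.index, "log2fc": lfc.to_numpy(float),
        "q": q.to_numpy(float), "neg_log10_q": y,
    })

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table["log2fc"], table["neg_log10_q"], s=8, alpha=0.6)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"log2 fold change ({group_a} vs {group_b})")
    ax.set_ylabel("-log10 q")
    fig.tight_layout()
    return FigureBundle(fig, table, {"kind": "volcano",
                                     "contrast": (group_a, group_b)})


def difference_plot(stats: ExpressionStatsResults, ref_gene: str,
                    order: str = "most", metric: str = "mean_abs") -> FigureBundle:
    """Compare every transcript's expression profile to one reference gene.

    For gene g and group s, d(g, s) = log2((mean_gs + eps) / (mean_ref,s
    + eps)). Points are coloured on a diverging blue (up-regulated vs the
    reference) / yellow (no difference) / red (down-regulated) scale, and
    genes are ranked by a similarity score -- by default the mean absolute
    log2 difference across groups (alternatives: ``euclidean``,
    ``correlation`` distance) -- ascending for ``order="most"`` similar,
    descending for ``"least"``.
    """
    if ref_gene not in stats.group_means.index:
        raise KeyError(f"unknown reference gene {ref_gene!r}")
    if order not in ("most", "least"):
        raise ValueError("order must be 'most' or 'least'")
    eps = stats.epsilon
    logm = np.log2(stats.group_means.to_numpy(float) + eps)
    ref = np.log2(stats.group_means.loc[ref_gene].to_numpy(float) + eps)
    d = logm - ref
    if metric == "mean_abs":
        score = np.abs(d).mean(axis=1)
    elif metric == "euclidean":
        score = np.sqrt((d ** 2).sum(axis=1))
    elif metric == "correlation":
        c = np.array([np.corrcoef(row, ref)[0, 1] if np.std(row) > 0 and
                      np.std(ref) > 0 else np.nan for row in logm])
        score = 1 - c
    else:
        raise ValueError(f"unknown similarity metric {metric!r}")

    genes = stats.group_means.index
    table = pd.DataFrame({
        "gene": np.repeat(genes, len(stats.groups)),
        "group": np.tile(stats.groups, len(genes)),
        "log2_diff": d.ravel(),
        "similarity_score": np.repeat(score, len(stats.groups)),
    })
    ranking = pd.Series(score, index=genes).sort_values(
        ascending=(order == "most"), kind="stable")
    table["rank"] = table["gene"].map(
        pd.Series(np.arange(len(ranking)), index=ranking.index))
    table = table.sort_values(["rank", "group"],
                              key=lambda s: s if s.name == "rank"
                              else s.map({g: i for i, g in
                                          enumerate(stats.groups)}),
                              kind="stable").reset_index(drop=True)

    shown = list(ranking.index[:MAX_DOT_PANELS])
    span = np.nanmax(np.abs(d)) or 1.0
    norm = Normalize(vmin=-span, vmax=span)
    ncol = min(len(shown), 5)
    nrow = int(np.ceil(len(shown) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.4 * ncol, 2.2 * nrow),
                             squeeze=False, sharey=True)
    x = np.arange(len(stats.groups))
    for ax, g in zip(axes.flat, shown):
        dg = d[genes.get_loc(g)]
        ax.scatter(x, dg, c=DIFF_CMAP(norm(dg)), s=20)
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_title(g, fontsize=8)
        ax.set_xticks(x, stats.groups, rotation=90, fontsize=6)
    for ax in axes.flat[len(shown):]:
        ax.set_visible(False)
    fig.tight_layout()
    return FigureBundle(fig, table, {
        "kind": "difference", "ref_gene": ref_gene, "order": order,
        "metric": metric, "shown": shown,
    })


@dataclass
class HeatmapOptions:
    """Display pipeline switches for :func:`heatmap`; applied in the order
    truncate -> log-transform -> normalize -> cluster."""

    normalize: str = "none"        # none | rows | columns
    cluster_rows: bool = False
    cluster_cols: bool = False
    log_transform: bool = False
    max_rows: int = 50

    def __post_init__(self) -> None:
        if self.normalize not in ("none", "rows", "columns"):
            raise ValueError("normalize must be one of none/rows/columns")
        if self.max_rows < 1:
            raise ValueError("max_rows must be >= 1")


def _zscore(mat: np.ndarray, axis: int) -> np.ndarray:
    mean = mat.mean(axis=axis, keepdims=True)
    sd = mat.std(axis=axis, ddof=0, keepdims=True)
    out = np.where(sd > 0, (mat - mean) / np.where(sd == 0, 1, sd), 0.0)
    return out


def heatmap(stats: ExpressionStatsResults, genes,
            opts: HeatmapOptions | None = None) -> FigureBundle:
    """Group-mean heatmap: transcripts as rows, sample groups as columns,
    black (low) to yellow (high).

    Only the first ``max_rows`` transcripts of the incoming order are
    displayed (pass genes in the canonical q-ascending display order);
    optional log2(x + eps) transform, row/column z-scoring, and
    hierarchical clustering (Euclidean distance, complete linkage) of
    rows and/or columns.
    """
    opts = opts or HeatmapOptions()
    genes = _check_genes(stats, genes)
    if not genes:
        raise ValueError("no genes to plot")
    genes = genes[: opts.max_rows]
    mat = stats.group_means.loc[genes, stats.groups].to_numpy(float)
    if opts.log_transform:
        mat = np.log2(mat + stats.epsilon)
    if opts.normalize == "rows":
        mat = _zscore(mat, axis=1)
    elif opts.normalize == "columns":
        mat = _zscore(mat, axis=0)
    row_order = np.arange(len(genes))
    col_order = np.arange(len(stats.groups))
    if opts.cluster_rows and len(genes) > 1:
        row_order = leaves_list(linkage(mat, method="complete",
                                        metric="euclidean"))
    if opts.cluster_cols and len(stats.groups) > 1:
        col_order = leaves_list(linkage(mat.T, method="complete",
                                        metric="euclidean"))
    mat = mat[np.ix_(row_order, col_order)]
    row_labels = [genes[i] for i in row_order]
    col_labels = [stats.groups[j] for j in col_order]
    table = pd.DataFrame(mat, index=pd.Index(row_labels, name="gene"),
                         columns=col_labels)

    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(col_labels),
                                    1 + 0.16 * len(row_labels)))
    im = ax.imshow(mat, aspect="auto", cmap=HEAT_CMAP)
    ax.set_xticks(np.arange(len(col_labels)), col_labels, rotation=90,
                  fontsize=6)
    ax.set_yticks(np.arange(len(row_labels)), row_labels, fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    return FigureBundle(fig, table, {
        "kind": "heatmap", "options": opts, "row_order": row_labels,
        "col_order": col_labels,
    })


def pca_plot(stats: ExpressionStatsResults, genes) -> FigureBundle:
    """PCA of transcripts over sample groups.

    The genes x groups matrix of log2(mean + eps) is column-centred (each
    group's mean across the selected genes removed), decomposed by SVD
    without variance scaling, and gene scores on the first two components
    are scattered with the % variance explained on each axis; a second
    panel shows the PC1/PC2 loadings per group. Within each component the
    largest-magnitude loading is made positive, fixing the sign
    deterministically.
    """
    genes = _check_genes(stats, genes)
    if len(genes) < 3:
        raise ValueError("PCA needs at least 3 genes")
    if len(stats.groups) < 2:
        raise ValueError("PCA needs at least 2 sample groups")
    X = np.log2(stats.group_means.loc[genes, stats.groups].to_numpy(float)
                + stats.epsilon)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading of each PC is positive
    for j in range(len(s)):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U * s
    loadings = Vt.T                      # groups x components, unit columns
    total = (s ** 2).sum()
    var_pct = (s ** 2) / total * 100 if total > 0 else np.zeros_like(s)

    table = pd.DataFrame({
        "gene": genes,
        "pc1": scores[:, 0],
        "pc2": scores[:, 1] if scores.shape[1] > 1 else 0.0,
    })
    loading_frame = pd.DataFrame(
        loadings[:, :2] if loadings.shape[1] > 1 else
        np.column_stack([loadings[:, 0], np.zeros(len(stats.groups))]),
        index=pd.Index(stats.groups, name="group"), columns=["pc1", "pc2"],
    )

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4),
                                   gridspec_kw={"width_ratios": [2, 1]})
    ax1.scatter(table["pc1"], table["pc2"], s=10, alpha=0.6)
    ax1.set_xlabel(f"PC1 ({var_pct[0]:.1f}% variance)")
    ax1.set_ylabel(f"PC2 ({var_pct[1]:.1f}% variance)"
                   if len(var_pct) > 1 else "PC2")
    x = np.arange(len(stats.groups))
    w = 0.35
    ax2.bar(x - w / 2, loading_frame["pc1"], w, label="PC1")
    ax2.bar(x + w / 2, loading_frame["pc2"], w, label="PC2")
    ax2.set_xticks(x, stats.groups, rotation=90, fontsize=6)
    ax2.set_ylabel("loading")
    ax2.legend(fontsize=7)
    fig.tight_layout()
    return FigureBundle(fig, table, {
        "kind": "pca",
        "variance_explained_pct": var_pct,
        "loadings": loading_frame,
        "scores": scores,
        "all_loadings": loadings,
        "singular_values": s,
    })
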