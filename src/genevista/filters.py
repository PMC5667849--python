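"""Composable transcript filters over a Dataset + fitted statistics.

Six criteria, all pure functions returning gene sets: browser-style
case-insensitive substring search on symbol, description or GO terms;
an expression-level window; a fold-change threshold against a chosen
reference group; and a maximum ANOVA q-value. :func:`apply_query`
combines them: the three text criteria form one search facet (a gene
matching ANY active text criterion survives the facet), which is then
intersected (AND) with each numeric criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .ingest import Dataset
from .model import FLAG_OK, ExpressionStatsResults

logger = logging.getLogger(__name__)


@dataclass
class FilterQuery:
    """A conjunction of filter criteria; unset fields are inactive and an
    all-empty query selects every gene."""

    symbols: list[str] = field(default_factory=list)
    description_terms: list[str] = field(default_factory=list)
    go_terms: list[str] = field(default_factory=list)
    expr_range: tuple[float, float] | None = None   # (lo, hi) expression units
    fc: tuple[str, float] | None = None             # (ref_group, min_fold >= 1)
    max_q: float | None = None

    def __post_init__(self) -> None:
        if self.expr_range is not None:
            lo, hi = self.expr_range
            if lo > hi:
                raise ValueError(f"expression range lo ({lo}) exceeds hi ({hi})")
        if self.fc is not None and self.fc[1] < 1:
            raise ValueError("min_fold must be >= 1")
        if self.max_q is not None and not 0 < self.max_q <= 1:
            raise ValueError("max_q must lie in (0, 1]")

    @property
    def text_active(self) -> bool:
        return bool(self.symbols or self.description_terms or self.go_terms)

    def to_dict(self) -> dict:
        return {
            "symbols": list(self.symbols),
            "description_terms": list(self.description_terms),
            "go_terms": list(self.go_terms),
            "expr_range": list(self.expr_range) if self.expr_range else None,
            "fc": [self.fc[0], self.fc[1]] if self.fc else None,
            "max_q": self.max_q,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterQuery":
        return cls(
            symbols=list(d.get("symbols") or []),
            description_terms=list(d.get("description_terms") or []),
            go_terms=list(d.get("go_terms") or []),
            expr_range=tuple(d["expr_range"]) if d.get("expr_range") else None,
            fc=(d["fc"][0], float(d["fc"][1])) if d.get("fc") else None,
            max_q=d.get("max_q"),
        )

    @classmethod
    def from_yaml(cls, text: str) -> "FilterQuery":
        return cls.from_dict(yaml.safe_load(text) or {})


@dataclass
class FilterResult:
    """Surviving genes in display order plus an audit trail of survivor
    counts after each applied criterion."""

    genes: list[str]
    counts: dict[str, int]

    def __len__(self) -> int:
        return len(self.genes)


def _matches_any(text: str, terms: list[str]) -> bool:
    low = text.lower()
    return any(t.lower() in low for t in terms)


def filter_by_symbol(ds: Dataset, terms: list[str]) -> set[str]:
    """Genes whose symbol contains any search term (case-insensitive)."""
    return {g for g in ds.genes if _matches_any(g, terms)}


def filter_by_description(ds: Dataset, terms: list[str]) -> set[str]:
    """Genes whose merged description contains any term; genes without a
    description never match."""
    desc = ds.annotations["description"]
    return {g for g in ds.genes if desc[g] and _matches_any(desc[g], terms)}


def filter_by_go(ds: Dataset, terms: list[str]) -> set[str]:
    """Genes with at least one GO term containing any search term."""
    go = ds.annotations["go_terms"]
    return {
        g for g in ds.genes
        if any(_matches_any(term, terms) for term in go[g])
    }


def filter_by_expression_range(stats: ExpressionStatsResults,
                               lo: float, hi: float) -> set[str]:
    """Genes whose highest group mean lies in [lo, hi]: "is this gene
    expressed at this level in any sample group?"."""
    if not 0 <= lo <= hi:
        raise ValueError("require 0 <= lo <= hi")
    peak = stats.group_means.max(axis=1)
    return set(peak.index[(peak >= lo) & (peak <= hi)])


def filter_by_fold_change(stats: ExpressionStatsResults, ref_group: str,
                          min_fold: float) -> set[str]:
    """Genes up- or down-regulated at least ``min_fold``-fold in some
    group relative to ``ref_group`` (pseudocounted ratio, two-sided)."""
    if ref_group not in stats.groups:
        raise ValueError(
            f"unknown reference group {ref_group!r}; valid groups: {stats.groups}"
        )
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    thresh = np.log2(min_fold)
    survivors: set[str] = set()
    for g in stats.groups:
        if g == ref_group:
            continue
        lfc = stats.log2fc(g, ref_group)
        survivors |= set(lfc.index[np.abs(lfc) >= thresh])
    return survivors


def filter_by_qvalue(stats: ExpressionStatsResults, max_q: float) -> set[str]:
    """Genes with ANOVA q <= max_q; genes flagged degenerate or with
    undefined ANOVA are excluded (logged)."""
    if not 0 < max_q <= 1:
        raise ValueError("max_q must lie in (0, 1]")
    ok = stats.anova["flag"] == FLAG_OK
    dropped = int((~ok).sum())
    if dropped:
        logger.info("q-value filter excluding %d flagged genes", dropped)
    keep = ok & (stats.anova["q"] <= max_q)
    return set(stats.anova.index[keep])


def display_order(stats: ExpressionStatsResults, genes) -> list[str]:
    """Canonical display order: ANOVA q ascending, ties (and undefined q)
    broken alphabetically by symbol."""
    q = stats.anova["q"]
    return sorted(genes, key=lambda g: (np.isnan(q[g]), q[g], g))


def apply_query(ds: Dataset, stats: ExpressionStatsResults,
                query: FilterQuery) -> FilterResult:
    """Evaluate a full query: OR within the text facet, AND across facets;
    result ordered by :func:`display_order`."""
    survivors = set(ds.genes)
    counts: dict[str, int] = {"input": len(survivors)}

    if query.text_active:
        text_hits: set[str] = set()
        if query.symbols:
            text_hits |= filter_by_symbol(ds, query.symbols)
        if query.description_terms:
            text_hits |= filter_by_description(ds, query.description_terms)
        if query.go_terms:
            text_hits |= filter_by_go(ds, query.go_terms)
        survivors &= text_hits
        counts["text"] = len(survivors)
    if query.expr_range is not None:
        survivors &= filter_by_expression_range(stats, *query.expr_range)
        counts["expression_range"] = len(survivors)
    if query.fc is not None:
        survivors &= filter_by_fold_change(stats, *query.fc)
        counts["fold_change"] = len(survivors)
    if query.max_q is not None:
        survivors &= filter_by_qvalue(stats, query.max_q)
        counts["max_q"] = len(survivors)

    return FilterResult(genes=display_order(stats, survivors), counts=counts)
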