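"""Parsing and validation of the two input CSV dialects.

Two files feed the pipeline:

* a wide-format **expression CSV**: one row per gene, a gene-identifier
  column (``gene`` or ``Symbol``) followed by one column per biological
  sample, named ``<GROUP><replicate#>`` (e.g. ``STOMACH1`` ... ``STOMACH3``,
  ``SALIVARY_GLAND1`` ...); cells hold non-negative expression values
  (counts, FPKM, TPM -- whatever the upstream normalisation produced);
* an **annotation CSV** with columns ``geneLink``, ``GO``, ``Symbol``,
  ``description`` and one row per (gene, GO term).

Both are merged on the official gene symbol (case-sensitive exact match)
into a :class:`Dataset`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_ID_COLUMNS = ("gene", "Symbol")

_TRAILING_DIGITS = re.compile(r"^(.*?)(\d+)$")


class FormatError(ValueError):
    """An input file violates the expected CSV dialect."""


@dataclass(frozen=True)
class SampleColumn:
    """A sample-column header split into its group label and replicate index."""

    group: str
    replicate: int

    def __post_init__(self) -> None:
        if not self.group or self.group[-1].isdigit():
            raise FormatError(f"invalid group label {self.group!r}")
        if self.replicate < 1:
            raise FormatError(f"replicate index must be >= 1, got {self.replicate}")

    def header(self) -> str:
        """The wide-CSV column header this object round-trips to."""
        return f"{self.group}{self.replicate}"


def parse_column_name(header: str) -> SampleColumn:
    """Split a sample header into (group, replicate).

    The replicate index is the maximal trailing run of decimal digits;
    everything before it is the group label. ``"SALIVARY_GLAND3"`` ->
    ``SampleColumn("SALIVARY_GLAND", 3)``.

    Raises :class:`FormatError` if the header has no trailing digits or
    nothing precedes them.
    """
    m = _TRAILING_DIGITS.match(header)
    if m is None:
        raise FormatError(
            f"sample column {header!r} has no trailing replicate number"
        )
    group, digits = m.group(1), m.group(2)
    if not group:
        raise FormatError(f"sample column {header!r} has an empty group label")
    return SampleColumn(group=group, replicate=int(digits))


class ExpressionMatrix:
    """Genes x samples matrix with columns labelled (group, replicate).

    ``data`` is a DataFrame indexed by gene symbol with a two-level column
    MultiIndex ``(group, replicate)``. Missing cells are NaN and are
    excluded from per-group replicate counts downstream.
    """

    def __init__(self, data: pd.DataFrame, group_order: list[str] | None = None):
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()][0]
            raise FormatError(f"duplicate gene symbol {dup!r}")
        if group_order is None:
            seen: dict[str, None] = {}
            for g, _ in data.columns:
                seen.setdefault(g, None)
            group_order = list(seen)
        counts = {g: len(data[g].columns) for g in group_order}
        for g, n in counts.items():
            if n < 2:
                raise FormatError(
                    f"group {g!r} has only {n} replicate; at least 2 are "
                    "required for SEM and ANOVA"
                )
            reps = list(data[g].columns)
            if len(set(reps)) != len(reps):
                raise FormatError(f"group {g!r} has duplicate replicate indices")
        vals = data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise FormatError("expression values must be non-negative")
        if np.isinf(vals).any():
            raise FormatError("expression values must be finite")
        self.data = data
        self.groups = list(group_order)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_genes(self) -> int:
        return len(self.data.index)

    def columns(self) -> list[SampleColumn]:
        return [SampleColumn(g, int(r)) for g, r in self.data.columns]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ExpressionMatrix {self.n_genes} genes x "
            f"{self.data.shape[1]} samples ({len(self.groups)} groups)>"
        )


def read_expression_csv(path) -> ExpressionMatrix:
    """Read a wide-format expression CSV into an :class:`ExpressionMatrix`.

    The first column must be the gene identifier (header ``gene`` or
    ``Symbol``); every other header must parse via
    :func:`parse_column_name`. Empty cells become NaN (missing replicate);
    non-numeric or negative cells are format errors naming the offending
    row and column.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise FormatError("expression CSV needs a gene column plus sample columns")
    gene_col = raw.columns[0]
    if gene_col not in GENE_ID_COLUMNS:
        raise FormatError(
            f"first column must be one of {GENE_ID_COLUMNS}, got {gene_col!r}"
        )
    sample_cols = [parse_column_name(h) for h in raw.columns[1:]]

    genes = raw[gene_col].astype(str)
    dup_mask = genes.duplicated()
    if dup_mask.any():
        raise FormatError(f"duplicate gene symbol {genes[dup_mask].iloc[0]!r}")

    values = np.full((len(raw), len(sample_cols)), np.nan)
    for j, header in enumerate(raw.columns[1:]):
        col = raw[header].str.strip()
        blank = col == ""
        try:
            nums = pd.to_numeric(col.where(~blank))
        except (ValueError, TypeError):
            bad = col[~blank][pd.to_numeric(col[~blank], errors="coerce").isna()]
            raise FormatError(
                f"non-numeric value {bad.iloc[0]!r} in column {header!r}, "
                f"gene {genes.iloc[bad.index[0]]!r}"
            ) from None
        neg = nums < 0
        if neg.any():
            i = int(np.flatnonzero(neg.to_numpy())[0])
            raise FormatError(
                f"negative value in column {header!r}, gene {genes.iloc[i]!r}"
            )
        values[:, j] = nums.to_numpy(dtype=float)

    columns = pd.MultiIndex.from_tuples(
        [(c.group, c.replicate) for c in sample_cols], names=["group", "replicate"]
    )
    data = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=columns)
    seen: dict[str, None] = {}
    for c in sample_cols:
        seen.setdefault(c.group, None)
    return ExpressionMatrix(data, group_order=list(seen))


def write_expression_csv(matrix: ExpressionMatrix, path) -> None:
    """Write the matrix back in the wide dialect, headers reconstructed
    as ``<GROUP><replicate#>``; round-trips through
    :func:`read_expression_csv` exactly."""
    out = matrix.data.copy()
    out.columns = [SampleColumn(g, int(r)).header() for g, r in out.columns]
    # integers print without a trailing ".0" so a written file matches its source
    out = out.map(lambda v: int(v) if v == int(v) else v, na_action="ignore")
    out.index.name = "gene"
    out.to_csv(path)


ENTREZ_TERM_MARKER = "?term="


def _entrez_id(link: str) -> str:
    pos = link.find(ENTREZ_TERM_MARKER)
    return link[pos + len(ENTREZ_TERM_MARKER):] if pos >= 0 else ""


class AnnotationTable:
    """Per-symbol annotation records: Entrez link/ID, description, GO terms.

    ``records`` is a DataFrame indexed by symbol with columns
    ``gene_link``, ``entrez_id``, ``description``, ``go_terms`` (a frozenset
    of term strings).
    """

    REQUIRED_COLUMNS = ("geneLink", "GO", "Symbol", "description")

    def __init__(self, records: pd.DataFrame):
        self.records = records

    @property
    def symbols(self) -> list[str]:
        return list(self.records.index)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.records.index

    def go_terms(self, symbol: str) -> frozenset[str]:
        if symbol in self.records.index:
            return self.records.at[symbol, "go_terms"]
        return frozenset()

    @classmethod
    def empty(cls) -> "AnnotationTable":
        return cls(
            pd.DataFrame(
                columns=["gene_link", "entrez_id", "description", "go_terms"],
                index=pd.Index([], name="Symbol"),
            )
        )


def read_annotation_csv(path) -> AnnotationTable:
    """Read the long-format annotation CSV (one row per gene x GO term).

    Rows sharing a Symbol are aggregated: GO terms are unioned; the link
    and description come from the first row (conflicting descriptions are
    logged). Rows with an empty Symbol are skipped with a warning.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in AnnotationTable.REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"annotation CSV is missing column(s): {missing}")
    blank = raw["Symbol"].str.strip() == ""
    if blank.any():
        logger.warning("skipping %d annotation rows with empty Symbol", blank.sum())
        raw = raw[~blank]
    if raw.empty:
        return AnnotationTable.empty()

    rows = []
    for symbol, grp in raw.groupby("Symbol", sort=False):
        descriptions = grp["description"].unique()
        if len(descriptions) > 1:
            logger.warning(
                "symbol %s has %d distinct descriptions; keeping the first",
                symbol, len(descriptions),
            )
        link = grp["geneLink"].iloc[0]
        go = frozenset(t for t in grp["GO"] if t.strip())
        rows.append((symbol, link, _entrez_id(link), descriptions[0], go))
    records = pd.DataFrame(
        rows, columns=["Symbol", "gene_link", "entrez_id", "description", "go_terms"]
    ).set_index("Symbol")
    return AnnotationTable(records)


@dataclass
class Dataset:
    """Expression matrix merged with annotations on the gene symbol.

    ``annotations`` has one row per expression gene, in expression order;
    genes absent from the annotation file carry empty fields. Symbols that
    appear only in the annotation file are dropped (their count is logged).
    """

    expr: ExpressionMatrix
    annot: AnnotationTable
    annotations: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        genes = self.expr.data.index
        merged = self.annot.records.reindex(genes)
        merged["gene_link"] = merged["gene_link"].fillna("")
        merged["entrez_id"] = merged["entrez_id"].fillna("")
        merged["description"] = merged["description"].fillna("")
        merged["go_terms"] = merged["go_terms"].apply(
            lambda v: v if isinstance(v, frozenset) else frozenset()
        )
        dropped = len(set(self.annot.records.index) - set(genes))
        if dropped:
            logger.info("dropped %d annotation-only symbols with no expression data", dropped)
        self.annotations = merged

    @property
    def genes(self) -> list[str]:
        return self.expr.genes

    @property
    def groups(self) -> list[str]:
        return self.expr.groups


def merge(expr: ExpressionMatrix, annot: AnnotationTable) -> Dataset:
    """Join expression and annotation tables on the gene symbol
    (case-sensitive exact match)."""
    return Dataset(expr=expr, annot=annot)


def load_dataset(expression_path, annotation_path=None) -> Dataset:
    """Convenience: read both CSVs and merge. ``annotation_path=None``
    yields a dataset with all-empty annotations."""
    expr = read_expression_csv(expression_path)
    annot = (
        read_annotation_csv(annotation_path)
        if annotation_path is not None
        else AnnotationTable.empty()
    )
    return merge(expr, annot)
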