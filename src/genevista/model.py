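"""Per-gene summary statistics for replicated expression matrices.

The model answers, for every gene in a dataset of ``k`` sample groups with
replicates: what is the mean expression and its standard error in each
group; do the group means differ at all (one-way fixed-effects ANOVA,
F = MS_between / MS_within); and for every pair of groups, how large is
the shift (log2 fold change of group means, with a pseudocount) and is it
significant (Welch two-sample t-test)? p-values are converted to q-values
by Benjamini–Hochberg, one family per test: the ANOVA across all genes,
and each pairwise contrast across all genes.

All tests run on expression values exactly as supplied (no internal log
transform): the intended inputs are already-normalised units such as FPKM,
and testing on the supplied scale keeps the browser's numbers traceable
to the input file.

The fitted :class:`ExpressionStatsResults` is the "lookup table" every
downstream filter and plot reads; it persists to a wide CSV plus a JSON
sidecar and is reloaded instead of recomputed when the input content hash
matches.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ingest import Dataset, load_dataset

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 1.0

#: degeneracy flags attached to per-gene results
FLAG_OK = ""
FLAG_DEGENERATE = "degenerate"          # zero within-group variance, nonzero effect
FLAG_INSUFFICIENT = "insufficient_replicates"   # < 2 observed values in some group


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    On the ascending-sorted p-vector, q_(i) = min_{j >= i} p_(j) * m / j,
    clipped to 1 and mapped back to the input order. NaN entries propagate
    to NaN and do not count toward m.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if pv.size == 0:
        return q
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[ok] = out
    return q


def _group_moments(dataset: Dataset):
    """Per (gene, group) replicate count, mean and sample variance (ddof=1)."""
    data = dataset.expr.data
    by_group = data.T.groupby(level="group", sort=False)
    ns = by_group.count().T[dataset.groups]
    means = by_group.mean().T[dataset.groups]
    variances = by_group.var(ddof=1).T[dataset.groups]
    return ns, means, variances


class ExpressionStatsResults:
    """Fitted per-gene statistics: the precomputed lookup table.

    Attributes
    ----------
    group_ns, group_means, group_sems : DataFrame (genes x groups)
        Observed replicate counts, group means, standard errors of the
        mean (s / sqrt(n), NaN where n < 2).
    anova : DataFrame (genes x [F, df_between, df_within, p, q, flag])
        One-way ANOVA across all groups; q is BH-adjusted across genes.
    pairwise : dict[(group_a, group_b)] -> DataFrame
        One frame per unordered group pair, columns
        [log2fc, t, df, p, q, flag]; log2fc is group_a relative to
        group_b, and BH runs across genes within the contrast.
    epsilon : float
        Pseudocount added to both group means before the fold-change
        ratio, in expression units.
    """

    def __init__(self, dataset: Dataset | None, *, groups, group_ns, group_means,
                 group_sems, anova, pairwise, epsilon, input_hash=None):
        self.dataset = dataset
        self.groups = list(groups)
        self.group_ns = group_ns
        self.group_means = group_means
        self.group_sems = group_sems
        self.anova = anova
        self.pairwise = pairwise
        self.epsilon = float(epsilon)
        self.input_hash = input_hash

    # -- accessors -------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.group_means.index)

    @property
    def contrasts(self) -> list[tuple[str, str]]:
        return list(self.pairwise)

    def _contrast_frame(self, a: str, b: str) -> tuple[pd.DataFrame, float]:
        if (a, b) in self.pairwise:
            return self.pairwise[(a, b)], 1.0
        if (b, a) in self.pairwise:
            return self.pairwise[(b, a)], -1.0
        raise KeyError(f"no contrast between {a!r} and {b!r}; groups: {self.groups}")

    def log2fc(self, group: str, ref: str) -> pd.Series:
        """log2((mean_group + eps) / (mean_ref + eps)); antisymmetric in
        its arguments."""
        if group == ref:
            return pd.Series(0.0, index=self.group_means.index, name="log2fc")
        frame, sign = self._contrast_frame(group, ref)
        return sign * frame["log2fc"]

    def fold_change(self, group: str, ref: str) -> pd.Series:
        return 2.0 ** self.log2fc(group, ref)

    def pairwise_q(self, a: str, b: str) -> pd.Series:
        frame, _ = self._contrast_frame(a, b)
        return frame["q"]

    # -- tables ----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """The wide lookup table: ``avg_<G>``, ``sem_<G>`` per group,
        ``anova_F/p/q``, and ``log2fc_<A>_vs_<B>`` / ``q_<A>_vs_<B>`` per
        contrast, one row per gene."""
        parts = {}
        for g in self.groups:
            parts[f"avg_{g}"] = self.group_means[g]
            parts[f"sem_{g}"] = self.group_sems[g]
        parts["anova_F"] = self.anova["F"]
        parts["anova_p"] = self.anova["p"]
        parts["anova_q"] = self.anova["q"]
        for (a, b), frame in self.pairwise.items():
            parts[f"log2fc_{a}_vs_{b}"] = frame["log2fc"]
            parts[f"q_{a}_vs_{b}"] = frame["q"]
        out = pd.DataFrame(parts)
        out.index.name = "gene"
        return out

    def summary(self) -> str:
        """A short fit report in the style of regression results tables."""
        n_sig = int((self.anova["q"] <= 0.05).sum())
        n_flag = int((self.anova["flag"] != FLAG_OK).sum())
        lines = [
            "Expression profile statistics",
            "=" * 46,
            f"{'Genes:':<28}{len(self.genes):>18}",
            f"{'Sample groups:':<28}{len(self.groups):>18}",
            f"{'Pairwise contrasts:':<28}{len(self.pairwise):>18}",
            f"{'Fold-change pseudocount:':<28}{self.epsilon:>18g}",
            f"{'ANOVA df:':<28}" + f"({int(self.anova['df_between'].iloc[0])}, "
            f"{int(self.anova['df_within'].iloc[0])})".rjust(18)
            if len(self.anova) else "",
            f"{'Genes with ANOVA q <= 0.05:':<28}{n_sig:>18}",
            f"{'Flagged genes:':<28}{n_flag:>18}",
            "=" * 46,
        ]
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Persist as ``<path>`` (wide CSV) + ``<path>.meta.json`` sidecar."""
        path = Path(path)
        wide = self.to_frame()
        flags = pd.DataFrame({"anova_flag": self.anova["flag"]})
        for (a, b), frame in self.pairwise.items():
            flags[f"flag_{a}_vs_{b}"] = frame["flag"]
        for g in self.groups:
            flags[f"n_{g}"] = self.group_ns[g]
        pd.concat([wide, flags], axis=1).to_csv(path)
        meta = {
            "epsilon": self.epsilon,
            "groups": self.groups,
            "contrasts": [list(c) for c in self.pairwise],
            "input_hash": self.input_hash,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1)
        )

    @classmethod
    def load(cls, path, dataset: Dataset | None = None) -> "ExpressionStatsResults":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        table = pd.read_csv(path, index_col="gene", keep_default_na=False,
                            na_values=[""])
        groups = meta["groups"]
        means = pd.DataFrame({g: table[f"avg_{g}"] for g in groups})
        sems = pd.DataFrame({g: table[f"sem_{g}"] for g in groups})
        ns = pd.DataFrame({g: table[f"n_{g}"] for g in groups})
        flag = table["anova_flag"].fillna("").astype(str)
        anova = pd.DataFrame({
            "F": table["anova_F"], "p": table["anova_p"], "q": table["anova_q"],
            "df_between": len(groups) - 1,
            "df_within": ns.sum(axis=1) - len(groups),
            "flag": flag,
        })
        pairwise = {}
        for a, b in (tuple(c) for c in meta["contrasts"]):
            pairwise[(a, b)] = pd.DataFrame({
                "log2fc": table[f"log2fc_{a}_vs_{b}"],
                "q": table[f"q_{a}_vs_{b}"],
                "flag": table[f"flag_{a}_vs_{b}"].fillna("").astype(str),
            })
        return cls(dataset, groups=groups, group_ns=ns, group_means=means,
                   group_sems=sems, anova=anova, pairwise=pairwise,
                   epsilon=meta["epsilon"], input_hash=meta.get("input_hash"))


class ExpressionProfileModel:
    """Model of group-structured expression: per-gene group locations with
    ANOVA and pairwise Welch contrasts.

    Parameters
    ----------
    dataset : Dataset
        Merged expression + annotation data.
    pseudocount : float, default 1.0
        Added to both numerator and denominator group means before fold
        changes, in expression units; keeps ratios finite for zero-count
        genes.
    """

    def __init__(self, dataset: Dataset, pseudocount: float = DEFAULT_PSEUDOCOUNT):
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if len(dataset.groups) < 2:
            raise ValueError("at least two sample groups are required")
        self.dataset = dataset
        self.pseudocount = float(pseudocount)

    @classmethod
    def from_csv(cls, expression_path, annotation_path=None,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT) -> "ExpressionProfileModel":
        return cls(load_dataset(expression_path, annotation_path), pseudocount)

    # -- fitting ---------------------------------------------------------

    def fit(self) -> ExpressionStatsResults:
        ds = self.dataset
        ns, means, variances = _group_moments(ds)
        sems = np.sqrt(variances).div(np.sqrt(ns)).where(ns >= 2)

        anova = self._anova(ns, means, variances)
        pairwise = {
            (a, b): self._welch_contrast(a, b, ns, means, variances)
            for a, b in itertools.combinations(ds.groups, 2)
        }
        return ExpressionStatsResults(
            ds, groups=ds.groups, group_ns=ns, group_means=means,
            group_sems=sems, anova=anova, pairwise=pairwise,
            epsilon=self.pseudocount, input_hash=dataset_hash(ds, self.pseudocount),
        )

    def _anova(self, ns: pd.DataFrame, means: pd.DataFrame,
               variances: pd.DataFrame) -> pd.DataFrame:
        """Vectorised one-way fixed-effects ANOVA from per-group moments.

        SS_between = sum_g n_g (mean_g - grand)^2, SS_within =
        sum_g (n_g - 1) s_g^2; identical to computing from the raw
        replicates. Zero-variance degeneracies get the boundary p-values
        rather than NaN so downstream q-value ranking stays total.
        """
        k = len(self.dataset.groups)
        n = ns.to_numpy(dtype=float)
        m = means.to_numpy(dtype=float)
        v = variances.to_numpy(dtype=float)

        usable = (n >= 2).all(axis=1)
        N = n.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            grand = (n * m).sum(axis=1) / N
            ss_b = (n * (m - grand[:, None]) ** 2).sum(axis=1)
            ss_w = ((n - 1) * v).sum(axis=1)
            df_b = k - 1
            df_w = N - k
            ms_b = ss_b / df_b
            ms_w = ss_w / df_w
            F = ms_b / ms_w
            p = sps.f.sf(F, df_b, df_w)

        flag = np.array([FLAG_OK] * len(n), dtype=object)
        # zero within-group variance: all replicates identical per group
        zero_w = usable & np.isclose(ms_w, 0.0)
        null_b = np.isclose(ms_b, 0.0)
        F = np.where(zero_w & null_b, 0.0, F)
        p = np.where(zero_w & null_b, 1.0, p)
        F = np.where(zero_w & ~null_b, np.inf, F)
        p = np.where(zero_w & ~null_b, 0.0, p)
        flag[zero_w & ~null_b] = FLAG_DEGENERATE
        F = np.where(usable, F, np.nan)
        p = np.where(usable, p, np.nan)
        flag[~usable] = FLAG_INSUFFICIENT

        return pd.DataFrame(
            {"F": F, "df_between": df_b, "df_within": df_w, "p": p,
             "q": bh_qvalues(p), "flag": flag},
            index=means.index,
        )

    def _welch_contrast(self, a: str, b: str, ns, means, variances) -> pd.DataFrame:
        """Welch unequal-variance t-test of group a vs group b plus the
        pseudocounted log2 fold change, across all genes at once."""
        eps = self.pseudocount
        na, nb = ns[a].to_numpy(float), ns[b].to_numpy(float)
        ma, mb = means[a].to_numpy(float), means[b].to_numpy(float)
        va, vb = variances[a].to_numpy(float), variances[b].to_numpy(float)
        usable = (na >= 2) & (nb >= 2)

        with np.errstate(invalid="ignore", divide="ignore"):
            log2fc = np.log2(ma + eps) - np.log2(mb + eps)
            se2 = va / na + vb / nb
            t = (ma - mb) / np.sqrt(se2)
            df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            p = 2.0 * sps.t.sf(np.abs(t), df)

        flag = np.array([FLAG_OK] * len(na), dtype=object)
        zero_var = usable & np.isclose(se2, 0.0)
        equal = np.isclose(ma, mb)
        t = np.where(zero_var & equal, 0.0, t)
        p = np.where(zero_var & equal, 1.0, p)
        t = np.where(zero_var & ~equal, np.where(ma >= mb, np.inf, -np.inf), t)
        p = np.where(zero_var & ~equal, 0.0, p)
        flag[zero_var & ~equal] = FLAG_DEGENERATE
        p = np.where(usable, p, np.nan)
        t = np.where(usable, t, np.nan)
        flag[~usable] = FLAG_INSUFFICIENT

        return pd.DataFrame(
            {"log2fc": log2fc, "t": t, "df": df, "p": p,
             "q": bh_qvalues(p), "flag": flag},
            index=means.index,
        )


def dataset_hash(dataset: Dataset, epsilon: float) -> str:
    """Content hash of the inputs that determine the lookup table."""
    h = hashlib.sha256()
    h.update(repr(epsilon).encode())
    h.update(",".join(dataset.genes).encode())
    h.update(repr(list(dataset.expr.data.columns)).encode())
    h.update(np.ascontiguousarray(dataset.expr.data.to_numpy(float)).tobytes())
    for sym, row in dataset.annotations.iterrows():
        h.update(f"{sym}|{row['gene_link']}|{row['description']}|"
                 f"{sorted(row['go_terms'])}".encode())
    return h.hexdigest()


def build_stats_table(dataset: Dataset, epsilon: float = DEFAULT_PSEUDOCOUNT,
                      cache_path=None) -> ExpressionStatsResults:
    """Fit the model, or reload a cached lookup table whose input hash
    matches; a stale cache triggers a logged recompute."""
    expected = dataset_hash(dataset, epsilon)
    if cache_path is not None and Path(cache_path).exists():
        cached = ExpressionStatsResults.load(cache_path, dataset)
        if cached.input_hash == expected:
            logger.info("lookup-table cache hit: %s", cache_path)
            return cached
        logger.info("lookup-table cache stale (input hash changed); recomputing")
    results = ExpressionProfileModel(dataset, epsilon).fit()
    if cache_path is not None:
        results.save(cache_path)
    return results
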