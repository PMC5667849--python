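"""Synthetic replicated-expression datasets with known ground truth.

The generator emulates the statistical structure the per-gene model
assumes: genes with a baseline expression level, sample groups with
replicates, and a subset of "planted" differentially-expressed genes
whose mean is shifted by a known log2 effect in one randomly chosen
group. Per-gene baselines b_g are Normal(mu0, tau) on the log2 scale;
replicate values are either lognormal, 2^(b_g + shift + Normal(0,
sigma)), or negative-binomial with the matching mean and a quadratic
dispersion (var = m + phi m^2). Output files use exactly the wide
expression and long annotation CSV dialects the ingest module reads,
with a designated planted-pathway GO term attached to every DE gene so
annotation filters are testable against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ExpressionStatsResults

PLANTED_PATHWAY_TERM = "planted pathway activity"

#: small fixed vocabulary of synthetic GO-like terms
GO_VOCABULARY = (
    "kinase activity",
    "plasma membrane",
    "nucleus",
    "signal transduction",
    "oxidoreductase activity",
    "transcription factor binding",
    "mitochondrion",
    "cell adhesion",
    "immune response",
    "lipid metabolic process",
    "ion transport",
    "cytoskeleton organization",
)


@dataclass
class SimulationConfig:
    """Generative parameters; defaults give a moderately noisy FPKM-like
    experiment with strong planted effects (effect = 4 x noise sd)."""

    n_genes: int = 1000
    n_groups: int = 4
    n_reps: int = 3
    de_fraction: float = 0.1      # fraction of genes with a planted shift
    effect: float = 2.0           # planted log2 fold change, delta >= 0
    base_mean: float = 6.0        # mu0, log2 scale (~64 expression units)
    base_spread: float = 2.0      # tau, log2 scale
    noise: float = 0.5            # sigma, within-group sd on log2 scale
    distribution: str = "lognormal"   # lognormal | negative-binomial
    dispersion: float = 0.1       # phi, NB quadratic overdispersion
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_groups < 2 or self.n_reps < 2:
            raise ValueError("need n_genes >= 1, n_groups >= 2, n_reps >= 2")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.noise <= 0:
            raise ValueError("noise must be > 0")
        if self.distribution not in ("lognormal", "negative-binomial"):
            raise ValueError("distribution must be lognormal or negative-binomial")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


@dataclass
class TruthTable:
    """Ground truth per simulated gene: whether it carries a planted
    effect, in which group, and its size (log2)."""

    table: pd.DataFrame   # index gene; is_de, affected_group, true_log2_effect

    @property
    def de_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_de"]])

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "TruthTable":
        t = pd.read_csv(path, index_col="gene", keep_default_na=False,
                        na_values=[""])
        t["is_de"] = t["is_de"].astype(bool)
        t["affected_group"] = t["affected_group"].fillna("").astype(str)
        return cls(t)


def simulate_dataset(cfg: SimulationConfig):
    """Draw one dataset; returns (expression DataFrame in the wide
    dialect, annotation DataFrame in the long dialect, TruthTable).
    Byte-identical outputs for identical configs."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"SIM{i:05d}" for i in range(1, cfg.n_genes + 1)]
    groups = [f"GROUP{chr(ord('A') + i)}" for i in range(cfg.n_groups)]

    n_de = round(cfg.de_fraction * cfg.n_genes)
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    is_de = np.zeros(cfg.n_genes, dtype=bool)
    is_de[de_idx] = True
    affected = np.full(cfg.n_genes, "", dtype=object)
    affected[de_idx] = rng.choice(groups, size=n_de)

    baseline = rng.normal(cfg.base_mean, cfg.base_spread, size=cfg.n_genes)
    log2_mean = np.tile(baseline[:, None], (1, cfg.n_groups))
    for i in de_idx:
        log2_mean[i, groups.index(affected[i])] += cfg.effect

    shape = (cfg.n_genes, cfg.n_groups, cfg.n_reps)
    if cfg.distribution == "lognormal":
        values = 2.0 ** (log2_mean[:, :, None] +
                         rng.normal(0.0, cfg.noise, size=shape))
    else:
        mean = 2.0 ** log2_mean[:, :, None] * np.ones(shape)
        # NB with var = m + phi m^2, via Gamma-Poisson mixture
        lam = rng.gamma(1.0 / cfg.dispersion, cfg.dispersion * mean)
        values = rng.poisson(lam).astype(float)

    columns = [f"{g}{r + 1}" for g in groups for r in range(cfg.n_reps)]
    expr = pd.DataFrame(values.reshape(cfg.n_genes, -1),
                        index=pd.Index(genes, name="gene"), columns=columns)

    ann_rows = []
    n_terms = rng.integers(1, 7, size=cfg.n_genes)
    for i, g in enumerate(genes):
        terms = list(rng.choice(GO_VOCABULARY, size=min(n_terms[i],
                                                        len(GO_VOCABULARY)),
                                replace=False))
        if is_de[i]:
            terms.append(PLANTED_PATHWAY_TERM)
        link = f"https://www.ncbi.nlm.nih.gov/gene/?term={900000 + i}"
        for t in terms:
            ann_rows.append((link, t, g, f"synthetic transcript {g.lower()}"))
    annot = pd.DataFrame(ann_rows,
                         columns=["geneLink", "GO", "Symbol", "description"])

    truth = TruthTable(pd.DataFrame({
        "is_de": is_de,
        "affected_group": affected,
        "true_log2_effect": np.where(is_de, cfg.effect, 0.0),
    }, index=pd.Index(genes, name="gene")))
    return expr, annot, truth


def write_simulated_files(cfg: SimulationConfig, out_dir) -> dict[str, Path]:
    """Simulate and write expression.csv / annotation.csv / truth.csv
    under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, annot, truth = simulate_dataset(cfg)
    paths = {
        "expression": out / "expression.csv",
        "annotation": out / "annotation.csv",
        "truth": out / "truth.csv",
    }
    expr.to_csv(paths["expression"])
    annot.to_csv(paths["annotation"], index=False)
    truth.to_csv(paths["truth"])
    return paths


def recovery_report(stats: ExpressionStatsResults, truth: TruthTable,
                    q_threshold: float) -> tuple[float, float]:
    """Score recovery of the planted genes: (power, realized FDR) at an
    ANOVA q-value call threshold.

    power = fraction of truly DE genes called; realized FDR = fraction of
    called genes that are null (0.0 when nothing is called).
    """
    truth_genes = set(truth.table.index)
    if truth_genes != set(stats.genes):
        raise ValueError("truth table and statistics cover different gene sets")
    q = stats.anova["q"].reindex(truth.table.index)
    called = (q <= q_threshold).fillna(False).to_numpy()
    is_de = truth.table["is_de"].to_numpy()
    power = called[is_de].mean() if is_de.any() else float("nan")
    fdr = (~is_de[called]).mean() if called.any() else 0.0
    return float(power), float(fdr)
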