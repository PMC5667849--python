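import io

import pytest

from genevista import (
    ExpressionProfileModel,
    merge,
    read_annotation_csv,
    read_expression_csv,
)
from genevista.demo import load_demo_annotation, load_demo_dataset
from genevista.ingest import AnnotationTable
from genevista.simulate import SimulationConfig, simulate_dataset


def dataset_from_frames(expr_df, annot_df=None):
    """Round-trip simulated frames through the CSV readers so fixtures
    exercise the same ingest path as real files."""
    expr = read_expression_csv(io.StringIO(expr_df.to_csv()))
    if annot_df is None:
        return merge(expr, AnnotationTable.empty())
    annot = read_annotation_csv(io.StringIO(annot_df.to_csv(index=False)))
    return merge(expr, annot)


def simulated_fit(pseudocount=1.0, **cfg_kwargs):
    """Simulate, ingest and fit in one go; returns (results, truth)."""
    cfg = SimulationConfig(**cfg_kwargs)
    expr, annot, truth = simulate_dataset(cfg)
    ds = dataset_from_frames(expr, annot)
    return ExpressionProfileModel(ds, pseudocount).fit(), truth


@pytest.fixture(scope="session")
def demo_dataset():
    return load_demo_dataset()


@pytest.fixture(scope="session")
def demo_annotation():
    return load_demo_annotation()


@pytest.fixture(scope="session")
def demo_stats(demo_dataset):
    return ExpressionProfileModel(demo_dataset).fit()


@pytest.fixture(scope="session")
def small_sim():
    """A 200-gene, 3-group dataset with strong planted effects, fitted."""
    return simulated_fit(n_genes=200, n_groups=3, n_reps=3,
                         de_fraction=0.2, effect=2.0, noise=0.5, seed=11)
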