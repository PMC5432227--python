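import numpy as np
import pandas as pd
import pytest

from pathscore.expression_io import (
    BENIGN,
    PLATFORM_CONTINUOUS,
    TUMOUR,
    ExpressionMatrix,
    SampleAnnotation,
)
from pathscore.pathway_catalog import PathwayCatalog, PathwayDefinition
from pathscore.synthetic_data import PathwayEffect, SyntheticConfig, simulate_cohort, synthetic_catalog


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture
def small_catalog():
    return PathwayCatalog(pathways=(
        PathwayDefinition(name="alpha", genes=("gA1", "gA2", "gA3", "gA4", "gA5", "gA6")),
        PathwayDefinition(name="beta", genes=("gB1", "gB2", "gB3")),
    ))


@pytest.fixture
def tiny_matrix():
    values = pd.DataFrame(
        [[1.0, 3.0, 4.0, 5.0],
         [2.0, 2.0, 6.0, 2.0],
         [0.5, 1.5, 2.5, 3.5]],
        index=["gA1", "gA2", "gB1"],
        columns=["b1", "b2", "t1", "t2"],
    )
    return ExpressionMatrix(values=values, platform=PLATFORM_CONTINUOUS)


@pytest.fixture
def tiny_annotations():
    return [
        SampleAnnotation(sample_id="b1", group=BENIGN),
        SampleAnnotation(sample_id="b2", group=BENIGN),
        SampleAnnotation(sample_id="t1", group=TUMOUR),
        SampleAnnotation(sample_id="t2", group=TUMOUR),
    ]


@pytest.fixture
def planted_cohort():
    """28 benign / 40 tumour, one 10-gene pathway shifted by 2 benign-SD."""
    catalog = synthetic_catalog(n_pathways=3, genes_per_pathway=10)
    config = SyntheticConfig(
        n_benign=28, n_tumour=40, catalog=catalog, n_genes=30, seed=11,
        effects={"pathway_01": PathwayEffect(delta=2.0)},
    )
    matrix, annotations, truth = simulate_cohort(config)
    return matrix, annotations, truth, catalog
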