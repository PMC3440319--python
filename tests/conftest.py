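import numpy as np
import pandas as pd
import pytest

from sarcsig import (
    ExpressionMatrix,
    ExpressionSimConfig,
    PhenotypeTable,
    simulate_expression_cohort,
)


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples with annotation spanning autosome and sex chromosomes."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 2.0, 2.0], [0.0, 1.0, 0.0, 1.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    annotation = pd.DataFrame(
        {
            "chrom": ["1", "X", "20"],
            "start": [100, 200, 300],
            "end": [1100, 1200, 1300],
        },
        index=pd.Index(["GA", "GB", "GC"], name="gene"),
    )
    return ExpressionMatrix(values, annotation)


@pytest.fixture
def tiny_phenotypes():
    return PhenotypeTable(
        pd.DataFrame(
            {
                "disease_class": ["HC", "HC", "CS", "CS"],
                "population": ["AA", "EA", "AA", "EA"],
            },
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
        )
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """Moderate planted cohort (CS vs HC) shared by the slower tests."""
    cfg = ExpressionSimConfig(
        n_genes=300,
        n_signature=20,
        n_per_class={"HC": 35, "US": 17, "CS": 22},
        delta=1.0,
        additive_factor=2.0,
        frac_down=0.9,
        noise_sd=0.5,
        seed=20260918,
    )
    return simulate_expression_cohort(cfg)


def binary_cs_hc(matrix, phenotypes):
    samples = phenotypes.select_samples(classes=["CS", "HC"])
    y = phenotypes.binary_labels(samples, ["CS"], ["HC"])
    return matrix.subset_samples(samples), y


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
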