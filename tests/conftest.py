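"""Shared fixtures: the default synthetic cohort and the elastic-net
benchmark run over its 10 patient-level splits (computed once per
session; several analyses and acceptance checks consume them)."""

import numpy as np
import pandas as pd
import pytest

from crossomics import io_prep, partition, pipeline, regressors, simulate
from crossomics.containers import AbundanceTable, SampleMetadata


@pytest.fixture(scope="session")
def default_cohort():
    """Reference recovery cohort: 40 patients × 5 visits, 100 mGx → 50
    mBx features, 10 planted signal outputs at SNR 5, seed 0."""
    cfg = simulate.SyntheticConfig()
    tables, metadata, truth = simulate.generate_paired(cfg)
    return cfg, tables, metadata, truth


@pytest.fixture(scope="session")
def paired_default(default_cohort):
    _, tables, metadata, _ = default_cohort
    return io_prep.make_paired(tables["mGx"], tables["mBx"], metadata)


@pytest.fixture(scope="session")
def plans10(paired_default):
    return partition.make_splits(paired_default.metadata, n_splits=10)


@pytest.fixture(scope="session")
def en_results(paired_default, plans10):
    """Elastic net fitted and scored on each of the 10 splits."""
    spec = regressors.RegressorSpec(kind="elastic_net")
    return pipeline.run_model_over_splits(paired_default, plans10, spec)


@pytest.fixture(scope="session")
def en_feature_scores(en_results):
    return pipeline.feature_scores(en_results)


@pytest.fixture()
def tiny_table():
    """3 samples × 4 features, hand-checkable."""
    data = pd.DataFrame(
        [[2.0, 2.0, 0.0, 4.0],
         [1.0, 1.0, 1.0, 1.0],
         [0.0, 3.0, 0.0, 1.0]],
        index=["s1", "s2", "s3"],
        columns=["f1", "f2", "f3", "f4"],
    )
    return AbundanceTable(data, modality="mGx", scale="relative")


@pytest.fixture()
def tiny_metadata():
    return SampleMetadata(pd.DataFrame(
        {"patient_id": ["p1", "p1", "p2"],
         "diagnosis": ["UC", "UC", "HC"],
         "visit": [0, 1, 0]},
        index=["s1", "s2", "s3"],
    ))


def random_relative_table(rng, n=12, p=6, modality="mGx", zero_frac=0.2):
    """Random closed nonnegative table used by property-style tests."""
    values = rng.gamma(0.8, size=(n, p))
    mask = rng.random((n, p)) < zero_frac
    values[mask] = 0.0
    values[values.sum(axis=1) == 0, 0] = 1.0  # keep rows non-degenerate
    values = values / values.sum(axis=1, keepdims=True)
    return AbundanceTable(
        pd.DataFrame(values,
                     index=[f"s{i}" for i in range(n)],
                     columns=[f"{modality}_f{j}" for j in range(p)]),
        modality=modality, scale="relative", normalized=True,
    )
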