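import numpy as np
import pandas as pd
import pytest

from putarget import (
    BaggingConfig,
    BaseLearnerSpec,
    SplitConfig,
    SyntheticConfig,
    assign_labels,
    build_feature_matrix,
    generate_evidence,
    generate_stage_table,
    make_working_split,
)


def make_dataset(config: SyntheticConfig, split_seed: int = 0):
    """Generate evidence, features, PU labels and partitions in one go."""
    records, truth = generate_evidence(config)
    matrix = build_feature_matrix(records, universe=truth.index)
    stages = generate_stage_table(truth, seed=config.seed + 1)
    labels = assign_labels(stages, matrix.index)
    partition = make_working_split(labels, SplitConfig(seed=split_seed))
    return {
        "records": records,
        "truth": truth,
        "matrix": matrix,
        "stages": stages,
        "labels": labels,
        "partition": partition,
    }


@pytest.fixture(scope="session")
def strong_dataset():
    """Clearly separable classes: high target activation, disjoint score ranges."""
    return make_dataset(
        SyntheticConfig(
            n_genes=2000,
            true_target_fraction=0.25,
            labelled_fraction=0.6,
            activation_prob_target=0.4,
            score_shape_target=(3.0, 1.5),
            seed=101,
        ),
        split_seed=5,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default (moderate-signal, sparse) regime."""
    return make_dataset(SyntheticConfig(n_genes=1500, seed=202), split_seed=7)


@pytest.fixture
def fast_tree_spec():
    return BaseLearnerSpec("decision_tree", {"max_depth": 3})


@pytest.fixture
def fast_bagging():
    return BaggingConfig(n_bags=10, seed=0)
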