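import numpy as np
import pandas as pd
import pytest

import omixnet as ox


@pytest.fixture
def expr_matrix():
    """3 samples x 4 features expression layer with one missing entry."""
    df = pd.DataFrame(
        [[2.0, 4.0, 6.0, 1.0],
         [5.0, 5.0, 5.0, 5.0],
         [1.0, np.nan, 3.0, 2.0]],
        index=["s1", "s2", "s3"],
        columns=["g1", "g2", "g3", "g4"],
    )
    return ox.OmicsMatrix("gene_expression", df)


@pytest.fixture
def snp_matrix():
    df = pd.DataFrame(
        [["A", "T", "missing"],
         ["G", "C", "A"]],
        index=["s1", "s2"], columns=["m1", "m2", "m3"], dtype=object,
    )
    return ox.OmicsMatrix("snp", df)


@pytest.fixture(scope="session")
def small_cohort():
    """200-sample single-layer planted-signal dataset used across model tests.

    Effect size 2 sd on 10 of 100 features: strongly separable (an L2
    logistic regression reaches AUC ~1), so any competent learner should
    score >= 0.95.
    """
    spec = ox.SyntheticSpec(
        n_samples=200,
        layers=[ox.LayerSpec("gene_expression", 100, 10, 2.0)],
        seed=11,
    )
    mats, labels, manifest = ox.generate_tables(spec)
    d = ox.build_dataset(mats, labels, seed=11)
    return d, manifest


@pytest.fixture(scope="session")
def trained_small(small_cohort):
    """A multi-CNN trained on the small cohort's 60/20/20 split."""
    d, _ = small_cohort
    plan = ox.split_dataset(d, (0.6, 0.2, 0.2), seed=3)
    spec = ox.ModelSpec(task="categorical", max_epochs=60, patience=15)
    graph = ox.build_model(spec, d.input_shapes(), seed=3)
    model = ox.train_model(graph, d.subset(plan.train_ids),
                           d.subset(plan.val_ids), spec, seed=3)
    return model, d, plan


@pytest.fixture(scope="session")
def trio_cohort():
    """Three-layer cohort (expression + SNP + CNV) for multi-branch tests."""
    spec = ox.SyntheticSpec(
        n_samples=120,
        layers=[ox.LayerSpec("gene_expression", 60, 6, 2.0, missing_rate=0.05),
                ox.LayerSpec("snp", 40, 4, 2.0, missing_rate=0.02),
                ox.LayerSpec("cnv", 30, 3, 2.0)],
        seed=5,
    )
    mats, labels, manifest = ox.generate_tables(spec)
    d = ox.build_dataset(mats, labels, seed=5)
    return d, manifest
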