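from __future__ import annotations

import numpy as np
import pytest

from dtiknn import (
    RunConfig,
    build_pair_vectors,
    build_subspaces,
    encode_proteins,
    fit_pca,
    pair_matrix,
    partition_descriptors,
    standardize,
)
from dtiknn import fixtures
from dtiknn.evaluation import cross_validate_vectors


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def build_pipeline(spec: fixtures.FixtureSpec):
    """Run the full encoding pipeline on a fixture spec."""
    prop = fixtures.make_property_table(spec)
    model = fit_pca(standardize(prop), n_components=spec.n_pca)
    records = fixtures.make_sequences(spec)
    encoded = encode_proteins(records, model, spec.n_frag)
    drugs, dataset, manifest = fixtures.make_labeled_pairs(spec)
    pairs = build_pair_vectors(dataset.pair_list(), drugs, encoded)
    x, y = pair_matrix(pairs)
    partition = partition_descriptors(drugs.n_descriptors, spec.n_pca)
    subspaces = build_subspaces(spec.n_pca, spec.n_frag, partition)
    return {
        "spec": spec,
        "model": model,
        "records": records,
        "encoded": encoded,
        "drugs": drugs,
        "dataset": dataset,
        "pairs": pairs,
        "x": x,
        "y": y,
        "partition": partition,
        "subspaces": subspaces,
    }


#: A deliberately small geometry for fast end-to-end tests.
SMALL_SPEC = dict(
    n_drugs=45,
    n_proteins=8,
    n_positive=15,
    seq_len_range=(30, 60),
    n_descriptors=40,
    n_properties=60,
    property_rank=4,
    n_pca=2,
    n_frag=3,
    signal_subspace=(1, 2),
    seed=7,
)


@pytest.fixture(scope="session")
def small_pipeline():
    return build_pipeline(fixtures.FixtureSpec(**SMALL_SPEC))


@pytest.fixture(scope="session")
def signal_pipeline():
    """Full-scale planted-signal fixture (study-condition defaults)."""
    return build_pipeline(fixtures.FixtureSpec())


@pytest.fixture(scope="session")
def signal_cv(signal_pipeline):
    """10-fold cross-validation of the unanimity ensemble on the
    planted-signal fixture."""
    p = signal_pipeline
    with np.errstate(all="ignore"):
        return cross_validate_vectors(
            p["x"], p["y"], p["subspaces"], RunConfig(seed=p["spec"].seed)
        )


@pytest.fixture(scope="session")
def null_cv():
    """10-fold cross-validation on the matched zero-effect (null) fixture."""
    p = build_pipeline(fixtures.FixtureSpec(effect_size=0.0))
    return cross_validate_vectors(
        p["x"], p["y"], p["subspaces"], RunConfig(seed=p["spec"].seed)
    )
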