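import numpy as np
import pandas as pd
import pytest

from thalamograd.prep import (
    average_connectivity,
    concatenate,
    normalise_sigmoid,
    qc_participants,
    qc_seeds,
)
from thalamograd.synthetic import SyntheticConfig, generate_dataset


def small_config(**overrides) -> SyntheticConfig:
    base = dict(
        n_seeds=150,
        n_genes=100,
        n_regions=40,
        n_participants=8,
        marker_specs={},
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config(), rng_seed=42)


def prepare(ds):
    """Minimal matrix assembly for a generated dataset."""
    qc = qc_participants(ds.inclusion)
    retained_p = list(qc.loc[qc["retained"], "participant"])
    keep = qc_seeds(ds.inclusion.loc[retained_p], ds.has_expression)
    pids = list(ds.inclusion.index)
    mats = [ds.participant_connectivity[pids.index(p)] for p in retained_p]
    avg = average_connectivity(mats, retained_seeds=keep)
    conn = normalise_sigmoid(avg, kind="cortical_region")
    genes = normalise_sigmoid(ds.expression.loc[keep], kind="gene")
    joint = concatenate(conn, genes)
    coords = ds.seeds.set_index("seed_id").loc[keep, ["x", "y", "z"]]
    return joint, conn, genes, coords, keep


@pytest.fixture(scope="session")
def small_prepared(small_dataset):
    return prepare(small_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def rank1_matrix():
    """Noiseless rank-1 seeds-by-features fixture (values offset into [0,1])."""
    from thalamograd.prep import FeatureMatrix

    g = np.linspace(-1, 1, 40)
    w = np.array([0.5, -0.2, 0.8, 0.3, -0.6])
    X = np.outer(g, w)
    X = (X - X.min()) / (X.max() - X.min())
    return FeatureMatrix(
        values=pd.DataFrame(X, index=[f"s{i}" for i in range(40)]),
        feature_kind=pd.Series("gene", index=pd.RangeIndex(5)),
        normalised=True,
    ), g
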