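import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from rhizoadapt import synthetic as syn


@pytest.fixture(scope="session")
def panel12():
    return syn.gen_panel(12, seed=11)


@pytest.fixture(scope="session")
def panel40():
    return syn.gen_panel(40, seed=7)


@pytest.fixture(scope="session")
def taxonomy80():
    return syn.gen_taxonomy("16s", 80, seed=2, n_ammonia_oxidizers=10,
                            n_diazotroph_matches=12)


@pytest.fixture(scope="session")
def small_community(panel12, taxonomy80):
    """A small but structured community: 12 genotypes x 3 replicates."""
    spec = replace(syn.spec_16s(), n_taxa=80, depth=2000,
                   group_ra_gradient=(0.02, 0.04))
    table, meta = syn.gen_feature_table(
        panel12, n_replicates=3, n_blocks=3, spec=spec,
        taxonomy=taxonomy80, seed=3,
    )
    return table, meta


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def euclidean_dm(points, ids=None):
    from scipy.spatial.distance import pdist, squareform
    from rhizoadapt.datatypes import DistanceMatrix

    points = np.asarray(points, float)
    if ids is None:
        ids = [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(ids, squareform(pdist(points)), "euclidean")
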