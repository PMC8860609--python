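import math

import numpy as np
import pytest

from tcpscan import features, profiles, synthetic
from tcpscan.folding import ConstantBackend, GCProxyBackend, NussinovBackend


@pytest.fixture(scope="session")
def small_cfg():
    return synthetic.SyntheticConfig(
        n_genes=40,
        utr_len_law=(math.log(80.0), 0.35),
        p_uaug_high=0.6,
        p_uaug_low=0.6,
        depth=8.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """Annotations, truth and Poisson footprints for a 40-gene transcriptome."""
    return synthetic.simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_profiles(small_dataset):
    ann, truth, recs = small_dataset
    profs, _ = profiles.build_profiles(recs, ann)
    norm, _ = profiles.normalize_by_mrna(profs, ann)
    return norm


@pytest.fixture(scope="session")
def small_pssm(small_dataset):
    ann, _, _ = small_dataset
    return features.build_context_pssm(ann, top_fraction=0.2)


@pytest.fixture
def const_backend():
    return ConstantBackend(0.0)


@pytest.fixture
def gc_backend():
    return GCProxyBackend(0.1)


@pytest.fixture(scope="session")
def nussinov_backend():
    return NussinovBackend()


@pytest.fixture
def uniform_pssm():
    """A 9x4 context PSSM with all probabilities 0.25."""
    return features.ContextPSSM(np.full((9, 4), 0.25))
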