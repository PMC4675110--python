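import numpy as np
import pytest

from otubench.synthetic import CommunitySpec, generate_community


@pytest.fixture
def rng():
    return np.random.default_rng(20150)


@pytest.fixture(scope="session")
def planted_community():
    """Well-separated error-free community: 5 clusters, intra 0.01, inter 0.10."""
    spec = CommunitySpec(
        n_clusters=5,
        variants_per_cluster=3,
        intra_divergence=0.01,
        inter_divergence=0.10,
        seq_length=250,
        n_reads=500,
        error_rate=0.0,
        abundance_model="lognormal",
        seed=7,
    )
    return generate_community(spec)
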