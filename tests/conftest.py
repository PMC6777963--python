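import numpy as np
import pytest

from tdcsnet import NetworkConfig, NeuronParams, PlasticityParams


@pytest.fixture
def neuron() -> NeuronParams:
    return NeuronParams()


@pytest.fixture
def tiny_net() -> NetworkConfig:
    """A few neurons, no external drive: deterministic stepping for unit tests."""
    return NetworkConfig(
        n_e=4, n_i=2, gamma_ei=0.5, gamma_ie=0.5, gamma_ii=0.5,
        r_ext=0.0, dt=0.1, delay=1.0,
    )


def make_pools_from_matrix(A: np.ndarray, free_pre=None, free_post=None):
    """Element pools consistent with a given E->E synapse-count matrix."""
    from tdcsnet import ElementPools

    n = A.shape[0]
    pools = ElementPools.zeros(n)
    pools.bound_pre = A.sum(axis=0).astype(np.int64)
    pools.bound_post = A.sum(axis=1).astype(np.int64)
    if free_pre is not None:
        pools.free_pre = np.asarray(free_pre, dtype=np.int64).copy()
    if free_post is not None:
        pools.free_post = np.asarray(free_post, dtype=np.int64).copy()
    pools.z_pre = (pools.free_pre + pools.bound_pre).astype(float)
    pools.z_post = (pools.free_post + pools.bound_post).astype(float)
    return pools
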