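import numpy as np
import pytest

from pdjdsnmf import (
    LayerDims,
    OmicsMatrix,
    PenaltyWeights,
    PriorNetwork,
    SyntheticSpec,
    build_feature_graph,
    generate,
)


def make_omics(rng, n, p, name):
    return OmicsMatrix(
        rng.normal(size=(n, p)),
        [f"s{j}" for j in range(n)],
        [f"{name}_f{j}" for j in range(p)],
        name,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_trio(rng):
    """Three tiny omics matrices over shared samples plus a PPI and graphs."""
    n, p = 6, (5, 4, 3)
    X = [make_omics(rng, n, pi, name) for pi, name in zip(p, ("mrna", "lncrna", "mirna"))]
    A = np.zeros((5, 5))
    A[0, 1] = A[1, 0] = 1.0
    A[2, 3] = A[3, 2] = 1.0
    prior = PriorNetwork(A, X[0].feature_ids)
    graphs = [build_feature_graph(x, tau=0.5) for x in X]
    return X, prior, graphs


@pytest.fixture(scope="session")
def planted_noiseless():
    """Noiseless draw from a planted model (n=40, p=(60,40,20), k=[8,6,4])."""
    spec = SyntheticSpec(
        n=40, p=(60, 40, 20), dims=LayerDims([8, 6, 4]), module_size=(6, 4, 2),
        snr=np.inf, seed=0,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def planted_noisy_small():
    """Small noisy draw used by fit/behaviour tests (snr=10)."""
    spec = SyntheticSpec(
        n=30, p=(40, 24, 12), dims=LayerDims([6, 4]), module_size=(4, 2, 1),
        snr=10.0, seed=1,
    )
    return generate(spec)
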