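import warnings

import numpy as np
import pytest

from spadom.datasets import build_spatial_graph, preprocess_expression
from spadom.mgae import AutoencoderConfig, AutoencoderWeights
from spadom.simulate import SyntheticSpec, generate


@pytest.fixture(scope="session")
def tiny_dataset():
    """16-spot, 12-gene planted dataset on a 4x4 lattice."""
    return generate(SyntheticSpec(grid=(4, 4), C=2, layout="stripes", n_genes=12,
                                  markers_per_domain=3, seed=2))


@pytest.fixture(scope="session")
def tiny_graph(tiny_dataset):
    X = preprocess_expression(tiny_dataset, n_hvg=12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lattice ties are expected
        return build_spatial_graph(tiny_dataset.coords, X, k=3)


@pytest.fixture()
def tiny_weights(tiny_graph):
    cfg = AutoencoderConfig(shared_dim=6, scale_dims=(5, 4), n_heads=2,
                            dtype="float64", seed=3)
    rng = np.random.default_rng(3)
    return AutoencoderWeights.init(tiny_graph.n_features, cfg, rng), cfg


def brute_force_gat(X, layer, neighbor_sets):
    """Independent dense evaluation of one GAT layer, scalar loops only."""
    K = layer.n_heads
    n = X.shape[0]
    outs = []
    for k in range(K):
        W, a_src, a_dst = layer.W[k], layer.a_src[k], layer.a_dst[k]
        Z = np.array([W @ X[i] for i in range(n)])
        pre = np.zeros((n, Z.shape[1]))
        for i in range(n):
            nbrs = list(neighbor_sets[i])
            scores = []
            for j in nbrs:
                e = float(a_src @ Z[i] + a_dst @ Z[j])
                scores.append(e if e >= 0 else 0.01 * e)
            scores = np.array(scores)
            w = np.exp(scores - scores.max())
            w /= w.sum()
            for wj, j in zip(w, nbrs):
                pre[i] += wj * Z[j]
        outs.append(pre)
    if layer.combine == "concat":
        P = np.hstack(outs)
    else:
        P = np.mean(outs, axis=0)
    p = float(layer.prelu)
    return np.where(P > 0, P, p * P)
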