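"""Multi-scale masked graph-attention autoencoder.

The encoder is a shared graph-attention (GAT) layer followed by M parallel
scale-specific GAT layers that embed every spot at different granularities
(dimensionalities).  Training is self-supervised: a random subset of spots
has its feature vector replaced by a learnable mask token, the surviving
features are encoded, the *same* spots' latent vectors are re-masked with a
second learnable token, and one single-layer GAT decoder per scale must
reconstruct the original features of the masked spots from their
neighbours.  The reconstruction loss is the scaled cosine error

    L = (1/M) sum_m (1/|V~|) sum_{i in V~} (1 - cos(x_i, z_i^m))^gamma

averaged over masked spots ``V~`` and scales.  Masking is applied only
during training; embeddings are always read out from the unmasked forward
pass.

The network is small (three GAT layers deep), so forward and backward
passes are written directly in NumPy; gradients are exact (they are checked
against finite differences in the test suite) and optimisation uses Adam
with decoupled weight decay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import h5py
import numpy as np
import scipy.sparse as sp

from .datasets import SpatialGraph

__all__ = [
    "GATLayerWeights",
    "AutoencoderConfig",
    "AutoencoderWeights",
    "MaskPlan",
    "MultiScaleEmbeddings",
    "mask_features",
    "remask",
    "attention_coefficients",
    "gat_layer_forward",
    "encode_multiscale",
    "decode_scale",
    "sce_loss",
    "mse_loss",
    "train_autoencoder",
    "infer_embeddings",
    "save_checkpoint",
    "load_checkpoint",
]

LEAKY_SLOPE = 0.01


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class GATLayerWeights:
    """Parameters of one multi-head GAT layer.

    ``W`` has shape ``(K, d_head, d_in)``; the attention scorer is a
    single-layer feed-forward network without bias on the concatenated pair
    ``[W x_i || W x_j]``, stored as the split vectors ``a_src``/``a_dst``
    (each ``(K, d_head)``) so the pair score is
    ``e_ij = a_src . Wx_i + a_dst . Wx_j``.  ``prelu`` is the learnable
    PReLU slope applied after head combination.
    """

    W: np.ndarray
    a_src: np.ndarray
    a_dst: np.ndarray
    prelu: np.ndarray
    combine: str = "average"  # or "concat"

    @property
    def n_heads(self) -> int:
        return self.W.shape[0]

    @property
    def d_in(self) -> int:
        return self.W.shape[2]

    @property
    def d_out(self) -> int:
        k, d_head, _ = self.W.shape
        return d_head * k if self.combine == "concat" else d_head

    @staticmethod
    def init(d_in: int, d_out: int, n_heads: int, rng: np.random.Generator,
             combine: str = "average", dtype=np.float32) -> "GATLayerWeights":
        if combine == "concat":
            if d_out % n_heads:
                raise ValueError("concat combination needs d_out divisible by n_heads")
            d_head = d_out // n_heads
        elif combine == "average":
            d_head = d_out
        else:
            raise ValueError(f"unknown head combination {combine!r}")
        limit = np.sqrt(6.0 / (d_in + d_head))
        W = rng.uniform(-limit, limit, size=(n_heads, d_head, d_in))
        a_src = rng.normal(0.0, 0.1, size=(n_heads, d_head))
        a_dst = rng.normal(0.0, 0.1, size=(n_heads, d_head))
        return GATLayerWeights(
            W=W.astype(dtype),
            a_src=a_src.astype(dtype),
            a_dst=a_dst.astype(dtype),
            prelu=np.asarray(0.25, dtype=dtype),
            combine=combine,
        )

    def params(self, prefix: str) -> dict:
        return {
            f"{prefix}.W": self.W,
            f"{prefix}.a_src": self.a_src,
            f"{prefix}.a_dst": self.a_dst,
            f"{prefix}.prelu": self.prelu,
        }


@dataclass
class MaskPlan:
    """Which nodes were masked, at what rate, under which seed."""

    rate: float
    masked_set: np.ndarray
    seed: int


@dataclass
class MultiScaleEmbeddings:
    """Per-scale node embeddings ``H^m``, each ``(N, d'_m)`` spot-major."""

    per_scale: List[np.ndarray]

    def __post_init__(self) -> None:
        ns = {h.shape[0] for h in self.per_scale}
        if len(ns) > 1:
            raise ValueError("per-scale embeddings disagree on the number of spots")
        for m, h in enumerate(self.per_scale):
            if not np.all(np.isfinite(h)):
                raise ValueError(f"non-finite entries in scale-{m} embedding")

    @property
    def n_scales(self) -> int:
        return len(self.per_scale)

    @property
    def n_spots(self) -> int:
        return self.per_scale[0].shape[0]


@dataclass
class AutoencoderConfig:
    n_scales: int = 2
    shared_dim: int = 512
    scale_dims: Tuple[int, ...] = (128, 64)
    n_heads: int = 4
    mask_rate: float = 0.6
    gamma: float = 2.0
    epochs: int = 500
    lr: float = 1e-3
    weight_decay: float = 1e-4
    seed: int = 0
    loss: str = "sce"  # or "mse"
    combine: str = "average"
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if len(self.scale_dims) != self.n_scales:
            raise ValueError("scale_dims length must equal n_scales")
        if not 0.0 <= self.mask_rate <= 1.0:
            raise ValueError("mask_rate must lie in [0, 1]")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if self.loss not in ("sce", "mse"):
            raise ValueError("loss must be 'sce' or 'mse'")


@dataclass
class AutoencoderWeights:
    shared_encoder: GATLayerWeights
    scale_encoders: List[GATLayerWeights]
    scale_decoders: List[GATLayerWeights]
    enc_token: np.ndarray
    dec_tokens: List[np.ndarray]
    gamma: float = 2.0

    @property
    def n_scales(self) -> int:
        return len(self.scale_encoders)

    @staticmethod
    def init(d: int, config: AutoencoderConfig, rng: np.random.Generator) -> "AutoencoderWeights":
        dtype = np.dtype(config.dtype).type
        shared = GATLayerWeights.init(d, config.shared_dim, config.n_heads, rng,
                                      config.combine, dtype)
        encs = [GATLayerWeights.init(config.shared_dim, dm, config.n_heads, rng,
                                     config.combine, dtype)
                for dm in config.scale_dims]
        # decoders reconstruct the d-dimensional input; heads always averaged
        decs = [GATLayerWeights.init(dm, d, config.n_heads, rng, "average", dtype)
                for dm in config.scale_dims]
        enc_token = rng.normal(0.0, 0.02, size=d).astype(dtype)
        dec_tokens = [rng.normal(0.0, 0.02, size=dm).astype(dtype)
                      for dm in config.scale_dims]
        return AutoencoderWeights(shared, encs, decs, enc_token, dec_tokens,
                                  gamma=config.gamma)

    def params(self) -> dict:
        out = self.shared_encoder.params("shared")
        for m, (e, d) in enumerate(zip(self.scale_encoders, self.scale_decoders)):
            out.update(e.params(f"enc{m}"))
            out.update(d.params(f"dec{m}"))
        out["enc_token"] = self.enc_token
        for m, t in enumerate(self.dec_tokens):
            out[f"dec_token{m}"] = t
        return out


# ---------------------------------------------------------------------------
# masking


def mask_features(
    X: np.ndarray,
    rate: float,
    token: np.ndarray,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Replace ``floor(rate * N)`` uniformly sampled rows of ``X`` by ``token``.

    Returns the masked matrix and the sorted masked index set.  Rows outside
    the masked set are bitwise-identical to the input.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mask rate must lie in [0, 1], got {rate}")
    n = X.shape[0]
    if rng is None:
        rng = np.random.default_rng(seed)
    n_mask = int(np.floor(rate * n))
    masked_set = np.sort(rng.choice(n, size=n_mask, replace=False))
    X_masked = X.copy()
    X_masked[masked_set] = np.asarray(token, dtype=X.dtype)
    return X_masked, masked_set


def remask(H: np.ndarray, masked_set: np.ndarray, token_m: np.ndarray) -> np.ndarray:
    """Replace the previously masked rows of an embedding by the decode token."""
    token_m = np.asarray(token_m)
    if token_m.shape[0] != H.shape[1]:
        raise ValueError(
            f"re-mask token has dimension {token_m.shape[0]} but embedding has {H.shape[1]}"
        )
    out = H.copy()
    out[np.asarray(masked_set, dtype=np.intp)] = token_m.astype(H.dtype)
    return out


# ---------------------------------------------------------------------------
# GAT layer forward / backward


def _edge_arrays(graph: SpatialGraph):
    return graph.edge_arrays()


def _attention_forward(X, layer: GATLayerWeights, tgt, src, ptr):
    """Per-head projections and softmax attention over each neighbourhood.

    Returns ``(Z, a, e)`` with ``Z``: (K, N, d_head) projected features,
    ``a``: (K, E) attention coefficients and ``e``: (K, E) raw pair scores
    (pre-LeakyReLU).
    """
    Z = np.einsum("nd,kod->kno", X, layer.W)
    s_src = np.einsum("kno,ko->kn", Z, layer.a_src)
    s_dst = np.einsum("kno,ko->kn", Z, layer.a_dst)
    e = s_src[:, tgt] + s_dst[:, src]
    le = np.where(e >= 0, e, LEAKY_SLOPE * e)
    if not np.all(np.isfinite(le)):
        k, idx = np.unravel_index(int(np.argmax(~np.isfinite(le))), le.shape)
        raise FloatingPointError(
            f"non-finite attention score at head {k}, edge ({tgt[idx]}, {src[idx]})"
        )
    seg = ptr[:-1]
    m = np.maximum.reduceat(le, seg, axis=1)
    ex = np.exp(le - m[:, tgt])
    denom = np.add.reduceat(ex, seg, axis=1)
    a = ex / denom[:, tgt]
    return Z, a, e


def attention_coefficients(
    feats: np.ndarray, layer: GATLayerWeights, graph: SpatialGraph, head: int = 0
) -> sp.csr_matrix:
    """Attention matrix ``a_{i,j}`` of one head as a sparse N x N matrix.

    Row ``i`` holds the softmax-normalised weights over ``j in V_i``; every
    row sums to one.
    """
    tgt, src, ptr = _edge_arrays(graph)
    _, a, _ = _attention_forward(feats.astype(layer.W.dtype, copy=False), layer, tgt, src, ptr)
    n = graph.n_nodes
    return sp.csr_matrix((a[head], src, ptr), shape=(n, n))


def _gat_forward(X, layer: GATLayerWeights, tgt, src, ptr, cache: bool = False):
    n = X.shape[0]
    Z, a, e = _attention_forward(X, layer, tgt, src, ptr)
    K = layer.n_heads
    pre = np.empty((K, n, Z.shape[2]), dtype=Z.dtype)
    for k in range(K):
        At = sp.csr_matrix((a[k], src, ptr), shape=(n, n))
        pre[k] = At @ Z[k]
    if layer.combine == "concat":
        P = np.transpose(pre, (1, 0, 2)).reshape(n, -1)
    else:
        P = pre.mean(axis=0)
    p = layer.prelu
    out = np.where(P > 0, P, p * P)
    if not cache:
        return out
    return out, {"X": X, "Z": Z, "a": a, "e": e, "P": P,
                 "tgt": tgt, "src": src, "ptr": ptr}


def _gat_backward(dOut, layer: GATLayerWeights, cache):
    X, Z, a, e, P = cache["X"], cache["Z"], cache["a"], cache["e"], cache["P"]
    tgt, src, ptr = cache["tgt"], cache["src"], cache["ptr"]
    n, K = X.shape[0], layer.n_heads
    p = layer.prelu
    dP = dOut * np.where(P > 0, 1.0, p).astype(dOut.dtype)
    d_prelu = np.sum(dOut * np.where(P > 0, 0.0, P))
    if layer.combine == "concat":
        dpre = np.transpose(dP.reshape(n, K, -1), (1, 0, 2))
    else:
        dpre = np.broadcast_to((dP / K)[None], (K, n, dP.shape[1]))
    dW = np.empty_like(layer.W)
    da_src = np.empty_like(layer.a_src)
    da_dst = np.empty_like(layer.a_dst)
    dX = np.zeros_like(X)
    leaky_grad = np.where(e >= 0, 1.0, LEAKY_SLOPE).astype(X.dtype)
    seg = ptr[:-1]
    for k in range(K):
        At = sp.csr_matrix((a[k], src, ptr), shape=(n, n))
        dZ = At.T @ dpre[k]
        # attention coefficient gradient
        da = np.einsum("eo,eo->e", dpre[k][tgt], Z[k][src])
        s = np.add.reduceat(a[k] * da, seg)
        dl = a[k] * (da - s[tgt])
        de = dl * leaky_grad[k]
        ds_src = np.add.reduceat(de, seg)
        ds_dst = np.bincount(src, weights=de, minlength=n).astype(X.dtype)
        dZ = dZ + ds_src[:, None] * layer.a_src[k][None, :] \
                + ds_dst[:, None] * layer.a_dst[k][None, :]
        da_src[k] = Z[k].T @ ds_src
        da_dst[k] = Z[k].T @ ds_dst
        dW[k] = dZ.T @ X
        dX += dZ @ layer.W[k]
    grads = {"W": dW, "a_src": da_src, "a_dst": da_dst,
             "prelu": np.asarray(d_prelu, dtype=layer.prelu.dtype)}
    return dX, grads


def gat_layer_forward(
    feats: np.ndarray, layer: GATLayerWeights, graph: SpatialGraph
) -> np.ndarray:
    """One multi-head GAT layer: attention-weighted neighbour aggregation
    per head, head combination (mean or concat), then PReLU."""
    if feats.shape[1] != layer.d_in:
        raise ValueError(
            f"layer expects {layer.d_in} input features, got {feats.shape[1]}"
        )
    tgt, src, ptr = _edge_arrays(graph)
    return _gat_forward(feats.astype(layer.W.dtype, copy=False), layer, tgt, src, ptr)


def encode_multiscale(
    graph: SpatialGraph, X_masked: np.ndarray, weights: AutoencoderWeights
) -> MultiScaleEmbeddings:
    """Shared GAT layer followed by each scale-specific GAT encoder."""
    shared = gat_layer_forward(X_masked, weights.shared_encoder, graph)
    return MultiScaleEmbeddings(
        [gat_layer_forward(shared, enc, graph) for enc in weights.scale_encoders]
    )


def decode_scale(
    graph: SpatialGraph, H_remasked: np.ndarray, decoder_m: GATLayerWeights
) -> np.ndarray:
    """Single-layer GAT decoder mapping a (re-masked) embedding back to d features."""
    return gat_layer_forward(H_remasked, decoder_m, graph)


# ---------------------------------------------------------------------------
# losses


def sce_loss(
    X: np.ndarray,
    Z_list: Sequence[np.ndarray],
    masked_set: np.ndarray,
    gamma: float,
    _with_grads: bool = False,
):
    """Scaled cosine error over masked nodes, averaged over scales.

    ``(1/M) sum_m (1/|V~|) sum_{i in V~} (1 - cos(x_i, z_i^m))^gamma``;
    bounded in ``[0, 2^gamma]`` and zero exactly when every masked
    reconstruction is a positive scalar multiple of its target.
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    masked_set = np.asarray(masked_set, dtype=np.intp)
    if masked_set.size == 0:
        raise ValueError("masked set is empty; the loss is undefined")
    M = len(Z_list)
    Xm = np.asarray(X, dtype=np.float64)[masked_set]
    xn = np.linalg.norm(Xm, axis=1)
    if np.any(xn == 0):
        bad = masked_set[np.flatnonzero(xn == 0)[0]]
        raise ValueError(f"zero-norm target feature vector at node {bad}")
    total = 0.0
    grads = []
    for Zfull in Z_list:
        Zm = np.asarray(Zfull, dtype=np.float64)[masked_set]
        zn = np.linalg.norm(Zm, axis=1)
        if np.any(zn == 0):
            bad = masked_set[np.flatnonzero(zn == 0)[0]]
            raise ValueError(f"zero-norm reconstruction at node {bad}")
        cos = np.einsum("ij,ij->i", Xm, Zm) / (xn * zn)
        cos = np.clip(cos, -1.0, 1.0)
        term = (1.0 - cos) ** gamma
        total += term.mean()
        if _with_grads:
            coef = -gamma * (1.0 - cos) ** (gamma - 1.0) / (M * masked_set.size)
            dcos_dZ = Xm / (xn * zn)[:, None] - (cos / zn**2)[:, None] * Zm
            dZ = np.zeros_like(Zfull, dtype=np.float64)
            dZ[masked_set] = coef[:, None] * dcos_dZ
            grads.append(dZ.astype(Zfull.dtype))
    loss = total / M
    if _with_grads:
        return loss, grads
    return loss


def mse_loss(X, Z_list, masked_set, _with_grads: bool = False):
    """Plain mean squared error on masked rows (ablation arm)."""
    masked_set = np.asarray(masked_set, dtype=np.intp)
    if masked_set.size == 0:
        raise ValueError("masked set is empty; the loss is undefined")
    M = len(Z_list)
    d = X.shape[1]
    Xm = np.asarray(X, dtype=np.float64)[masked_set]
    total = 0.0
    grads = []
    for Zfull in Z_list:
        diff = np.asarray(Zfull, dtype=np.float64)[masked_set] - Xm
        total += np.mean(diff**2)
        if _with_grads:
            dZ = np.zeros_like(Zfull, dtype=np.float64)
            dZ[masked_set] = 2.0 * diff / (M * masked_set.size * d)
            grads.append(dZ.astype(Zfull.dtype))
    loss = total / M
    if _with_grads:
        return loss, grads
    return loss


# ---------------------------------------------------------------------------
# training


class _Adam:
    """Adam with decoupled weight decay on the GAT weight tensors."""

    def __init__(self, params: dict, lr: float, weight_decay: float):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = np.asarray(grads[k], dtype=np.float64)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            update = (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            if self.wd and (".W" in k or ".a_" in k):
                update = update + self.wd * np.asarray(p, dtype=np.float64)
            p -= (self.lr * update).astype(p.dtype)


def _forward_backward(graph, X, weights: AutoencoderWeights, masked_set, loss_kind: str,
                      loss_set=None):
    """One masked forward pass plus exact gradients for every parameter.

    ``loss_set`` defaults to ``masked_set``; the unmasked ablation passes an
    empty ``masked_set`` with the loss taken over every node instead.
    """
    if loss_set is None:
        loss_set = masked_set
    tgt, src, ptr = _edge_arrays(graph)
    dtype = weights.shared_encoder.W.dtype
    X = X.astype(dtype, copy=False)

    X_masked = X.copy()
    X_masked[masked_set] = weights.enc_token
    shared, c_sh = _gat_forward(X_masked, weights.shared_encoder, tgt, src, ptr, cache=True)

    Hs, c_enc, H_rem, c_dec, Z_list = [], [], [], [], []
    for m, enc in enumerate(weights.scale_encoders):
        H, c = _gat_forward(shared, enc, tgt, src, ptr, cache=True)
        Hs.append(H)
        c_enc.append(c)
        Hr = H.copy()
        Hr[masked_set] = weights.dec_tokens[m]
        H_rem.append(Hr)
        Zm, cd = _gat_forward(Hr, weights.scale_decoders[m], tgt, src, ptr, cache=True)
        Z_list.append(Zm)
        c_dec.append(cd)

    if loss_kind == "sce":
        loss, dZs = sce_loss(X, Z_list, loss_set, weights.gamma, _with_grads=True)
    else:
        loss, dZs = mse_loss(X, Z_list, loss_set, _with_grads=True)

    grads = {k: None for k in weights.params()}
    d_shared = np.zeros_like(shared)
    for m in range(weights.n_scales):
        dHr, g_dec = _gat_backward(dZs[m], weights.scale_decoders[m], c_dec[m])
        for name, g in g_dec.items():
            grads[f"dec{m}.{name}"] = g
        grads[f"dec_token{m}"] = dHr[masked_set].sum(axis=0)
        dH = dHr.copy()
        dH[masked_set] = 0.0  # re-mask stops the gradient at masked rows
        dSh, g_enc = _gat_backward(dH, weights.scale_encoders[m], c_enc[m])
        for name, g in g_enc.items():
            grads[f"enc{m}.{name}"] = g
        d_shared += dSh
    dXm, g_sh = _gat_backward(d_shared, weights.shared_encoder, c_sh)
    for name, g in g_sh.items():
        grads[f"shared.{name}"] = g
    grads["enc_token"] = dXm[masked_set].sum(axis=0)
    return loss, grads


def infer_embeddings(graph: SpatialGraph, weights: AutoencoderWeights) -> MultiScaleEmbeddings:
    """Mask-free deterministic forward pass of the encoder."""
    return encode_multiscale(graph, graph.features, weights)


def train_autoencoder(
    graph: SpatialGraph, config: AutoencoderConfig
) -> Tuple[AutoencoderWeights, MultiScaleEmbeddings, List[float]]:
    """Train the masked autoencoder and return weights, embeddings, loss trace.

    Each epoch samples a fresh masked node set, runs the masked forward
    pass, and takes one Adam step on the reconstruction loss.  A zero mask
    rate degenerates to a plain (unmasked) reconstruction objective.  After
    training the embeddings are read out without masking.
    """
    rng = np.random.default_rng(config.seed)
    weights = AutoencoderWeights.init(graph.n_features, config, rng)
    params = weights.params()
    opt = _Adam(params, config.lr, config.weight_decay)
    X = graph.features
    n = graph.n_nodes
    trace: List[float] = []
    for epoch in range(config.epochs):
        n_mask = int(np.floor(config.mask_rate * n))
        if n_mask > 0:
            masked_set = np.sort(rng.choice(n, size=n_mask, replace=False))
            loss_set = masked_set
        else:
            # unmasked ablation: nothing is replaced, reconstruct every node
            masked_set = np.empty(0, dtype=np.intp)
            loss_set = np.arange(n)
        loss, grads = _forward_backward(graph, X, weights, masked_set, config.loss,
                                        loss_set=loss_set)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at epoch {epoch}: {loss}")
        trace.append(float(loss))
        opt.step(grads)
    return weights, infer_embeddings(graph, weights), trace


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, weights: AutoencoderWeights, config: AutoencoderConfig,
                    trace: Sequence[float]) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(vars(config) | {"scale_dims": list(config.scale_dims)})
        f.attrs["gamma"] = weights.gamma
        f.create_dataset("loss_trace", data=np.asarray(trace, dtype=np.float64))
        for name, arr in weights.params().items():
            f.create_dataset(f"params/{name}", data=arr)
        for prefix, layer in _iter_layers(weights):
            f.attrs[f"{prefix}.combine"] = layer.combine


def _iter_layers(weights: AutoencoderWeights):
    yield "shared", weights.shared_encoder
    for m, (e, d) in enumerate(zip(weights.scale_encoders, weights.scale_decoders)):
        yield f"enc{m}", e
        yield f"dec{m}", d


def load_checkpoint(path) -> Tuple[AutoencoderWeights, AutoencoderConfig, np.ndarray]:
    with h5py.File(path, "r") as f:
        cfg_dict = json.loads(f.attrs["config"])
        cfg_dict["scale_dims"] = tuple(cfg_dict["scale_dims"])
        config = AutoencoderConfig(**cfg_dict)
        trace = f["loss_trace"][...]
        p = {name: f[f"params/{name}"][...] for name in _param_names(config)}
        combines = {k: f.attrs[f"{k}.combine"] for k in
                    ["shared"] + [f"enc{m}" for m in range(config.n_scales)]
                    + [f"dec{m}" for m in range(config.n_scales)]}

    def layer(prefix):
        return GATLayerWeights(
            W=p[f"{prefix}.W"], a_src=p[f"{prefix}.a_src"],
            a_dst=p[f"{prefix}.a_dst"], prelu=p[f"{prefix}.prelu"],
            combine=combines[prefix],
        )

    weights = AutoencoderWeights(
        shared_encoder=layer("shared"),
        scale_encoders=[layer(f"enc{m}") for m in range(config.n_scales)],
        scale_decoders=[layer(f"dec{m}") for m in range(config.n_scales)],
        enc_token=p["enc_token"],
        dec_tokens=[p[f"dec_token{m}"] for m in range(config.n_scales)],
        gamma=config.gamma,
    )
    return weights, config, trace


def _param_names(config: AutoencoderConfig):
    names = []
    for prefix in (["shared"] + [f"enc{m}" for m in range(config.n_scales)]
                   + [f"dec{m}" for m in range(config.n_scales)]):
        names += [f"{prefix}.W", f"{prefix}.a_src", f"{prefix}.a_dst", f"{prefix}.prelu"]
    names.append("enc_token")
    names += [f"dec_token{m}" for m in range(config.n_scales)]
    return names
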