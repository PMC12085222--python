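"""Reading spatial expression data, preprocessing, and spatial graph construction.

A spatial transcriptomics assay yields a spot-by-gene count matrix together
with the 2-D position of every capture spot.  This module loads those inputs
from the common on-disk layouts (MatrixMarket triplets, delimited tables, or
an ``.h5ad`` single-cell container), normalises the expression matrix, and
builds the k-nearest-neighbour (or fixed-radius) spatial graph that the
graph-attention autoencoder consumes.

All node matrices are stored spot-major (rows = spots) throughout the
package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialExpressionDataset",
    "SpatialGraph",
    "load_dataset",
    "preprocess_expression",
    "build_spatial_graph",
    "save_graph",
    "load_graph",
]


@dataclass
class SpatialExpressionDataset:
    """Raw spot-by-gene expression with spatial coordinates.

    Attributes
    ----------
    counts
        ``(n_spots, n_genes)`` non-negative expression matrix (raw counts or
        already-normalised values).
    coords
        ``(n_spots, 2)`` spatial coordinates.
    gene_names, spot_ids
        Row/column identifiers, order preserved from the source files.
    labels
        Optional per-spot ground-truth domain labels.
    """

    counts: np.ndarray
    coords: np.ndarray
    gene_names: list = field(default_factory=list)
    spot_ids: list = field(default_factory=list)
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        n = self.counts.shape[0]
        if n < 1:
            raise ValueError("dataset must contain at least one spot")
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coordinate table has {self.coords.shape[0]} rows but the "
                f"expression matrix has {n} spots"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite entries")
        if np.any(self.counts < 0):
            raise ValueError("counts contain negative entries")
        if not self.gene_names:
            self.gene_names = [f"gene_{i}" for i in range(self.counts.shape[1])]
        if not self.spot_ids:
            self.spot_ids = [f"spot_{i}" for i in range(n)]
        if len(self.gene_names) != self.counts.shape[1]:
            raise ValueError("gene_names length does not match counts columns")
        if len(self.spot_ids) != n:
            raise ValueError("spot_ids length does not match counts rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != n:
                raise ValueError("labels length does not match number of spots")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class SpatialGraph:
    """A spatial neighbour graph ``G = (V, A, X)``.

    ``features`` is the ``(N, d)`` node feature matrix (spot-major),
    ``adjacency`` a symmetric binary CSR matrix with self-loops on every
    node, and ``coords`` the ``(N, 2)`` spot positions.
    """

    features: np.ndarray
    adjacency: sp.csr_matrix
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        n = self.features.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match feature rows")
        if (self.adjacency != self.adjacency.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if np.any(self.adjacency.diagonal() == 0):
            raise ValueError("every node must carry a self-loop")

    @property
    def n_nodes(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def neighbor_sets(self) -> list:
        """Per-node neighbour index arrays (each includes the node itself)."""
        A = self.adjacency
        return [A.indices[A.indptr[i]: A.indptr[i + 1]] for i in range(self.n_nodes)]

    def edge_arrays(self):
        """Edges as ``(targets, sources, row_ptr)`` in CSR order.

        ``targets[e] = i`` and ``sources[e] = j`` enumerate every ordered
        pair ``j in V_i``; ``row_ptr`` delimits the edges of each target
        node, so segment reductions over neighbourhoods are contiguous.
        """
        A = self.adjacency
        counts = np.diff(A.indptr)
        targets = np.repeat(np.arange(self.n_nodes), counts)
        return targets, A.indices.copy(), A.indptr.copy()


def _read_coords_table(path: Path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    if "x" in cols and "y" in cols:
        coords = df[[cols["x"], cols["y"]]].to_numpy(dtype=float)
    else:  # fall back to the first two numeric columns
        num = df.select_dtypes("number")
        coords = num.iloc[:, :2].to_numpy(dtype=float)
    ids_col = next((cols[c] for c in ("spot", "spot_id", "barcode", "id") if c in cols), None)
    ids = df[ids_col].astype(str).tolist() if ids_col else []
    return coords, ids


def load_dataset(path, fmt: str = "delimited") -> SpatialExpressionDataset:
    """Load a :class:`SpatialExpressionDataset` from disk.

    Parameters
    ----------
    path
        For ``mtx_dir``: a directory containing ``matrix.mtx`` (spots x genes
        or genes x spots with matching ``barcodes.tsv``/``features.tsv``) and
        ``coords.csv``.  For ``delimited``: a spots-x-genes table with a
        header row; a sibling ``<stem>.coords.csv`` (or ``coords.csv`` in the
        same directory) supplies positions.  For ``h5_container``: an
        ``.h5ad`` file with ``obs`` columns ``x``/``y`` and optionally
        ``label``.
    fmt
        One of ``{"mtx_dir", "delimited", "h5_container"}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input path does not exist: {path}")

    if fmt == "mtx_dir":
        mtx = path / "matrix.mtx"
        barcodes = path / "barcodes.tsv"
        features = path / "features.tsv"
        coords_f = path / "coords.csv"
        for f in (mtx, barcodes, features, coords_f):
            if not f.exists():
                raise FileNotFoundError(f"required file missing: {f}")
        mat = scipy.io.mmread(mtx)
        counts = np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=float)
        spot_ids = pd.read_csv(barcodes, header=None, sep="\t")[0].astype(str).tolist()
        gene_names = pd.read_csv(features, header=None, sep="\t")[0].astype(str).tolist()
        if counts.shape == (len(gene_names), len(spot_ids)) and counts.shape[0] != counts.shape[1]:
            counts = counts.T  # stored genes x spots, as 10x convention
        coords, _ = _read_coords_table(coords_f)
        labels = None
        labels_f = path / "labels.csv"
        if labels_f.exists():
            labels = pd.read_csv(labels_f)["label"].to_numpy()
        return SpatialExpressionDataset(counts, coords, gene_names, spot_ids, labels)

    if fmt == "delimited":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        counts = df.to_numpy(dtype=float)
        coords_f = path.with_suffix(".coords.csv")
        if not coords_f.exists():
            coords_f = path.parent / "coords.csv"
        if not coords_f.exists():
            raise FileNotFoundError(f"coordinate table missing: {coords_f}")
        coords, ids = _read_coords_table(coords_f)
        spot_ids = df.index.astype(str).tolist()
        return SpatialExpressionDataset(counts, coords, df.columns.tolist(), spot_ids)

    if fmt == "h5_container":
        import anndata as ad

        adata = ad.read_h5ad(path)
        counts = adata.X
        if sp.issparse(counts):
            counts = np.asarray(counts.todense())
        for col in ("x", "y"):
            if col not in adata.obs:
                raise ValueError(f"h5 container lacks obs column '{col}'")
        coords = adata.obs[["x", "y"]].to_numpy(dtype=float)
        labels = adata.obs["label"].to_numpy() if "label" in adata.obs else None
        return SpatialExpressionDataset(
            np.asarray(counts, dtype=float),
            coords,
            adata.var_names.tolist(),
            adata.obs_names.tolist(),
            labels,
        )

    raise ValueError(f"unknown format: {fmt!r}")


def preprocess_expression(
    ds: SpatialExpressionDataset,
    n_hvg: int = 3000,
    target_sum: float = 1e4,
    scale_clip: float = 10.0,
) -> np.ndarray:
    """Normalise counts and return the ``(N, d)`` feature matrix.

    The pipeline is the community-standard one: per-spot library-size
    normalisation to ``target_sum``, ``log1p``, selection of the ``n_hvg``
    highest-variance genes, then per-gene standardisation clipped at
    ``+/- scale_clip``.  Genes with zero variance standardise to all-zero
    columns.  Deterministic: identical input gives a bitwise-identical
    output.
    """
    if n_hvg > ds.n_genes:
        raise ValueError(f"n_hvg={n_hvg} exceeds the number of genes {ds.n_genes}")
    lib = ds.counts.sum(axis=1)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        ids = [ds.spot_ids[i] for i in zero[:10]]
        raise ValueError(f"spots with all-zero counts: {ids}")
    X = ds.counts * (target_sum / lib)[:, None]
    X = np.log1p(X)
    var = X.var(axis=0)
    # top-n_hvg by variance; stable order among ties, original gene order kept
    order = np.argsort(-var, kind="stable")[:n_hvg]
    keep = np.sort(order)
    X = X[:, keep]
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std_safe = np.where(std > 0, std, 1.0)
    X = (X - mean) / std_safe
    X[:, std == 0] = 0.0
    np.clip(X, -scale_clip, scale_clip, out=X)
    return X


def _knn_edges(coords: np.ndarray, k: int) -> sp.csr_matrix:
    """Directed kNN relation with deterministic ascending-index tie-break."""
    n = coords.shape[0]
    rows = np.empty(n * k, dtype=np.int64)
    cols = np.empty(n * k, dtype=np.int64)
    chunk = max(1, int(2e7) // max(n, 1))
    dup_warned = False
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = np.linalg.norm(coords[start:stop, None, :] - coords[None, :, :], axis=2)
        for local, i in enumerate(range(start, stop)):
            di = d[local].copy()
            di[i] = np.inf  # self excluded; self-loop added separately
            order = np.argsort(di, kind="stable")  # stable => index tie-break
            nn = order[:k]
            if not dup_warned and k < n - 1 and di[order[k - 1]] == di[order[k]]:
                warnings.warn(
                    "duplicate neighbour distances; ties broken by ascending node index",
                    stacklevel=3,
                )
                dup_warned = True
            rows[i * k: (i + 1) * k] = i
            cols[i * k: (i + 1) * k] = nn
    data = np.ones(n * k, dtype=np.int8)
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def build_spatial_graph(
    coords: np.ndarray,
    features: np.ndarray,
    method: str = "knn",
    k: int = 6,
    radius: float = 1.0,
) -> SpatialGraph:
    """Build the spatial neighbour graph over spot coordinates.

    ``knn`` links every spot to its ``k`` nearest Euclidean neighbours, then
    symmetrises the relation (union) and adds self-loops; ``radius`` links
    every pair within ``radius``.  Ties in neighbour distance are broken by
    ascending node index so graph construction is deterministic.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("a spatial graph needs at least two spots")
    if method == "knn":
        if not 1 <= k < n:
            raise ValueError(f"knn requires 1 <= k < N, got k={k}, N={n}")
        A = _knn_edges(coords, k)
        A = ((A + A.T) > 0).astype(np.int8)  # symmetrize by union
    elif method == "radius":
        if radius <= 0:
            raise ValueError("radius must be positive")
        from scipy.spatial import cKDTree

        tree = cKDTree(coords)
        pairs = tree.query_pairs(radius, output_type="ndarray")
        if pairs.size:
            rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
            cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
            A = sp.csr_matrix(
                (np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(n, n)
            )
        else:
            A = sp.csr_matrix((n, n), dtype=np.int8)
    else:
        raise ValueError(f"unknown graph method: {method!r}")
    A = (A + sp.identity(n, dtype=np.int8, format="csr")) > 0
    A = A.astype(np.int8).tocsr()
    A.sort_indices()
    return SpatialGraph(features=np.asarray(features), adjacency=A, coords=coords)


def save_graph(graph: SpatialGraph, path) -> None:
    """Serialise a :class:`SpatialGraph` to HDF5 (features, edge list, coords)."""
    coo = graph.adjacency.tocoo()
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=graph.features)
        f.create_dataset("coords", data=graph.coords)
        f.create_dataset("edges", data=np.stack([coo.row, coo.col], axis=1))


def load_graph(path) -> SpatialGraph:
    with h5py.File(path, "r") as f:
        features = f["features"][...]
        coords = f["coords"][...]
        edges = f["edges"][...]
    n = features.shape[0]
    A = sp.csr_matrix(
        (np.ones(edges.shape[0], dtype=np.int8), (edges[:, 0], edges[:, 1])),
        shape=(n, n),
    )
    A.sort_indices()
    return SpatialGraph(features=features, adjacency=A, coords=coords)
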