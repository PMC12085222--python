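"""Synthetic spatial transcriptomics data with planted spatial domains.

The generator lays spots on a rectangular lattice, partitions the lattice
into ``C`` spatial domains (stripes, blocks, or a Voronoi tessellation of
random seed points), assigns each domain a disjoint set of up-regulated
marker genes, and draws expression as

    log-expression  L = baseline_g + effect * [g is a marker of domain(i)] + noise

with either Gaussian noise in log space (``gaussian_log``; counts are
``expm1(L)``) or Poisson counts with rate ``expm1(L)``.  Because domains
are spatially contiguous, the k-nearest-neighbour graph built on the
lattice has mostly within-domain edges — the spatial-coherence assumption
the clustering method exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .datasets import SpatialExpressionDataset
from .mgae import MultiScaleEmbeddings

__all__ = ["SyntheticSpec", "generate", "make_embedding_fixture"]


@dataclass
class SyntheticSpec:
    """Parameters of a planted-domain simulation."""

    grid: Tuple[int, int] = (40, 40)
    C: int = 5
    layout: str = "blocks"  # stripes | blocks | voronoi
    n_genes: int = 200
    markers_per_domain: int = 10
    effect: float = 2.0
    noise_sd: float = 0.5
    count_model: str = "gaussian_log"  # gaussian_log | poisson
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid
        if self.C > rows * cols:
            raise ValueError("more domains than lattice spots")
        if self.markers_per_domain * self.C > self.n_genes:
            raise ValueError("marker genes exceed the gene panel size")
        if self.layout not in ("stripes", "blocks", "voronoi"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.count_model not in ("gaussian_log", "poisson"):
            raise ValueError(f"unknown count model {self.count_model!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _domain_labels(spec: SyntheticSpec, coords: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.grid
    r, c = coords[:, 0], coords[:, 1]
    if spec.layout == "stripes":
        # C horizontal bands of (near-)equal height
        return np.minimum((r * spec.C) // rows, spec.C - 1).astype(int)
    if spec.layout == "blocks":
        # split the lattice into a near-square grid of C tiles
        g_rows = int(np.floor(np.sqrt(spec.C)))
        g_cols = int(np.ceil(spec.C / g_rows))
        tile_r = np.minimum((r * g_rows) // rows, g_rows - 1)
        tile_c = np.minimum((c * g_cols) // cols, g_cols - 1)
        return np.minimum(tile_r * g_cols + tile_c, spec.C - 1).astype(int)
    seeds = rng.uniform([0, 0], [rows, cols], size=(spec.C, 2))
    d = np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=2)
    return np.argmin(d, axis=1).astype(int)


def generate(spec: SyntheticSpec) -> SpatialExpressionDataset:
    """Draw one dataset from the spec; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    labels = _domain_labels(spec, coords, rng)

    baseline = rng.uniform(0.5, 2.0, size=spec.n_genes)
    marker_sets = np.arange(spec.markers_per_domain * spec.C).reshape(spec.C, -1)
    L = np.tile(baseline, (coords.shape[0], 1))
    for c in range(spec.C):
        rows_c = np.flatnonzero(labels == c)
        L[np.ix_(rows_c, marker_sets[c])] += spec.effect

    if spec.count_model == "gaussian_log":
        L = L + rng.normal(0.0, spec.noise_sd, size=L.shape)
        counts = np.expm1(np.maximum(L, 0.0))
    else:
        counts = rng.poisson(np.expm1(L)).astype(float)

    gene_names = [f"gene_{g}" for g in range(spec.n_genes)]
    spot_ids = [f"spot_{i}" for i in range(coords.shape[0])]
    return SpatialExpressionDataset(counts, coords, gene_names, spot_ids, labels)


def make_embedding_fixture(
    N: int,
    M: int = 2,
    C: int = 3,
    sep: float = 5.0,
    spread: float = 1.0,
    dims: Tuple[int, ...] = (16, 8),
    seed: int = 0,
) -> Tuple[MultiScaleEmbeddings, np.ndarray]:
    """Gaussian-blob embeddings shared across M scales, for clustering tests.

    Per scale, C isotropic blobs with minimum centre separation ``sep`` and
    standard deviation ``spread``; every scale carries the same planted
    labels.  ``sep = 0`` collapses all centres to the origin (no signal).
    """
    if len(dims) != M:
        raise ValueError("dims length must equal M")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, C, size=N)
    # make sure every cluster is populated
    labels[:C] = np.arange(C)
    per_scale = []
    for d in dims:
        centers = rng.standard_normal((C, d))
        if sep > 0:
            dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
            np.fill_diagonal(dists, np.inf)
            centers *= sep / dists.min()
        else:
            centers[:] = 0.0
        pts = centers[labels] + spread * rng.standard_normal((N, d))
        per_scale.append(pts)
    return MultiScaleEmbeddings(per_scale), labels
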