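"""Clustering quality metrics.

External metrics (ARI, NMI, purity) compare predicted domains with
ground-truth labels; internal metrics (silhouette coefficient, higher is
better; Davies-Bouldin index, lower is better) score a clustering against
an embedding when no labels exist.  ARI/NMI/silhouette/Davies-Bouldin
delegate to scikit-learn; NMI uses the arithmetic-mean normalisation.
All metrics are invariant to relabelling of cluster ids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from sklearn import metrics as skm

__all__ = [
    "MetricReport",
    "ari",
    "nmi",
    "purity",
    "silhouette",
    "davies_bouldin",
    "evaluate_clustering",
]


def _check_labels(truth, pred):
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError(
            f"label vectors differ in length: {truth.shape} vs {pred.shape}"
        )
    return truth, pred


def ari(truth, pred) -> float:
    """Adjusted Rand index, in [-1, 1]."""
    truth, pred = _check_labels(truth, pred)
    return float(skm.adjusted_rand_score(truth, pred))


def nmi(truth, pred) -> float:
    """Normalised mutual information (arithmetic-mean normalisation), in [0, 1]."""
    truth, pred = _check_labels(truth, pred)
    return float(skm.normalized_mutual_info_score(truth, pred, average_method="arithmetic"))


def purity(truth, pred) -> float:
    """Fraction of spots whose cluster's majority true class matches them.

    purity = (1/N) * sum over predicted clusters of the largest overlap
    with any true class.
    """
    truth, pred = _check_labels(truth, pred)
    cm = skm.cluster.contingency_matrix(truth, pred)
    return float(cm.max(axis=0).sum() / cm.sum())


def silhouette(embedding, pred) -> float:
    """Mean silhouette coefficient on Euclidean distances, in [-1, 1]."""
    pred = np.asarray(pred)
    if np.unique(pred).size < 2:
        raise ValueError("silhouette needs at least two clusters")
    return float(skm.silhouette_score(np.asarray(embedding), pred, metric="euclidean"))


def davies_bouldin(embedding, pred) -> float:
    """Davies-Bouldin index (>= 0, lower is better).

    Raises when two clusters share a centroid, where the index diverges.
    """
    embedding = np.asarray(embedding, dtype=float)
    pred = np.asarray(pred)
    clusters = np.unique(pred)
    if clusters.size < 2:
        raise ValueError("Davies-Bouldin needs at least two clusters")
    cents = np.stack([embedding[pred == c].mean(axis=0) for c in clusters])
    dc = np.linalg.norm(cents[:, None] - cents[None, :], axis=2)
    np.fill_diagonal(dc, np.inf)
    if np.any(dc[np.isfinite(dc)] == 0):
        raise ValueError("coincident cluster centroids: Davies-Bouldin diverges")
    return float(skm.davies_bouldin_score(embedding, pred))


@dataclass
class MetricReport:
    """All metrics for one clustering, serialisable to JSON."""

    ari: float
    nmi: float
    purity: float
    silhouette: float
    davies_bouldin: float
    n_spots: int
    C_true: int
    C_pred: int

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(s)
        return s


def evaluate_clustering(truth, pred, embedding) -> MetricReport:
    """Compute the full metric panel for a labelled clustering."""
    truth, pred = _check_labels(truth, pred)
    return MetricReport(
        ari=ari(truth, pred),
        nmi=nmi(truth, pred),
        purity=purity(truth, pred),
        silhouette=silhouette(embedding, pred),
        davies_bouldin=davies_bouldin(embedding, pred),
        n_spots=int(truth.size),
        C_true=int(np.unique(truth).size),
        C_pred=int(np.unique(pred).size),
    )
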