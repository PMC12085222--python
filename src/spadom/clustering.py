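"""Unified multi-scale clustering by alternating block minimisation.

Given per-scale embeddings ``H^m`` (spots x d'_m, m = 1..M) the model
factorises every scale into a *common* representation ``Hc`` (dc x N)
shared by all scales and a *scale-specific* representation ``Hs^m``
(ds x N), and clusters both jointly with a hard indicator matrix ``U``
(C x N, one-hot columns):

    min  sum_m ||H^m - Hc^T Wm - Hs^{m,T} Pm||_F^2
         + beta ||Hc^T||_F^2 + beta sum_m ||Hs^{m,T}||_F^2
         + sum_m alpha_m ||Hs^m - Vm U||_F^2
         + alpha_{M+1} ||Hc - V_{M+1} U||_F^2
         + lambda sum_{m=1}^{M+1} ||Vm^T Vm - I||_F^2
         + delta sum_{m=1}^{M+1} alpha_m ln alpha_m

    s.t. alpha >= 0, sum alpha = 1, U one-hot per column.

The common representation is treated as an (M+1)-th "scale" with its own
centroids; the Shannon-entropy term turns the scale weights ``alpha`` into
a softmax of the per-scale clustering costs, so scales that cluster well
gain influence.  The orthogonality penalty ``lambda`` pushes each centroid
matrix towards orthonormal columns, discouraging collapsed centres.

Every block update is the exact minimiser of the objective with the other
blocks fixed, except the centroids, whose subproblem is quartic in ``Vm``
and is driven by projected gradient descent with backtracking from the
``lambda = 0`` closed form.  The objective is therefore non-increasing
across updates (up to the 1e-8 ridge used for conditioning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .mgae import MultiScaleEmbeddings

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringState",
    "ClusterResult",
    "init_state",
    "objective",
    "update_mappings",
    "update_common",
    "update_specific",
    "update_centers",
    "update_assignments",
    "update_weights",
    "fit",
]

RIDGE = 1e-8


@dataclass
class ClusteringState:
    """All blocks of the alternating optimisation.

    ``Hc``: (dc, N) common representation; ``Hs[m]``: (ds, N) specific;
    ``Wmaps[m]``: (dc, d'_m) and ``Pmaps[m]``: (ds, d'_m) mapping matrices;
    ``centers[m]``: (ds, C) for the M scales plus (dc, C) for the common
    block; ``U``: (C, N) one-hot columns; ``alpha``: (M+1,) simplex weights.
    """

    Hc: np.ndarray
    Hs: List[np.ndarray]
    Wmaps: List[np.ndarray]
    Pmaps: List[np.ndarray]
    centers: List[np.ndarray]
    U: np.ndarray
    alpha: np.ndarray
    beta: float
    lam: float
    delta: float
    C: int
    trace: List[float] = field(default_factory=list)

    @property
    def n_scales(self) -> int:
        return len(self.Hs)

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.U, axis=0)


@dataclass
class ClusterResult:
    labels: np.ndarray
    alpha: np.ndarray
    objective_trace: List[float]
    n_iter: int
    converged: bool


def _one_hot(labels: np.ndarray, C: int) -> np.ndarray:
    U = np.zeros((C, labels.size))
    U[labels, np.arange(labels.size)] = 1.0
    return U


def _semi_orthogonal(rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((rows, cols))
    u, _, vt = np.linalg.svd(A, full_matrices=False)
    return u @ vt


def _truncated_factor(H: np.ndarray, dim: int) -> np.ndarray:
    """Rank-``dim`` left factor (dim x N) of a spots-major matrix via SVD."""
    u, s, _ = np.linalg.svd(H, full_matrices=False)
    dim = min(dim, s.size)
    return (u[:, :dim] * s[:dim]).T


def init_state(
    H: MultiScaleEmbeddings,
    C: int,
    dc: int = 64,
    ds: int = 32,
    beta: float = 0.1,
    lam: float = 1.0,
    delta: Optional[float] = None,
    seed: int = 0,
) -> ClusteringState:
    """Initialise all blocks.

    Mapping matrices start semi-orthogonal; ``Hc``/``Hs^m`` come from
    truncated SVD factorisations; ``U`` from k-means on the concatenated
    embeddings; centroids from cluster means.  ``delta`` defaults to the
    mean initial clustering cost, placing the entropy softmax in its
    responsive regime.
    """
    N = H.n_spots
    if C < 2:
        raise ValueError("need at least two clusters")
    if C > N:
        raise ValueError(f"C={C} exceeds the number of spots N={N}")
    M = H.n_scales
    dims = [h.shape[1] for h in H.per_scale]
    dc = min(dc, N)
    ds = min(ds, N)
    rng = np.random.default_rng(seed)

    Hm64 = [np.asarray(h, dtype=np.float64) for h in H.per_scale]
    concat = np.hstack(Hm64)
    Hc = _truncated_factor(concat, dc)
    if Hc.shape[0] < dc:  # rank-deficient input: pad with zero rows
        Hc = np.vstack([Hc, np.zeros((dc - Hc.shape[0], N))])
    Hs = []
    for h in Hm64:
        f = _truncated_factor(h, ds)
        if f.shape[0] < ds:
            f = np.vstack([f, np.zeros((ds - f.shape[0], N))])
        Hs.append(f)
    Wmaps = [_semi_orthogonal(dc, dm, rng) for dm in dims]
    Pmaps = [_semi_orthogonal(ds, dm, rng) for dm in dims]

    km = KMeans(n_clusters=C, n_init=10, random_state=int(rng.integers(2**31)))
    labels = km.fit_predict(concat)
    U = _one_hot(labels, C)

    centers = []
    for R in Hs + [Hc]:
        V = np.zeros((R.shape[0], C))
        for c in range(C):
            idx = np.flatnonzero(labels == c)
            if idx.size:
                V[:, c] = R[:, idx].mean(axis=1)
        centers.append(V)

    alpha = np.full(M + 1, 1.0 / (M + 1))
    state = ClusteringState(
        Hc=Hc, Hs=Hs, Wmaps=Wmaps, Pmaps=Pmaps, centers=centers, U=U,
        alpha=alpha, beta=beta, lam=lam, delta=0.0, C=C,
    )
    if delta is None:
        delta = float(np.mean(_clustering_costs(state)))
        delta = max(delta, 1e-12)
    if delta <= 0:
        raise ValueError("delta must be positive")
    state.delta = float(delta)
    state.trace.append(objective(state, H))
    return state


def _clustering_costs(state: ClusteringState) -> np.ndarray:
    """Per-representation clustering cost ||R - V U||_F^2 (common block last)."""
    reps = state.Hs + [state.Hc]
    return np.array([
        np.linalg.norm(R - V @ state.U) ** 2 for R, V in zip(reps, state.centers)
    ])


def objective(state: ClusteringState, H: MultiScaleEmbeddings) -> float:
    """Evaluate the full clustering objective at the current state."""
    val = 0.0
    for m, Hm in enumerate(H.per_scale):
        resid = np.asarray(Hm, dtype=np.float64) \
            - state.Hc.T @ state.Wmaps[m] - state.Hs[m].T @ state.Pmaps[m]
        val += np.linalg.norm(resid) ** 2
    val += state.beta * np.linalg.norm(state.Hc) ** 2
    val += state.beta * sum(np.linalg.norm(h) ** 2 for h in state.Hs)
    costs = _clustering_costs(state)
    val += float(state.alpha @ costs)
    for V in state.centers:
        G = V.T @ V - np.eye(state.C)
        val += state.lam * np.linalg.norm(G) ** 2
    a = state.alpha
    ent = np.where(a > 0, a * np.log(np.where(a > 0, a, 1.0)), 0.0)
    val += state.delta * float(ent.sum())
    return float(val)


def update_mappings(state: ClusteringState, H: MultiScaleEmbeddings) -> ClusteringState:
    """Exact ridge-regularised least-squares update of every Wm then Pm."""
    Hc = state.Hc
    Gc = Hc @ Hc.T + RIDGE * np.eye(Hc.shape[0])
    for m, Hm in enumerate(H.per_scale):
        Hm = np.asarray(Hm, dtype=np.float64)
        state.Wmaps[m] = np.linalg.solve(Gc, Hc @ (Hm - state.Hs[m].T @ state.Pmaps[m]))
    for m, Hm in enumerate(H.per_scale):
        Hm = np.asarray(Hm, dtype=np.float64)
        S = state.Hs[m]
        Gs = S @ S.T + RIDGE * np.eye(S.shape[0])
        state.Pmaps[m] = np.linalg.solve(Gs, S @ (Hm - state.Hc.T @ state.Wmaps[m]))
    return state


def update_common(state: ClusteringState, H: MultiScaleEmbeddings) -> ClusteringState:
    """Exact linear-system update of the common representation Hc."""
    dc = state.Hc.shape[0]
    aM1 = state.alpha[-1]
    A = (state.beta + aM1 + RIDGE) * np.eye(dc)
    B = aM1 * state.centers[-1] @ state.U
    for m, Hm in enumerate(H.per_scale):
        Wm = state.Wmaps[m]
        A += Wm @ Wm.T
        Rm = np.asarray(Hm, dtype=np.float64) - state.Hs[m].T @ state.Pmaps[m]
        B += Wm @ Rm.T
    state.Hc = np.linalg.solve(A, B)
    return state


def update_specific(state: ClusteringState, H: MultiScaleEmbeddings) -> ClusteringState:
    """Exact linear-system update of every scale-specific representation Hs^m."""
    ds = state.Hs[0].shape[0]
    for m, Hm in enumerate(H.per_scale):
        Pm = state.Pmaps[m]
        am = state.alpha[m]
        A = Pm @ Pm.T + (state.beta + am + RIDGE) * np.eye(ds)
        Rm = np.asarray(Hm, dtype=np.float64) - state.Hc.T @ state.Wmaps[m]
        B = Pm @ Rm.T + am * state.centers[m] @ state.U
        state.Hs[m] = np.linalg.solve(A, B)
    return state


def _center_block_value(V, R, U, alpha_m, lam, C):
    G = V.T @ V - np.eye(C)
    return alpha_m * np.linalg.norm(R - V @ U) ** 2 + lam * np.linalg.norm(G) ** 2


def update_centers(
    state: ClusteringState,
    H: MultiScaleEmbeddings,
    max_steps: int = 50,
    tol: float = 1e-10,
) -> ClusteringState:
    """Monotone descent on each centroid matrix Vm.

    The subproblem ``alpha_m ||R - V U||^2 + lambda ||V^T V - I||^2`` is
    quartic in V; it is minimised by gradient descent with backtracking,
    warm-started at the better of the current V and the ``lambda = 0``
    closed form (cluster means).  Empty clusters are re-seeded at the
    worst-fit column of R.
    """
    reps = state.Hs + [state.Hc]
    U = state.U
    counts = U.sum(axis=1)
    for m, (R, V) in enumerate(zip(reps, state.centers)):
        alpha_m = state.alpha[m]
        if np.any(counts == 0):
            V = V.copy()
            # re-seed empty clusters at the points worst explained now
            cost = np.linalg.norm(R - V @ U, axis=0)
            for c in np.flatnonzero(counts == 0):
                j = int(np.argmax(cost))
                V[:, c] = R[:, j]
                cost[j] = -np.inf
            logger.warning("re-seeded %d empty cluster(s) in centre update",
                           int((counts == 0).sum()))
        f_cur = _center_block_value(V, R, U, alpha_m, state.lam, state.C)
        # lambda = 0 closed form: cluster means (ridge keeps empties finite)
        V0 = R @ U.T @ np.linalg.inv(np.diag(np.maximum(counts, 0.0)) + RIDGE * np.eye(state.C))
        f0 = _center_block_value(V0, R, U, alpha_m, state.lam, state.C)
        if f0 < f_cur:
            V, f_cur = V0, f0
        step = 1.0 / (2 * alpha_m * max(counts.max(), 1.0)
                      + 8 * state.lam * max(np.linalg.norm(V, 2) ** 2, 1.0))
        for _ in range(max_steps):
            G = V.T @ V - np.eye(state.C)
            grad = 2 * alpha_m * (V @ U - R) @ U.T + 4 * state.lam * V @ G
            gnorm = np.linalg.norm(grad)
            if gnorm**2 < tol:
                break
            # backtracking: only accept strictly non-increasing steps
            accepted = False
            s = step
            for _ in range(30):
                V_new = V - s * grad
                f_new = _center_block_value(V_new, R, U, alpha_m, state.lam, state.C)
                if f_new <= f_cur:
                    V, f_cur, accepted = V_new, f_new, True
                    break
                s *= 0.5
            if not accepted:
                break
        state.centers[m] = V
    return state


def update_assignments(state: ClusteringState, H: MultiScaleEmbeddings) -> ClusteringState:
    """Assign every spot to its cheapest cluster (ties to the lowest index).

    The columns of U are independent given the other blocks, so the exact
    minimiser is the per-spot argmin of the alpha-weighted squared
    distances to the centroids across all M+1 representations.
    """
    reps = state.Hs + [state.Hc]
    N = state.U.shape[1]
    cost = np.zeros((state.C, N))
    for alpha_m, R, V in zip(state.alpha, reps, state.centers):
        # squared distances between columns of R (dxN) and V (dxC)
        d2 = (
            np.sum(R**2, axis=0)[None, :]
            - 2.0 * V.T @ R
            + np.sum(V**2, axis=0)[:, None]
        )
        cost += alpha_m * d2
    labels = np.argmin(cost, axis=0)  # argmin takes the lowest index on ties
    state.U = _one_hot(labels, state.C)
    return state


def update_weights(state: ClusteringState, H: MultiScaleEmbeddings) -> ClusteringState:
    """Exact entropy-regularised weight update: softmax of -cost/delta."""
    if state.delta <= 0:
        raise ValueError("delta must be positive")
    costs = _clustering_costs(state)
    z = -costs / state.delta
    z -= z.max()
    w = np.exp(z)
    state.alpha = w / w.sum()
    return state


_BLOCKS = (
    update_mappings,
    update_common,
    update_specific,
    update_centers,
    update_assignments,
    update_weights,
)


def fit(
    H: MultiScaleEmbeddings,
    C: int,
    dc: int = 64,
    ds: int = 32,
    beta: float = 0.1,
    lam: float = 1.0,
    delta: Optional[float] = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    seed: int = 0,
) -> ClusterResult:
    """Run the alternating optimisation to convergence.

    One iteration sweeps the blocks in the order mappings, common,
    specific, centroids, assignments, weights; convergence is declared when
    the relative objective change over one sweep drops below ``tol``.
    """
    state = init_state(H, C, dc=dc, ds=ds, beta=beta, lam=lam, delta=delta, seed=seed)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for block in _BLOCKS:
            block(state, H)
        val = objective(state, H)
        if not np.isfinite(val):
            raise RuntimeError(f"non-finite objective after iteration {it}")
        prev = state.trace[-1]
        state.trace.append(val)
        if abs(prev - val) <= tol * max(abs(prev), 1.0):
            converged = True
            break
    return ClusterResult(
        labels=state.labels,
        alpha=state.alpha.copy(),
        objective_trace=list(state.trace),
        n_iter=it if max_iter > 0 else 0,
        converged=converged,
    )
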