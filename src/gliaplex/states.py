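"""Unsupervised discovery of glial states by spectral clustering.

The pairwise affinity is the scaled exponential similarity kernel
``W_ij = exp(−d_ij² / (µ·ε_ij²))`` with the local scale
``ε_ij = (mean_K(i) + mean_K(j) + d_ij)/3`` built from K-nearest-neighbor
mean distances, *without* K-NN sparsification of W. Clustering follows the
normalized spectral embedding (symmetric Laplacian, row-normalized
eigenvectors, k-means). The number of clusters is assessed with the
eigengap heuristic and with a rotation (discretisation) cost on the leading
eigenvectors; resulting clusters are named homeostatic / intermediate /
reactive by ranking a reactivity score over the reactive marker panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh, svd
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import KMeans

from .panel import REACTIVE_PANEL, STATE_NAMES
from .profiles import IntensityMatrix

__all__ = [
    "AffinityGraph",
    "ClusteringResult",
    "affinity_matrix",
    "spectral_cluster",
    "estimate_k",
    "name_states",
    "crosstab_states",
    "display_scale",
    "cluster_states",
]

_DEGREE_FLOOR = 1e-12


@dataclass
class AffinityGraph:
    """Symmetric nonnegative affinity matrix with its kernel parameters."""

    W: np.ndarray
    K: int
    mu: float

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.all(np.isfinite(W)):
            raise ValueError("W must be finite")
        self.W = (W + W.T) / 2.0

    def __len__(self):
        return self.W.shape[0]


@dataclass
class ClusteringResult:
    labels: np.ndarray  # state names, per profile
    cluster_index: np.ndarray  # raw cluster ids 0..k-1
    k: int
    eigenvalues: np.ndarray  # leading ascending spectrum of the normalized Laplacian
    eigengap_choice: int
    rotation_choice: int
    display_matrix: pd.DataFrame  # markers × states, scaled 0–100
    state_means: pd.DataFrame  # markers × states, raw mean z


def affinity_matrix(X, K: int = 20, mu: float = 0.5) -> AffinityGraph:
    """Scaled exponential similarity kernel over the rows of X.

    No K-NN sparsification is applied: K only enters through the local
    scale ε. Coincident rows get affinity exp(0) = 1.
    """
    values = X.values.to_numpy() if isinstance(X, IntensityMatrix) else np.asarray(X, float)
    n = values.shape[0]
    if K >= n:
        raise ValueError(f"K={K} must be smaller than n={n}")
    if mu <= 0:
        raise ValueError("mu must be positive")
    D = squareform(pdist(values, metric="euclidean"))
    # mean distance to the K nearest neighbors, excluding self
    sortd = np.sort(D, axis=1)[:, 1 : K + 1]
    mean_k = sortd.mean(axis=1)
    eps = (mean_k[:, None] + mean_k[None, :] + D) / 3.0
    eps = np.maximum(eps, np.finfo(float).tiny)
    W = np.exp(-(D**2) / (mu * eps**2))
    return AffinityGraph(W=W, K=K, mu=mu)


def _normalized_laplacian(W: np.ndarray) -> np.ndarray:
    deg = W.sum(axis=1)
    if np.any(deg <= 0):
        warnings.warn("zero-degree node(s); applying degree floor", stacklevel=3)
        deg = np.maximum(deg, _DEGREE_FLOOR)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = -W * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    np.fill_diagonal(L, 1.0 + np.diagonal(L))
    return (L + L.T) / 2.0


def _spectrum(W: np.ndarray, m: int):
    """Smallest m eigenpairs of the normalized Laplacian, ascending."""
    L = _normalized_laplacian(W)
    m = min(m, L.shape[0])
    vals, vecs = eigh(L, subset_by_index=(0, m - 1))
    return vals, vecs


def spectral_cluster(W, k: int, seed: int = 0, n_init: int = 50) -> np.ndarray:
    """Normalized spectral clustering (Ng–Jordan–Weiss) into k clusters.

    Embeds rows into the k eigenvectors of the smallest eigenvalues of the
    symmetric normalized Laplacian, row-normalizes to unit length, and runs
    k-means with ``n_init`` restarts at a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    W = W.W if isinstance(W, AffinityGraph) else np.asarray(W, float)
    _, vecs = _spectrum(W, k)
    U = vecs[:, :k]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    U = U / np.maximum(norms, np.finfo(float).tiny)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(U)


def _rotation_cost(U: np.ndarray, n_iter: int = 30) -> float:
    """Discretisation (rotation) cost of an eigenvector block.

    Alternates between snapping the rotated eigenvectors to the nearest
    cluster-indicator matrix and re-solving the optimal orthogonal rotation
    (Procrustes); returns the final normalized misfit
    ``‖X − U R‖²_F / n = 2(1 − Σσ/n)``. Near-zero cost means the leading
    subspace is rotatable to an indicator structure, i.e. k fits.
    """
    n, k = U.shape
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    U = U / np.maximum(norms, np.finfo(float).tiny)
    # deterministic farthest-point init of the rotation (as in ncut discretisation)
    R = np.zeros((k, k))
    R[:, 0] = U[0]
    c = np.zeros(n)
    for j in range(1, k):
        c += np.abs(U @ R[:, j - 1])
        R[:, j] = U[int(np.argmin(c))]
    last = None
    for _ in range(n_iter):
        X = np.zeros((n, k))
        X[np.arange(n), np.argmax(U @ R, axis=1)] = 1.0
        M = X.T @ U
        P, S, Qt = svd(M)
        R = (P @ Qt).T
        total = S.sum()
        if last is not None and abs(total - last) < 1e-10:
            break
        last = total
    return float(2.0 * (1.0 - total / n))


def estimate_k(W, k_range=range(2, 11), seed: int = 0) -> tuple[int, int]:
    """Assess the number of clusters two ways.

    Returns ``(eigengap_choice, rotation_choice)``: the k maximizing the gap
    ``λ_{k+1} − λ_k`` of the ascending normalized-Laplacian spectrum, and
    the k minimizing the rotation (discretisation) cost of the first k
    eigenvectors.
    """
    del seed  # both criteria are deterministic; kept for interface stability
    W = W.W if isinstance(W, AffinityGraph) else np.asarray(W, float)
    ks = sorted(k_range)
    if ks[0] < 2 or ks[-1] >= W.shape[0]:
        raise ValueError("k_range must lie within 2..n-1")
    vals, vecs = _spectrum(W, ks[-1] + 1)
    gaps = {k: vals[k] - vals[k - 1] for k in ks}
    eigengap_choice = max(ks, key=lambda k: gaps[k])
    eps = np.finfo(float).eps
    costs = {}
    for k in ks:
        # the misfit alone cannot punish under-clustering (dropping an
        # indicator eigenvector collapses clusters), so it is weighted by the
        # spectral ratio (1-λ_{k+1})/(1-λ_k), small exactly when k indicator
        # directions are exhausted
        ratio = max(1.0 - vals[k], eps) / max(1.0 - vals[k - 1], eps)
        costs[k] = ratio * (1.0 + _rotation_cost(vecs[:, :k]))
    rotation_choice = min(ks, key=lambda k: costs[k])
    return eigengap_choice, rotation_choice


def name_states(cluster_index: np.ndarray, X: IntensityMatrix, cell_type: str) -> dict:
    """Map raw cluster ids to state names by mean reactivity score.

    The reactivity score of a cluster is the mean z-score over the
    cell type's reactive marker panel; clusters ranked ascending are named
    homeostatic, intermediate, reactive (with generic ``state{i}`` names
    beyond three clusters).
    """
    markers = [m for m in REACTIVE_PANEL[cell_type] if m in X.markers]
    if not markers:
        raise ValueError(f"matrix has no reactive-panel markers for {cell_type}")
    score = X.values[markers].mean(axis=1).to_numpy()
    ids = np.unique(cluster_index)
    means = {cid: score[cluster_index == cid].mean() for cid in ids}
    ranked = sorted(ids, key=lambda cid: means[cid])
    names = list(STATE_NAMES) if len(ids) == 3 else [f"state{i + 1}" for i in range(len(ids))]
    return {cid: names[i] for i, cid in enumerate(ranked)}


def crosstab_states(states, diagnoses) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """State-by-diagnosis composition tables.

    Returns ``(within_diagnosis, within_state, counts)``: row-stochastic
    proportions of states within each diagnosis, column-stochastic
    proportions of diagnoses within each state, and the raw 2×k contingency
    table, columns ordered homeostatic < intermediate < reactive.
    """
    states = pd.Series(states, name="state")
    diagnoses = pd.Series(diagnoses, name="diagnosis")
    counts = pd.crosstab(diagnoses, states)
    order = [s for s in STATE_NAMES if s in counts.columns] + [
        s for s in counts.columns if s not in STATE_NAMES
    ]
    counts = counts[order]
    row_order = [d for d in ("CTRL", "AD") if d in counts.index] + [
        d for d in counts.index if d not in ("CTRL", "AD")
    ]
    counts = counts.loc[row_order]
    within_diagnosis = counts.div(counts.sum(axis=1), axis=0)
    within_state = counts.div(counts.sum(axis=0), axis=1)
    return within_diagnosis, within_state, counts


def display_scale(state_means: pd.DataFrame) -> pd.DataFrame:
    """Affine-rescale each marker row to [0, 100] for heatmap display."""
    out = state_means.copy().astype(float)
    for mk in out.index:
        row = out.loc[mk]
        lo, hi = row.min(), row.max()
        if hi <= lo:
            warnings.warn(f"constant display row for {mk!r}; set to 50", stacklevel=2)
            out.loc[mk] = 50.0
        else:
            out.loc[mk] = (row - lo) / (hi - lo) * 100.0
    return out


def cluster_states(
    X: IntensityMatrix,
    cell_type: str,
    k: int | str = "auto",
    K: int = 20,
    mu: float = 0.5,
    seed: int = 0,
    k_range=range(2, 11),
) -> ClusteringResult:
    """Full state-discovery pipeline on an intensity matrix.

    With ``k='auto'`` the eigengap choice is used (the rotation choice is
    still reported); pass an integer to override — the final cluster count
    in this kind of study is partly a human call.
    """
    graph = affinity_matrix(X, K=K, mu=mu)
    eigengap_choice, rotation_choice = estimate_k(graph, k_range=k_range)
    k_final = eigengap_choice if k == "auto" else int(k)
    vals, _ = _spectrum(graph.W, max(k_final, max(k_range)) + 1)
    cluster_index = spectral_cluster(graph, k_final, seed=seed)
    mapping = name_states(cluster_index, X, cell_type)
    labels = np.array([mapping[c] for c in cluster_index])
    state_means = (
        X.values.assign(_state=labels).groupby("_state").mean().T
    )
    order = [s for s in STATE_NAMES if s in state_means.columns] + [
        s for s in state_means.columns if s not in STATE_NAMES
    ]
    state_means = state_means[order]
    return ClusteringResult(
        labels=labels,
        cluster_index=cluster_index,
        k=k_final,
        eigenvalues=vals,
        eigengap_choice=eigengap_choice,
        rotation_choice=rotation_choice,
        display_matrix=display_scale(state_means),
        state_means=state_means,
    )
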