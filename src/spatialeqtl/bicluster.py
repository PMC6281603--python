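"""Convex biclustering of phenotype sharing matrices.

Solves the convex biclustering (COBRA-style) problem

    minimise  F_gamma(U) = 1/2 ||X - U||_F^2
              + gamma * [ sum_{(i,j)} w_ij ||U_:i - U_:j||_2
                        + sum_{(k,l)} w~_kl ||U_k: - U_l:||_2 ]

where the column weights w and row weights w~ come from a Gaussian kernel
restricted to k-nearest neighbours.  The fusion penalties pull similar
columns (and rows) toward identical profiles; as gamma grows the solution
path coarsens until everything fuses at the grand mean.  A hold-out
validation over a gamma grid selects the smoothing level, and clusters
are read off the smoothed matrix as connected components of near-identical
columns/rows.

Solver
------
The objective is minimised by majorisation-minimisation on the
epsilon-smoothed penalty sqrt(||d||^2 + eps^2) (iteratively reweighted
ridge).  Each MM step solves the Sylvester-type system

    U + gamma * (L_r U + U L_c) = X

with the current weighted graph Laplacians L_r, L_c, exactly via their
eigendecompositions; the smoothed objective therefore decreases
monotonically.  Matrices here are small (tens of phenotypes), so the
per-iteration eigendecompositions are cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


@dataclass
class WeightGraph:
    """Sparse symmetric fusion weights for columns and rows.

    ``col_edges``/``row_edges`` are (E, 2) index arrays with i < j;
    weights are non-negative and each edge set forms a connected graph
    (required for a unique fully-fused limit).
    """

    col_edges: np.ndarray
    col_weights: np.ndarray
    row_edges: np.ndarray
    row_weights: np.ndarray
    phi: float
    k: int


@dataclass
class CobraResult:
    """Solution path, validation curve and clustering of one biclustering run."""

    gammas: np.ndarray
    errors: np.ndarray
    gamma_opt: float
    index_opt: int
    U_opt: np.ndarray
    U_path: list = field(default_factory=list)
    row_clusters: np.ndarray | None = None
    col_clusters: np.ndarray | None = None
    holdout_mask: np.ndarray | None = None


def _knn_edges(D2: np.ndarray, k: int) -> set[tuple[int, int]]:
    """Union-symmetrised k-nearest-neighbour edge set from squared distances."""
    m = D2.shape[0]
    edges: set[tuple[int, int]] = set()
    for i in range(m):
        order = np.argsort(D2[i], kind="stable")
        picked = [j for j in order if j != i][:k]
        for j in picked:
            edges.add((min(i, j), max(i, j)))
    return edges


def _is_connected(n: int, edges: np.ndarray) -> bool:
    if n <= 1:
        return True
    if len(edges) == 0:
        return False
    g = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    ncomp, _ = connected_components(g, directed=False)
    return ncomp == 1


def _axis_weights(V: np.ndarray, k: int, phi: float) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel kNN weights over the columns of V (as vectors)."""
    m = V.shape[1]
    if m < 2:
        raise ValueError("need at least 2 columns/rows to build weights")
    G = V.T @ V
    sq = np.diag(G)
    D2 = np.maximum(sq[:, None] + sq[None, :] - 2 * G, 0.0)
    k_eff = min(k, m - 1)
    while True:
        edge_set = _knn_edges(D2, k_eff)
        edges = np.array(sorted(edge_set), dtype=np.int64).reshape(-1, 2)
        if _is_connected(m, edges):
            break
        k_eff += 1
        warnings.warn(
            f"kNN graph disconnected; escalating k to {k_eff}", stacklevel=3
        )
    w = np.exp(-phi * D2[edges[:, 0], edges[:, 1]])
    total = w.sum()
    if total > 0:
        w = w / total  # normalise each edge set to unit mass
    return edges, w


def build_weights(X: np.ndarray, k: int = 5, phi: float = 0.5) -> WeightGraph:
    """Combined Gaussian-kernel k-nearest-neighbour fusion weights.

    Column weights: w_ij = exp(-phi * ||X_:i - X_:j||^2), kept only when j
    is among i's k nearest columns (symmetrised by union), then normalised
    to unit total mass; row weights analogously.  If either kNN graph is
    disconnected, k is escalated with a warning until it connects.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    col_edges, col_w = _axis_weights(X, k, phi)
    row_edges, row_w = _axis_weights(X.T, k, phi)
    return WeightGraph(
        col_edges=col_edges,
        col_weights=col_w,
        row_edges=row_edges,
        row_weights=row_w,
        phi=phi,
        k=k,
    )


def gamma_grid(
    n: int = 100, low: float = 1.0, high: float = 1000.0, log: bool = True
) -> np.ndarray:
    """Regularisation path grid: n values from low to high, log10-spaced.

    Equal spacing on the log10 scale between 10^0 and 10^3 by default
    (endpoints exact); ``log=False`` gives linear spacing.
    """
    if n < 2:
        raise ValueError("grid needs n >= 2")
    if not (0 < low < high):
        raise ValueError("require 0 < low < high")
    if log:
        return np.logspace(np.log10(low), np.log10(high), n)
    return np.linspace(low, high, n)


def _penalty(U: np.ndarray, weights: WeightGraph, eps: float = 0.0) -> float:
    dc = U[:, weights.col_edges[:, 0]] - U[:, weights.col_edges[:, 1]]
    dr = U[weights.row_edges[:, 0], :] - U[weights.row_edges[:, 1], :]
    nc = np.sqrt((dc * dc).sum(axis=0) + eps * eps)
    nr = np.sqrt((dr * dr).sum(axis=1) + eps * eps)
    return float(weights.col_weights @ nc + weights.row_weights @ nr)


def cobra_objective(
    X: np.ndarray, U: np.ndarray, weights: WeightGraph, gamma: float, eps: float = 0.0
) -> float:
    """F_gamma(U), optionally with the eps-smoothed fusion norms."""
    fid = 0.5 * float(((X - U) ** 2).sum())
    return fid + gamma * _penalty(U, weights, eps)


def _laplacian(n: int, edges: np.ndarray, w: np.ndarray) -> np.ndarray:
    L = np.zeros((n, n))
    i, j = edges[:, 0], edges[:, 1]
    np.add.at(L, (i, i), w)
    np.add.at(L, (j, j), w)
    np.add.at(L, (i, j), -w)
    np.add.at(L, (j, i), -w)
    return L


def cobra_solve(
    X: np.ndarray,
    weights: WeightGraph,
    gamma: float,
    tol: float = 1e-6,
    max_iter: int = 500,
    eps: float = 1e-6,
    U0: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Minimise the convex biclustering objective at one gamma.

    Returns ``(U, info)`` where ``info`` carries the monotone objective
    history (eps-smoothed objective), the exact objective at the solution,
    iteration count and convergence flag.  gamma = 0 returns X exactly.
    A run hitting ``max_iter`` warns and returns the best iterate.
    """
    X = np.asarray(X, dtype=float)
    p, m = X.shape
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if gamma == 0.0:
        return X.copy(), {
            "objective_history": [0.0],
            "objective": 0.0,
            "iterations": 0,
            "converged": True,
        }
    U = X.copy() if U0 is None else np.asarray(U0, dtype=float).copy()
    ce, cw = weights.col_edges, weights.col_weights
    re_, rw = weights.row_edges, weights.row_weights
    history = [cobra_objective(X, U, weights, gamma, eps)]
    converged = False
    for it in range(1, max_iter + 1):
        dc = U[:, ce[:, 0]] - U[:, ce[:, 1]]
        dr = U[re_[:, 0], :] - U[re_[:, 1], :]
        sc = np.sqrt((dc * dc).sum(axis=0) + eps * eps)
        sr = np.sqrt((dr * dr).sum(axis=1) + eps * eps)
        Lc = _laplacian(m, ce, cw / sc)
        Lr = _laplacian(p, re_, rw / sr)
        lam_c, Qc = np.linalg.eigh(Lc)
        lam_r, Qr = np.linalg.eigh(Lr)
        denom = 1.0 + gamma * (lam_r[:, None] + lam_c[None, :])
        U = Qr @ ((Qr.T @ X @ Qc) / denom) @ Qc.T
        obj = cobra_objective(X, U, weights, gamma, eps)
        history.append(obj)
        if abs(history[-2] - obj) <= tol * max(1.0, abs(history[-2])):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"cobra_solve: max_iter={max_iter} reached at gamma={gamma:g} "
            "without meeting tolerance; returning best iterate",
            stacklevel=2,
        )
    return U, {
        "objective_history": history,
        "objective": cobra_objective(X, U, weights, gamma, 0.0),
        "iterations": len(history) - 1,
        "converged": converged,
    }


def extract_clusters(
    U: np.ndarray, tol_cluster: float = 0.02
) -> tuple[np.ndarray, np.ndarray]:
    """Read row and column partitions off a smoothed matrix.

    Columns i, j share a label iff they are connected through edges with
    ||U_:i - U_:j||_2 <= tol_cluster * scale(U), where scale is the value
    range of U (1 if constant); rows analogously.  Returns
    (row_labels, col_labels) as 0-based integer arrays.
    """
    U = np.asarray(U, dtype=float)
    scale = float(U.max() - U.min())
    if scale == 0.0:
        scale = 1.0
    thr = tol_cluster * scale

    def labels_of(V: np.ndarray) -> np.ndarray:
        m = V.shape[1]
        G = V.T @ V
        sq = np.diag(G)
        D = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2 * G, 0.0))
        adj = coo_matrix(D <= thr)
        _, lab = connected_components(adj, directed=False)
        return lab

    return labels_of(U.T), labels_of(U)


def validate_path(
    X: np.ndarray,
    grid: np.ndarray | None = None,
    holdout_fraction: float = 0.1,
    seed: int = 0,
    weights: WeightGraph | None = None,
    k: int = 5,
    phi: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 500,
    tol_cluster: float = 0.02,
    keep_path: bool = False,
) -> CobraResult:
    """Hold-out validation over the gamma path; smooth at the best gamma.

    A seeded random subset of entries is held out and replaced by the mean
    of the observed entries; the solver runs along the grid (warm-started)
    on the completed matrix, and the validation error at each gamma is the
    mean squared difference between the smoothed matrix and the true
    held-out values.  gamma* is the argmin; the returned ``U_opt`` is the
    solution at gamma* on the full (un-masked) matrix, with row/column
    clusters extracted from it.
    """
    X = np.asarray(X, dtype=float)
    if not (0.0 < holdout_fraction <= 0.5):
        raise ValueError("holdout_fraction must lie in (0, 0.5]")
    if grid is None:
        grid = gamma_grid()
    grid = np.asarray(grid, dtype=float)
    if weights is None:
        weights = build_weights(X, k=k, phi=phi)
    rng = np.random.default_rng(seed)
    n_entries = X.size
    n_hold = max(1, int(round(holdout_fraction * n_entries)))
    flat = rng.choice(n_entries, size=n_hold, replace=False)
    mask = np.zeros(n_entries, dtype=bool)
    mask[flat] = True
    mask = mask.reshape(X.shape)
    X_completed = X.copy()
    X_completed[mask] = X[~mask].mean()
    errors = np.empty(len(grid))
    U_path: list[np.ndarray] = []
    U_warm = None
    for g_idx, gamma in enumerate(grid):
        U_g, _ = cobra_solve(
            X_completed, weights, gamma, tol=tol, max_iter=max_iter, U0=U_warm
        )
        U_warm = U_g
        errors[g_idx] = float(((U_g[mask] - X[mask]) ** 2).mean())
        if keep_path:
            U_path.append(U_g)
    index_opt = int(np.argmin(errors))
    gamma_opt = float(grid[index_opt])
    U_opt, _ = cobra_solve(X, weights, gamma_opt, tol=tol, max_iter=max_iter)
    row_clusters, col_clusters = extract_clusters(U_opt, tol_cluster=tol_cluster)
    return CobraResult(
        gammas=grid,
        errors=errors,
        gamma_opt=gamma_opt,
        index_opt=index_opt,
        U_opt=U_opt,
        U_path=U_path,
        row_clusters=row_clusters,
        col_clusters=col_clusters,
        holdout_mask=mask,
    )
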