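"""Independent brute-force oracles used to cross-check the implementation."""

import networkx as nx
import numpy as np


def gabriel_edges_bruteforce(xy: np.ndarray) -> set:
    """O(n^3) Gabriel edge set: (i, j) kept iff no k has
    d2(i,k) + d2(j,k) < d2(i,j) (Thales: strict interior of the open
    diametral disk); cocircular points do not block."""
    n = len(xy)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            blocked = False
            for k in range(n):
                if k in (i, j):
                    continue
                if d2[i, k] + d2[j, k] < d2[i, j] * (1 - 1e-12):
                    blocked = True
                    break
            if not blocked:
                edges.add((i, j))
    return edges


def components_bfs(n: int, edges) -> np.ndarray:
    """Connected-component labels via networkx breadth-first search."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    labels = np.full(n, -1)
    for lab, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            labels[node] = lab
    return labels


def covariance_eigenvalues(Y: np.ndarray) -> np.ndarray:
    """PCA eigenvalues from an explicit covariance eigendecomposition."""
    Yc = Y - Y.mean(axis=0)
    cov = Yc.T @ Yc / (len(Y) - 1)
    vals = np.linalg.eigvalsh(cov)[::-1]
    return vals[vals > 1e-12 * max(vals[0], 1.0)]


def hat_matrix_fit(Y: np.ndarray, X: np.ndarray):
    """Explicit hat-matrix RDA fit: Yhat = H_X Yc with H_X = Xc pinv(Xc).

    Standardization does not change the column space, so this is
    independent of how the implementation conditions X.
    """
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    H = Xc @ np.linalg.pinv(Xc)
    Yhat = H @ Yc
    r2 = float(np.sum(Yhat**2) / np.sum(Yc**2))
    return Yhat, r2


def greedy_forward_path(Y: np.ndarray, X: np.ndarray):
    """Exhaustive greedy forward path: at each step evaluate R^2 of the
    selected set plus each remaining candidate by an explicit hat-matrix
    fit and take the best. Returns (order, cumulative R2 list)."""
    m = X.shape[1]
    remaining = list(range(m))
    selected, cums = [], []
    while remaining:
        best, best_r2 = None, -np.inf
        for j in remaining:
            _, r2 = hat_matrix_fit(Y, X[:, selected + [j]])
            if r2 > best_r2 + 1e-12:
                best, best_r2 = j, r2
        selected.append(best)
        remaining.remove(best)
        cums.append(best_r2)
    return selected, cums
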