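"""Gabriel-graph spatial neighbor networks.

The Gabriel graph connects two sites if and only if no third site lies
strictly inside the open disk whose diameter is the segment between them.
It is a subgraph of the Delaunay triangulation and, for points in general
position drawn from a connected region, is itself connected — the property
the Moran's-eigenvector machinery downstream relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cs_components
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "Coordinates",
    "SpatialWeights",
    "build_gabriel_graph",
    "connected_components",
    "edges_to_csv",
]

# relative slack on the squared circumradius: a third point exactly on the
# circle (cocircular) does NOT block the edge
_COCIRCULAR_RTOL = 1e-12


@dataclass(frozen=True)
class Coordinates:
    """Planar site positions in projected units (e.g. km).

    Parameters
    ----------
    xy : (n, 2) array of planar positions.
    site_ids : optional sequence of n unique labels; defaults to s001..s00n.
    """

    xy: np.ndarray
    site_ids: tuple = field(default=None)

    def __post_init__(self):
        xy = np.asarray(self.xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError(f"coordinates must be (n, 2), got {xy.shape}")
        if not np.all(np.isfinite(xy)):
            raise ValueError("coordinates contain non-finite values")
        object.__setattr__(self, "xy", xy)
        n = len(xy)
        ids = self.site_ids
        if ids is None:
            width = max(3, len(str(n)))
            ids = tuple(f"s{i + 1:0{width}d}" for i in range(n))
        else:
            ids = tuple(str(s) for s in ids)
            if len(ids) != n:
                raise ValueError("site_ids length does not match coordinates")
            if len(set(ids)) != n:
                raise ValueError("site_ids are not unique")
        object.__setattr__(self, "site_ids", ids)
        dup = self._duplicate_pairs()
        if dup:
            names = ", ".join(f"({ids[i]}, {ids[j]})" for i, j in dup[:5])
            raise ValueError(f"duplicate coordinates for site pairs: {names}")

    def _duplicate_pairs(self):
        order = np.lexsort(self.xy.T)
        same = np.all(self.xy[order[1:]] == self.xy[order[:-1]], axis=1)
        return [(int(order[k]), int(order[k + 1])) for k in np.nonzero(same)[0]]

    @property
    def n(self) -> int:
        return len(self.xy)


@dataclass(frozen=True)
class SpatialWeights:
    """Symmetric binary spatial weights over ``n`` sites.

    ``edges`` holds unordered pairs (i, j) with i < j; weight 1 marks
    neighbors, the diagonal is zero.
    """

    n: int
    edges: tuple
    site_ids: tuple = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("spatial weights need at least 2 sites")
        edges = tuple(sorted((min(i, j), max(i, j)) for i, j in self.edges))
        for i, j in edges:
            if i == j:
                raise ValueError(f"self-loop at site index {i}")
            if not (0 <= i < self.n and 0 <= j < self.n):
                raise ValueError(f"edge ({i}, {j}) out of range for n={self.n}")
        if len(set(edges)) != len(edges):
            raise ValueError("duplicate edges")
        if not edges:
            raise ValueError("weights must contain at least one edge")
        object.__setattr__(self, "edges", edges)
        ids = self.site_ids
        if ids is not None:
            ids = tuple(str(s) for s in ids)
            if len(ids) != self.n:
                raise ValueError("site_ids length does not match n")
        object.__setattr__(self, "site_ids", ids)

    def matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix."""
        W = np.zeros((self.n, self.n))
        idx = np.asarray(self.edges)
        W[idx[:, 0], idx[:, 1]] = 1.0
        W[idx[:, 1], idx[:, 0]] = 1.0
        return W

    def sparse(self) -> csr_matrix:
        idx = np.asarray(self.edges)
        row = np.concatenate([idx[:, 0], idx[:, 1]])
        col = np.concatenate([idx[:, 1], idx[:, 0]])
        return csr_matrix((np.ones(len(row)), (row, col)), shape=(self.n, self.n))

    @property
    def total_weight(self) -> float:
        """Sum of all weights w_ij (each edge counted twice)."""
        return 2.0 * len(self.edges)


def _candidate_edges(xy: np.ndarray):
    """Delaunay edges when qhull accepts the input, otherwise all pairs."""
    n = len(xy)
    try:
        tri = Delaunay(xy)
    except QhullError:
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    pairs = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = int(simplex[a]), int(simplex[b])
                pairs.add((min(i, j), max(i, j)))
    return sorted(pairs)


def build_gabriel_graph(coords: Coordinates) -> SpatialWeights:
    """Build the Gabriel graph over planar site coordinates.

    An edge (i, j) is kept iff no third site falls strictly inside the open
    disk with diameter ij; cocircular third points do not block. Candidate
    edges are taken from the Delaunay triangulation (the Gabriel graph is a
    subgraph of it); degenerate inputs fall back to all pairs.
    """
    if coords.n < 3:
        raise ValueError("Gabriel graph construction requires n >= 3 sites")
    xy = coords.xy
    edges = []
    for i, j in _candidate_edges(xy):
        center = 0.5 * (xy[i] + xy[j])
        r2 = 0.25 * np.sum((xy[i] - xy[j]) ** 2)
        d2 = np.sum((xy - center) ** 2, axis=1)
        d2[i] = d2[j] = np.inf
        if np.min(d2) >= r2 * (1.0 - _COCIRCULAR_RTOL):
            edges.append((i, j))
    return SpatialWeights(n=coords.n, edges=tuple(edges), site_ids=coords.site_ids)


def connected_components(W: SpatialWeights) -> np.ndarray:
    """Component label per site (0-based); sites sharing a path share a label."""
    _, labels = _cs_components(W.sparse(), directed=False)
    return labels


def edges_to_csv(W: SpatialWeights, path) -> Path:
    """Write the edge list as a two-column CSV, lexicographically sorted."""
    ids = W.site_ids or tuple(str(i) for i in range(W.n))
    rows = sorted(tuple(sorted((ids[i], ids[j]))) for i, j in W.edges)
    df = pd.DataFrame(rows, columns=["site_id_a", "site_id_b"])
    path = Path(path)
    df.to_csv(path, index=False)
    return path
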