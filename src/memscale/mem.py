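"""Moran's Eigenvector Maps (MEMs).

MEMs are the eigenvectors of the doubly centered spatial weighting matrix
Omega = H W H, with H = I - 11'/n the centering projector and W a symmetric
binary adjacency (here: the Gabriel graph). They form an orthonormal basis
of the site space orthogonal to the constant vector, ordered from broad
spatial patterns (large positive eigenvalue, positive Moran's I) to fine
ones (negative eigenvalue, negative Moran's I). A connected graph yields
exactly n - 1 eigenvectors: the full centered eigenbasis, including any
structurally-zero-eigenvalue directions that symmetric site
configurations produce.

For each eigenvector v_k with eigenvalue lambda_k the Moran coefficient
obeys the closed form I(v_k) = n * lambda_k / sum(W), because v_k is
centered and unit-norm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import SpatialWeights, connected_components

__all__ = ["MEMBasis", "mem_basis", "morans_i", "split_by_sign", "basis_to_files"]

# |lambda| below this fraction of max|lambda| is treated as the structural null
_EIGENVALUE_RTOL = 1e-9


@dataclass(frozen=True)
class MEMBasis:
    """Orthonormal spatial eigenvectors with eigenvalues and Moran's I.

    ``vectors`` is n x k with columns ordered by descending eigenvalue;
    every column is unit norm and orthogonal to the constant vector.
    """

    vectors: np.ndarray
    eigenvalues: np.ndarray
    morans_i: np.ndarray
    n: int

    @property
    def k(self) -> int:
        return self.vectors.shape[1]


def morans_i(x: np.ndarray, W: SpatialWeights) -> float:
    """Moran's spatial autocorrelation coefficient of ``x`` on ``W``.

    I = (n / sum_ij w_ij) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (W.n,):
        raise ValueError(f"x must have shape ({W.n},), got {x.shape}")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("Moran's I undefined for constant x (zero variance)")
    Wm = W.sparse()
    cross = float(z @ (Wm @ z))
    return W.n / W.total_weight * cross / denom


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def _order_descending(vals: np.ndarray, vecs: np.ndarray):
    """Descending eigenvalue order; exact ties broken lexicographically on
    the (sign-fixed) eigenvector coordinates for reproducibility."""
    order = np.argsort(-vals, kind="stable")
    vals, vecs = vals[order], vecs[:, order]
    # resolve exact ties deterministically
    start = 0
    while start < len(vals):
        stop = start + 1
        while stop < len(vals) and vals[stop] == vals[start]:
            stop += 1
        if stop - start > 1:
            block = vecs[:, start:stop]
            key = np.lexsort(block[::-1])  # lexicographic by coordinates
            vecs[:, start:stop] = block[:, key]
        start = stop
    return vals, vecs


def mem_basis(W: SpatialWeights) -> MEMBasis:
    """Eigendecompose the doubly centered weights into the MEM basis.

    Raises if the graph is disconnected (the n-1 count and the scalogram
    interpretation both assume a single connected network).
    """
    if W.n < 3:
        raise ValueError("MEM basis requires at least 3 sites")
    labels = connected_components(W)
    n_comp = labels.max() + 1
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"spatial graph is disconnected: {n_comp} components with sizes "
            f"{sizes.tolist()}; MEMs require a connected graph"
        )
    n = W.n
    Wm = W.matrix()
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    omega = H @ Wm @ H
    omega = 0.5 * (omega + omega.T)  # guard symmetry against roundoff
    vals, vecs = np.linalg.eigh(omega)
    null = np.abs(vals) <= _EIGENVALUE_RTOL * np.max(np.abs(vals))
    keep_vals, keep_vecs = vals[~null], vecs[:, ~null]
    # the null space always holds the constant vector; symmetric site
    # configurations can add centered directions with a structurally zero
    # eigenvalue, which still belong to the basis (their Moran's I is 0)
    N = vecs[:, null]
    Nc = N - N.mean(axis=0)
    U, s, _ = np.linalg.svd(Nc, full_matrices=False)
    extra = U[:, s > 1e-9]
    if extra.shape[1]:
        keep_vals = np.concatenate([keep_vals, np.zeros(extra.shape[1])])
        keep_vecs = np.column_stack([keep_vecs, extra])
    vecs = _fix_signs(keep_vecs)
    vals, vecs = _order_descending(keep_vals, vecs)
    mi = n * vals / W.total_weight
    return MEMBasis(vectors=vecs, eigenvalues=vals, morans_i=mi, n=n)


def split_by_sign(basis: MEMBasis, tol: float = 1e-12):
    """Partition MEM columns into broad-medium (I > 0) and fine (I < 0) sets.

    Returns (broad_medium_indices, fine_indices); eigenvectors with |I|
    below ``tol`` are assigned to the fine set with a warning.
    """
    mi = basis.morans_i
    zero = np.abs(mi) < tol
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} MEM(s) with |Moran's I| < {tol} assigned to the fine-scale set",
            stacklevel=2,
        )
    broad = np.nonzero(mi >= tol)[0]
    fine = np.nonzero(mi < tol)[0]
    return broad, fine


def basis_to_files(basis: MEMBasis, csv_path, json_path, site_ids=None):
    """Export the basis: sites x vectors CSV plus a JSON eigenvalue sidecar."""
    names = [f"MEM{k + 1}" for k in range(basis.k)]
    index = list(site_ids) if site_ids is not None else list(range(basis.n))
    pd.DataFrame(basis.vectors, columns=names, index=pd.Index(index, name="site_id")).to_csv(csv_path)
    sidecar = {
        "n": basis.n,
        "eigenvalues": basis.eigenvalues.tolist(),
        "morans_i": basis.morans_i.tolist(),
    }
    Path(json_path).write_text(json.dumps(sidecar, indent=2))
    return Path(csv_path), Path(json_path)
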