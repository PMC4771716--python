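"""Scalograms: multi-scale variance decomposition of ordination scores.

A scalogram projects a centered axis-score vector onto the orthonormal MEM
basis and records the share of score variance, R^2_k = (v_k' s)^2 / (s' s),
carried by each eigenvector. Because the MEMs span the centered site space
these shares sum to one. Smoothing collocates successive eigenvectors
(ordered broad to fine) into consecutive blocks whose R^2 values are
summed, turning n-1 noisy bars into a small number of spatial components.

The R^2max test asks whether the largest smoothed component exceeds what
spatially unstructured scores would produce: the score values are randomly
permuted across sites, the smoothed scalogram recomputed, and the maximum
compared with the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mem import MEMBasis

__all__ = ["Scalogram", "mem_scalogram", "smooth_scalogram", "r2max_test"]

_CENTER_TOL = 1e-8


@dataclass(frozen=True)
class Scalogram:
    """Per-MEM and smoothed-component R^2 with the permutation-test result."""

    r2_per_mem: np.ndarray
    smoothed: np.ndarray
    group_bounds: tuple          # (start, stop) slice per component
    r2max: float
    argmax_component: int        # 0-based index of the maximal component
    p_value: float
    null_upper95: np.ndarray     # per-component 95% quantile of the null
    nperm: int
    seed: object

    @property
    def n_groups(self) -> int:
        return len(self.smoothed)


def _check_scores(scores: np.ndarray, n: int) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    if s.shape != (n,):
        raise ValueError(f"scores must have shape ({n},), got {s.shape}")
    scale = max(float(np.max(np.abs(s))), 1.0)
    if abs(s.mean()) > _CENTER_TOL * scale:
        raise ValueError("scores must be centered (mean zero)")
    if float(s @ s) == 0.0:
        raise ValueError("scores are constant (zero variance)")
    return s


def mem_scalogram(scores, basis: MEMBasis) -> np.ndarray:
    """Per-MEM R^2 of a centered score vector: (v_k' s)^2 / (s' s)."""
    s = _check_scores(scores, basis.n)
    proj = basis.vectors.T @ s
    return proj**2 / float(s @ s)


def _group_bounds(k: int, n_groups: int):
    """Consecutive near-equal blocks; earlier (broader) blocks take extras."""
    base, extra = divmod(k, n_groups)
    bounds, start = [], 0
    for g in range(n_groups):
        size = base + (1 if g < extra else 0)
        bounds.append((start, start + size))
        start += size
    return tuple(bounds)


def smooth_scalogram(r2: np.ndarray, n_groups: int) -> np.ndarray:
    """Sum consecutive eigenvalue-ordered per-MEM R^2 into ``n_groups`` blocks."""
    r2 = np.asarray(r2, dtype=float)
    if not 1 <= n_groups <= len(r2):
        raise ValueError(f"n_groups must be in [1, {len(r2)}], got {n_groups}")
    bounds = _group_bounds(len(r2), n_groups)
    return np.array([r2[a:b].sum() for a, b in bounds])


def r2max_test(scores, basis: MEMBasis, n_groups: int = 8,
               nperm: int = 999, seed=None) -> Scalogram:
    """Permutation test of the maximal smoothed scalogram component.

    The null permutes the score values across sites (no spatial pattern);
    p = (1 + #{max_perm >= max_obs}) / (nperm + 1). The per-component 95%
    null quantile gives the confidence limit drawn on scalogram plots.
    """
    if nperm < 99:
        raise ValueError("nperm must be >= 99")
    s = _check_scores(scores, basis.n)
    r2 = mem_scalogram(s, basis)
    smoothed = smooth_scalogram(r2, n_groups)
    bounds = _group_bounds(len(r2), n_groups)
    obs_max = float(smoothed.max())
    argmax = int(np.argmax(smoothed))

    rng = np.random.default_rng(seed)
    # all permutations at once: columns of P are permuted score vectors
    P = np.empty((basis.n, nperm))
    for b in range(nperm):
        P[:, b] = s[rng.permutation(basis.n)]
    proj = basis.vectors.T @ P                     # (n-1) x nperm
    r2_null = proj**2 / float(s @ s)
    smoothed_null = np.vstack([r2_null[a:b].sum(axis=0) for a, b in bounds])  # G x nperm
    max_null = smoothed_null.max(axis=0)
    hits = int(np.sum(max_null >= obs_max - 1e-12))
    p = (1 + hits) / (nperm + 1)
    upper95 = np.quantile(smoothed_null, 0.95, axis=1)
    return Scalogram(
        r2_per_mem=r2, smoothed=smoothed, group_bounds=bounds,
        r2max=obs_max, argmax_component=argmax, p_value=p,
        null_upper95=upper95, nperm=nperm, seed=seed,
    )
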