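"""Community-matrix transformations.

The Hellinger transform (square root of within-site relative abundance)
emphasizes abundant species and makes Euclidean-based ordination
appropriate for count data; the chi-square transform (Legendre–Gallagher)
up-weights rare species instead. Both map a sites x species count table to
a real matrix suitable for PCA/RDA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CommunityMatrix", "TransformedMatrix", "hellinger_transform", "chisq_transform"]


@dataclass(frozen=True)
class CommunityMatrix:
    """Non-negative integer abundance counts, sites x species."""

    counts: np.ndarray
    species_ids: tuple = None
    site_ids: tuple = None

    def __post_init__(self):
        Y = np.asarray(self.counts, dtype=float)
        if Y.ndim != 2:
            raise ValueError("counts must be 2-D (sites x species)")
        if np.any(Y < 0) or not np.all(np.isfinite(Y)):
            raise ValueError("counts must be finite and non-negative")
        object.__setattr__(self, "counts", Y)
        sp = self.species_ids
        sp = tuple(sp) if sp is not None else tuple(f"sp{j + 1}" for j in range(Y.shape[1]))
        if len(sp) != Y.shape[1]:
            raise ValueError("species_ids length mismatch")
        object.__setattr__(self, "species_ids", sp)
        si = self.site_ids
        if si is not None:
            si = tuple(si)
            if len(si) != Y.shape[0]:
                raise ValueError("site_ids length mismatch")
        object.__setattr__(self, "site_ids", si)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CommunityMatrix":
        return cls(counts=df.to_numpy(dtype=float), species_ids=tuple(df.columns),
                   site_ids=tuple(df.index.astype(str)))


@dataclass(frozen=True)
class TransformedMatrix:
    """Transformed abundances plus the tag of the transform that made them."""

    values: np.ndarray
    transform: str
    species_ids: tuple = None
    site_ids: tuple = None


def _row_totals(Y: np.ndarray, community: CommunityMatrix) -> np.ndarray:
    totals = Y.sum(axis=1)
    if np.any(totals <= 0):
        bad = np.nonzero(totals <= 0)[0]
        ids = community.site_ids or tuple(range(len(totals)))
        names = ", ".join(str(ids[i]) for i in bad[:10])
        raise ValueError(f"sites with zero total abundance cannot be transformed: {names}")
    return totals


def hellinger_transform(Y: CommunityMatrix) -> TransformedMatrix:
    """y'_ij = sqrt(y_ij / y_i+); every transformed row has unit sum of squares."""
    counts = Y.counts
    totals = _row_totals(counts, Y)
    values = np.sqrt(counts / totals[:, None])
    return TransformedMatrix(values=values, transform="hellinger",
                             species_ids=Y.species_ids, site_ids=Y.site_ids)


def chisq_transform(Y: CommunityMatrix) -> TransformedMatrix:
    """y'_ij = sqrt(y_++) * y_ij / (y_i+ * sqrt(y_+j)) — the chi-square
    transformation; rows with proportional profiles collapse to equality."""
    counts = Y.counts
    row = _row_totals(counts, Y)
    col = counts.sum(axis=0)
    if np.any(col <= 0):
        bad = np.nonzero(col <= 0)[0]
        names = ", ".join(str(Y.species_ids[j]) for j in bad)
        raise ValueError(f"species with zero total abundance cannot be chi-square transformed: {names}")
    grand = counts.sum()
    values = np.sqrt(grand) * counts / (row[:, None] * np.sqrt(col)[None, :])
    return TransformedMatrix(values=values, transform="chisq",
                             species_ids=Y.species_ids, site_ids=Y.site_ids)


TRANSFORMS = {"hellinger": hellinger_transform, "chisq": chisq_transform}
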