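"""PCA, redundancy analysis (RDA) and partial residual analysis (PRA).

RDA is the PCA of the fitted values from a multivariate linear regression
of the (transformed) community table on explanatory variables: the
constrained share of community variance. PRA is the PCA of the residuals
of that regression — the patterns left once the environment is accounted
for. Site scores are reported in scaling 1 (distance preserving), with
each axis's sign fixed so the largest-magnitude species loading is
positive. Explained-variance significance uses a row-permutation test on
R^2, and adjusted R^2 follows Ezekiel's formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "ExplanatoryMatrix",
    "OrdinationResult",
    "pca",
    "rda",
    "pra",
    "adjusted_r2",
    "partial_residuals",
    "rda_permutation_test",
]

_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class ExplanatoryMatrix:
    """Sites x variables design matrix with named columns."""

    values: np.ndarray
    variable_ids: tuple = None

    def __post_init__(self):
        X = np.asarray(self.values, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2:
            raise ValueError("explanatory values must be 2-D")
        if not np.all(np.isfinite(X)):
            raise ValueError("explanatory matrix contains missing or non-finite values")
        object.__setattr__(self, "values", X)
        ids = self.variable_ids
        ids = tuple(ids) if ids is not None else tuple(f"x{j + 1}" for j in range(X.shape[1]))
        if len(ids) != X.shape[1]:
            raise ValueError("variable_ids length mismatch")
        object.__setattr__(self, "variable_ids", ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExplanatoryMatrix":
        return cls(values=df.to_numpy(dtype=float), variable_ids=tuple(df.columns))

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class OrdinationResult:
    """Eigenvalues, scores and loadings of a PCA/RDA/PRA fit.

    ``proportion`` is each axis's share of the TOTAL inertia of the input
    table, so it sums to 1 for PCA and to the constrained share R^2 for
    RDA (``proportion_constrained`` sums to 1 there). ``site_scores`` are
    scaling-1 scores; for RDA they are the fitted ("LC") scores and
    ``wa_scores`` additionally holds the weighted-average site scores.
    """

    kind: str
    eigenvalues: np.ndarray
    proportion: np.ndarray
    site_scores: np.ndarray
    loadings: np.ndarray
    total_inertia: float
    species_ids: tuple = None
    r2: float = None
    adj_r2: float = None
    proportion_constrained: np.ndarray = None
    wa_scores: np.ndarray = None

    @property
    def n_axes(self) -> int:
        return self.site_scores.shape[1]


def _centered(values: np.ndarray) -> np.ndarray:
    return values - values.mean(axis=0)


def _standardized(X: np.ndarray) -> np.ndarray:
    Xc = _centered(X)
    sd = Xc.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return Xc / sd


def _check_rank(Xc: np.ndarray, names) -> None:
    """Reject rank-deficient designs, naming the collinear columns."""
    if Xc.shape[1] == 0:
        return
    _, R, piv = scipy.linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = _RANK_RTOL * max(diag[0], 1.0) * max(Xc.shape)
    bad = piv[np.nonzero(diag < tol)[0]] if diag[0] >= tol else piv
    if len(np.atleast_1d(bad)):
        offenders = ", ".join(str(names[j]) for j in np.atleast_1d(bad))
        raise ValueError(f"explanatory matrix is rank deficient; collinear columns: {offenders}")


def _orth_basis(Xc: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(Xc)
    return Q


def _svd_ordination(Yc: np.ndarray, kind: str, total_inertia: float,
                    species_ids=None, **extra) -> OrdinationResult:
    n = Yc.shape[0]
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    keep = s > max(s[0], 1.0) * 1e-12 if s.size and s[0] > 0 else np.zeros(s.shape, bool)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    # axis sign: largest-magnitude species loading positive
    if s.size:
        idx = np.argmax(np.abs(Vt), axis=1)
        signs = np.sign(Vt[np.arange(Vt.shape[0]), idx])
        signs[signs == 0] = 1.0
        Vt = Vt * signs[:, None]
        U = U * signs[None, :]
    eig = s**2 / (n - 1)
    prop = eig / total_inertia if total_inertia > 0 else np.zeros_like(eig)
    return OrdinationResult(
        kind=kind,
        eigenvalues=eig,
        proportion=prop,
        site_scores=U * s,
        loadings=Vt.T,
        total_inertia=total_inertia,
        species_ids=species_ids,
        **extra,
    )


def _values_of(Yt) -> np.ndarray:
    return Yt.values if hasattr(Yt, "values") and not isinstance(Yt, np.ndarray) else np.asarray(Yt, float)


def _species_of(Yt):
    return getattr(Yt, "species_ids", None)


def pca(Yt) -> OrdinationResult:
    """Principal component analysis of a (transformed) community table.

    Column-centered SVD; eigenvalues are squared singular values / (n-1)
    and the variance proportions over all axes sum to 1.
    """
    Y = _values_of(Yt)
    if Y.shape[0] <= 1:
        raise ValueError("PCA requires more than one site")
    Yc = _centered(Y)
    total = float(np.sum(Yc**2)) / (Y.shape[0] - 1)
    if total == 0:
        raise ValueError("input table has zero variance")
    return _svd_ordination(Yc, "pca", total, species_ids=_species_of(Yt))


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel's adjustment: R2_a = 1 - (1 - R2) (n - 1) / (n - m - 1)."""
    if not 0.0 <= r2 <= 1.0 + 1e-12:
        raise ValueError(f"R2 must be in [0, 1], got {r2}")
    if n <= m + 1:
        raise ValueError(f"adjusted R2 requires n > m + 1 (n={n}, m={m})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _prepare_xy(Yt, X: ExplanatoryMatrix):
    Y = _values_of(Yt)
    n = Y.shape[0]
    if X.values.shape[0] != n:
        raise ValueError("Y and X row counts differ")
    if n <= X.m + 1:
        raise ValueError(f"need n > m + 1 sites (n={n}, m={X.m})")
    Xs = _standardized(X.values)
    _check_rank(Xs, X.variable_ids)
    return _centered(Y), Xs


def rda(Yt, X: ExplanatoryMatrix) -> OrdinationResult:
    """Redundancy analysis: PCA of the least-squares fit of Yt on X.

    R^2 = SS(fitted)/SS(total); the canonical site scores are the fitted
    (LC) scores, with weighted-average (WA) scores alongside.
    """
    Yc, Xs = _prepare_xy(Yt, X)
    n = Yc.shape[0]
    Q = _orth_basis(Xs)
    Yhat = Q @ (Q.T @ Yc)
    ss_tot = float(np.sum(Yc**2))
    ss_fit = float(np.sum(Yhat**2))
    r2 = ss_fit / ss_tot
    total = ss_tot / (n - 1)
    res = _svd_ordination(
        Yhat, "rda", total, species_ids=_species_of(Yt),
        r2=r2, adj_r2=adjusted_r2(r2, n, X.m),
    )
    prop_c = res.eigenvalues / res.eigenvalues.sum() if res.eigenvalues.size else res.eigenvalues
    wa = Yc @ res.loadings
    return OrdinationResult(
        kind=res.kind, eigenvalues=res.eigenvalues, proportion=res.proportion,
        site_scores=res.site_scores, loadings=res.loadings, total_inertia=res.total_inertia,
        species_ids=res.species_ids, r2=res.r2, adj_r2=res.adj_r2,
        proportion_constrained=prop_c, wa_scores=wa,
    )


def partial_residuals(Yt, X: ExplanatoryMatrix) -> np.ndarray:
    """Residual matrix of the multivariate regression of Yt on X.

    Each residual column is orthogonal to every centered column of X and
    SS(total) = SS(fitted) + SS(residual).
    """
    Yc, Xs = _prepare_xy(Yt, X)
    Q = _orth_basis(Xs)
    return Yc - Q @ (Q.T @ Yc)


def pra(Yt, X: ExplanatoryMatrix) -> OrdinationResult:
    """Partial residual analysis: PCA of the residuals of Yt on X."""
    R = partial_residuals(Yt, X)
    n = R.shape[0]
    total = float(np.sum(_centered(_values_of(Yt)) ** 2)) / (n - 1)
    if not np.any(np.abs(R) > 1e-12):
        # X spans Yt: degenerate but valid — all eigenvalues zero
        return OrdinationResult(
            kind="pra", eigenvalues=np.zeros(0), proportion=np.zeros(0),
            site_scores=np.zeros((n, 0)), loadings=np.zeros((R.shape[1], 0)),
            total_inertia=total, species_ids=_species_of(Yt),
        )
    return _svd_ordination(R, "pra", total, species_ids=_species_of(Yt))


def rda_permutation_test(Yt, X: ExplanatoryMatrix, nperm: int = 999, seed=None) -> float:
    """Row-permutation test of the RDA R^2.

    p = (1 + #{R2_perm >= R2_obs}) / (nperm + 1), permuting the rows of Yt.
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    Yc, Xs = _prepare_xy(Yt, X)
    Q = _orth_basis(Xs)
    ss_tot = float(np.sum(Yc**2))
    r2_obs = float(np.sum((Q.T @ Yc) ** 2)) / ss_tot
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(nperm):
        perm = rng.permutation(Yc.shape[0])
        r2_p = float(np.sum((Q.T @ Yc[perm]) ** 2)) / ss_tot
        if r2_p >= r2_obs - 1e-12:
            hits += 1
    return (1 + hits) / (nperm + 1)
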