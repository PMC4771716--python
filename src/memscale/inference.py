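"""Forward selection with the double-stopping rule and variation partitioning.

Forward selection adds, at each step, the candidate variable that raises
the explained community variance (RDA R^2) the most, admitting it only if
its marginal permutation p-value is at or below alpha, and halts as soon
as the selected subset's cumulative adjusted R^2 exceeds the adjusted R^2
of the global model on all candidates. The marginal test uses the
pseudo-F of the candidate conditional on the already-selected set, with
rows of the reduced-model residuals permuted (Freedman–Lane scheme).
Because the best-of-m candidate statistic is a minimum p-value, selection
only begins if the global model itself passes a permutation test at
alpha — the guard that keeps the procedure's type I error near nominal.
A saturated candidate set (m >= n - 1, R^2 identically 1) makes the
global test and the adjusted-R^2 stop vacuous; only the alpha stop binds.

Variation partitioning decomposes the adjusted R^2 of two or three
explanatory-variable sets into unique and shared fractions by
inclusion–exclusion; unique fractions are tested by the same
residual-permutation partial test. Negative adjusted fractions are
reported as computed, preserving the additivity identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.linalg

from .ordination import ExplanatoryMatrix, adjusted_r2, _centered, _standardized, _check_rank

__all__ = ["SelectionResult", "PartitionResult", "forward_select", "partial_rda_r2", "variation_partition"]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a two-stop forward selection.

    ``table`` mirrors the usual selection-table layout: one row per
    admitted variable with marginal R2, cumulative R2, cumulative adjusted
    R2, pseudo-F and permutation p. ``stopping_reason`` is one of
    'global_test' (global model not significant, nothing selected),
    'alpha', 'global_adjR2', 'exhausted'.
    """

    selected: tuple
    table: pd.DataFrame
    stopping_reason: str
    global_r2: float
    global_adj_r2: float

    @property
    def r2(self) -> float:
        return float(self.table["R2Cum"].iloc[-1]) if len(self.table) else 0.0


@dataclass(frozen=True)
class PartitionResult:
    """Adjusted-R^2 fractions of a 2- or 3-set variation partitioning.

    ``fractions`` maps fraction labels to adjusted R^2 values (unique
    fractions labelled by their set name, shared ones by '&'-joined
    names); ``pvalues`` carries permutation p-values for the testable
    (unique) fractions only. All fractions plus ``residual`` sum to 1.
    """

    set_names: tuple
    fractions: dict
    residual: float
    pvalues: dict
    union_adj_r2: dict


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, ExplanatoryMatrix):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(X, dtype=float).T).T


def _names_of(X, m, prefix="x"):
    if isinstance(X, ExplanatoryMatrix):
        return list(X.variable_ids)
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    return [f"{prefix}{j + 1}" for j in range(m)]


def _yvalues(Yt) -> np.ndarray:
    return Yt.values if hasattr(Yt, "values") and not isinstance(Yt, np.ndarray) else np.asarray(Yt, float)


def _fit_r2(Q: np.ndarray, Yc: np.ndarray, ss_tot: float) -> float:
    if Q.shape[1] == 0:
        return 0.0
    return float(np.sum((Q.T @ Yc) ** 2)) / ss_tot


def _pseudo_f(r2_full: float, r2_red: float, n: int, m_full: int, m_add: int) -> float:
    denom = (1.0 - r2_full) / (n - m_full - 1)
    if denom <= 0:
        return np.inf
    return ((r2_full - r2_red) / m_add) / denom


def _partial_permutation_p(Yc, Q_red, Q_full, m_full, m_add, nperm, rng) -> tuple:
    """Freedman–Lane partial test: permute reduced-model residuals."""
    n = Yc.shape[0]
    ss_tot = float(np.sum(Yc**2))
    r2_full = _fit_r2(Q_full, Yc, ss_tot)
    r2_red = _fit_r2(Q_red, Yc, ss_tot)
    f_obs = _pseudo_f(r2_full, r2_red, n, m_full, m_add)
    fitted_red = Q_red @ (Q_red.T @ Yc) if Q_red.shape[1] else np.zeros_like(Yc)
    resid_red = Yc - fitted_red
    hits = 0
    for _ in range(nperm):
        Ystar = fitted_red + resid_red[rng.permutation(n)]
        Ystar = Ystar - Ystar.mean(axis=0)
        ss_star = float(np.sum(Ystar**2))
        r2f = _fit_r2(Q_full, Ystar, ss_star)
        r2r = _fit_r2(Q_red, Ystar, ss_star)
        if _pseudo_f(r2f, r2r, n, m_full, m_add) >= f_obs - 1e-12:
            hits += 1
    return f_obs, (1 + hits) / (nperm + 1)


def forward_select(Yt, X, alpha: float = 0.05, nperm: int = 999, seed=None) -> SelectionResult:
    """Two-stop forward selection of explanatory variables for RDA.

    Stops at the first candidate whose permutation p exceeds ``alpha`` or
    whose admission would push the cumulative adjusted R^2 above the
    global model's adjusted R^2.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if nperm < 99:
        raise ValueError("nperm must be >= 99 for a stable selection test")
    Xm = _as_matrix(X)
    if Xm.shape[1] == 0:
        raise ValueError("no candidate variables supplied")
    names = _names_of(X, Xm.shape[1])
    Yc = _centered(_yvalues(Yt))
    n, m_all = Yc.shape[0], Xm.shape[1]
    Xs = _standardized(Xm)
    ss_tot = float(np.sum(Yc**2))

    rng = np.random.default_rng(seed)
    if n > m_all + 1:
        _check_rank(Xs, names)
        Q_all, _ = np.linalg.qr(Xs)
        global_r2 = _fit_r2(Q_all, Yc, ss_tot)
        global_adj = adjusted_r2(global_r2, n, m_all)
        hits = 0
        for _ in range(nperm):
            Yp = Yc[rng.permutation(n)]
            if _fit_r2(Q_all, Yp, ss_tot) >= global_r2 - 1e-12:
                hits += 1
        p_global = (1 + hits) / (nperm + 1)
        if p_global > alpha:
            empty = pd.DataFrame(columns=["variable", "order", "R2", "R2Cum", "AdjR2Cum", "F", "pval"])
            return SelectionResult(selected=(), table=empty, stopping_reason="global_test",
                                   global_r2=global_r2, global_adj_r2=global_adj)
    else:
        # saturated candidate set (e.g. all n-1 MEMs): the global model
        # spans the centered space, so only the alpha criterion can stop
        global_r2, global_adj = 1.0, 1.0
    remaining = list(range(m_all))
    Q_sel = np.zeros((n, 0))
    r2_sel = 0.0
    rows, selected = [], []
    reason = "exhausted"
    while remaining:
        if selected and adjusted_r2(min(r2_sel, 1.0), n, len(selected)) > global_adj + 1e-12:
            reason = "global_adjR2"
            break
        # marginal gain of each candidate = squared projection of its
        # component orthogonal to the selected set
        best_j, best_gain, best_q = -1, -np.inf, None
        for j in remaining:
            x = Xs[:, j] - Q_sel @ (Q_sel.T @ Xs[:, j])
            norm = np.linalg.norm(x)
            if norm < 1e-10:  # fully collinear with selected set
                continue
            q = x / norm
            gain = float(np.sum((q @ Yc) ** 2)) / ss_tot
            if gain > best_gain + 1e-15 or (abs(gain - best_gain) <= 1e-15 and j < best_j):
                best_j, best_gain, best_q = j, gain, q
        if best_j < 0:
            break
        Q_cand = np.column_stack([Q_sel, best_q])
        f_obs, p = _partial_permutation_p(
            Yc, Q_sel, Q_cand, m_full=len(selected) + 1, m_add=1, nperm=nperm, rng=rng,
        )
        if p > alpha:
            reason = "alpha"
            break
        r2_new = r2_sel + best_gain
        adj_new = adjusted_r2(min(r2_new, 1.0), n, len(selected) + 1)
        selected.append(best_j)
        remaining.remove(best_j)
        Q_sel, r2_sel = Q_cand, r2_new
        rows.append({
            "variable": names[best_j],
            "order": best_j + 1,
            "R2": best_gain,
            "R2Cum": r2_sel,
            "AdjR2Cum": adj_new,
            "F": f_obs,
            "pval": p,
        })
    table = pd.DataFrame(rows, columns=["variable", "order", "R2", "R2Cum", "AdjR2Cum", "F", "pval"])
    return SelectionResult(
        selected=tuple(names[j] for j in selected),
        table=table,
        stopping_reason=reason,
        global_r2=global_r2,
        global_adj_r2=global_adj,
    )


def _union_r2(Yc, ss_tot, blocks):
    # scipy.linalg.orth: an exact column-space basis even when the union
    # of blocks is collinear (e.g. one subset inside another's span)
    Xu = np.column_stack(blocks) if blocks else np.zeros((Yc.shape[0], 0))
    if Xu.shape[1] == 0:
        return 0.0, 0
    Q = scipy.linalg.orth(_standardized(Xu))
    return _fit_r2(Q, Yc, ss_tot), Xu.shape[1]


def partial_rda_r2(Yt, X, Z=None) -> tuple:
    """Semipartial R^2 of X given covariates Z, with its adjusted version.

    Returns (R^2(X|Z), adjusted value) where the raw value is
    R^2(X u Z) - R^2(Z) and the adjusted one is the difference of the
    Ezekiel-adjusted values of the two nested models.
    """
    Yc = _centered(_yvalues(Yt))
    ss_tot = float(np.sum(Yc**2))
    n = Yc.shape[0]
    Xm = _as_matrix(X)
    blocks = [Xm]
    if Z is not None:
        Zm = _as_matrix(Z)
        if Zm.shape[1]:
            blocks.append(Zm)
    # each block must be internally full rank; overlap BETWEEN X and Z is
    # legitimate (X inside span(Z) simply yields a zero semipartial)
    for b, tag in zip(blocks, ("X", "Z")):
        _check_rank(_standardized(b), [f"{tag}{j + 1}" for j in range(b.shape[1])])
    r2_full, m_full = _union_r2(Yc, ss_tot, blocks)
    if n <= m_full + 1:
        raise ValueError(f"need n > m + 1 (n={n}, m={m_full})")
    r2_red, m_red = _union_r2(Yc, ss_tot, blocks[1:])
    semi = r2_full - r2_red
    adj_full = adjusted_r2(r2_full, n, m_full)
    adj_red = adjusted_r2(r2_red, n, m_red) if m_red else 0.0
    return semi, adj_full - adj_red


def variation_partition(Yt, subsets: dict, nperm: int = 999, seed=None) -> PartitionResult:
    """Inclusion–exclusion partition of adjusted R^2 over 2 or 3 variable sets.

    ``subsets`` maps set names to explanatory matrices. Unique fractions
    are tested by permuting the residuals of the model on the remaining
    sets; shared fractions are not individually testable.
    """
    if not 2 <= len(subsets) <= 3:
        raise ValueError("variation partitioning supports exactly 2 or 3 subsets")
    names = tuple(subsets)
    mats = {k: _as_matrix(v) for k, v in subsets.items()}
    for k, v in mats.items():
        if v.shape[1] == 0:
            raise ValueError(f"subset '{k}' is empty")
    Yc = _centered(_yvalues(Yt))
    n = Yc.shape[0]
    ss_tot = float(np.sum(Yc**2))
    m_total = sum(v.shape[1] for v in mats.values())
    if n <= m_total + 1:
        raise ValueError(f"combined model inestimable: n={n}, total m={m_total}")
    _check_rank(_standardized(np.column_stack(list(mats.values()))),
                [f"{k}:{j}" for k in names for j in range(mats[k].shape[1])])

    adj = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            r2_u, m_u = _union_r2(Yc, ss_tot, [mats[k] for k in combo])
            adj[frozenset(combo)] = adjusted_r2(r2_u, n, m_u)

    fractions = {}
    full = frozenset(names)
    if len(names) == 2:
        a, b = names
        fractions[a] = adj[full] - adj[frozenset([b])]
        fractions[b] = adj[full] - adj[frozenset([a])]
        fractions[f"{a}&{b}"] = adj[frozenset([a])] + adj[frozenset([b])] - adj[full]
    else:
        a, b, c = names
        ua, ub, uc = (adj[frozenset([k])] for k in names)
        uab, uac, ubc = adj[frozenset([a, b])], adj[frozenset([a, c])], adj[frozenset([b, c])]
        uabc = adj[full]
        fa = uabc - ubc
        fb = uabc - uac
        fc = uabc - uab
        fab = uac + ubc - uabc - uc
        fbc = uab + uac - uabc - ua
        fac = uab + ubc - uabc - ub
        fabc = uabc - fa - fb - fc - fab - fbc - fac
        fractions.update({
            a: fa, b: fb, c: fc,
            f"{a}&{b}": fab, f"{b}&{c}": fbc, f"{a}&{c}": fac,
            f"{a}&{b}&{c}": fabc,
        })
    residual = 1.0 - adj[full]

    rng = np.random.default_rng(seed)
    pvalues = {}
    for k in names:
        others = [mats[o] for o in names if o != k]
        Xo = np.column_stack(others)
        Q_red, _ = np.linalg.qr(_standardized(Xo))
        Q_full, _ = np.linalg.qr(_standardized(np.column_stack([Xo, mats[k]])))
        m_full = Xo.shape[1] + mats[k].shape[1]
        _, p = _partial_permutation_p(
            Yc, Q_red, Q_full, m_full=m_full, m_add=mats[k].shape[1], nperm=nperm, rng=rng,
        )
        pvalues[k] = p
    return PartitionResult(set_names=names, fractions=fractions, residual=residual,
                           pvalues=pvalues, union_adj_r2={"+".join(sorted(k)): v for k, v in adj.items()})
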