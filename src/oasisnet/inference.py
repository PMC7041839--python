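"""Permutation inference for dyadic matrices and node metrics.

Matrix regression uses the quadratic assignment procedure (QAP): observations
are the off-diagonal cells of aligned square matrices, and the null
distribution comes from simultaneous row/column permutations, which preserve
the dyadic dependence structure.  Multiple predictors are handled by double
semi-partialling: each predictor is residualized on the others and the
residual *matrix* is permuted, so the test for one coefficient controls for
the rest.  Vector tests (Welch t, Kruskal-Wallis, OLS slope) draw their nulls
from node-label permutations.  All p-values follow the add-one rule
p = (count + 1) / (n_perm + 1) and all tests are two-sided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QAPResult",
    "NodePermResult",
    "mrqap_dsp",
    "node_perm_ttest",
    "node_perm_kruskal",
    "node_perm_regression",
    "kruskal_h",
]


@dataclass(frozen=True)
class QAPResult:
    betas: np.ndarray  # intercept first
    p_values: np.ndarray  # per non-intercept predictor
    r: float  # model correlation (signed Pearson r for one predictor)
    n_perm: int
    n_nodes: int
    predictor_names: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        names = self.predictor_names or tuple(f"x{i + 1}" for i in range(len(self.p_values)))
        return {
            "intercept": float(self.betas[0]),
            "coefficients": {nm: float(b) for nm, b in zip(names, self.betas[1:])},
            "p_values": {nm: float(p) for nm, p in zip(names, self.p_values)},
            "r": float(self.r),
            "n_perm": int(self.n_perm),
            "n_nodes": int(self.n_nodes),
        }


@dataclass(frozen=True)
class NodePermResult:
    statistic: float
    p: float
    n_perm: int
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"statistic": float(self.statistic), "p": float(self.p), "n_perm": int(self.n_perm), **self.extra}


# ---------------------------------------------------------------------------
# MR-QAP with double semi-partialling

def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def _vec(M: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return M[mask]


def mrqap_dsp(
    y_matrix: np.ndarray,
    x_matrices: list[np.ndarray] | np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
    predictor_names: tuple[str, ...] = (),
) -> QAPResult:
    """Matrix regression with double-semi-partialling QAP p-values.

    The dependent and predictor matrices must share one node ordering;
    diagonals are excluded.  Coefficients come from OLS on the vectorized
    off-diagonal cells (both (i,j) and (j,i) for symmetric matrices — the
    doubling leaves coefficients unchanged).  For each predictor, its
    residual matrix (after regressing out the other predictors cell-wise) is
    permuted by simultaneous row/column relabelling; the permuted residual
    replaces the predictor, the model is refit, and the two-sided p-value is
    (#{|beta*| >= |beta|} + 1) / (n_perm + 1).
    """
    rng = np.random.default_rng(rng)
    Y = np.asarray(y_matrix, dtype=float)
    if isinstance(x_matrices, np.ndarray) and x_matrices.ndim == 2:
        x_matrices = [x_matrices]
    Xm = [np.asarray(x, dtype=float) for x in x_matrices]
    n = Y.shape[0]
    if Y.shape != (n, n) or any(x.shape != (n, n) for x in Xm):
        raise ValueError("all matrices must be square with identical dimensions")
    if n < 4:
        raise ValueError("need at least 4 nodes")
    mask = _offdiag_mask(n)
    y = _vec(Y, mask)
    if np.ptp(y) == 0:
        raise ValueError("constant dependent matrix after vectorization")
    cols = [_vec(x, mask) for x in Xm]
    for ci, c in enumerate(cols):
        if np.ptp(c) == 0:
            name = predictor_names[ci] if predictor_names else f"x{ci + 1}"
            raise ValueError(f"constant predictor after vectorization: {name}")
    D = np.column_stack([np.ones_like(y)] + cols)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        # find a predictor explained by the others
        for ci in range(len(cols)):
            others = np.column_stack([np.ones_like(y)] + [c for k, c in enumerate(cols) if k != ci])
            resid = cols[ci] - others @ np.linalg.lstsq(others, cols[ci], rcond=None)[0]
            if np.allclose(resid, 0):
                name = predictor_names[ci] if predictor_names else f"x{ci + 1}"
                raise ValueError(f"rank-deficient design: predictor {name} is collinear")
        raise ValueError("rank-deficient design")
    betas, *_ = np.linalg.lstsq(D, y, rcond=None)
    fitted = D @ betas
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if len(cols) == 1:
        r = float(np.corrcoef(y, cols[0])[0, 1])
    else:
        r = math.sqrt(max(r2, 0.0))

    p_values = np.empty(len(cols))
    perms = [rng.permutation(n) for _ in range(n_perm)]
    for j, xj in enumerate(Xm):
        Z = np.column_stack([np.ones_like(y)] + [c for k, c in enumerate(cols) if k != j])
        Q, _ = np.linalg.qr(Z)
        # residual matrix of predictor j on the others, cell-wise
        e_vec = cols[j] - Q @ (Q.T @ cols[j])
        E = np.zeros((n, n))
        E[mask] = e_vec
        y_res = y - Q @ (Q.T @ y)
        beta_obs = float(y_res @ e_vec / (e_vec @ e_vec))
        count = 0
        for perm in perms:
            ep = _vec(E[np.ix_(perm, perm)], mask)
            ep_res = ep - Q @ (Q.T @ ep)
            denom = ep_res @ ep_res
            if denom <= 0:
                continue
            beta_star = float(y_res @ ep_res / denom)
            if abs(beta_star) >= abs(beta_obs) - 1e-12:
                count += 1
        p_values[j] = (count + 1) / (n_perm + 1)
    return QAPResult(
        betas=betas,
        p_values=p_values,
        r=r,
        n_perm=n_perm,
        n_nodes=n,
        predictor_names=tuple(predictor_names),
    )


# ---------------------------------------------------------------------------
# node-permutation vector tests

def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = math.sqrt(va / na + vb / nb)
    diff = a.mean() - b.mean()
    if denom == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return diff / denom


def _two_group_perm(
    values: np.ndarray,
    labels: np.ndarray,
    stat_fn,
    n_perm: int,
    rng: np.random.Generator,
    exhaustive: bool,
) -> tuple[float, float, int]:
    groups = pd.unique(labels)
    ia = np.flatnonzero(labels == groups[0])
    ib = np.flatnonzero(labels == groups[1])
    t_obs = stat_fn(values[ia], values[ib])
    n = len(values)
    if exhaustive:
        count = total = 0
        for combo in itertools.combinations(range(n), len(ia)):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            t_star = stat_fn(values[sel], values[~sel])
            total += 1
            if abs(t_star) >= abs(t_obs) - 1e-12:
                count += 1
        return t_obs, count / total, total
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        t_star = stat_fn(values[perm[: len(ia)]], values[perm[len(ia):]])
        if abs(t_star) >= abs(t_obs) - 1e-12:
            count += 1
    return t_obs, (count + 1) / (n_perm + 1), n_perm


def node_perm_ttest(
    values,
    labels,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> NodePermResult:
    """Welch t-test with a node-label permutation null (two-sided).

    ``exhaustive=True`` enumerates every distinct two-group label split (the
    identity split is part of the reference set, so no add-one correction).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("need exactly 2 groups")
    if min((labels == g).sum() for g in groups) < 2:
        raise ValueError("each group needs >= 2 values")
    rng = np.random.default_rng(rng)
    t_obs, p, n_used = _two_group_perm(values, labels, _welch_t, n_perm, rng, exhaustive)
    return NodePermResult(statistic=float(t_obs), p=float(p), n_perm=n_used)


def kruskal_h(values: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Kruskal-Wallis H statistic."""
    ranks = stats.rankdata(values)
    n = len(values)
    h = 0.0
    for g in pd.unique(labels):
        rg = ranks[labels == g]
        h += len(rg) * (rg.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie == 0:
        return 0.0
    return h / tie


def node_perm_kruskal(
    values,
    labels,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
    posthoc: bool = True,
) -> NodePermResult:
    """Kruskal-Wallis across >= 2 groups with a node-permutation p-value.

    Post-hoc pairwise comparisons reuse the same permutation machinery on
    each group pair and Bonferroni-adjust their p-values.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if len(values) < 5:
        raise ValueError("need total n >= 5")
    rng = np.random.default_rng(rng)
    if np.ptp(values) == 0:
        return NodePermResult(statistic=0.0, p=1.0, n_perm=n_perm)
    h_obs = kruskal_h(values, labels)
    count = 0
    for _ in range(n_perm):
        if kruskal_h(values, labels[rng.permutation(len(labels))]) >= h_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    extra: dict = {}
    if posthoc and len(groups) > 2:
        ncomp = len(groups) * (len(groups) - 1) // 2
        pair_p = {}
        for ga, gb in itertools.combinations(groups, 2):
            sel = (labels == ga) | (labels == gb)
            sub_v, sub_l = values[sel], labels[sel]
            h_pair = kruskal_h(sub_v, sub_l)
            c = 0
            for _ in range(n_perm):
                if kruskal_h(sub_v, sub_l[rng.permutation(len(sub_l))]) >= h_pair - 1e-12:
                    c += 1
            pair_p[f"{ga}|{gb}"] = min(1.0, ncomp * (c + 1) / (n_perm + 1))
        extra["posthoc_bonferroni"] = pair_p
    return NodePermResult(statistic=float(h_obs), p=float(p), n_perm=n_perm, extra=extra)


def node_perm_regression(
    y,
    x,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> NodePermResult:
    """Simple OLS of node metric y on node covariate x with permutation p.

    The null permutes y across nodes; the two-sided p-value is on the slope.
    Reports the slope and adjusted r-squared = 1 - (1 - r2)(n - 1)/(n - 2).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) != len(x):
        raise ValueError("y and x must have the same length")
    n = len(y)
    if n < 4:
        raise ValueError("need n >= 4")
    if np.ptp(x) == 0:
        raise ValueError("constant x")
    rng = np.random.default_rng(rng)
    xc = x - x.mean()
    sxx = float(xc @ xc)

    def slope(yy: np.ndarray) -> float:
        return float(xc @ (yy - yy.mean()) / sxx)

    b_obs = slope(y)
    r2 = 0.0
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0:
        resid = (y - y.mean()) - b_obs * xc
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    count = 0
    for _ in range(n_perm):
        if abs(slope(y[rng.permutation(n)])) >= abs(b_obs) - 1e-15:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return NodePermResult(
        statistic=b_obs, p=float(p), n_perm=n_perm, extra={"adj_r2": float(adj_r2)}
    )
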