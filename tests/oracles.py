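"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where possible, the
libraries) used by the package: enumeration instead of scipy's rank-sum,
pair counting instead of the rank-based AUC formula, residual regressions
instead of the precision-matrix partial correlation.
"""

from __future__ import annotations

import itertools

import numpy as np


def exact_ranksum_pvalue(x, y) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments.

    Assumes tie-free pooled data.  p = 2 * min(P(U <= u), P(U >= u)),
    capped at 1, with U the Mann-Whitney statistic of the first group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1 = x.size
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for combo in itertools.combinations(range(pooled.size), n1):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(combo)] = True
        a, b = pooled[mask], pooled[~mask]
        us.append(sum(1 for ai in a for bj in b if ai > bj))
    us = np.asarray(us)
    p_lo = np.mean(us <= u_obs)
    p_hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_lo, p_hi))


def auc_pair_count(pos, neg) -> float:
    """AUC by exhaustive concordant-pair counting (ties count one half)."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (pos.size * neg.size)


def partial_corr_residuals(X: np.ndarray, i: int, j: int) -> float:
    """Partial correlation of rows i and j of X given all other rows,
    via least-squares residuals (with intercept)."""
    others = [k for k in range(X.shape[0]) if k not in (i, j)]
    design = np.column_stack([np.ones(X.shape[1])] + [X[k] for k in others])

    def residual(v):
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    ri, rj = residual(X[i]), residual(X[j])
    return float(np.dot(ri, rj) / np.sqrt(np.dot(ri, ri) * np.dot(rj, rj)))


def pc1_projection(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Direct eigendecomposition oracle for the PC1 score.

    Standardizes rows of X (ddof=1), eigendecomposes the correlation matrix
    and projects.  Returns (scores, weights, explained_share); the
    eigenvector sign is unconstrained.
    """
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
    corr = np.corrcoef(Z)
    eigvals, eigvecs = np.linalg.eigh(corr)
    w = eigvecs[:, -1]
    return w @ Z, w, float(eigvals[-1] / eigvals.sum())


def kruskal_h(groups: list[np.ndarray]) -> float:
    """Hand computation of the (untied) Kruskal-Wallis H statistic."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, pooled.size + 1)
    n = pooled.size
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += g.size * (r.mean() - (n + 1) / 2) ** 2
        start += g.size
    return 12.0 / (n * (n + 1)) * h
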