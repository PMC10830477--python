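"""Statistical evaluation of a signature score.

Group comparison (Kruskal-Wallis plus pairwise rank-sum post hocs), ROC
discrimination with DeLong confidence intervals, Youden-index cutoff
selection, full-order partial-correlation networks and the signature versus
single-gene benchmark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ExpressionDataset
from .deg import rank_sum_test
from .signature import SignatureModel, SignatureScores, score_samples

__all__ = [
    "GroupComparison",
    "ROCResult",
    "CutoffResult",
    "PartialCorrelationNetwork",
    "kruskal_wallis",
    "pairwise_posthoc",
    "roc_auc",
    "youden_cutoff",
    "partial_correlation_matrix",
    "compare_signature_vs_gene",
    "category_score_summary",
    "DEFAULT_POSTHOC_PAIRS",
]

DEFAULT_POSTHOC_PAIRS = (("low", "0"), ("low", "3+"))


@dataclass
class GroupComparison:
    """Kruskal-Wallis result plus optional post hoc pairwise p-values."""

    kw_statistic: float
    kw_p: float
    groups_used: list[str]
    posthoc: dict[tuple[str, str], float | None] = field(default_factory=dict)


def _split_groups(
    values: Sequence[float] | SignatureScores, labels: Sequence[str]
) -> dict[str, np.ndarray]:
    vals = np.asarray(
        values.values if isinstance(values, SignatureScores) else values, dtype=float
    )
    labels = np.asarray(labels)
    if vals.size != labels.size:
        raise ValueError("scores and group labels must be aligned")
    return {g: vals[labels == g] for g in pd.unique(labels)}


def kruskal_wallis(
    values: Sequence[float] | SignatureScores, labels: Sequence[str]
) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H with a chi-square (k-1 df) p-value.

    Empty groups are dropped with a warning; fully degenerate data (all
    observations identical) yields H = 0, p = 1 with a warning.
    """
    groups = _split_groups(values, labels)
    nonempty = {g: v for g, v in groups.items() if v.size > 0}
    if len(nonempty) < len(groups):
        warnings.warn(
            f"dropping empty group(s): {sorted(set(groups) - set(nonempty))}",
            stacklevel=2,
        )
    if len(nonempty) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 non-empty groups")
    arrays = list(nonempty.values())
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        warnings.warn(
            "Kruskal-Wallis degenerate: all observations identical; H = 0, p = 1",
            stacklevel=2,
        )
        return GroupComparison(0.0, 1.0, sorted(nonempty))
    h, p = stats.kruskal(*arrays)
    return GroupComparison(float(h), float(p), sorted(nonempty))


def pairwise_posthoc(
    values: Sequence[float] | SignatureScores,
    labels: Sequence[str],
    pairs: Sequence[tuple[str, str]] = DEFAULT_POSTHOC_PAIRS,
    adjust: str = "none",
) -> dict[tuple[str, str], float | None]:
    """Two-sided rank-sum p-value for each requested group pair.

    Unadjusted by default; ``adjust='bonferroni'`` multiplies by the number
    of requested pairs.  Pairs with an empty side are reported as ``None``.
    """
    if adjust not in {"none", "bonferroni"}:
        raise ValueError("adjust must be 'none' or 'bonferroni'")
    groups = _split_groups(values, labels)
    out: dict[tuple[str, str], float | None] = {}
    m = len(pairs)
    for a, b in pairs:
        ga, gb = groups.get(a, np.array([])), groups.get(b, np.array([]))
        if ga.size == 0 or gb.size == 0:
            warnings.warn(f"post hoc pair ({a}, {b}) has an empty group; reported "
                          "as missing", stacklevel=2)
            out[(a, b)] = None
            continue
        p = rank_sum_test(ga, gb)
        if adjust == "bonferroni":
            p = min(1.0, p * m)
        out[(a, b)] = p
    return out


@dataclass
class ROCResult:
    """AUC with a 95% DeLong confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    positive_class: str
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.auc <= self.ci_high <= 1):
            raise ValueError("require 0 <= ci_low <= auc <= ci_high <= 1")


def _auc_and_components(
    pos: np.ndarray, neg: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mann-Whitney AUC (ties half) and the DeLong structural components."""
    m, n = pos.size, neg.size
    combined = np.concatenate([pos, neg])
    r_all = stats.rankdata(combined)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (r_all[:m] - r_pos) / n          # per-positive placement values
    v01 = 1.0 - (r_all[m:] - r_neg) / m    # per-negative placement values
    return float(auc), v10, v01


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    positive_class: str = "positive",
    conf_level: float = 0.95,
) -> ROCResult:
    """AUC (probability a random positive outscores a random negative, ties
    counting one half) with a DeLong confidence interval.

    Degenerate AUC of exactly 0 or 1 gets its interval clipped to [0, 1]
    with a warning (the DeLong variance collapses there).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size != labels.size:
        raise ValueError("scores and labels must be aligned")
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present to compute an AUC")
    auc, v10, v01 = _auc_and_components(pos, neg)
    s10 = v10.var(ddof=1) if pos.size > 1 else 0.0
    s01 = v01.var(ddof=1) if neg.size > 1 else 0.0
    se = np.sqrt(s10 / pos.size + s01 / neg.size)
    z = stats.norm.ppf(0.5 + conf_level / 2)
    lo, hi = auc - z * se, auc + z * se
    if auc in (0.0, 1.0):
        warnings.warn(
            "degenerate AUC (perfect separation); confidence interval "
            "clipped to [0, 1]",
            stacklevel=2,
        )
    lo, hi = max(0.0, min(lo, auc)), min(1.0, max(hi, auc))
    return ROCResult(
        auc=auc,
        ci_low=float(lo),
        ci_high=float(hi),
        positive_class=positive_class,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


@dataclass
class CutoffResult:
    """Youden-optimal cutoff with its sensitivity/specificity."""

    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


def youden_cutoff(
    scores: Sequence[float], labels: Sequence[bool]
) -> CutoffResult:
    """Maximize J = sensitivity + specificity - 1 over candidate cutoffs.

    A sample is called positive when its score exceeds the cutoff.
    Candidates are the midpoints between adjacent distinct scores plus
    -inf/+inf; ties on J are broken toward the smallest cutoff (maximizing
    sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present to choose a cutoff")
    distinct = np.unique(scores)
    if distinct.size == 1:
        warnings.warn("all scores identical; Youden index degenerate at 0",
                      stacklevel=2)
    candidates = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2, [np.inf]]
    )
    best: CutoffResult | None = None
    for c in candidates:
        sens = float((pos > c).mean())
        spec = float((neg <= c).mean())
        j = sens + spec - 1.0
        if best is None or j > best.youden_j + 1e-12:
            best = CutoffResult(float(c), sens, spec, j)
    assert best is not None
    return best


@dataclass
class PartialCorrelationNetwork:
    """Full-order partial correlations of a gene set plus its edge list."""

    genes: list[str]
    r_p: np.ndarray
    threshold: float
    edges: pd.DataFrame  # columns: gene_a, gene_b, r_p


def partial_correlation_matrix(
    dataset: ExpressionDataset,
    genes: Sequence[str],
    threshold: float = 0.30,
) -> PartialCorrelationNetwork:
    """Partial correlation of each gene pair given all remaining genes.

    Computed from the precision matrix Omega (inverse correlation matrix) as
    r_p(i, j) = -Omega_ij / sqrt(Omega_ii * Omega_jj).  Edges with
    |r_p| > ``threshold`` (default 0.30, the reporting bar) are listed.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    if dataset.n_samples <= len(genes) + 1:
        raise ValueError(
            f"need more than {len(genes) + 1} samples for a stable "
            f"{len(genes)}-gene precision matrix; have {dataset.n_samples}"
        )
    X = dataset.submatrix(genes)
    corr = np.corrcoef(X)
    if not np.all(np.isfinite(corr)):
        raise ValueError("correlation matrix not computable (constant gene?)")
    cond = np.linalg.cond(corr)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "correlation matrix is (near-)singular; reduce or decorrelate "
            "the gene set"
        )
    omega = np.linalg.inv(corr)
    d = np.sqrt(np.diag(omega))
    r_p = -omega / np.outer(d, d)
    np.fill_diagonal(r_p, 1.0)

    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if abs(r_p[i, j]) > threshold:
                rows.append(
                    {"gene_a": genes[i], "gene_b": genes[j], "r_p": float(r_p[i, j])}
                )
    rows.sort(key=lambda r: -abs(r["r_p"]))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r_p"])
    return PartialCorrelationNetwork(
        genes=genes, r_p=r_p, threshold=threshold, edges=edges
    )


def compare_signature_vs_gene(
    model: SignatureModel,
    dataset: ExpressionDataset,
    benchmark_gene: str,
    positive_groups: Sequence[str] = ("low",),
    standardization_mode: str = "per-dataset",
) -> tuple[ROCResult, ROCResult, float]:
    """AUC of the signature versus a single benchmark gene's expression.

    Both classifiers are evaluated against the same binary labels (HER2
    group in ``positive_groups`` versus the rest).  Returns the two ROC
    results plus the AUC difference (signature minus gene).
    """
    labels = np.isin(dataset.her2_groups(), list(positive_groups))
    scores = score_samples(model, dataset, standardization_mode=standardization_mode)
    positive_name = "|".join(positive_groups)
    roc_sig = roc_auc(scores.values, labels, positive_class=positive_name)
    roc_gene = roc_auc(
        dataset.gene_row(benchmark_gene), labels, positive_class=positive_name
    )
    return roc_sig, roc_gene, roc_sig.auc - roc_gene.auc


def category_score_summary(
    values: Sequence[float] | SignatureScores, labels: Sequence[str]
) -> pd.DataFrame:
    """Five-number summary of scores per category (box-plot-ready table)."""
    groups = _split_groups(values, labels)
    rows = []
    for cat in sorted(groups):
        v = groups[cat]
        if v.size == 0:
            continue
        rows.append(
            {
                "category": cat,
                "n": int(v.size),
                "min": float(v.min()),
                "q1": float(np.percentile(v, 25)),
                "median": float(np.median(v)),
                "q3": float(np.percentile(v, 75)),
                "max": float(v.max()),
            }
        )
    return pd.DataFrame(rows, columns=["category", "n", "min", "q1", "median", "q3", "max"])
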