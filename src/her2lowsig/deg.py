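"""One-vs-rest contrast screening and Venn selection of category-specific genes.

The screen is two-stage: genes are first filtered on |log2FC| > threshold
for a given one-vs-rest contrast, then only the filtered genes are tested
with a two-sided Wilcoxon rank-sum test and Bonferroni-adjusted within the
contrast's family of filtered genes.  Genes significant in exactly one
contrast of interest are "specific" to that contrast (Venn selection);
specific sets from several discovery datasets are merged into a single
category-labelled gene list.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "Contrast",
    "ContrastResult",
    "VennPartition",
    "DiscoverySelection",
    "CONTRAST_NAMES",
    "VENN_CONTRASTS",
    "contrast_category",
    "make_contrast",
    "make_all_contrasts",
    "log2_fold_change",
    "rank_sum_test",
    "bonferroni_adjust",
    "select_contrast_degs",
    "venn_specific_genes",
    "merge_discovery",
]

#: the five screened one-vs-rest contrasts
CONTRAST_NAMES = (
    "0-vs-others",
    "1+-vs-others",
    "2+-vs-others",
    "3+-vs-others",
    "low-vs-others",
)

#: contrasts whose specific cells feed the signature (three-set Venn)
VENN_CONTRASTS = ("1+-vs-others", "2+-vs-others", "low-vs-others")

_FOCAL_CATEGORIES = {
    "0-vs-others": ("0",),
    "1+-vs-others": ("1+",),
    "2+-vs-others": ("2+",),
    "3+-vs-others": ("3+",),
    "low-vs-others": ("1+", "2+"),
}


def contrast_category(contrast_name: str) -> str:
    """Category label attached to genes specific to a contrast."""
    return {"low-vs-others": "low"}.get(
        contrast_name, contrast_name.split("-vs-")[0]
    )


@dataclass(frozen=True)
class Contrast:
    """A one-vs-rest split of a dataset's samples."""

    name: str
    focal_samples: frozenset[str]
    rest_samples: frozenset[str]

    def __post_init__(self) -> None:
        if self.focal_samples & self.rest_samples:
            raise ValueError(f"contrast {self.name}: focal and rest overlap")


def make_contrast(dataset: ExpressionDataset, name: str) -> Contrast | None:
    """Build a named contrast on a dataset; ``None`` if the focal set is empty."""
    if name not in _FOCAL_CATEGORIES:
        raise ValueError(f"unknown contrast {name!r}; expected one of {CONTRAST_NAMES}")
    cats = dataset.ihc_scores()
    focal_mask = np.isin(cats, _FOCAL_CATEGORIES[name])
    ids = np.array(dataset.sample_ids)
    if not focal_mask.any():
        warnings.warn(
            f"dataset {dataset.name!r}: contrast {name} skipped "
            "(no focal samples)",
            stacklevel=2,
        )
        return None
    if focal_mask.all():
        warnings.warn(
            f"dataset {dataset.name!r}: contrast {name} skipped "
            "(no rest samples)",
            stacklevel=2,
        )
        return None
    return Contrast(
        name=name,
        focal_samples=frozenset(ids[focal_mask]),
        rest_samples=frozenset(ids[~focal_mask]),
    )


def make_all_contrasts(
    dataset: ExpressionDataset, names: Sequence[str] = CONTRAST_NAMES
) -> dict[str, Contrast]:
    """Build all feasible contrasts, dropping duplicates of the same split.

    In cohorts lacking categories, a multi-category focal set can collapse
    onto a single-category one (e.g. the joint 1+/2+ split equals the 1+
    split when no 2+ samples exist); the single-category contrast is kept
    and the collapsed duplicate dropped with a warning, since both would
    carry identical results and would annihilate each other in the Venn.
    """
    contrasts: dict[str, Contrast] = {}
    seen_focals: dict[frozenset[str], str] = {}
    for name in names:
        c = make_contrast(dataset, name)
        if c is None:
            continue
        if c.focal_samples in seen_focals:
            warnings.warn(
                f"dataset {dataset.name!r}: contrast {name} duplicates "
                f"{seen_focals[c.focal_samples]} and is dropped",
                stacklevel=2,
            )
            continue
        seen_focals[c.focal_samples] = name
        contrasts[name] = c
    return contrasts


def _group_indices(
    dataset: ExpressionDataset, contrast: Contrast
) -> tuple[np.ndarray, np.ndarray]:
    ids = np.array(dataset.sample_ids)
    focal = np.isin(ids, list(contrast.focal_samples))
    rest = np.isin(ids, list(contrast.rest_samples))
    if not focal.any() or not rest.any():
        raise ValueError(
            f"contrast {contrast.name}: empty group on dataset {dataset.name!r}"
        )
    return np.where(focal)[0], np.where(rest)[0]


def log2_fold_change(
    dataset: ExpressionDataset, contrast: Contrast, gene: str
) -> float:
    """Difference of group mean log2 expression (focal minus rest)."""
    fi, ri = _group_indices(dataset, contrast)
    row = dataset.gene_row(gene)
    return float(row[fi].mean() - row[ri].mean())


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the smaller group has <= 8 observations and the
    pooled values are tie-free; otherwise the normal approximation with tie
    and continuity corrections.  Fully degenerate input (every value
    identical) returns p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("rank-sum test degenerate: all values identical; p = 1",
                      stacklevel=2)
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def bonferroni_adjust(p_values: Sequence[float], m: int) -> np.ndarray:
    """Bonferroni adjustment: each p mapped to min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than {p.size} tests")
    return np.minimum(1.0, p * m)


@dataclass
class ContrastResult:
    """Per-gene screening results for one contrast."""

    contrast: str
    dataset: str
    table: pd.DataFrame  # columns: gene, log2fc, p_raw, p_adj, passed_fc, passed_sig
    fc_threshold: float
    alpha: float
    n_flagged: int

    @property
    def significant_genes(self) -> set[str]:
        return set(self.table.loc[self.table["passed_sig"], "gene"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _empty_result(
    contrast_name: str, dataset_name: str, fc_threshold: float, alpha: float
) -> ContrastResult:
    table = pd.DataFrame(
        columns=["gene", "log2fc", "p_raw", "p_adj", "passed_fc", "passed_sig"]
    )
    return ContrastResult(contrast_name, dataset_name, table, fc_threshold, alpha, 0)


def select_contrast_degs(
    dataset: ExpressionDataset,
    contrast: Contrast | None,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    *,
    test_all_genes: bool = False,
) -> ContrastResult:
    """Two-stage screen of one contrast.

    Stage 1 flags genes with |log2FC| > ``fc_threshold``; stage 2 applies the
    rank-sum test to flagged genes only, with Bonferroni family size equal to
    the number of flagged genes in this contrast.  ``test_all_genes=True``
    switches to testing every gene with a whole-transcriptome family (the
    alternative reading of the screening procedure).
    """
    if contrast is None:
        return _empty_result("skipped", dataset.name, fc_threshold, alpha)
    fi, ri = _group_indices(dataset, contrast)
    if fi.size < 2 or ri.size < 2:
        warnings.warn(
            f"contrast {contrast.name} on {dataset.name!r}: fewer than 2 "
            "samples in a group; skipped",
            stacklevel=2,
        )
        return _empty_result(contrast.name, dataset.name, fc_threshold, alpha)

    fc = dataset.matrix[:, fi].mean(axis=1) - dataset.matrix[:, ri].mean(axis=1)
    passed_fc = np.abs(fc) > fc_threshold
    tested = np.ones_like(passed_fc) if test_all_genes else passed_fc
    m = int(tested.sum())

    p_raw = np.full(dataset.n_genes, np.nan)
    for gi in np.where(tested)[0]:
        p_raw[gi] = rank_sum_test(dataset.matrix[gi, fi], dataset.matrix[gi, ri])
    p_adj = np.full(dataset.n_genes, np.nan)
    if m:
        p_adj[tested] = bonferroni_adjust(p_raw[tested], m)
    passed_sig = passed_fc & (np.nan_to_num(p_adj, nan=1.0) < alpha)

    table = pd.DataFrame(
        {
            "gene": dataset.genes,
            "log2fc": fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "passed_fc": passed_fc,
            "passed_sig": passed_sig,
        }
    )
    logger.info(
        "dataset %s contrast %s: %d/%d genes flagged, %d significant",
        dataset.name,
        contrast.name,
        m,
        dataset.n_genes,
        int(passed_sig.sum()),
    )
    return ContrastResult(contrast.name, dataset.name, table, fc_threshold, alpha, m)


@dataclass
class VennPartition:
    """Assignment of significant genes to exactly-one-contrast cells."""

    dataset: str
    specific: dict[str, set[str]]
    overlaps: dict[tuple[str, ...], set[str]]

    @property
    def all_significant(self) -> set[str]:
        out: set[str] = set()
        for s in self.specific.values():
            out |= s
        for s in self.overlaps.values():
            out |= s
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for contrast, genes in sorted(self.specific.items()):
            for g in sorted(genes):
                rows.append({"gene": g, "cell": contrast, "specific": True})
        for cell, genes in sorted(self.overlaps.items()):
            for g in sorted(genes):
                rows.append({"gene": g, "cell": "&".join(cell), "specific": False})
        return pd.DataFrame(rows, columns=["gene", "cell", "specific"])


def venn_specific_genes(
    results: Mapping[str, ContrastResult],
    contrasts_of_interest: Sequence[str] = VENN_CONTRASTS,
) -> VennPartition:
    """Partition significant genes into contrast-specific and overlap cells.

    A gene is specific to contrast K iff it is significant in K and in no
    other contrast of interest.  Multi-contrast overlap cells are reported
    for diagnostics but excluded from every specific set.
    """
    names = [n for n in contrasts_of_interest if n in results]
    sig = {n: results[n].significant_genes for n in names}
    dataset = next(iter(results.values())).dataset if results else ""

    membership: dict[str, tuple[str, ...]] = {}
    for gene in set().union(*sig.values()) if sig else set():
        membership[gene] = tuple(n for n in names if gene in sig[n])

    specific: dict[str, set[str]] = {n: set() for n in names}
    overlaps: dict[tuple[str, ...], set[str]] = {}
    for gene, cell in membership.items():
        if len(cell) == 1:
            specific[cell[0]].add(gene)
        else:
            overlaps.setdefault(cell, set()).add(gene)
    return VennPartition(dataset=dataset, specific=specific, overlaps=overlaps)


@dataclass
class DiscoverySelection:
    """Merged, category-labelled specific genes from the discovery datasets."""

    table: pd.DataFrame  # columns: gene, category, sources

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def genes_for(self, category: str) -> list[str]:
        return list(self.table.loc[self.table["category"] == category, "gene"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def merge_discovery(
    partitions: Mapping[str, VennPartition],
    categories: Sequence[str] = ("1+", "2+", "low"),
    on_conflict: str = "error",
) -> DiscoverySelection:
    """Merge per-dataset Venn-specific genes into one labelled list.

    A gene specific to the same category in several datasets is kept once
    (sources concatenated).  A gene specific to different categories in
    different datasets is a conflict: ``on_conflict='error'`` (default)
    raises, ``'drop'`` removes the gene with a warning.
    """
    if not partitions:
        raise ValueError("need at least one partition to merge")
    if on_conflict not in {"error", "drop"}:
        raise ValueError("on_conflict must be 'error' or 'drop'")

    assignment: dict[str, dict[str, list[str]]] = {}  # gene -> category -> sources
    for label, part in partitions.items():
        for contrast_name, genes in part.specific.items():
            category = contrast_category(contrast_name)
            if category not in categories:
                continue
            for gene in genes:
                assignment.setdefault(gene, {}).setdefault(category, []).append(label)

    rows = []
    for gene in sorted(assignment):
        cats = assignment[gene]
        if len(cats) > 1:
            msg = (
                f"gene {gene!r} specific to conflicting categories across "
                f"datasets: { {c: sorted(src) for c, src in cats.items()} }"
            )
            if on_conflict == "error":
                raise ValueError(msg)
            warnings.warn(msg + "; dropped", stacklevel=2)
            continue
        category, sources = next(iter(cats.items()))
        rows.append(
            {"gene": gene, "category": category, "sources": ",".join(sorted(sources))}
        )
    order = {c: i for i, c in enumerate(categories)}
    rows.sort(key=lambda r: (order[r["category"]], r["gene"]))
    return DiscoverySelection(
        table=pd.DataFrame(rows, columns=["gene", "category", "sources"])
    )
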