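"""Config-driven orchestration: discover -> merge -> fit -> score -> evaluate.

A :class:`PipelineConfig` names the discovery and confirmatory datasets and
every threshold/policy; :func:`run_pipeline` executes the full workflow and
returns a bundle whose report is deterministic for a fixed config (no
timestamps inside ``report.json``).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import (
    ExpressionDataset,
    cohort_summary,
    read_expression_dataset,
)
from .deg import (
    CONTRAST_NAMES,
    VENN_CONTRASTS,
    ContrastResult,
    DiscoverySelection,
    VennPartition,
    make_all_contrasts,
    merge_discovery,
    select_contrast_degs,
    venn_specific_genes,
)
from .evaluation import (
    DEFAULT_POSTHOC_PAIRS,
    category_score_summary,
    compare_signature_vs_gene,
    kruskal_wallis,
    pairwise_posthoc,
    partial_correlation_matrix,
    roc_auc,
    youden_cutoff,
)
from .signature import SignatureModel, SignatureScores, fit_signature, score_samples

logger = logging.getLogger(__name__)

__all__ = [
    "DatasetRole",
    "PipelineConfig",
    "PipelineStageError",
    "run_pipeline",
    "write_report",
]


class PipelineStageError(ValueError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class DatasetRole:
    """One input dataset: file paths plus its role in the workflow."""

    name: str
    matrix: Path
    annotations: Path
    role: str = "discovery"  # or "confirmatory"

    def __post_init__(self) -> None:
        if self.role not in {"discovery", "confirmatory"}:
            raise ValueError(f"role must be discovery/confirmatory, got {self.role!r}")


@dataclass
class PipelineConfig:
    """Thresholds, policies and inputs of one pipeline run."""

    datasets: list[DatasetRole]
    fc_threshold: float = 1.0
    alpha: float = 0.05
    posthoc_adjust: str = "none"
    posthoc_pairs: tuple[tuple[str, str], ...] = DEFAULT_POSTHOC_PAIRS
    rp_threshold: float = 0.30
    fit_dataset: str | None = None
    standardization_mode: str = "per-dataset"
    missing_gene_policy: str = "error"
    merge_conflict: str = "error"
    test_all_genes: bool = False
    subset_hr_status: str | None = None
    benchmark_gene: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if not any(d.role == "discovery" for d in self.datasets):
            raise ValueError("need at least one discovery dataset")
        if not self.fc_threshold >= 0:
            raise ValueError("fc_threshold must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.rp_threshold <= 1:
            raise ValueError("rp_threshold must lie in [0, 1]")
        names = [d.name for d in self.datasets]
        if len(set(names)) != len(names):
            raise ValueError("dataset names must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent
        datasets = [
            DatasetRole(
                name=d["name"],
                matrix=base / d["matrix"],
                annotations=base / d["annotations"],
                role=d.get("role", "discovery"),
            )
            for d in raw.pop("datasets")
        ]
        pairs = raw.pop("posthoc_pairs", None)
        cfg = cls(datasets=datasets, **raw)
        if pairs is not None:
            cfg.posthoc_pairs = tuple((str(a), str(b)) for a, b in pairs)
        cfg.validate()
        return cfg

    def decided_defaults(self) -> dict:
        """Every default left open by the source procedure, for the run log."""
        return {
            "fc_threshold": self.fc_threshold,
            "alpha": self.alpha,
            "bonferroni_family": "per-contrast flagged genes"
            if not self.test_all_genes
            else "all genes",
            "venn_contrasts_of_interest": list(VENN_CONTRASTS),
            "posthoc_test": "two-sided rank-sum",
            "posthoc_adjust": self.posthoc_adjust,
            "auc_ci_method": "DeLong (normal scale, clipped to [0, 1])",
            "cutoff_candidates": "midpoints of adjacent distinct scores, ties -> smallest",
            "rp_edge_threshold": self.rp_threshold,
            "standardization_mode": self.standardization_mode,
            "missing_gene_policy": self.missing_gene_policy,
            "merge_conflict": self.merge_conflict,
            "ihc2plus_unknown_ish": "mapped to HER2-low",
        }


def _posthoc_labels(dataset: ExpressionDataset) -> np.ndarray:
    """Collapse IHC categories to the 0 / low / 3+ comparison labels."""
    mapping = {"0": "0", "1+": "low", "2+": "low", "3+": "3+"}
    return np.array([mapping[c] for c in dataset.ihc_scores()])


def _evaluate_scores(
    dataset: ExpressionDataset,
    scores: SignatureScores,
    config: PipelineConfig,
) -> dict:
    keep = np.ones(dataset.n_samples, dtype=bool)
    if config.subset_hr_status is not None:
        keep = np.array(
            [s.hr_status == config.subset_hr_status for s in dataset.samples]
        )
        logger.info(
            "dataset %s: evaluation restricted to hr_status=%s (%d/%d samples)",
            dataset.name,
            config.subset_hr_status,
            int(keep.sum()),
            dataset.n_samples,
        )
    values = scores.values[keep]
    sub = dataset.subset_samples(keep)
    ihc = sub.ihc_scores()
    groups3 = _posthoc_labels(sub)
    low_labels = sub.her2_groups() == "low"

    out: dict = {"n_evaluated": int(keep.sum())}
    try:
        kw = kruskal_wallis(values, ihc)
        out["kruskal_wallis"] = {
            "statistic": kw.kw_statistic,
            "p": kw.kw_p,
            "groups": kw.groups_used,
        }
    except ValueError as exc:
        out["kruskal_wallis"] = {"error": str(exc)}
    posthoc = pairwise_posthoc(
        values, groups3, pairs=config.posthoc_pairs, adjust=config.posthoc_adjust
    )
    out["posthoc"] = {f"{a}_vs_{b}": p for (a, b), p in posthoc.items()}

    if low_labels.any() and not low_labels.all():
        roc = roc_auc(values, low_labels, positive_class="low")
        cut = youden_cutoff(values, low_labels)
        out["roc_low_vs_others"] = {
            "auc": roc.auc,
            "ci_low": roc.ci_low,
            "ci_high": roc.ci_high,
            "n_pos": roc.n_pos,
            "n_neg": roc.n_neg,
        }
        out["youden"] = {
            "cutoff": cut.cutoff if np.isfinite(cut.cutoff) else None,
            "sensitivity": cut.sensitivity,
            "specificity": cut.specificity,
            "youden_j": cut.youden_j,
        }
    else:
        out["roc_low_vs_others"] = {"error": "only one class present"}
    out["score_summary"] = category_score_summary(values, ihc).to_dict(
        orient="records"
    )
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and return the result bundle.

    Bundle keys: ``model`` (SignatureModel), ``scores`` (per dataset),
    ``contrast_results``, ``venns``, ``selection``, ``datasets`` and
    ``report`` (the JSON-ready deterministic report).
    """
    config.validate()

    # -- load ------------------------------------------------------------------
    datasets: dict[str, ExpressionDataset] = {}
    try:
        for spec in config.datasets:
            datasets[spec.name] = read_expression_dataset(
                spec.matrix, spec.annotations, name=spec.name
            )
    except (OSError, ValueError) as exc:
        raise PipelineStageError("load", str(exc)) from exc
    discovery = [d.name for d in config.datasets if d.role == "discovery"]
    confirmatory = [d.name for d in config.datasets if d.role == "confirmatory"]

    # -- discovery screening + venn -------------------------------------------
    contrast_results: dict[str, dict[str, ContrastResult]] = {}
    venns: dict[str, VennPartition] = {}
    try:
        for name in discovery:
            ds = datasets[name]
            contrasts = make_all_contrasts(ds, CONTRAST_NAMES)
            results = {
                cname: select_contrast_degs(
                    ds,
                    contrast,
                    fc_threshold=config.fc_threshold,
                    alpha=config.alpha,
                    test_all_genes=config.test_all_genes,
                )
                for cname, contrast in contrasts.items()
            }
            contrast_results[name] = results
            venns[name] = venn_specific_genes(results, VENN_CONTRASTS)
    except ValueError as exc:
        raise PipelineStageError("discover", str(exc)) from exc

    try:
        selection = merge_discovery(venns, on_conflict=config.merge_conflict)
    except ValueError as exc:
        raise PipelineStageError("merge", str(exc)) from exc
    if len(selection.genes) < 2:
        raise PipelineStageError(
            "merge",
            f"only {len(selection.genes)} specific gene(s) recovered; "
            "need >= 2 to fit a signature",
        )

    # -- fit -------------------------------------------------------------------
    fit_name = config.fit_dataset or _default_fit_dataset(datasets, discovery)
    if fit_name not in datasets:
        raise PipelineStageError("fit", f"unknown fit dataset {fit_name!r}")
    try:
        model = fit_signature(datasets[fit_name], selection.genes)
    except (ValueError, KeyError) as exc:
        raise PipelineStageError("fit", str(exc)) from exc

    # -- score -----------------------------------------------------------------
    scores: dict[str, SignatureScores] = {}
    try:
        for name, ds in datasets.items():
            scores[name] = score_samples(
                model,
                ds,
                standardization_mode=config.standardization_mode,
                missing=config.missing_gene_policy,
            )
    except (ValueError, KeyError) as exc:
        raise PipelineStageError("score", str(exc)) from exc

    # -- evaluate --------------------------------------------------------------
    evaluation: dict[str, dict] = {}
    try:
        for name, ds in datasets.items():
            evaluation[name] = _evaluate_scores(ds, scores[name], config)
        evaluation["pooled"] = _evaluate_pooled(datasets, scores, config)
        rp = partial_correlation_matrix(
            datasets[fit_name], model.genes, threshold=config.rp_threshold
        )
        benchmark = _benchmark_section(model, datasets, config)
    except (ValueError, KeyError) as exc:
        raise PipelineStageError("evaluate", str(exc)) from exc

    summary = cohort_summary(list(datasets.values()))
    report = {
        "version": __version__,
        "seed": config.seed,
        "decided_defaults": config.decided_defaults(),
        "datasets": {
            name: {
                "role": "discovery" if name in discovery else "confirmatory",
                "n_samples": ds.n_samples,
                "n_genes": ds.n_genes,
            }
            for name, ds in datasets.items()
        },
        "cohort_summary": {
            "n_per_cohort": summary.n_per_cohort,
            "n_total": summary.n_total,
            "her2_group_counts": summary.group_counts,
        },
        "discovery": {
            name: {
                "contrasts": {
                    cname: {
                        "n_flagged": res.n_flagged,
                        "n_significant": len(res.significant_genes),
                    }
                    for cname, res in results.items()
                },
                "venn_specific_counts": {
                    cname: len(genes)
                    for cname, genes in venns[name].specific.items()
                },
                "venn_overlap_counts": {
                    "&".join(cell): len(genes)
                    for cell, genes in venns[name].overlaps.items()
                },
            }
            for name, results in contrast_results.items()
        },
        "merged_genes": selection.table.to_dict(orient="records"),
        "signature": {
            "genes": model.genes,
            "weights": [float(w) for w in model.weights],
            "orientation": model.orientation,
            "explained_share": model.explained_share,
            "fit_dataset": model.fit_cohort,
        },
        "partial_correlations": {
            "threshold": rp.threshold,
            "edges": rp.edges.to_dict(orient="records"),
        },
        "evaluation": evaluation,
        "benchmark": benchmark,
    }
    return {
        "model": model,
        "scores": scores,
        "contrast_results": contrast_results,
        "venns": venns,
        "selection": selection,
        "datasets": datasets,
        "cohort_summary": summary,
        "partial_correlations": rp,
        "report": report,
    }


def _default_fit_dataset(
    datasets: Mapping[str, ExpressionDataset], discovery: Sequence[str]
) -> str:
    """Prefer the discovery cohort carrying all four IHC categories."""
    for name in discovery:
        if len(set(datasets[name].ihc_scores())) == 4:
            return name
    return discovery[0]


def _evaluate_pooled(
    datasets: Mapping[str, ExpressionDataset],
    scores: Mapping[str, SignatureScores],
    config: PipelineConfig,
) -> dict:
    """Pooled evaluation across every scored dataset (per-dataset z-scores
    make the concatenation platform-offset invariant)."""
    names = sorted(datasets)
    pooled_values = np.concatenate([scores[n].values for n in names])
    pooled_genes: list[str] = []
    samples = [s for n in names for s in datasets[n].samples]
    pooled_ds = ExpressionDataset(
        genes=["_pooled_placeholder"],
        samples=samples,
        matrix=np.zeros((1, len(samples))),
        name="pooled",
    )
    fake_scores = SignatureScores(
        sample_ids=pooled_ds.sample_ids,
        values=pooled_values,
        standardization_mode=config.standardization_mode,
        dataset="pooled",
    )
    return _evaluate_scores(pooled_ds, fake_scores, config)


def _benchmark_section(
    model: SignatureModel,
    datasets: Mapping[str, ExpressionDataset],
    config: PipelineConfig,
) -> dict:
    gene = config.benchmark_gene
    if gene is None:
        return {"skipped": "no benchmark gene configured"}
    out: dict = {"gene": gene}
    for name, ds in sorted(datasets.items()):
        if gene not in ds.genes:
            out[name] = {"error": f"benchmark gene {gene!r} absent"}
            continue
        groups = ds.her2_groups()
        if not ((groups == "low").any() and (groups != "low").any()):
            out[name] = {"error": "only one class present"}
            continue
        roc_sig, roc_gene, diff = compare_signature_vs_gene(
            model, ds, gene, standardization_mode=config.standardization_mode
        )
        out[name] = {
            "signature_auc": roc_sig.auc,
            "signature_ci": [roc_sig.ci_low, roc_sig.ci_high],
            "gene_auc": roc_gene.auc,
            "gene_ci": [roc_gene.ci_low, roc_gene.ci_high],
            "auc_difference": diff,
        }
    return out


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def write_report(bundle: Mapping, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle's artifacts; returns the paths written.

    ``report.json`` is byte-deterministic for a given config and input data.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise PipelineStageError("report", f"cannot create {outdir}: {exc}") from exc

    paths: dict[str, Path] = {}
    report = bundle["report"]
    paths["report_json"] = outdir / "report.json"
    paths["report_json"].write_text(
        json.dumps(report, indent=2, sort_keys=True, allow_nan=False) + "\n"
    )
    paths["model_json"] = outdir / "model.json"
    bundle["model"].to_json(paths["model_json"])

    for name, sc in bundle["scores"].items():
        ds = bundle["datasets"][name]
        frame = pd.DataFrame(
            {
                "sample_id": sc.sample_ids,
                "cohort": [s.cohort for s in ds.samples],
                "ihc_score": ds.ihc_scores(),
                "her2_group": ds.her2_groups(),
                "score": sc.values,
            }
        )
        p = outdir / f"scores_{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths[f"scores_{name}"] = p

    for name, results in bundle["contrast_results"].items():
        for cname, res in results.items():
            p = outdir / f"contrast_{name}_{cname.replace('+', 'p')}.tsv"
            res.to_tsv(p)
    for name, venn in bundle["venns"].items():
        venn.to_frame().to_csv(outdir / f"venn_{name}.tsv", sep="\t", index=False)
    bundle["selection"].to_tsv(outdir / "merged_genes.tsv")
    bundle["cohort_summary"].to_tsv(outdir / "summary")
    bundle["partial_correlations"].edges.to_csv(
        outdir / "partial_correlation_edges.tsv", sep="\t", index=False
    )

    paths["report_md"] = outdir / "report.md"
    paths["report_md"].write_text(_markdown_report(report))
    return paths


def _markdown_report(report: Mapping) -> str:
    lines = ["# HER2-low signature pipeline report", ""]
    cs = report["cohort_summary"]
    lines += ["## Cohorts", ""]
    lines.append("| cohort | n |")
    lines.append("|---|---|")
    for name, n in sorted(cs["n_per_cohort"].items()):
        lines.append(f"| {name} | {n} |")
    lines.append(f"| **total** | **{cs['n_total']}** |")
    lines.append("")
    lines.append(
        "HER2 groups (pooled): "
        + ", ".join(f"{g} = {n}" for g, n in sorted(cs["her2_group_counts"].items()))
    )
    lines += ["", "## Discovery screening", ""]
    for name, d in sorted(report["discovery"].items()):
        cells = ", ".join(
            f"{c}: {n}" for c, n in sorted(d["venn_specific_counts"].items())
        )
        lines.append(f"- **{name}** specific cells: {cells}")
        if d["venn_overlap_counts"]:
            lines.append(
                f"  overlaps: "
                + ", ".join(f"{c}: {n}" for c, n in sorted(d["venn_overlap_counts"].items()))
            )
    n_merged = len(report["merged_genes"])
    per_cat: dict[str, int] = {}
    for row in report["merged_genes"]:
        per_cat[row["category"]] = per_cat.get(row["category"], 0) + 1
    lines.append("")
    lines.append(
        f"Merged signature gene list: {n_merged} genes ("
        + ", ".join(f"{c}: {n}" for c, n in sorted(per_cat.items()))
        + ")"
    )
    sig = report["signature"]
    lines += [
        "",
        "## Signature",
        "",
        f"- fit dataset: {sig['fit_dataset']}",
        f"- explained variance share of PC1: {sig['explained_share']:.3f}",
        f"- orientation: {sig['orientation']:+d}",
        "",
        "## Evaluation",
        "",
    ]
    for name, ev in sorted(report["evaluation"].items()):
        lines.append(f"### {name}")
        kw = ev.get("kruskal_wallis", {})
        if "p" in kw:
            lines.append(
                f"- Kruskal-Wallis: H = {kw['statistic']:.3f}, p = {kw['p']:.3g}"
            )
        for pair, p in sorted(ev.get("posthoc", {}).items()):
            lines.append(f"- post hoc {pair}: p = {'NA' if p is None else format(p, '.3g')}")
        roc = ev.get("roc_low_vs_others", {})
        if "auc" in roc:
            lines.append(
                f"- AUC (low vs others): {roc['auc']:.3f} "
                f"(95% CI {roc['ci_low']:.3f}-{roc['ci_high']:.3f})"
            )
            if roc["auc"] in (0.0, 1.0):
                lines.append("  - warning: degenerate AUC; CI clipped to [0, 1]")
        if "youden" in ev:
            y = ev["youden"]
            cut_txt = "NA" if y["cutoff"] is None else format(y["cutoff"], ".4g")
            lines.append(
                f"- Youden cutoff: {cut_txt} "
                f"(sens {y['sensitivity']:.2f}, spec {y['specificity']:.2f})"
            )
        if ev.get("score_summary"):
            lines.append("")
            lines.append("| category | n | min | q1 | median | q3 | max |")
            lines.append("|---|---|---|---|---|---|---|")
            for row in ev["score_summary"]:
                lines.append(
                    f"| {row['category']} | {row['n']} | {row['min']:.3f} | "
                    f"{row['q1']:.3f} | {row['median']:.3f} | {row['q3']:.3f} | "
                    f"{row['max']:.3f} |"
                )
        lines.append("")
    bm = report.get("benchmark", {})
    if "gene" in bm:
        lines.append("## Signature vs single-gene benchmark")
        lines.append("")
        for name, entry in sorted(bm.items()):
            if not isinstance(entry, dict) or "signature_auc" not in entry:
                continue
            lines.append(
                f"- {name}: signature AUC {entry['signature_auc']:.3f} vs "
                f"{bm['gene']} AUC {entry['gene_auc']:.3f} "
                f"(difference {entry['auc_difference']:+.3f})"
            )
        lines.append("")
    elif "skipped" in bm:
        lines.append(f"_Benchmark comparison skipped: {bm['skipped']}._")
        lines.append("")
    return "\n".join(lines) + "\n"
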