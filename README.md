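# her2lowsig

Reusable pipeline for gene-expression-based HER2-low breast cancer
classification: one-vs-rest differential-expression screening per HER2 IHC
category, Venn selection of category-specific genes, a PC1-weighted
signature score, and a full evaluation battery (Kruskal–Wallis with post hoc
pairwise comparisons, ROC/AUC with DeLong confidence intervals, Youden
cutoff, partial-correlation network). A synthetic multi-cohort generator
with planted category effects makes every stage testable without external
data.

## Modules

| module | purpose |
|---|---|
| `her2lowsig.datasets` | expression-matrix + annotation I/O, IHC→HER2-group mapping (0→zero; 1+ and 2+ without ISH amplification→low; amplified 2+ and 3+→positive), cohort summary tables |
| `her2lowsig.synthetic` | synthetic cohorts with planted contrast-specific genes, an ordinal `ERBB2L` marker gene, a latent bell-shape factor and per-cohort platform offsets; ground-truth sidecar for recovery metrics |
| `her2lowsig.deg` | log2 fold-change filter (\|log2FC\| > 1), two-sided Wilcoxon rank-sum tests on the filtered genes, per-contrast Bonferroni adjustment, Venn-specific gene selection, multi-dataset merge |
| `her2lowsig.signature` | z-scoring, PC1 of the gene–gene correlation matrix, orientation (low scores above zero scores), scoring with per-dataset or train-parameter standardization |
| `her2lowsig.evaluation` | Kruskal–Wallis + rank-sum post hocs, AUC with DeLong 95% CI, Youden-index cutoff, precision-matrix partial correlations, signature-vs-single-gene benchmark |
| `her2lowsig.pipeline` / `her2lowsig.cli` | config-driven orchestration and reporting |

## CLI

```bash
# draw a synthetic three-cohort study (config: SyntheticConfig YAML)
her2lowsig simulate --config sim.yaml --out simdir/

# full workflow: discover -> venn/merge -> fit -> score -> evaluate
her2lowsig run-all --config pipeline.yaml --out results/
```

A minimal pipeline config:

```yaml
datasets:
  - {name: INT1, matrix: simdir/INT1_matrix.tsv, annotations: simdir/INT1_annotations.tsv, role: discovery}
  - {name: INT2, matrix: simdir/INT2_matrix.tsv, annotations: simdir/INT2_annotations.tsv, role: discovery}
  - {name: INT3, matrix: simdir/INT3_matrix.tsv, annotations: simdir/INT3_annotations.tsv, role: confirmatory}
merge_conflict: drop        # library default is 'error'
benchmark_gene: ERBB2L
seed: 1
```

`run-all` writes `report.json` (byte-deterministic for a fixed config and
inputs), `report.md`, `model.json`, per-dataset score TSVs, per-contrast
result TSVs, Venn tables and the partial-correlation edge list. Individual
stages are also exposed (`discover`, `fit`, `score`, `report`). Exit codes:
0 ok, 1 user error, 2 internal error.

Input formats: matrix TSV/CSV with gene symbols in the first column and a
header row of sample ids; annotation TSV/CSV with columns
`sample_id, cohort, ihc_score, ish_amplified, hr_status, pam50, grade,
size_class, age_years`. Missing expression values are rejected, not
imputed.

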