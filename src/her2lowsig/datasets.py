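"""Data model and I/O for annotated expression cohorts.

An :class:`ExpressionDataset` couples a genes x samples log2 expression
matrix with per-sample clinical annotations.  The module also provides the
IHC-category to HER2-group mapping (zero / low / positive) and cohort
summary tables (per-variable counts and HER2-group cross-tabulations).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SampleAnnotation",
    "HER2Group",
    "ExpressionDataset",
    "CohortSummary",
    "classify_her2_group",
    "cohort_summary",
    "read_expression_dataset",
    "write_expression_dataset",
    "annotations_frame",
    "percent_half_up",
    "normalize_ihc",
]

#: canonical IHC tokens plus tolerant aliases seen in public annotation files
IHC_CANONICAL = ("0", "1+", "2+", "3+")
_IHC_ALIASES = {
    "0": "0",
    "1+": "1+",
    "2+": "2+",
    "3+": "3+",
    "1": "1+",
    "2": "2+",
    "3": "3+",
}

_TRISTATE = {"amplified", "not_amplified", "unknown"}
_HR_LEVELS = {"positive", "negative", "unknown"}
_PAM50_LEVELS = {
    "LumA",
    "LumB",
    "HER2E",
    "Basal",
    "Normal",
    "Undetermined",
    "unknown",
}

ANNOTATION_COLUMNS = (
    "sample_id",
    "cohort",
    "ihc_score",
    "ish_amplified",
    "hr_status",
    "pam50",
    "grade",
    "size_class",
    "age_years",
)


def normalize_ihc(token: object) -> str:
    """Map an IHC score spelling to its canonical token.

    Accepts ``0/1+/2+/3+`` plus the bare aliases ``1/2/3`` (warned).
    Raises ``ValueError`` listing the accepted spellings otherwise.
    """
    tok = str(token).strip()
    if tok not in _IHC_ALIASES:
        raise ValueError(
            f"unrecognized IHC score {token!r}; accepted spellings: "
            f"{sorted(_IHC_ALIASES)}"
        )
    canon = _IHC_ALIASES[tok]
    if tok != canon:
        warnings.warn(
            f"IHC score token {tok!r} interpreted as {canon!r}", stacklevel=2
        )
    return canon


class HER2Group(str, Enum):
    """Three-level HER2 grouping derived from IHC and ISH."""

    ZERO = "zero"
    LOW = "low"
    POSITIVE = "positive"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SampleAnnotation:
    """Clinical annotations for one sample.

    ``ihc_score`` is mandatory; the remaining variables default to their
    "unknown"/missing level.
    """

    sample_id: str
    cohort: str
    ihc_score: str
    ish_amplified: str = "unknown"
    hr_status: str = "unknown"
    pam50: str = "unknown"
    grade: str | None = None
    size_class: str | None = None
    age_years: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ihc_score", normalize_ihc(self.ihc_score))
        if self.ish_amplified not in _TRISTATE:
            raise ValueError(
                f"ish_amplified must be one of {sorted(_TRISTATE)}, "
                f"got {self.ish_amplified!r}"
            )
        if self.hr_status not in _HR_LEVELS:
            raise ValueError(
                f"hr_status must be one of {sorted(_HR_LEVELS)}, "
                f"got {self.hr_status!r}"
            )
        if self.age_years is not None and not self.age_years > 0:
            raise ValueError("age_years must be positive when present")


def classify_her2_group(annotation: SampleAnnotation) -> HER2Group:
    """Assign the HER2 group from the IHC score and (for 2+) ISH status.

    Mapping: 0 -> zero; 1+ -> low; 2+ without amplification (including
    unknown ISH) -> low; 2+ amplified -> positive; 3+ -> positive.  An
    ``amplified`` ISH result on a non-2+ sample does not influence the
    mapping and is flagged with a warning.
    """
    ihc = annotation.ihc_score
    if ihc != "2+" and annotation.ish_amplified == "amplified":
        warnings.warn(
            f"sample {annotation.sample_id}: ish_amplified=amplified ignored "
            f"for IHC {ihc} (only meaningful for 2+)",
            stacklevel=2,
        )
    if ihc == "0":
        return HER2Group.ZERO
    if ihc == "1+":
        return HER2Group.LOW
    if ihc == "2+":
        if annotation.ish_amplified == "amplified":
            return HER2Group.POSITIVE
        if annotation.ish_amplified == "unknown":
            logger.debug(
                "sample %s: IHC 2+ with unknown ISH mapped to low",
                annotation.sample_id,
            )
        return HER2Group.LOW
    return HER2Group.POSITIVE  # 3+


@dataclass
class ExpressionDataset:
    """A log2 expression matrix aligned with sample annotations.

    ``matrix`` is genes x samples; ``genes`` and ``samples`` give the row
    and column identities.  Values must be finite (missing entries are
    rejected at load time rather than imputed).
    """

    genes: list[str]
    samples: list[SampleAnnotation]
    matrix: np.ndarray
    scale_note: str = "log2"
    name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        dupes = _duplicates(self.genes)
        if dupes:
            raise ValueError(f"duplicate gene symbols: {sorted(dupes)}")
        sid_dupes = _duplicates([s.sample_id for s in self.samples])
        if sid_dupes:
            raise ValueError(f"duplicate sample ids: {sorted(sid_dupes)}")
        if not np.all(np.isfinite(self.matrix)):
            gi, si = np.argwhere(~np.isfinite(self.matrix))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.genes[gi]!r}, sample {self.samples[si].sample_id!r}"
            )
        if self.scale_note != "log2":
            raise ValueError(f"expected log2-scale data, got {self.scale_note!r}")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    # -- convenience accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            return self.matrix[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in dataset {self.name!r}") from None

    def ihc_scores(self) -> np.ndarray:
        return np.array([s.ihc_score for s in self.samples])

    def her2_groups(self) -> np.ndarray:
        return np.array([classify_her2_group(s).value for s in self.samples])

    def subset_samples(self, keep: Sequence[bool] | Sequence[int]) -> "ExpressionDataset":
        """Return a new dataset restricted to the selected sample columns."""
        idx = np.arange(self.n_samples)[np.asarray(keep)]
        return ExpressionDataset(
            genes=list(self.genes),
            samples=[self.samples[i] for i in idx],
            matrix=self.matrix[:, idx].copy(),
            scale_note=self.scale_note,
            name=self.name,
        )

    def submatrix(self, genes: Sequence[str]) -> np.ndarray:
        missing = [g for g in genes if g not in self._gene_index]
        if missing:
            raise KeyError(f"genes absent from dataset {self.name!r}: {missing}")
        return self.matrix[[self._gene_index[g] for g in genes]]


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_expression_dataset(
    matrix_path: str | Path,
    annotation_path: str | Path,
    name: str | None = None,
) -> ExpressionDataset:
    """Load a dataset from a delimited matrix file and an annotation table.

    The matrix file is genes-in-rows / samples-in-columns with a header row
    of sample ids and gene symbols in the first column.  Samples are
    intersected between the two files (dropped ids are logged); order
    follows the matrix columns.
    """
    matrix_path = Path(matrix_path)
    annotation_path = Path(annotation_path)
    mdf = pd.read_csv(
        matrix_path,
        sep=_sep_for(matrix_path),
        index_col=0,
        float_precision="round_trip",  # bit-exact write/read round-trips
    )
    dupes = _duplicates([str(g) for g in mdf.index])
    if dupes:
        raise ValueError(
            f"{matrix_path}: duplicate gene symbols: {sorted(dupes)}"
        )
    values = mdf.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(values.isna().to_numpy())
    if bad.size:
        gi, si = bad[0]
        raise ValueError(
            f"{matrix_path}: missing or non-numeric expression value at "
            f"gene {mdf.index[gi]!r}, sample column {mdf.columns[si]!r} "
            f"(row {gi + 2}, column {si + 2})"
        )

    adf = pd.read_csv(
        annotation_path, sep=_sep_for(annotation_path), dtype={"sample_id": str}
    )
    required = {"sample_id", "cohort", "ihc_score"}
    if not required.issubset(adf.columns):
        raise ValueError(
            f"{annotation_path}: missing required columns "
            f"{sorted(required - set(adf.columns))}"
        )
    adf = adf.set_index("sample_id", drop=False)

    matrix_ids = [str(c) for c in mdf.columns]
    common = [sid for sid in matrix_ids if sid in adf.index]
    if not common:
        raise ValueError(
            f"no overlapping samples between {matrix_path} and {annotation_path}"
        )
    dropped = (set(matrix_ids) | set(adf.index)) - set(common)
    if dropped:
        logger.info(
            "dropped %d unmatched sample(s) while loading %s: %s",
            len(dropped),
            matrix_path.name,
            sorted(dropped),
        )

    annotations = [_annotation_from_row(adf.loc[sid]) for sid in common]
    return ExpressionDataset(
        genes=[str(g) for g in mdf.index],
        samples=annotations,
        matrix=values[common].to_numpy(dtype=float),
        name=name or matrix_path.stem,
    )


def _annotation_from_row(row: pd.Series) -> SampleAnnotation:
    def _opt(col: str) -> str | None:
        val = row.get(col)
        if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
            return None
        return str(val)

    def _tri(col: str) -> str:
        return _opt(col) or "unknown"

    age = row.get("age_years")
    age = None if age is None or pd.isna(age) else float(age)
    return SampleAnnotation(
        sample_id=str(row["sample_id"]),
        cohort=str(row["cohort"]),
        ihc_score=str(row["ihc_score"]),
        ish_amplified=_tri("ish_amplified"),
        hr_status=_tri("hr_status"),
        pam50=_tri("pam50"),
        grade=_opt("grade"),
        size_class=_opt("size_class"),
        age_years=age,
    )


def write_expression_dataset(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    annotation_path: str | Path,
) -> None:
    """Write a dataset back to the delimited-file formats read by
    :func:`read_expression_dataset` (value round-trip is bit-exact)."""
    matrix_path = Path(matrix_path)
    annotation_path = Path(annotation_path)
    mdf = pd.DataFrame(dataset.matrix, index=dataset.genes, columns=dataset.sample_ids)
    mdf.index.name = "gene"
    mdf.to_csv(matrix_path, sep=_sep_for(matrix_path))
    rows = []
    for s in dataset.samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "cohort": s.cohort,
                "ihc_score": s.ihc_score,
                "ish_amplified": s.ish_amplified,
                "hr_status": s.hr_status,
                "pam50": s.pam50,
                "grade": s.grade if s.grade is not None else "",
                "size_class": s.size_class if s.size_class is not None else "",
                "age_years": s.age_years if s.age_years is not None else "",
            }
        )
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(
        annotation_path, sep=_sep_for(annotation_path), index=False
    )


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

MISSING_LEVEL = "missing"

_SUMMARY_VARIABLES = ("ihc_score", "her2_group", "hr_status", "pam50", "grade", "size_class")
_CROSSTAB_VARIABLES = ("hr_status", "pam50", "grade", "size_class")


def percent_half_up(count: int, total: int) -> int:
    """Integer percent with exact half-up rounding (printed-table style)."""
    if total == 0:
        return 0
    return int(Fraction(count, total) * 100 + Fraction(1, 2)).__index__()


def annotations_frame(datasets: Sequence[ExpressionDataset]) -> pd.DataFrame:
    """Stack all sample annotations into one tidy frame (adds her2_group)."""
    rows = []
    for ds in datasets:
        for s in ds.samples:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "cohort": s.cohort,
                    "ihc_score": s.ihc_score,
                    "her2_group": classify_her2_group(s).value,
                    "ish_amplified": s.ish_amplified,
                    "hr_status": _level_or_missing(s.hr_status),
                    "pam50": _level_or_missing(s.pam50),
                    "grade": s.grade if s.grade is not None else MISSING_LEVEL,
                    "size_class": s.size_class if s.size_class is not None else MISSING_LEVEL,
                    "age_years": s.age_years,
                }
            )
    return pd.DataFrame(rows)


def _level_or_missing(level: str) -> str:
    return MISSING_LEVEL if level == "unknown" else level


@dataclass
class CohortSummary:
    """Per-cohort and pooled annotation summaries plus HER2-group cross-tabs."""

    n_per_cohort: dict[str, int]
    n_total: int
    per_variable: dict[str, pd.DataFrame]
    crosstabs: dict[str, pd.DataFrame]
    group_counts: dict[str, int]

    def pooled_count(self, variable: str, level: str) -> int:
        return int(self.per_variable[variable].loc[level, "pooled_n"])

    def pooled_percent(self, variable: str, level: str) -> int:
        return int(self.per_variable[variable].loc[level, "pooled_pct"])

    def crosstab_percent(self, variable: str, level: str, group: str) -> int:
        """Column percent of ``level`` within one HER2 group (half-up)."""
        tab = self.crosstabs[variable]
        return percent_half_up(int(tab.loc[level, group]), int(tab[group].sum()))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_per_cohort": self.n_per_cohort,
            "n_total": self.n_total,
            "group_counts": self.group_counts,
            "per_variable": {
                v: df.to_dict(orient="index") for v, df in self.per_variable.items()
            },
            "crosstabs": {
                v: df.to_dict(orient="index") for v, df in self.crosstabs.items()
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_tsv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for variable, df in self.per_variable.items():
            df.to_csv(directory / f"summary_{variable}.tsv", sep="\t")
        for variable, df in self.crosstabs.items():
            df.to_csv(directory / f"crosstab_her2_group_x_{variable}.tsv", sep="\t")


def cohort_summary(datasets: Sequence[ExpressionDataset]) -> CohortSummary:
    """Tabulate annotation variables per cohort and pooled.

    Counts include a ``missing`` level so each variable's column sums to the
    cohort n; percentages are computed on the total n with half-up rounding.
    Cross-tabulations of HER2 group against HR status, PAM50, grade and size
    are returned as count tables.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    frame = annotations_frame(datasets)
    cohorts = sorted(frame["cohort"].unique())
    n_per_cohort = {c: int((frame["cohort"] == c).sum()) for c in cohorts}
    n_total = len(frame)

    per_variable: dict[str, pd.DataFrame] = {}
    for variable in _SUMMARY_VARIABLES:
        levels = sorted(frame[variable].unique())
        table = pd.DataFrame(index=levels)
        for c in cohorts:
            sub = frame.loc[frame["cohort"] == c, variable]
            table[f"{c}_n"] = [int((sub == lv).sum()) for lv in levels]
        table["pooled_n"] = [int((frame[variable] == lv).sum()) for lv in levels]
        table["pooled_pct"] = [
            percent_half_up(n, n_total) for n in table["pooled_n"]
        ]
        per_variable[variable] = table

    crosstabs = {
        variable: pd.crosstab(frame[variable], frame["her2_group"])
        for variable in _CROSSTAB_VARIABLES
    }
    group_counts = {
        g.value: int((frame["her2_group"] == g.value).sum()) for g in HER2Group
    }
    return CohortSummary(
        n_per_cohort=n_per_cohort,
        n_total=n_total,
        per_variable=per_variable,
        crosstabs=crosstabs,
        group_counts=group_counts,
    )
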