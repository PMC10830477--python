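"""PC1-weighted signature: fitting on a discovery cohort and scoring.

The signature is the first principal component of the gene-gene Pearson
correlation matrix of the selected genes, applied to standardized (z-scored)
expression.  The eigenvector sign is fixed so that HER2-low samples score
higher than HER2-zero samples on the fitting dataset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .datasets import ExpressionDataset, HER2Group

__all__ = [
    "StandardizationParams",
    "SignatureModel",
    "SignatureScores",
    "standardize_genes",
    "fit_signature",
    "score_samples",
]


@dataclass
class StandardizationParams:
    """Per-gene mean/sd used to z-score expression."""

    genes: list[str]
    mean: np.ndarray
    sd: np.ndarray


def standardize_genes(
    dataset: ExpressionDataset,
    genes: Sequence[str],
    mode: str = "fit",
    params: StandardizationParams | None = None,
    missing: str = "error",
) -> tuple[np.ndarray, StandardizationParams, list[str]]:
    """Z-score the requested genes.

    ``fit`` mode estimates per-gene mean and sd (ddof=1) from the dataset
    itself; ``apply`` mode uses the supplied ``params``.  Returns the
    standardized genes x samples matrix, the parameters used, and the list
    of genes actually standardized (relevant with ``missing='drop'``).
    """
    if mode not in {"fit", "apply"}:
        raise ValueError("mode must be 'fit' or 'apply'")
    if missing not in {"error", "drop"}:
        raise ValueError("missing policy must be 'error' or 'drop'")
    genes = list(genes)
    absent = [g for g in genes if g not in dataset._gene_index]
    if absent:
        if missing == "error":
            raise KeyError(
                f"dataset {dataset.name!r} lacks signature genes: {absent}"
            )
        warnings.warn(
            f"dataset {dataset.name!r}: dropping absent signature genes "
            f"{absent}",
            stacklevel=2,
        )
        genes = [g for g in genes if g not in set(absent)]
    if not genes:
        raise ValueError("no signature genes available to standardize")

    X = dataset.submatrix(genes)
    if mode == "fit":
        if dataset.n_samples < 2:
            raise ValueError("need >= 2 samples to fit standardization")
        mean = X.mean(axis=1)
        sd = X.std(axis=1, ddof=1)
        zero_sd = np.where(sd == 0)[0]
        if zero_sd.size:
            raise ValueError(
                "constant expression (sd = 0) for gene(s): "
                f"{[genes[i] for i in zero_sd]}"
            )
        params = StandardizationParams(genes=list(genes), mean=mean, sd=sd)
    else:
        if params is None:
            raise ValueError("apply mode requires standardization params")
        index = {g: i for i, g in enumerate(params.genes)}
        missing_params = [g for g in genes if g not in index]
        if missing_params:
            raise KeyError(f"params lack genes: {missing_params}")
        sel = [index[g] for g in genes]
        mean = params.mean[sel]
        sd = params.sd[sel]
        params = StandardizationParams(genes=list(genes), mean=mean, sd=sd)
    z = (X - params.mean[:, None]) / params.sd[:, None]
    return z, params, genes


@dataclass
class SignatureModel:
    """Fitted PC1 signature: genes, z-scoring parameters and unit weights."""

    genes: list[str]
    train_mean: np.ndarray
    train_sd: np.ndarray
    weights: np.ndarray
    orientation: int
    explained_share: float
    fit_cohort: str

    def __post_init__(self) -> None:
        self.train_mean = np.asarray(self.train_mean, dtype=float)
        self.train_sd = np.asarray(self.train_sd, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(np.linalg.norm(self.weights), 1.0, atol=1e-10):
            raise ValueError("PC1 weights must have unit L2 norm")
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be +1 or -1")
        if not 0 < self.explained_share <= 1:
            raise ValueError("explained_share must lie in (0, 1]")

    @property
    def train_params(self) -> StandardizationParams:
        return StandardizationParams(
            genes=list(self.genes), mean=self.train_mean, sd=self.train_sd
        )

    # -- JSON round-trip (bit-exact via float hex encoding) -------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "genes": self.genes,
            "train_mean": [v.hex() for v in map(float, self.train_mean)],
            "train_sd": [v.hex() for v in map(float, self.train_sd)],
            "weights": [v.hex() for v in map(float, self.weights)],
            "train_mean_repr": [float(v) for v in self.train_mean],
            "train_sd_repr": [float(v) for v in self.train_sd],
            "weights_repr": [float(v) for v in self.weights],
            "orientation": self.orientation,
            "explained_share": self.explained_share,
            "fit_cohort": self.fit_cohort,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SignatureModel":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        d = json.loads(text)
        return cls(
            genes=list(d["genes"]),
            train_mean=np.array([float.fromhex(v) for v in d["train_mean"]]),
            train_sd=np.array([float.fromhex(v) for v in d["train_sd"]]),
            weights=np.array([float.fromhex(v) for v in d["weights"]]),
            orientation=int(d["orientation"]),
            explained_share=float(d["explained_share"]),
            fit_cohort=d["fit_cohort"],
        )


@dataclass
class SignatureScores:
    """Per-sample signature values plus the standardization mode used."""

    sample_ids: list[str]
    values: np.ndarray
    standardization_mode: str
    dataset: str = ""


_EIGEN_TIE_RTOL = 1e-8


def fit_signature(
    dataset: ExpressionDataset,
    genes: Sequence[str],
    eigen_tie_rtol: float = _EIGEN_TIE_RTOL,
) -> SignatureModel:
    """Fit the PC1 signature on one dataset.

    Eigendecomposes the genes x genes Pearson correlation matrix, takes the
    leading unit-norm eigenvector as weights and records the explained
    variance share.  Orientation is chosen so the mean score of HER2-low
    samples exceeds that of HER2-zero samples on the fitting dataset.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("signature needs at least 2 genes")
    if dataset.n_samples < len(genes) + 2:
        warnings.warn(
            f"fitting {len(genes)}-gene signature on only "
            f"{dataset.n_samples} samples; estimates may be unstable",
            stacklevel=2,
        )
    z, params, genes = standardize_genes(dataset, genes, mode="fit")
    corr = np.corrcoef(z)
    if not np.all(np.isfinite(corr)):
        raise ValueError("correlation matrix not computable (constant gene?)")
    eigvals, eigvecs = np.linalg.eigh(corr)
    lam1, lam2 = eigvals[-1], eigvals[-2]
    if lam1 - lam2 <= eigen_tie_rtol * max(lam1, 1.0):
        raise ValueError(
            f"leading eigenvalues tied (lambda1={lam1:.6g}, lambda2={lam2:.6g}); "
            "review the gene set before trusting PC1"
        )
    weights = eigvecs[:, -1]
    weights = weights / np.linalg.norm(weights)
    explained_share = float(lam1 / eigvals.sum())

    raw_scores = weights @ z
    groups = dataset.her2_groups()
    low = raw_scores[groups == HER2Group.LOW.value]
    zero = raw_scores[groups == HER2Group.ZERO.value]
    if low.size == 0 or zero.size == 0:
        raise ValueError(
            "orientation rule needs both HER2-low and HER2-zero samples in "
            f"the fitting dataset {dataset.name!r}"
        )
    orientation = 1 if low.mean() > zero.mean() else -1

    return SignatureModel(
        genes=genes,
        train_mean=params.mean,
        train_sd=params.sd,
        weights=weights,
        orientation=orientation,
        explained_share=explained_share,
        fit_cohort=dataset.name,
    )


def score_samples(
    model: SignatureModel,
    dataset: ExpressionDataset,
    standardization_mode: str = "per-dataset",
    missing: str = "error",
) -> SignatureScores:
    """Score a dataset with a fitted signature.

    ``per-dataset`` mode (default) re-standardizes the signature genes
    within the scored dataset -- the platform-offset-invariant transfer rule;
    ``train-params`` reuses the fitting dataset's means and sds.  With
    ``missing='drop'`` absent genes are dropped and the remaining weights
    renormalized to unit length (warned).
    """
    if standardization_mode not in {"per-dataset", "train-params"}:
        raise ValueError("standardization_mode must be 'per-dataset' or 'train-params'")
    if standardization_mode == "train-params":
        z, _, genes = standardize_genes(
            dataset, model.genes, mode="apply", params=model.train_params,
            missing=missing,
        )
    else:
        z, _, genes = standardize_genes(
            dataset, model.genes, mode="fit", missing=missing
        )
    index = {g: i for i, g in enumerate(model.genes)}
    w = model.weights[[index[g] for g in genes]]
    if len(genes) < len(model.genes):
        w = w / np.linalg.norm(w)
        warnings.warn(
            f"scored {dataset.name!r} with {len(genes)}/{len(model.genes)} "
            "signature genes; weights renormalized",
            stacklevel=2,
        )
    values = model.orientation * (w @ z)
    return SignatureScores(
        sample_ids=dataset.sample_ids,
        values=values,
        standardization_mode=standardization_mode,
        dataset=dataset.name,
    )
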