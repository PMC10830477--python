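import numpy as np
import pytest

from her2lowsig.datasets import ExpressionDataset, SampleAnnotation


def build_dataset(
    matrix,
    ihc,
    genes=None,
    cohort="COH",
    name="test",
    hr=None,
    ish=None,
    pam50=None,
):
    """Construct an in-memory dataset from a matrix and per-sample IHC list."""
    matrix = np.asarray(matrix, dtype=float)
    n_genes, n_samples = matrix.shape
    if genes is None:
        genes = [f"g{i}" for i in range(n_genes)]
    samples = [
        SampleAnnotation(
            sample_id=f"{cohort}_s{i}",
            cohort=cohort,
            ihc_score=ihc[i],
            ish_amplified=(ish[i] if ish else "unknown"),
            hr_status=(hr[i] if hr else "unknown"),
            pam50=(pam50[i] if pam50 else "unknown"),
        )
        for i in range(n_samples)
    ]
    return ExpressionDataset(genes=list(genes), samples=samples, matrix=matrix, name=name)


@pytest.fixture
def make_dataset():
    return build_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240201)
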