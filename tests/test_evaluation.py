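import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from her2lowsig.evaluation import (
    category_score_summary,
    compare_signature_vs_gene,
    kruskal_wallis,
    pairwise_posthoc,
    partial_correlation_matrix,
    roc_auc,
    youden_cutoff,
)
from her2lowsig.deg import rank_sum_test
from her2lowsig.signature import fit_signature, score_samples
from her2lowsig.synthetic import ERBB2_LIKE_GENE, default_config, generate_cohorts

from conftest import build_dataset
from oracles import auc_pair_count, kruskal_h, partial_corr_residuals


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def test_kw_degenerate_identical_observations():
    with pytest.warns(UserWarning, match="degenerate"):
        res = kruskal_wallis([1.0] * 6, ["a"] * 2 + ["b"] * 2 + ["c"] * 2)
    assert res.kw_statistic == 0.0
    assert res.kw_p == 1.0


def test_kw_singletons_hand_computed():
    res = kruskal_wallis([1.0, 2.0, 3.0], ["a", "b", "c"])
    assert res.kw_statistic == pytest.approx(2.0)
    assert res.kw_p == pytest.approx(stats.chi2.sf(2.0, df=2))


def test_kw_matches_rank_oracle(rng):
    values = rng.normal(size=24)
    labels = np.repeat(["a", "b", "c"], 8)
    res = kruskal_wallis(values, labels)
    groups = [values[labels == g] for g in ("a", "b", "c")]
    assert res.kw_statistic == pytest.approx(kruskal_h(groups), rel=1e-12)


def test_kw_needs_two_groups(rng):
    values = np.r_[rng.normal(size=6), rng.normal(size=6)]
    res = kruskal_wallis(values, ["a"] * 6 + ["b"] * 6)
    assert set(res.groups_used) == {"a", "b"}
    with pytest.raises(ValueError, match=">= 2"):
        kruskal_wallis(values, ["a"] * 12)


def test_kw_two_groups_agrees_with_rank_sum(rng):
    """With 2 groups KW and the rank-sum test must reject (near-)identically."""
    n_reps, n = 1000, 50
    agree = 0
    for _ in range(n_reps):
        x = rng.normal(size=n)
        y = rng.normal(0.3, 1, size=n)
        p_kw = kruskal_wallis(np.r_[x, y], ["a"] * n + ["b"] * n).kw_p
        p_rs = rank_sum_test(x, y)
        agree += (p_kw < 0.05) == (p_rs < 0.05)
    assert agree / n_reps >= 0.99


# ---------------------------------------------------------------------------
# post hoc pairs
# ---------------------------------------------------------------------------

def test_posthoc_identical_groups_p1(rng):
    v = np.r_[np.arange(5.0), np.arange(5.0)]
    labels = ["low"] * 5 + ["0"] * 5
    out = pairwise_posthoc(v, labels, pairs=[("low", "0")])
    assert out[("low", "0")] == pytest.approx(1.0)


def test_posthoc_empty_pair_list():
    assert pairwise_posthoc([1.0, 2.0], ["a", "b"], pairs=[]) == {}


def test_posthoc_missing_group_reported_none(rng):
    v = rng.normal(size=6)
    with pytest.warns(UserWarning, match="empty"):
        out = pairwise_posthoc(v, ["low"] * 3 + ["0"] * 3, pairs=[("low", "3+")])
    assert out[("low", "3+")] is None


def test_posthoc_bonferroni_adjustment(rng):
    v = np.r_[rng.normal(size=10), rng.normal(3, 1, size=10), rng.normal(size=10)]
    labels = ["low"] * 10 + ["0"] * 10 + ["3+"] * 10
    raw = pairwise_posthoc(v, labels)
    adj = pairwise_posthoc(v, labels, adjust="bonferroni")
    for pair in raw:
        assert adj[pair] == pytest.approx(min(1.0, raw[pair] * 2))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def test_auc_perfect_separation_clips_ci():
    scores = [1.0, 2.0, 10.0, 11.0]
    labels = [False, False, True, True]
    with pytest.warns(UserWarning, match="clipped"):
        res = roc_auc(scores, labels)
    assert res.auc == 1.0
    assert res.ci_high == 1.0 and res.ci_low <= 1.0


def test_auc_enumerated_example():
    res = roc_auc([2, 3, 1, 2.5], [True, True, False, False])
    assert res.auc == pytest.approx(0.75)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        roc_auc([1.0, 2.0], [True, True])


def test_auc_null_concordance(rng):
    scores = rng.normal(size=2000)
    labels = rng.random(2000) < 0.5
    res = roc_auc(scores, labels)
    assert abs(res.auc - 0.5) < 3 / np.sqrt(1000)  # generous binomial band
    assert res.ci_low <= res.auc <= res.ci_high


@settings(max_examples=60, deadline=None)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 20), st.booleans()), min_size=4, max_size=50
    )
)
def test_auc_matches_pair_counting_oracle(data):
    scores = np.array([d[0] for d in data], dtype=float)
    labels = np.array([d[1] for d in data])
    if labels.all() or not labels.any():
        return
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = roc_auc(scores, labels)
    assert res.auc == pytest.approx(
        auc_pair_count(scores[labels], scores[~labels]), abs=1e-12
    )


def test_delong_ci_coverage(rng):
    """95% DeLong interval covers the true binormal AUC ~95% of the time."""
    mu = 1.0
    true_auc = stats.norm.cdf(mu / np.sqrt(2))
    n_reps, covered = 2000, 0
    for _ in range(n_reps):
        neg = rng.normal(size=100)
        pos = rng.normal(mu, 1, size=100)
        scores = np.r_[neg, pos]
        labels = np.r_[np.zeros(100, bool), np.ones(100, bool)]
        res = roc_auc(scores, labels)
        covered += res.ci_low <= true_auc <= res.ci_high
    assert 0.92 <= covered / n_reps <= 0.975


# ---------------------------------------------------------------------------
# Youden cutoff
# ---------------------------------------------------------------------------

def test_youden_perfect_separation_midgap():
    res = youden_cutoff([1.0, 2.0, 3.0, 4.0], [False, False, True, True])
    assert res.youden_j == pytest.approx(1.0)
    assert res.cutoff == pytest.approx(2.5)
    assert res.sensitivity == 1.0 and res.specificity == 1.0


def test_youden_tie_broken_to_smallest_cutoff():
    res = youden_cutoff([2, 3, 1, 2.5], [True, True, False, False])
    assert res.youden_j == pytest.approx(0.5)
    assert res.cutoff == pytest.approx(1.5)  # two candidates reach J=0.5
    assert res.youden_j == pytest.approx(res.sensitivity + res.specificity - 1)


def test_youden_degenerate_all_equal():
    with pytest.warns(UserWarning, match="degenerate"):
        res = youden_cutoff([1.0, 1.0, 1.0], [True, False, True])
    assert res.youden_j == pytest.approx(0.0)


def test_youden_single_class_rejected():
    with pytest.raises(ValueError):
        youden_cutoff([1.0, 2.0], [False, False])


# ---------------------------------------------------------------------------
# partial correlations
# ---------------------------------------------------------------------------

def test_two_genes_partial_equals_pearson(rng):
    X = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=60).T
    ds = build_dataset(X, ihc=["0"] * 60)
    net = partial_correlation_matrix(ds, ds.genes, threshold=0.0)
    assert net.r_p[0, 1] == pytest.approx(np.corrcoef(X)[0, 1], abs=1e-12)


def test_independent_genes_near_zero_partials(rng):
    n = 4000
    X = rng.normal(size=(5, n))
    ds = build_dataset(X, ihc=["0"] * n)
    net = partial_correlation_matrix(ds, ds.genes)
    off = net.r_p[~np.eye(5, dtype=bool)]
    assert np.all(np.abs(off) < 3 / np.sqrt(n))
    assert net.edges.empty


def test_partials_match_residual_regression_oracle(rng):
    cov = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.4], [0.3, 0.4, 1.0]])
    X = rng.multivariate_normal(np.zeros(3), cov, size=80).T
    ds = build_dataset(X, ihc=["0"] * 80)
    net = partial_correlation_matrix(ds, ds.genes, threshold=0.0)
    for i in range(3):
        for j in range(i + 1, 3):
            assert net.r_p[i, j] == pytest.approx(
                partial_corr_residuals(X, i, j), abs=1e-10
            )


def test_partial_matrix_symmetric_unit_diag(rng):
    X = rng.normal(size=(6, 100))
    ds = build_dataset(X, ihc=["0"] * 100)
    net = partial_correlation_matrix(ds, ds.genes)
    np.testing.assert_allclose(net.r_p, net.r_p.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(net.r_p), 1.0)
    assert np.all(np.abs(net.r_p) <= 1 + 1e-12)


def test_singular_correlation_rejected(rng):
    x = rng.normal(size=30)
    ds = build_dataset(np.vstack([x, 2 * x, rng.normal(size=30)]), ihc=["0"] * 30)
    with pytest.raises(ValueError, match="singular"):
        partial_correlation_matrix(ds, ds.genes)


def test_too_few_samples_rejected(rng):
    ds = build_dataset(rng.normal(size=(5, 6)), ihc=["0"] * 6)
    with pytest.raises(ValueError, match="samples"):
        partial_correlation_matrix(ds, ds.genes)


# ---------------------------------------------------------------------------
# signature vs single-gene benchmark
# ---------------------------------------------------------------------------

def test_identical_ranking_gives_identical_auc(rng):
    datasets, truth = generate_cohorts(default_config(seed=5, n_background_genes=60))
    ds = datasets[0]
    genes = list(truth.loc[truth["planted_contrast"].isin(["1+", "2+"]), "gene"])
    model = fit_signature(ds, genes)
    scores = score_samples(model, ds)
    # append the signature score itself as a fake benchmark gene
    import numpy as np

    augmented = build_dataset(
        np.vstack([ds.matrix, scores.values]),
        ihc=[s.ihc_score for s in ds.samples],
        genes=ds.genes + ["SCORE_GENE"],
        cohort="INT1",
    )
    roc_sig, roc_gene, diff = compare_signature_vs_gene(model, augmented, "SCORE_GENE")
    assert diff == pytest.approx(0.0, abs=1e-12)
    assert roc_sig.auc == pytest.approx(roc_gene.auc)


def test_permuted_labels_near_half(rng):
    datasets, truth = generate_cohorts(default_config(seed=6, n_background_genes=60))
    ds = datasets[0]
    genes = list(truth.loc[truth["planted_contrast"].isin(["1+", "2+"]), "gene"])
    model = fit_signature(ds, genes)
    scores = score_samples(model, ds)
    perm = rng.permutation(ds.n_samples)
    labels = (ds.her2_groups() == "low")[perm]
    res = roc_auc(scores.values, labels)
    assert abs(res.auc - 0.5) < 0.17  # 3-sigma-ish band at n=125


def test_category_score_summary_table():
    table = category_score_summary(
        [1.0, 2.0, 3.0, 10.0], ["a", "a", "a", "b"]
    )
    row = table.set_index("category").loc["a"]
    assert row["n"] == 3 and row["median"] == 2.0 and row["min"] == 1.0
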