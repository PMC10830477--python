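import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from her2lowsig.deg import (
    CONTRAST_NAMES,
    VENN_CONTRASTS,
    ContrastResult,
    VennPartition,
    bonferroni_adjust,
    contrast_category,
    log2_fold_change,
    make_all_contrasts,
    make_contrast,
    merge_discovery,
    rank_sum_test,
    select_contrast_degs,
    venn_specific_genes,
)
from her2lowsig.synthetic import PlantedSet, generate_cohorts, recovery_config

from conftest import build_dataset
from oracles import exact_ranksum_pvalue


# ---------------------------------------------------------------------------
# log2 fold change
# ---------------------------------------------------------------------------

def _two_group_dataset(focal_values, rest_values):
    values = list(focal_values) + list(rest_values)
    ihc = ["1+"] * len(focal_values) + ["0"] * len(rest_values)
    ds = build_dataset([values], ihc=ihc)
    contrast = make_contrast(ds, "1+-vs-others")
    return ds, contrast


@pytest.mark.parametrize(
    "focal,rest,expected",
    [
        ([3, 3], [1, 1], 2.0),
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([2.5, 3.5, 3.0], [1.0, 2.0], 1.5),
    ],
)
def test_log2_fold_change_examples(focal, rest, expected):
    ds, contrast = _two_group_dataset(focal, rest)
    assert log2_fold_change(ds, contrast, "g0") == pytest.approx(expected)


def test_fold_change_not_invariant_under_monotone_transform():
    ds, contrast = _two_group_dataset([3.0, 4.0], [1.0, 2.0])
    fc = log2_fold_change(ds, contrast, "g0")
    ds2, c2 = _two_group_dataset([9.0, 16.0], [1.0, 4.0])  # x -> x^2, monotone
    assert log2_fold_change(ds2, c2, "g0") != pytest.approx(fc)


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def test_rank_sum_identical_groups_p1():
    assert rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)


def test_rank_sum_degenerate_all_identical_warns():
    with pytest.warns(UserWarning, match="degenerate"):
        assert rank_sum_test([2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0


def test_rank_sum_exact_small_sample():
    assert rank_sum_test([1, 2], [3, 4]) == pytest.approx(1 / 3)


def test_rank_sum_matches_enumeration_oracle(rng):
    for n1 in range(1, 5):
        for n2 in range(1, 5):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            assert rank_sum_test(x, y) == pytest.approx(
                exact_ranksum_pvalue(x, y), rel=1e-12
            )


@settings(max_examples=40, deadline=None)
@given(
    x=st.lists(st.integers(0, 1000), min_size=2, max_size=12),
    y=st.lists(st.integers(0, 1000), min_size=2, max_size=12),
)
def test_rank_sum_invariant_under_monotone_transform(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(np.concatenate([x, y]) == x[0]):
        return
    p1 = rank_sum_test(x, y)
    p2 = rank_sum_test(np.exp(x / 200.0), np.exp(y / 200.0))
    assert p1 == pytest.approx(p2, rel=1e-9)


def test_rank_sum_empty_group_rejected():
    with pytest.raises(ValueError):
        rank_sum_test([], [1.0])


# ---------------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------------

def test_bonferroni_examples():
    assert bonferroni_adjust([0.01], 5)[0] == pytest.approx(0.05)
    assert bonferroni_adjust([0.3], 5)[0] == 1.0
    np.testing.assert_allclose(
        bonferroni_adjust([0.001, 0.02, 0.04], 3), [0.003, 0.06, 0.12]
    )


def test_bonferroni_family_too_small_rejected():
    with pytest.raises(ValueError, match="family size"):
        bonferroni_adjust([0.1, 0.2], 1)


# ---------------------------------------------------------------------------
# two-stage screening
# ---------------------------------------------------------------------------

def test_infinite_fc_threshold_flags_nothing(rng):
    ds = build_dataset(rng.normal(size=(10, 20)), ihc=["1+"] * 10 + ["0"] * 10)
    contrast = make_contrast(ds, "1+-vs-others")
    res = select_contrast_degs(ds, contrast, fc_threshold=np.inf)
    assert res.n_flagged == 0
    assert not res.table["passed_fc"].any()
    assert res.table["p_raw"].isna().all()  # no tests were run


def test_screen_recovers_strong_planted_genes(rng):
    cfg = recovery_config(seed=21, n_background_genes=200)
    cfg.planted = {"1+": PlantedSet(5, 2.0)}
    (ds,), truth = generate_cohorts(cfg)
    contrast = make_contrast(ds, "1+-vs-others")
    res = select_contrast_degs(ds, contrast)
    planted = set(truth.loc[truth["planted_contrast"] == "1+", "gene"])
    assert planted <= res.significant_genes


def test_screen_invariant_to_sample_order(rng):
    ds = build_dataset(
        rng.normal(size=(30, 24)), ihc=["1+"] * 8 + ["0"] * 8 + ["3+"] * 8
    )
    res1 = select_contrast_degs(ds, make_contrast(ds, "1+-vs-others"))
    perm = rng.permutation(ds.n_samples)
    ds2 = ds.subset_samples(perm)
    res2 = select_contrast_degs(ds2, make_contrast(ds2, "1+-vs-others"))
    np.testing.assert_allclose(res1.table["log2fc"], res2.table["log2fc"], atol=1e-12)
    np.testing.assert_allclose(
        res1.table["p_raw"].fillna(-1), res2.table["p_raw"].fillna(-1), atol=1e-12
    )


def test_significance_implies_fc_pass(rng):
    ds = build_dataset(
        rng.normal(size=(50, 30)) + np.linspace(0, 2, 50)[:, None],
        ihc=["1+"] * 15 + ["0"] * 15,
    )
    res = select_contrast_degs(ds, make_contrast(ds, "1+-vs-others"), fc_threshold=0.3)
    table = res.table
    assert (table.loc[table["passed_sig"], "passed_fc"]).all()
    flagged = table["passed_fc"]
    assert np.all(table.loc[flagged, "p_adj"] >= table.loc[flagged, "p_raw"] - 1e-15)


def test_empty_focal_category_skipped_with_warning(rng):
    ds = build_dataset(rng.normal(size=(3, 10)), ihc=["0"] * 5 + ["1+"] * 5)
    with pytest.warns(UserWarning, match="skipped"):
        assert make_contrast(ds, "2+-vs-others") is None
    res = select_contrast_degs(ds, None)
    assert res.table.empty


def test_collapsed_duplicate_contrast_dropped(rng):
    # no 2+ samples: the joint 1+/2+ split duplicates the 1+ split
    ds = build_dataset(rng.normal(size=(3, 10)), ihc=["0"] * 5 + ["1+"] * 5)
    with pytest.warns(UserWarning):
        contrasts = make_all_contrasts(ds)
    assert "1+-vs-others" in contrasts
    assert "low-vs-others" not in contrasts


# ---------------------------------------------------------------------------
# Venn selection
# ---------------------------------------------------------------------------

def _result_with(sig_genes, contrast, dataset="D"):
    import pandas as pd

    genes = sorted(sig_genes)
    table = pd.DataFrame(
        {
            "gene": genes,
            "log2fc": 2.0,
            "p_raw": 1e-6,
            "p_adj": 1e-4,
            "passed_fc": True,
            "passed_sig": True,
        }
    )
    return ContrastResult(contrast, dataset, table, 1.0, 0.05, len(genes))


def test_venn_set_arithmetic():
    results = {
        "1+-vs-others": _result_with({"a", "b", "c"}, "1+-vs-others"),
        "2+-vs-others": _result_with({"b", "d"}, "2+-vs-others"),
        "low-vs-others": _result_with({"e"}, "low-vs-others"),
    }
    part = venn_specific_genes(results, VENN_CONTRASTS)
    assert part.specific["1+-vs-others"] == {"a", "c"}
    assert part.specific["2+-vs-others"] == {"d"}
    assert part.specific["low-vs-others"] == {"e"}
    assert part.overlaps == {("1+-vs-others", "2+-vs-others"): {"b"}}


def test_venn_specific_sets_pairwise_disjoint_and_cover():
    results = {
        "1+-vs-others": _result_with({"a", "b"}, "1+-vs-others"),
        "2+-vs-others": _result_with({"b", "c"}, "2+-vs-others"),
        "low-vs-others": _result_with({"c", "d"}, "low-vs-others"),
    }
    part = venn_specific_genes(results)
    cells = list(part.specific.values()) + list(part.overlaps.values())
    union = set().union(*cells)
    assert union == {"a", "b", "c", "d"}
    assert sum(len(c) for c in cells) == len(union)  # disjoint partition


def test_venn_empty_and_single_contrast():
    empty = venn_specific_genes(
        {"1+-vs-others": _result_with(set(), "1+-vs-others")}
    )
    assert all(not v for v in empty.specific.values())
    solo = venn_specific_genes({"1+-vs-others": _result_with({"x", "y"}, "1+-vs-others")})
    assert solo.specific["1+-vs-others"] == {"x", "y"}


# ---------------------------------------------------------------------------
# merging discovery selections
# ---------------------------------------------------------------------------

def _partition(dataset, spec):
    return VennPartition(
        dataset=dataset,
        specific={f"{cat}-vs-others" if cat != "low" else "low-vs-others": set(genes)
                  for cat, genes in spec.items()},
        overlaps={},
    )


def test_merge_reference_counts_fixture():
    # two discovery partitions with specific counts (3, 8, 1) and (8, 0, 0)
    p1 = _partition(
        "D1",
        {
            "1+": {f"a{i}" for i in range(3)},
            "2+": {f"b{i}" for i in range(8)},
            "low": {"cplx_like"},
        },
    )
    p2 = _partition("D2", {"1+": {f"c{i}" for i in range(8)}})
    sel = merge_discovery({"D1": p1, "D2": p2})
    assert len(sel.genes) == 20
    counts = sel.table.groupby("category").size().to_dict()
    assert counts == {"1+": 11, "2+": 8, "low": 1}


def test_merge_dedup_same_category():
    p1 = _partition("D1", {"1+": {"g"}})
    p2 = _partition("D2", {"1+": {"g"}})
    sel = merge_discovery({"D1": p1, "D2": p2})
    assert sel.genes == ["g"]
    assert sel.table.loc[0, "sources"] == "D1,D2"


def test_merge_conflict_raises_then_drops():
    p1 = _partition("D1", {"1+": {"g"}})
    p2 = _partition("D2", {"2+": {"g"}})
    with pytest.raises(ValueError, match="conflicting"):
        merge_discovery({"D1": p1, "D2": p2})
    with pytest.warns(UserWarning, match="dropped"):
        sel = merge_discovery({"D1": p1, "D2": p2}, on_conflict="drop")
    assert sel.genes == []


def test_contrast_category_labels():
    assert contrast_category("1+-vs-others") == "1+"
    assert contrast_category("low-vs-others") == "low"
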