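import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirsel.datagen import SynthConfig, generate_feature_table
from mirsel.featsel import (
    FSConfig,
    FeatureClustering,
    SelectionError,
    cluster_features,
    combine_selections,
    discretize_equal_width,
    information_gain,
    rank_by_ig,
    select_hic,
    select_hig,
    select_lig,
    select_pcf,
    select_rfc,
    select_rfs,
    select_sfc,
    select_znf,
)
from mirsel.table import FeatureTable


def cfg(**kw) -> FSConfig:
    base = dict(m=2, k_clusters=2, n_bins=10, top_for_combined=10, seed=0)
    base.update(kw)
    return FSConfig(**base)


# ---------------------------------------------------------------------------
# discretization & information gain


def test_discretize_uniform_grid():
    bins = discretize_equal_width(np.arange(10.0), 10)
    assert bins.tolist() == list(range(10))


def test_discretize_constant_and_boundary():
    assert discretize_equal_width(np.full(5, 3.3), 4).tolist() == [0] * 5
    # w = 5: values below 5 -> bin 0, at/above 5 -> bin 1 (last bin closed)
    bins = discretize_equal_width(np.array([0.0, 4.999, 5.0, 10.0]), 2)
    assert bins.tolist() == [0, 0, 1, 1]


def test_information_gain_known_values():
    labels = np.array(["+", "+", "-", "-"])
    assert information_gain(np.array(list("AABB")), labels) == pytest.approx(1.0)
    assert information_gain(np.array(list("AAAA")), labels) == pytest.approx(0.0)
    # H(Y)=1, H(Y|X)=0.9183 -> IG=0.0817 bits
    bins = np.array(list("AABBBA"))
    labels6 = np.array(list("+++---"))
    assert information_gain(bins, labels6) == pytest.approx(0.0817, abs=5e-5)


def test_information_gain_length_mismatch():
    with pytest.raises(SelectionError, match="mismatch"):
        information_gain(np.array([0, 1]), np.array(["+"]))


def test_rank_by_ig_label_copy_first_and_permutation_invariant(toy_table):
    ranked = rank_by_ig(toy_table, cfg())
    assert ranked[0][0] == "label_copy"
    assert ranked[0][1] == pytest.approx(1.0)  # IG of label copy = H(labels)
    assert ranked[-1][1] == pytest.approx(0.0)  # constant feature at the bottom
    perm = np.random.default_rng(0).permutation(toy_table.n_samples)
    shuffled = toy_table.subset_rows(perm)
    assert rank_by_ig(shuffled, cfg()) == ranked


def test_rank_by_ig_requires_both_classes(toy_table):
    with pytest.raises(SelectionError, match="both classes"):
        rank_by_ig(toy_table.only_class("positive"), cfg())


# ---------------------------------------------------------------------------
# HIG / LIG / RFS


def test_hig_lig_exhaust_when_m_equals_p(toy_table):
    hig = select_hig(toy_table, cfg(m=4))
    lig = select_lig(toy_table, cfg(m=4))
    assert set(hig.features) == set(lig.features) == set(toy_table.feature_names)
    assert hig.features[0] == "label_copy"  # label copy has maximal IG
    assert lig.features[0] == "const"  # constant feature has IG 0


def test_rfs_seeded_and_uniform(toy_table):
    a = select_rfs(toy_table, cfg(m=2, seed=42))
    b = select_rfs(toy_table, cfg(m=2, seed=42))
    assert a.features == b.features
    # uniformity: p=10 features, m=1, 10,000 seeds -> each freq 0.1 +/- 0.01
    table = FeatureTable(
        values=np.zeros((2, 10)),
        feature_names=[f"f{j}" for j in range(10)],
        sample_ids=["a", "b"],
        labels=np.array(["positive", "negative"], dtype=object),
    )
    counts = {f: 0 for f in table.feature_names}
    for seed in range(10_000):
        counts[select_rfs(table, cfg(m=1, seed=seed)).features[0]] += 1
    freqs = np.array(list(counts.values())) / 10_000
    assert np.all(np.abs(freqs - 0.1) <= 0.01)


# ---------------------------------------------------------------------------
# clustering and cluster-based selectors


def duplicated_feature_table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    f1 = rng.normal(size=n)
    f3 = rng.normal(size=n)
    values = np.column_stack([f1, f1, f3])
    return FeatureTable(
        values=values,
        feature_names=["f1", "f2", "f3"],
        sample_ids=[f"s{i}" for i in range(n)],
        labels=np.array(["positive"] * (n // 2) + ["negative"] * (n - n // 2), dtype=object),
    )


def test_cluster_identical_features_together():
    t = duplicated_feature_table()
    cl = cluster_features(t, cfg(k_clusters=2))
    a = cl.assignment
    assert a["f1"] == a["f2"] != a["f3"]
    assert cl.sizes.sum() == 3


def test_cluster_singletons_when_k_equals_p(toy_table):
    cl = cluster_features(toy_table, cfg(k_clusters=4))
    assert sorted(cl.sizes.tolist()) == [1, 1, 1, 1]


def test_cluster_k_above_p_errors(toy_table):
    with pytest.raises(SelectionError, match="lower k"):
        cluster_features(toy_table, cfg(k_clusters=5))


def synthetic_clustering():
    """Hand-built clustering: sizes [5, 3, 2] over p=10; within each cluster
    features are ordered by distance to centroid following their number."""
    names = [f"f{i:02d}" for i in range(10)]
    labels = np.array([0] * 5 + [1] * 3 + [2] * 2)
    dist = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.15, 0.25, 0.35, 0.12, 0.22])
    return FeatureClustering(
        feature_names=names,
        labels=labels,
        centroids=np.zeros((3, 4)),
        centroid_dist=dist,
        k=3,
    )


def test_sfc_takes_centroid_closest_of_largest_clusters():
    cl = synthetic_clustering()
    sel = select_sfc(cl, cfg(m=2))
    # size-5 cluster rep f00, size-3 cluster rep f05
    assert sel.features == ["f00", "f05"]
    assert select_sfc(cl, cfg(m=1)).features == ["f00"]


def test_sfc_second_pass_continues_round_robin():
    cl = synthetic_clustering()
    sel = select_sfc(cl, cfg(m=5))
    assert sel.features == ["f00", "f05", "f08", "f01", "f06"]
    # first pass (first 3 = number of clusters) hits each cluster once
    first = sel.features[:3]
    assert len({cl.assignment[f] for f in first}) == 3


def test_rfc_at_most_one_member_per_cluster_and_seeded():
    cl = synthetic_clustering()
    s1 = select_rfc(cl, cfg(m=2, seed=5))
    s2 = select_rfc(cl, cfg(m=2, seed=5))
    assert s1.features == s2.features
    assert len({cl.assignment[f] for f in s1.features}) == len(s1.features)


def test_hic_reduces_to_hig_on_singletons(toy_table):
    cl = cluster_features(toy_table, cfg(k_clusters=4))
    hic = select_hic(toy_table, cl, cfg(m=3))
    hig = select_hig(toy_table, cfg(m=3))
    assert hic.features == hig.features


def test_hic_label_copy_is_its_clusters_representative(toy_table):
    cl = cluster_features(toy_table, cfg(k_clusters=2))
    hic = select_hic(toy_table, cl, cfg(m=2))
    assert hic.features[0] == "label_copy"
    assert len({cl.assignment[f] for f in hic.features}) == len(hic.features)


# ---------------------------------------------------------------------------
# ZNF / PCF


def test_znf_excludes_zeros_ranks_by_positive_sum():
    values = np.array(
        [
            [1.0, 0.0, 2.0],
            [2.0, 3.0, 2.0],
            [9.0, 9.0, 9.0],  # negative row: must not matter
        ]
    )
    t = FeatureTable(
        values=values,
        feature_names=["f1", "f2", "f3"],
        sample_ids=["a", "b", "c"],
        labels=np.array(["positive", "positive", "negative"], dtype=object),
    )
    sel = select_znf(t, cfg(m=1))
    assert sel.features == ["f3"]  # f2 has a zero among positives; sum f3=4 > f1=3
    # adding another negative row changes nothing
    t2 = FeatureTable(
        values=np.vstack([values, [[0.0, 0.0, 0.0]]]),
        feature_names=["f1", "f2", "f3"],
        sample_ids=["a", "b", "c", "d"],
        labels=np.array(["positive", "positive", "negative", "negative"], dtype=object),
    )
    assert select_znf(t2, cfg(m=1)).features == sel.features


def test_znf_needs_positives(toy_table):
    with pytest.raises(SelectionError, match="positive"):
        select_znf(toy_table.only_class("negative"), cfg())


def test_pcf_prefers_uncorrelated_feature():
    rng = np.random.default_rng(1)
    n = 200
    f1 = rng.normal(size=n)
    f3 = rng.normal(size=n)
    t = FeatureTable(
        values=np.column_stack([f1, f1, f3]),
        feature_names=["f1", "f2", "f3"],
        sample_ids=[f"s{i}" for i in range(n)],
        labels=np.array(["positive"] * n, dtype=object),
    )
    sel = select_pcf(t, cfg(m=1))
    assert sel.features == ["f3"]
    full = select_pcf(t, cfg(m=3))
    assert full.scores is not None
    assert all(0.0 <= s <= 1.0 for s in full.scores)


def test_pcf_single_feature_errors():
    t = FeatureTable(
        values=np.ones((3, 1)),
        feature_names=["f1"],
        sample_ids=["a", "b", "c"],
        labels=np.array(["positive"] * 3, dtype=object),
    )
    with pytest.raises(SelectionError, match="two features"):
        select_pcf(t, cfg())


# ---------------------------------------------------------------------------
# consensus


def test_combine_counts_frequencies():
    sel = combine_selections([["f1", "f2"], ["f1", "f3"]], cfg(m=1))
    assert sel.features == ["f1"]
    one = combine_selections([["f9", "f4"]], cfg(m=2))
    assert one.features == ["f9", "f4"]


def test_combine_matches_brute_force_counting():
    rng = np.random.default_rng(3)
    pool = [f"f{i}" for i in range(30)]
    rankings = [
        list(rng.choice(pool, size=10, replace=False)) for _ in range(5)
    ]
    sel = combine_selections(rankings, cfg(m=30, top_for_combined=30))
    brute = {f: sum(f in r for r in rankings) for r in rankings for f in r}
    assert sel.scores == [float(brute[f]) for f in sel.features]
    # frequencies non-increasing down the list
    assert all(a >= b for a, b in zip(sel.scores, sel.scores[1:]))


def test_combine_rejects_bad_input():
    with pytest.raises(SelectionError, match="no rankings"):
        combine_selections([], cfg())
    with pytest.raises(SelectionError, match="duplicate"):
        combine_selections([["f1", "f1"]], cfg())


# ---------------------------------------------------------------------------
# cross-cutting properties


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_all_selectors_return_valid_unique_selections(seed):
    scfg = SynthConfig(
        n_pos=15, n_neg=15, p=12, n_informative=3, n_weak=2,
        n_redundant_blocks=1, block_size=3, zero_inflation=0.1, seed=seed,
    )
    table, _ = generate_feature_table(scfg)
    c = cfg(m=5, k_clusters=4, top_for_combined=6, seed=seed)
    cl = cluster_features(table, c)
    selections = [
        select_hig(table, c), select_lig(table, c), select_rfs(table, c),
        select_rfc(cl, c), select_sfc(cl, c), select_hic(table, cl, c),
        select_znf(table, c), select_pcf(table, c),
    ]
    for sel in selections:
        assert len(set(sel.features)) == len(sel.features)
        assert set(sel.features) <= set(table.feature_names)
        assert len(sel.features) <= 5
        assert sel.m == len(sel.features)


def test_recovery_hig_finds_planted_lig_avoids_them(planted_500):
    _, table, man = planted_500
    planted = set(man.loc[man["role"] == "informative", "feature"])
    c = cfg(m=50, k_clusters=100, top_for_combined=100)
    hig, lig = select_hig(table, c), select_lig(table, c)
    assert len(planted & set(hig.features)) >= 18
    assert len(planted & set(lig.features)) <= 1
    # p >= 2m with distinct IG values: the two selections cannot overlap
    assert not (set(hig.features) & set(lig.features))
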