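"""Microsatellite statistics against hand calculations and oracles."""

import itertools
from math import comb, sqrt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from volesurf.io import GenotypeTable, SiteTable, ValidationError
from volesurf.msat import (
    allele_frequencies,
    amova,
    diversity_summary,
    hwe_test,
    nei_da,
    nj_tree,
    pairwise_fst,
    rarefied_richness,
)

from conftest import random_genotype_table
from oracles import (
    allele_freq_tally,
    hwe_exhaustive_p,
    rarefaction_enumeration,
    wc_theta_oracle,
)


def single_site_table(calls: np.ndarray, site: str = "s") -> GenotypeTable:
    inds = [f"{site}_{i}" for i in range(calls.shape[0])]
    return GenotypeTable(
        individuals=inds,
        loci=[f"L{j}" for j in range(calls.shape[1])],
        calls=calls,
        site_of={i: site for i in inds},
    )


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def test_allele_frequencies_hand_example():
    gt = single_site_table(np.array([[[150, 150]], [[150, 152]]]))
    f = allele_frequencies(gt)[("s", "L0")]
    assert f == {150: 0.75, 152: 0.25}


def test_allele_frequencies_monomorphic():
    gt = single_site_table(np.array([[[7, 7]], [[7, 7]]]))
    assert allele_frequencies(gt)[("s", "L0")] == {7: 1.0}


def test_allele_frequencies_match_bruteforce_tally():
    rng = np.random.default_rng(42)
    for _ in range(20):
        gt = random_genotype_table(
            rng, n_sites=3, n_per_site=6, n_loci=3, missing_rate=0.2
        )
        freqs = allele_frequencies(gt)
        for site in gt.sites:
            idx = gt.site_indices(site)
            for li, locus in enumerate(gt.loci):
                calls = gt.calls[idx, li, :]
                calls = calls[calls[:, 0] != 0]
                if calls.size == 0:
                    assert freqs[(site, locus)] == {}
                    continue
                expect = allele_freq_tally(calls)
                got = freqs[(site, locus)]
                assert set(got) == set(expect)
                for a in expect:
                    assert got[a] == pytest.approx(expect[a], abs=1e-15)


# ---------------------------------------------------------------------------
# rarefaction and diversity
# ---------------------------------------------------------------------------


def test_rarefaction_at_full_sample_equals_observed_count():
    assert rarefied_richness({1: 7, 2: 7}, 14) == pytest.approx(2.0)


def test_rarefaction_closed_form_small_case():
    # {A:3, B:1}, g=2: exhaustive over all 6 subsets gives mean 1.5
    assert rarefied_richness({1: 3, 2: 1}, 2) == pytest.approx(1.5)
    assert rarefaction_enumeration({1: 3, 2: 1}, 2) == pytest.approx(1.5)


def test_rarefaction_never_extrapolates():
    with pytest.raises(ValidationError):
        rarefied_richness({1: 3}, 4)


@given(
    counts=st.dictionaries(
        st.integers(1, 6), st.integers(1, 4), min_size=1, max_size=4
    ),
    data=st.data(),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_rarefaction_monotone_in_g_and_bounded(counts, data):
    N = sum(counts.values())
    g = data.draw(st.integers(1, N))
    ar_g = rarefied_richness(counts, g)
    assert ar_g <= len(counts) + 1e-12
    if g > 1:
        assert ar_g >= rarefied_richness(counts, g - 1) - 1e-12
    if N >= 2:
        assert 1.0 - 1e-12 <= rarefied_richness(counts, 2) <= 2.0 + 1e-12


def test_heterozygosity_hand_example():
    gt = single_site_table(np.array([[[1, 2]], [[1, 2]]]))
    div = diversity_summary(gt, g=2)
    row = div.per_locus.iloc[0]
    assert row["Ho"] == pytest.approx(1.0)
    assert row["He"] == pytest.approx(0.5)


def test_unbiased_he_dominates_biased():
    rng = np.random.default_rng(3)
    gt = random_genotype_table(rng, n_sites=2, n_per_site=10, n_loci=4)
    div = diversity_summary(gt, g=4)
    poly = div.per_locus[div.per_locus["He"] > 0]
    assert (poly["uHe"] > poly["He"]).all()


def test_private_and_rare_allele_lists():
    calls_a = np.array([[[1, 1]], [[1, 2]]])
    calls_b = np.array([[[2, 2]], [[2, 3]]])
    gt = GenotypeTable(
        individuals=["a_0", "a_1", "b_0", "b_1"],
        loci=["L0"],
        calls=np.concatenate([calls_a, calls_b]),
        site_of={"a_0": "a", "a_1": "a", "b_0": "b", "b_1": "b"},
    )
    div = diversity_summary(gt, g=2)
    assert div.private_alleles["a"] == [("L0", 1)]
    assert div.private_alleles["b"] == [("L0", 3)]
    # no frequency below 0.05 in these tiny samples
    assert div.rare_alleles["a"] == [] and div.rare_alleles["b"] == []


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------


def test_hwe_monomorphic_flagged():
    gt = single_site_table(np.array([[[1, 1]]] * 6))
    res = hwe_test(gt, "s", "L0", reps=100, seed=0)
    assert res.p_value == 1.0 and res.monomorphic


def test_hwe_null_case_not_rejected():
    # exact Hardy-Weinberg proportions 1:2:1 repeated
    block = [[[1, 1]], [[1, 2]], [[2, 1]], [[2, 2]]]
    gt = single_site_table(np.array(block * 5))
    res = hwe_test(gt, "s", "L0", reps=4000, seed=1)
    assert res.p_value > 0.5


def test_hwe_matches_exhaustive_pairing_enumeration():
    rng = np.random.default_rng(7)
    for _ in range(4):
        calls = rng.integers(1, 3, (5, 1, 2))
        if len(np.unique(calls)) == 1:
            continue
        gt = single_site_table(calls)
        mc = hwe_test(gt, "s", "L0", reps=20000, seed=11).p_value
        exact = hwe_exhaustive_p(calls[:, 0, :])
        assert mc == pytest.approx(exact, abs=0.02)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


def duplicated_sites_table(rng, n=20) -> GenotypeTable:
    calls = rng.integers(1, 5, (n, 2, 2))
    both = np.concatenate([calls, calls])
    inds = [f"a_{i}" for i in range(n)] + [f"b_{i}" for i in range(n)]
    site_of = {i: i.split("_")[0] for i in inds}
    return GenotypeTable(inds, ["L0", "L1"], both, site_of)


def test_theta_near_zero_for_identical_sites():
    gt = duplicated_sites_table(np.random.default_rng(5))
    theta = pairwise_fst(gt).get("a", "b")
    assert abs(theta) < 0.05


def test_theta_one_for_fixed_difference():
    calls = np.array([[[1, 1]]] * 8 + [[[2, 2]]] * 8)
    inds = [f"a_{i}" for i in range(8)] + [f"b_{i}" for i in range(8)]
    gt = GenotypeTable(inds, ["L0"], calls, {i: i.split("_")[0] for i in inds})
    assert pairwise_fst(gt).get("a", "b") == pytest.approx(1.0)


def test_theta_matches_independent_variance_component_oracle():
    rng = np.random.default_rng(2024)
    for _ in range(25):
        gt = random_genotype_table(
            rng, n_sites=2, n_per_site=4, n_loci=2, n_alleles=4, missing_rate=0.1
        )
        try:
            ours = pairwise_fst(gt).get("p0", "p1")
        except ValidationError:
            continue
        pops = [gt.calls[gt.site_indices(s)] for s in gt.sites]
        assert ours == pytest.approx(wc_theta_oracle(pops), abs=1e-12)


def test_theta_invariant_to_individual_and_locus_order():
    rng = np.random.default_rng(9)
    gt = random_genotype_table(rng, n_sites=3, n_per_site=8, n_loci=4)
    base = pairwise_fst(gt)
    perm_i = rng.permutation(gt.n_individuals)
    perm_l = rng.permutation(len(gt.loci))
    shuffled = GenotypeTable(
        individuals=[gt.individuals[i] for i in perm_i],
        loci=[gt.loci[j] for j in perm_l],
        calls=gt.calls[np.ix_(perm_i, perm_l)],
        site_of=gt.site_of,
    )
    other = pairwise_fst(shuffled)
    for a in gt.sites:
        for b in gt.sites:
            if a != b:
                assert base.get(a, b) == pytest.approx(other.get(a, b), abs=1e-12)


# ---------------------------------------------------------------------------
# Nei's D_a and the NJ tree
# ---------------------------------------------------------------------------


def freq_defined_table(freq_profiles: dict[str, list[list[int]]]) -> GenotypeTable:
    """Build a table whose per-site gene-copy pools are given explicitly."""
    inds, site_of, calls = [], {}, []
    for site, loci_pools in freq_profiles.items():
        n = len(loci_pools[0]) // 2
        for k in range(n):
            ind = f"{site}_{k}"
            inds.append(ind)
            site_of[ind] = site
            calls.append(
                [[pool[2 * k], pool[2 * k + 1]] for pool in loci_pools]
            )
    L = len(next(iter(freq_profiles.values())))
    return GenotypeTable(inds, [f"L{j}" for j in range(L)], np.array(calls), site_of)


def test_nei_da_identity_and_disjoint():
    gt = freq_defined_table({"a": [[1, 1, 2, 2]], "b": [[1, 1, 2, 2]]})
    _, D = nei_da(gt)
    assert D[0, 1] == pytest.approx(0.0)
    gt2 = freq_defined_table({"a": [[1, 1, 2, 2]], "b": [[3, 3, 4, 4]]})
    _, D2 = nei_da(gt2)
    assert D2[0, 1] == pytest.approx(1.0)


def test_nei_da_hand_computed_one_locus():
    # p = (0.5, 0.5) vs (1, 0): D_a = 1 - sqrt(0.5)
    gt = freq_defined_table({"a": [[1, 1, 2, 2]], "b": [[1, 1, 1, 1]]})
    _, D = nei_da(gt)
    assert D[0, 1] == pytest.approx(1 - sqrt(0.5), abs=1e-12)


def _patristic(newick: str) -> dict[frozenset, float]:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for t1, t2 in itertools.combinations(taxa, 2):
        out[frozenset({t1.label, t2.label})] = pdm.distance(t1, t2)
    return out


def test_nj_three_taxa_closed_form():
    # d(ab)=3, d(ac)=4, d(bc)=5 -> leaf branches (1, 2, 3)
    labels = ["a", "b", "c"]
    D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    nwk = nj_tree(labels, D)
    pat = _patristic(nwk)
    assert pat[frozenset({"a", "b"})] == pytest.approx(3.0, abs=1e-9)
    assert pat[frozenset({"a", "c"})] == pytest.approx(4.0, abs=1e-9)
    assert pat[frozenset({"b", "c"})] == pytest.approx(5.0, abs=1e-9)


def test_nj_recovers_additive_four_taxon_tree():
    # tree ((a:1,b:2):1.5,(c:0.5,d:3)) -> additive distances
    D = np.array(
        [
            [0.0, 3.0, 3.0, 5.5],
            [3.0, 0.0, 4.0, 6.5],
            [3.0, 4.0, 0.0, 3.5],
            [5.5, 6.5, 3.5, 0.0],
        ]
    )
    labels = ["a", "b", "c", "d"]
    pat = _patristic(nj_tree(labels, D))
    for i, j in itertools.combinations(range(4), 2):
        assert pat[frozenset({labels[i], labels[j]})] == pytest.approx(
            D[i, j], abs=1e-9
        )


def test_nj_ultrametric_matches_hierarchical_clustering():
    # nested ultrametric structure: cherries (a,b) and (d,e)
    labels = ["a", "b", "c", "d", "e"]
    D = np.array(
        [
            [0, 2, 6, 10, 10],
            [2, 0, 6, 10, 10],
            [6, 6, 0, 10, 10],
            [10, 10, 10, 0, 4],
            [10, 10, 10, 4, 0],
        ],
        dtype=float,
    )
    import dendropy

    tree = dendropy.Tree.get(data=nj_tree(labels, D), schema="newick")
    tree.encode_bipartitions()
    splits = {
        frozenset(leaf.taxon.label for leaf in e.head_node.leaf_iter())
        for e in tree.edges()
        if e.head_node is not tree.seed_node
    }
    # hierarchical (average-linkage) clustering of the same matrix
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    Z = hierarchy.linkage(squareform(D), method="average")
    assert {"a", "b"} in [set(s) for s in splits]
    assert {"d", "e"} in [set(s) for s in splits]
    # the first two merges of UPGMA are those same cherries
    first_merges = {frozenset({labels[int(Z[0, 0])], labels[int(Z[0, 1])]}),
                    frozenset({labels[int(Z[1, 0])], labels[int(Z[1, 1])]})}
    assert first_merges == {frozenset({"a", "b"}), frozenset({"d", "e"})}


def test_nj_rejects_asymmetric_input():
    with pytest.raises(ValidationError):
        nj_tree(["a", "b", "c"], np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]))


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


def test_amova_two_level_hand_worked_partition():
    gt = GenotypeTable(
        individuals=["i1", "i2", "i3", "i4"],
        loci=["L1"],
        calls=np.array([[[1, 1]], [[1, 2]], [[2, 2]], [[2, 2]]]),
        site_of={"i1": "A", "i2": "A", "i3": "B", "i4": "B"},
    )
    res = amova(gt, None, reps=0)
    # hand-worked nested sums of squares: SS_total = 15/8, SS_within = 3/4,
    # df 6 and 1, n' = 4 -> sigma_within = 0.125, sigma_among = 0.25
    assert res.components["within_sites"] == pytest.approx(0.125, abs=1e-12)
    assert res.components["among_sites"] == pytest.approx(0.25, abs=1e-12)
    assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-9)


def test_amova_extreme_cluster_differentiation(toy_meta):
    # clusters fixed for different alleles at every locus
    inds, site_of, calls = [], {}, []
    for site, allele in zip("abcdef", [1, 1, 1, 2, 2, 2]):
        for k in range(5):
            ind = f"{site}_{k}"
            inds.append(ind)
            site_of[ind] = site
            calls.append([[allele, allele]] * 3)
    gt = GenotypeTable(inds, ["L0", "L1", "L2"], np.array(calls), site_of)
    res = amova(gt, toy_meta, reps=0)
    assert res.percentages["among_clusters"] > 90.0
    assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-9)


def test_amova_single_site_cluster_rejected():
    inds = [f"s{i}_{k}" for i in range(3) for k in range(4)]
    site_of = {i: i.split("_")[0] for i in inds}
    rng = np.random.default_rng(1)
    gt = GenotypeTable(
        inds, ["L0"], rng.integers(1, 4, (12, 1, 2)), site_of
    )
    meta = SiteTable(
        pd.DataFrame(
            dict(site=["s0", "s1", "s2"], lat=[0.0] * 3, lon=[0.0, 1, 2],
                 cluster=["X", "X", "Y"])
        )
    )
    with pytest.raises(ValidationError, match="2-level"):
        amova(gt, meta, reps=0)
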