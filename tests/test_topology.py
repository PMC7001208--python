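"""Topology enumeration, exact weighting, window handling, gene-tree tests."""
import itertools

import numpy as np
import pytest

from admixscan.dstat import PolarizedSiteTable
from admixscan.errors import ConfigError
from admixscan.simulate import (SeqSimConfig, alignment_to_genotypes,
                                simulate_sequences_on_tree)
from admixscan.topology import (build_window_tree, enumerate_rooted_topologies,
                                gene_topology_test, topology_weights,
                                weight_summary, window_partition)
from admixscan.tree import read_newick
from admixscan.distance import patristic_matrix
from admixscan.io import GeneAlignment

from conftest import random_grouped_tree


# -- enumeration ------------------------------------------------------------
@pytest.mark.parametrize("k,expected", [(2, 1), (3, 3), (4, 15), (5, 105)])
def test_topology_counts(k, expected):
    topos = enumerate_rooted_topologies([f"G{i}" for i in range(k)], "O")
    assert len(topos) == expected
    assert len({t.newick for t in topos}) == expected


def test_enumeration_rejects_duplicates():
    with pytest.raises(ConfigError):
        enumerate_rooted_topologies(["A", "A", "B"], "O")


def test_enumeration_is_stable():
    a = enumerate_rooted_topologies(["x", "y", "z"], "O")
    b = enumerate_rooted_topologies(["z", "x", "y"], "O")
    assert [t.newick for t in a] == [t.newick for t in b]


# -- windows ----------------------------------------------------------------
def _sites(pairs):
    chrom = np.array([c for c, _ in pairs], dtype=object)
    pos = np.array([p for _, p in pairs])
    return PolarizedSiteTable(chrom=chrom, pos=pos,
                              codes=np.zeros((len(pairs), 4), dtype=np.int8))


def test_window_partition_trailing_dropped():
    sites = _sites([("chr1", p) for p in range(1, 251)])
    wins = window_partition(sites, 100)
    assert len(wins) == 2
    assert wins[0].site_indices == tuple(range(100))


def test_window_partition_respects_chromosomes():
    sites = _sites([("chr1", p) for p in range(1, 101)]
                   + [("chr2", p) for p in range(1, 101)])
    wins = window_partition(sites, 100)
    assert len(wins) == 2
    assert {w.chrom for w in wins} == {"chr1", "chr2"}


def test_window_partition_too_few_sites():
    sites = _sites([("chr1", p) for p in range(1, 100)])
    assert window_partition(sites, 100) == []


# -- weighting --------------------------------------------------------------
def _three_group_topos():
    return enumerate_rooted_topologies(["A", "B", "C"], "OUT")


def test_monophyletic_groups_weight_one():
    tree = read_newick(
        "(((a1:1,a2:1):1,(b1:1,b2:1):1):1,((c1:1,c2:1):2,o1:3):1);")
    groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B",
              "c1": "C", "c2": "C", "o1": "OUT"}
    topos = _three_group_topos()
    rec = topology_weights(tree, groups, topos)
    target = next(t for t in topos
                  if frozenset({"A", "B"}) in t.clusters)
    assert rec.weights[target.index] == pytest.approx(1.0)
    assert rec.n_subsamples == 8


def test_weights_sum_to_one_random_trees(rng):
    topos = _three_group_topos()
    for _ in range(20):
        tree, groups = random_grouped_tree(rng, tips_per_group=3, n_outgroup=2)
        rec = topology_weights(tree, groups, topos)
        assert rec.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert rec.n_subsamples == 3 * 3 * 3 * 2


def test_zero_length_polytomy_fractional_credit():
    tree = read_newick("(((a1:1,(b1:1,c1:1):0):1),o1:1);")
    groups = {"a1": "A", "b1": "B", "c1": "C", "o1": "OUT"}
    rec = topology_weights(tree, groups, _three_group_topos())
    assert np.allclose(rec.weights, [1 / 3] * 3)


def _oracle_weights_four_point(tree, groups, topos):
    """Independent oracle: for each trio-plus-outgroup combination decide
    the induced rooted triple with the four-point condition on patristic
    distances (all three sums equal = unresolved -> fractional credit)."""
    pm = patristic_matrix(_unit_lengths(tree))
    tips_by_group = {}
    for tip, g in groups.items():
        tips_by_group.setdefault(g, []).append(tip)
    ingroups = sorted(topos[0].labels)
    og = topos[0].outgroup
    by_pair = {next(iter(t.clusters)): t.index for t in topos}
    counts = np.zeros(len(topos))
    n = 0
    for combo in itertools.product(*(sorted(tips_by_group[g]) for g in ingroups),
                                   sorted(tips_by_group[og])):
        n += 1
        x, y, z, o = combo
        sums = {
            frozenset({ingroups[0], ingroups[1]}): pm[x, y] + pm[z, o],
            frozenset({ingroups[0], ingroups[2]}): pm[x, z] + pm[y, o],
            frozenset({ingroups[1], ingroups[2]}): pm[y, z] + pm[x, o],
        }
        lo = min(sums.values())
        winners = [p for p, s in sums.items() if abs(s - lo) < 1e-9]
        if len(winners) == 1:
            counts[by_pair[winners[0]]] += 1
        elif len(winners) == 3:
            for p in sums:
                counts[by_pair[p]] += 1 / 3
        else:
            raise AssertionError("two-way tie is not tree-like")
    return counts / n


def _unit_lengths(tree):
    t = tree.copy()
    for node in t.preorder():
        if node is not t.root and node.length is None:
            node.length = 1.0
    return t


def test_weights_match_four_point_oracle_random_trees(rng):
    topos = _three_group_topos()
    for _ in range(30):
        tree, groups = random_grouped_tree(rng, tips_per_group=3, n_outgroup=1)
        rec = topology_weights(tree, groups, topos)
        oracle = _oracle_weights_four_point(tree, groups, topos)
        assert np.allclose(rec.weights, oracle, atol=1e-12)


def test_weights_permute_with_group_labels(rng):
    tree, groups = random_grouped_tree(rng, tips_per_group=2)
    topos = _three_group_topos()
    rec = topology_weights(tree, groups, topos)
    swapped = {tip: {"A": "B", "B": "A"}.get(g, g) for tip, g in groups.items()}
    rec2 = topology_weights(tree, swapped, topos)
    # the (A,B) sister topology is invariant; the other two swap
    idx = {frozenset(next(iter(t.clusters))): t.index for t in topos}
    ab, ac, bc = (idx[frozenset(p)] for p in
                  ({"A", "B"}, {"A", "C"}, {"B", "C"}))
    assert rec2.weights[ab] == pytest.approx(rec.weights[ab])
    assert rec2.weights[ac] == pytest.approx(rec.weights[bc])
    assert rec2.weights[bc] == pytest.approx(rec.weights[ac])


def test_missing_group_errors():
    tree = read_newick("((a1:1,b1:1):1,o1:1);")
    with pytest.raises(ConfigError):
        topology_weights(tree, {"a1": "A", "b1": "B", "o1": "OUT"},
                         _three_group_topos())


# -- weight summary ---------------------------------------------------------
def _record(weights):
    from admixscan.topology import TopologyWeightRecord

    return TopologyWeightRecord(0, "chr1", 1, 2, np.array(weights), 1)


def test_identical_windows_zero_width_ci():
    recs = [_record([0.5, 0.3, 0.2])] * 5
    totals, lo, hi = weight_summary(recs, n_boot=200, seed=1)
    assert np.allclose(totals, [0.5, 0.3, 0.2])
    assert np.allclose(lo, totals) and np.allclose(hi, totals)


def test_two_window_bootstrap_matches_exhaustive_enumeration():
    w0, w1 = np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
    recs = [_record(w0), _record(w1)]
    totals, lo, hi = weight_summary(recs, n_boot=2000, seed=3)
    assert np.allclose(totals, [0.5, 0.5, 0.0])
    # exhaustive resamples of 2 windows: (0,0), (0,1), (1,0), (1,1)
    possible = {tuple(w0), tuple((w0 + w1) / 2), tuple(w1)}
    rng = np.random.default_rng(3)
    seen = set()
    for _ in range(2000):
        pick = rng.integers(0, 2, size=2)
        t = (np.stack([w0, w1])[pick]).sum(axis=0)
        seen.add(tuple(t / t.sum()))
    assert seen == possible
    assert lo[0] == 0.0 and hi[0] == 1.0  # extremes realized at n=2


def test_totals_invariant_to_window_order():
    recs = [_record([0.6, 0.3, 0.1]), _record([0.2, 0.5, 0.3]),
            _record([0.1, 0.1, 0.8])]
    t1, *_ = weight_summary(recs, n_boot=50, seed=0)
    t2, *_ = weight_summary(recs[::-1], n_boot=50, seed=0)
    assert np.allclose(t1, t2)


# -- window trees -----------------------------------------------------------
def test_window_tree_recovers_diverged_groups(rng):
    """Two clearly diverged groups plus outgroup come out reciprocally
    monophyletic in the rooted NJ window tree."""
    newick = ("(((a1:0.02,a2:0.02):0.3,(b1:0.02,b2:0.02):0.3):0.3,"
              "og:0.6);")
    guide = read_newick(newick)
    hits = 0
    n_rep = 30
    for rep in range(n_rep):
        aln = simulate_sequences_on_tree(
            SeqSimConfig(tree=guide, length=400, model="JC69", seed=1000 + rep))
        gt = alignment_to_genotypes(aln)
        if gt.n_sites < 4:
            continue
        tree = build_window_tree(gt, ["og"])
        # check reciprocal monophyly via the rooted tree's clusters
        clusters = []

        def collect(node):
            if node.is_leaf:
                return {node.label}
            s = set()
            for c in node.children:
                s |= collect(c)
            clusters.append(s)
            return s
        collect(tree.root)
        if {"a1", "a2"} in clusters and {"b1", "b2"} in clusters:
            hits += 1
    assert hits >= 0.95 * n_rep


def test_invariant_window_star_tree():
    aln = GeneAlignment.from_strings(["a", "b", "c", "og"], ["ACGT"] * 4)
    gt = alignment_to_genotypes(aln, polymorphic_only=False)
    with pytest.warns(UserWarning, match="star"):
        tree = build_window_tree(gt, ["og"])
    assert len(tree.root.children) == 4


# -- per-gene topology tests ------------------------------------------------
def test_gene_test_obvious_signal():
    # P1 and P2 identical, 50 diagnostic sites vs P3/O
    base = "ACGT" * 50
    p3 = "TGCA" * 25 + "ACGT" * 25
    aln = GeneAlignment.from_strings(
        ["P1", "P2", "P3", "O"], [base, base, p3, p3])
    res = gene_topology_test(aln, {n: n for n in aln.names}, seed=0)
    assert not res.omitted
    sel = res.topologies[res.selected]
    assert frozenset({"P1", "P2"}) in sel.clusters
    assert res.support[res.selected] > 0.99


def test_gene_test_identical_sequences_omitted():
    aln = GeneAlignment.from_strings(["P1", "P2", "P3", "O"], ["ACGTACGT"] * 4)
    res = gene_topology_test(aln, {n: n for n in aln.names}, seed=0)
    assert res.omitted and res.reason == "zero_likelihood_difference"


def test_gene_test_all_gap_omitted():
    aln = GeneAlignment.from_strings(["P1", "P2", "P3", "O"], ["NNNN"] * 4)
    res = gene_topology_test(aln, {n: n for n in aln.names}, seed=0)
    assert res.omitted and res.reason == "no_signal"


def test_rell_support_invariant_to_site_order(rng):
    guide = read_newick("(((P1:0.1,P2:0.1):0.05,P3:0.15):0.05,O:0.3);")
    aln = simulate_sequences_on_tree(
        SeqSimConfig(tree=guide, length=500, model="JC69", seed=7))
    perm = rng.permutation(aln.length)
    shuffled = GeneAlignment(aln.names, aln.codes[:, perm])
    r1 = gene_topology_test(aln, {n: n for n in aln.names}, seed=9)
    r2 = gene_topology_test(shuffled, {n: n for n in aln.names}, seed=9)
    assert np.allclose(r1.support, r2.support, atol=1e-12)
    assert np.allclose(sorted(r1.loglik), sorted(r2.loglik), atol=1e-6)
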