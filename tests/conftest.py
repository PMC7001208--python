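"""Shared fixtures: small genotype tables, random trees, and SV truth sets.

Everything is generated programmatically with fixed seeds; no data files.
"""
from __future__ import annotations

import numpy as np
import pytest

from admixscan.io import GenotypeTable
from admixscan.tree import Node, PhyloTree


def make_genotype_table(records, samples, ploidy=2):
    """Build a GenotypeTable from (chrom, pos, ref, alts, genotype-rows).

    Each genotype row is a list of per-sample allele tuples; use -1 for a
    missing allele.
    """
    chrom, pos, ref, alts, gts = [], [], [], [], []
    for c, p, r, a, row in records:
        chrom.append(c)
        pos.append(p)
        ref.append(r)
        alts.append(tuple(a))
        gts.append(np.array(row, dtype=np.int8).reshape(len(samples), ploidy))
    genotypes = (np.stack(gts) if gts
                 else np.zeros((0, len(samples), ploidy), dtype=np.int8))
    return GenotypeTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=ref, alts=alts, genotypes=genotypes, samples=list(samples))


def random_binary_tree(n_tips: int, rng: np.random.Generator,
                       min_len: float = 0.1, max_len: float = 1.0) -> PhyloTree:
    """Random rooted binary tree with positive branch lengths (additive)."""
    nodes = [Node(f"t{i}", float(rng.uniform(min_len, max_len)))
             for i in range(n_tips)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = Node(None, float(rng.uniform(min_len, max_len)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for x in nodes:
        root.add_child(x)
    return PhyloTree(root)


def random_grouped_tree(rng: np.random.Generator, tips_per_group: int = 3,
                        n_outgroup: int = 1) -> tuple[PhyloTree, dict]:
    """Random binary tree whose tips are labeled into groups A/B/C/OUT."""
    labels = ([f"A_{i}" for i in range(tips_per_group)]
              + [f"B_{i}" for i in range(tips_per_group)]
              + [f"C_{i}" for i in range(tips_per_group)]
              + [f"OUT_{i}" for i in range(n_outgroup)])
    nodes = [Node(lab, float(rng.uniform(0.1, 1.0))) for lab in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = Node(None, float(rng.uniform(0.1, 1.0)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for x in nodes:
        root.add_child(x)
    groups = {lab: lab.rsplit("_", 1)[0] for lab in labels}
    return PhyloTree(root), groups


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def qc_fixture_table():
    """Hand-enumerated QC fixture: an indel, a SNP 3 bp from it, a site
    missing in 3/10 samples, a site heterozygous in 1/10, and 5 clean SNPs.
    The three filter rules remove one site each, leaving 6."""
    samples = [f"s{i}" for i in range(10)]
    hom = [(0, 0)] * 10

    def with_missing(k):
        return [(-1, -1)] * k + [(0, 0)] * (10 - k)

    het1 = [(0, 1)] + [(0, 0)] * 9
    records = [
        ("chr1", 100, "A", ["ATT"], hom),        # indel: survives
        ("chr1", 103, "C", ["T"], hom),          # SNP 3 bp from indel: removed
        ("chr1", 500, "G", ["A"], with_missing(3)),  # 30% missing: removed
        ("chr1", 900, "T", ["C"], het1),         # 10% het: removed
        ("chr1", 1500, "A", ["G"], hom),
        ("chr1", 2000, "C", ["A"], hom),
        ("chr1", 2500, "G", ["T"], hom),
        ("chr1", 3000, "T", ["A"], hom),
        ("chr1", 3500, "A", ["C"], hom),
    ]
    return make_genotype_table(records, samples)
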