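"""Pairwise genetic distances and neighbor-joining tree construction.

Three distances are provided: the allele-sharing (identity-by-state)
distance used to relate population samples, and the JC69 and K2P corrected
sequence distances.  The NJ implementation is the classic Saitou-Nei
agglomeration with a deterministic tie-break so that trees are reproducible;
on additive input matrices it recovers the generating tree exactly.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import SaturatedDistanceError, UndefinedDistanceError, ValidationError
from .io import GenotypeTable
from .tree import Node, PhyloTree

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_VALID = set("ACGT")


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(m)) > 1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if np.any(m < -1e-12):
            raise ValidationError("negative distances")
        self.matrix = m

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.matrix[i, j])


# ---------------------------------------------------------------------------
# allele-sharing distance
# ---------------------------------------------------------------------------
def allele_sharing_distance(gt: GenotypeTable) -> DistanceMatrix:
    """Identity-by-state distance between all sample pairs.

    Per site the similarity between two diploid genotypes is the mean of the
    Kronecker delta over the four ordered allele pairings (1/4 * sum over
    alleles a of i, b of j of delta(a, b)); for haploid calls it is the
    delta of the two alleles.  The distance is one minus the mean similarity
    over sites where both samples are fully called; sites with missingness
    in a pair are skipped for that pair only.
    """
    G = gt.genotypes  # (S, N, ploidy)
    S, N, ploidy = G.shape
    ok = np.all(G >= 0, axis=2)  # (S, N)
    D = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            use = ok[:, i] & ok[:, j]
            if not np.any(use):
                raise UndefinedDistanceError(
                    f"no usable sites for pair ({gt.samples[i]}, {gt.samples[j]})")
            gi, gj = G[use, i], G[use, j]  # (U, ploidy)
            # mean delta over all ordered allele pairings
            eq = (gi[:, :, None] == gj[:, None, :]).mean(axis=(1, 2))
            d = 1.0 - eq.mean()
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(gt.samples), D)


# ---------------------------------------------------------------------------
# sequence distances
# ---------------------------------------------------------------------------
def _usable_pairs(seq_a: str, seq_b: str):
    if len(seq_a) != len(seq_b):
        raise ValidationError("sequences differ in length")
    pairs = [(a, b) for a, b in zip(seq_a.upper(), seq_b.upper())
             if a in _VALID and b in _VALID]
    if not pairs:
        raise UndefinedDistanceError("no usable (non-N, non-gap) sites")
    return pairs


def jc69_distance(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor corrected distance: d = -(3/4) ln(1 - (4/3) p)."""
    pairs = _usable_pairs(seq_a, seq_b)
    p = sum(a != b for a, b in pairs) / len(pairs)
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        raise SaturatedDistanceError(f"JC69 saturated: p = {p:.4f}")
    return -0.75 * math.log(arg)


def k2p_distance(seq_a: str, seq_b: str) -> tuple[float, float, float]:
    """Kimura 2-parameter distance.

    Returns ``(P, Q, d)`` where P and Q are the transition and transversion
    fractions over usable sites and
    ``d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)``.
    """
    pairs = _usable_pairs(seq_a, seq_b)
    n = len(pairs)
    ts = sum((a, b) in TRANSITIONS for a, b in pairs)
    tv = sum(a != b and (a, b) not in TRANSITIONS for a, b in pairs)
    P, Q = ts / n, tv / n
    a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if a1 <= 0 or a2 <= 0:
        raise SaturatedDistanceError(f"K2P saturated: P = {P:.4f}, Q = {Q:.4f}")
    d = -0.5 * math.log(a1) - 0.25 * math.log(a2)
    return P, Q, d


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------
def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion are broken by the lowest (row, column) index
    pair; negative branch-length estimates are clamped to zero with a
    warning.  The returned tree is unrooted (basal trifurcation).  When the
    input is additive the output path lengths reproduce the input exactly.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    D = dm.matrix.copy()
    nodes: list[Node] = [Node(label) for label in dm.ids]
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn("negative NJ branch length clamped to 0")
            return 0.0
        return x

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (row, col) tie-break via lexicographic argmin
        best = np.unravel_index(np.argmin(Q + 0.0, axis=None), Q.shape)
        qmin = Q[best]
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        ai, aj = min((min(i, j), max(i, j)) for i, j in ties)
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = clamp(0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2)))
        lj = clamp(dij - li)
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distance update
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(active[aj])

    # final three-point join
    i, j, k = active
    root = Node()
    li = clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    lj = clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    lk = clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = ln
        root.add_child(nodes[idx])
    return PhyloTree(root)


def patristic_matrix(tree: PhyloTree, ids: list[str] | None = None) -> DistanceMatrix:
    """Path-length (patristic) distances between all tips; absent branch
    lengths count as zero."""
    tips = tree.tips()
    order = ids or [t.label for t in tips]
    by_label = {t.label: t for t in tips}
    depth: dict[Node, float] = {}
    parent: dict[Node, Node] = {}

    for node in tree.preorder():
        if node is tree.root:
            depth[node] = 0.0
        for child in node.children:
            parent[child] = node
            depth[child] = depth[node] + (child.length or 0.0)

    def path(a: Node, b: Node) -> float:
        anc_a = {}
        cur = a
        while True:
            anc_a[cur] = depth[a] - depth[cur]
            if cur not in parent:
                break
            cur = parent[cur]
        cur = b
        while cur not in anc_a:
            cur = parent[cur]
        return anc_a[cur] + (depth[b] - depth[cur])

    n = len(order)
    M = np.zeros((n, n))
    for x in range(n):
        for y in range(x + 1, n):
            M[x, y] = M[y, x] = path(by_label[order[x]], by_label[order[y]])
    return DistanceMatrix(order, M)
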