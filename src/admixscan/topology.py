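"""Rooted-topology enumeration, exact topology weighting, and per-gene
topology selection.

Topology weighting follows the exact ("complete") scheme: every combination
of one tip per ingroup group (and one outgroup tip used to root) is pruned
out of the tree and the induced rooted ingroup topology is tallied; a
combination whose induced subtree is unresolved — a polytomy created by
collapsing zero-length internal edges — contributes fractional credit
1/(number of compatible resolved topologies) to each compatible topology.

The per-gene test fits JC69 branch lengths on each candidate quartet
topology by Felsenstein pruning and scores topologies with RELL bootstrap
support (resampling per-site log-likelihoods); a topology is selected only
when its support exceeds 0.95, and genes whose topologies are exactly tied
in likelihood are omitted.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ConfigError, ValidationError
from .io import GeneAlignment, GenotypeTable
from .tree import Node, PhyloTree, root_on_outgroup

__all__ = [
    "Topology", "enumerate_rooted_topologies", "window_partition",
    "build_window_tree", "topology_weights", "weight_summary",
    "gene_topology_test", "TopologyWeightRecord", "TopologyTestResult",
]


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------
def _canonical(struct):
    if isinstance(struct, str):
        return struct
    parts = sorted((_canonical(s) for s in struct), key=_struct_key)
    return tuple(parts)


def _struct_key(struct) -> str:
    if isinstance(struct, str):
        return struct
    return "(" + ",".join(_struct_key(s) for s in struct) + ")"


def _clusters(struct, out: set | None = None) -> set:
    """All tip-label clusters of size >= 2 (including the full set)."""
    if out is None:
        out = set()
    if isinstance(struct, str):
        return out
    labels = frozenset(_leaves(struct))
    out.add(labels)
    for s in struct:
        _clusters(s, out)
    return out


def _leaves(struct):
    if isinstance(struct, str):
        yield struct
    else:
        for s in struct:
            yield from _leaves(s)


@dataclass(frozen=True)
class Topology:
    """One rooted, fully resolved ingroup topology (outgroup basal)."""

    index: int
    structure: tuple
    outgroup: str

    @property
    def labels(self) -> frozenset:
        return frozenset(_leaves(self.structure))

    @property
    def clusters(self) -> frozenset:
        """Proper nontrivial clusters (size >= 2, excluding the full set)."""
        full = self.labels
        return frozenset(c for c in _clusters(self.structure) if c != full)

    @property
    def newick(self) -> str:
        return f"({_struct_key(self.structure)},{self.outgroup});"

    def __str__(self) -> str:
        return self.newick


def enumerate_rooted_topologies(group_labels: list[str],
                                outgroup_label: str) -> list[Topology]:
    """All distinct rooted fully-resolved topologies on the ingroup labels.

    For k ingroups the count is (2k-3)!! — 1, 3, 15, 105 for k = 2..5.
    The list is ordered canonically (sorted Newick form) and is stable
    across calls.
    """
    labels = list(group_labels)
    if len(set(labels)) != len(labels) or outgroup_label in labels:
        raise ConfigError("duplicate labels")
    if not 2 <= len(labels) <= 5:
        raise ConfigError("between 2 and 5 ingroup labels supported")

    def insertions(struct, x):
        yield (struct, x)
        if not isinstance(struct, str):
            a, b = struct
            for a2 in insertions(a, x):
                yield (a2, b)
            for b2 in insertions(b, x):
                yield (a, b2)

    trees = [(labels[0], labels[1])]
    for x in labels[2:]:
        trees = [t2 for t in trees for t2 in insertions(t, x)]
    canon = sorted({_canonical(t) for t in trees}, key=_struct_key)
    return [Topology(i, t, outgroup_label) for i, t in enumerate(canon)]


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Window:
    window_id: int
    chrom: str
    start: int  # 1-based position of first site
    end: int  # 1-based position of last site
    site_indices: tuple


def window_partition(sites, n_snps: int = 100) -> list[Window]:
    """Consecutive non-overlapping windows of exactly ``n_snps`` sites,
    never spanning a chromosome boundary; trailing partials are dropped.
    ``sites`` is anything with ``chrom`` and ``pos`` arrays."""
    chrom = np.asarray(sites.chrom, dtype=object)
    pos = np.asarray(sites.pos)
    windows: list[Window] = []
    wid = 0
    for c in sorted(set(chrom.tolist())):
        idx = np.flatnonzero(chrom == c)
        for k in range(len(idx) // n_snps):
            block = idx[k * n_snps:(k + 1) * n_snps]
            windows.append(Window(
                window_id=wid, chrom=str(c),
                start=int(pos[block[0]]), end=int(pos[block[-1]]),
                site_indices=tuple(int(i) for i in block)))
            wid += 1
    return windows


def build_window_tree(gt: GenotypeTable, outgroup_samples: list[str]) -> PhyloTree:
    """NJ tree on allele-sharing distances, rooted on the outgroup branch.

    When every pairwise distance is zero (an invariant window) a star tree
    is returned with a warning.
    """
    from .distance import allele_sharing_distance, neighbor_joining

    if gt.n_samples < 4:
        raise ValidationError("need at least 4 samples (incl. outgroup)")
    if not set(outgroup_samples) <= set(gt.samples):
        raise ValidationError("outgroup samples missing from table")
    dm = allele_sharing_distance(gt)
    if np.allclose(dm.matrix, 0.0):
        warnings.warn("all pairwise distances zero; returning star tree")
        root = Node()
        for s in gt.samples:
            root.add_child(Node(s, 0.0))
        return PhyloTree(root)
    unrooted = neighbor_joining(dm)
    return root_on_outgroup(unrooted, set(outgroup_samples))


# ---------------------------------------------------------------------------
# exact topology weighting
# ---------------------------------------------------------------------------
@dataclass
class TopologyWeightRecord:
    window_id: int
    chrom: str
    start: int
    end: int
    weights: np.ndarray
    n_subsamples: int


def _induced_clusters(adj, chosen: dict[str, Node],
                      outgroup_tip: Node) -> set:
    """Nontrivial resolved clusters (as frozensets of group labels) of the
    tree induced by the chosen tips, rooted at the outgroup tip.

    An internal edge path of total length zero collapses, so the cluster
    below it does not count as resolved.  Absent branch lengths count as
    resolved (length 1).
    """
    bit = {node: 1 << i for i, node in enumerate(chosen.values())}
    groups = list(chosen.keys())
    full = (1 << len(groups)) - 1

    mask_depth: dict[int, float] = {}
    # iterative DFS from the outgroup tip; post-order masks
    stack = [(outgroup_tip, None, 0.0, False)]
    masks: dict[Node, int] = {}
    depth_of: dict[Node, float] = {}
    while stack:
        node, parent, depth, done = stack.pop()
        if done:
            m = bit.get(node, 0)
            for other, _ in adj[node]:
                if other is not parent:
                    m |= masks[other]
            masks[node] = m
            if m:
                prev = mask_depth.get(m)
                if prev is None or depth_of[node] > prev:
                    mask_depth[m] = depth_of[node]
            continue
        depth_of[node] = depth
        stack.append((node, parent, depth, True))
        for other, length in adj[node]:
            if other is not parent:
                ln = 1.0 if length is None else float(length)
                stack.append((other, node, depth + ln, False))

    out = set()
    for m, depth in mask_depth.items():
        size = bin(m).count("1")
        if size < 2 or m == full:
            continue
        # parent = smallest strict superset present
        parent_masks = [pm for pm in mask_depth if pm != m and (pm & m) == m]
        pdepth = max(mask_depth[pm] for pm in parent_masks) if parent_masks else 0.0
        if depth - pdepth > 0:
            out.add(frozenset(groups[i] for i in range(len(groups))
                              if m & (1 << i)))
    return out


def topology_weights(tree: PhyloTree, groups: dict[str, str],
                     topologies: list[Topology]) -> TopologyWeightRecord:
    """Exact weights of each candidate topology in one tree.

    ``groups`` maps tip label -> group name and must cover every tip used;
    tips mapped to the outgroup group are iterated like any other group
    (n_subsamples = product of all group sizes including the outgroup's).
    """
    outgroup = topologies[0].outgroup
    ingroups = sorted(topologies[0].labels)
    tips_by_group: dict[str, list[str]] = {g: [] for g in ingroups + [outgroup]}
    for label, g in groups.items():
        if g in tips_by_group:
            tips_by_group[g].append(label)
    for g, members in tips_by_group.items():
        if not members:
            raise ConfigError(f"group {g!r} has no tips")
        members.sort()

    adj = tree.adjacency()
    tip_node = {t.label: t for t in tree.tips()}
    counts = np.zeros(len(topologies))
    combos = itertools.product(*(tips_by_group[g] for g in ingroups),
                               tips_by_group[outgroup])
    n_total = 0
    for combo in combos:
        n_total += 1
        chosen = {g: tip_node[label] for g, label in zip(ingroups, combo[:-1])}
        og_tip = tip_node[combo[-1]]
        induced = _induced_clusters(adj, chosen, og_tip)
        compatible = [t.index for t in topologies if induced <= t.clusters]
        if not compatible:  # conflicting clusters cannot arise from a tree
            raise RuntimeError("no compatible topology for induced subtree")
        for i in compatible:
            counts[i] += 1.0 / len(compatible)
    weights = counts / n_total
    return TopologyWeightRecord(
        window_id=-1, chrom="", start=0, end=0,
        weights=weights, n_subsamples=n_total)


def weight_summary(records: list[TopologyWeightRecord], n_boot: int = 1000,
                   seed: int = 0):
    """Genome-wide per-topology weights with 95% percentile bootstrap CIs.

    Windows are resampled with replacement; totals are normalized to sum
    to 1.  Returns ``(totals, lo, hi)`` arrays over topologies.
    """
    if len(records) < 2:
        raise ValidationError("need at least 2 windows")
    W = np.stack([r.weights for r in records])  # (n_windows, n_topo)
    totals = W.sum(axis=0)
    totals = totals / totals.sum()
    rng = np.random.default_rng(seed)
    n = W.shape[0]
    boots = np.empty((n_boot, W.shape[1]))
    for b in range(n_boot):
        pick = rng.integers(0, n, size=n)
        t = W[pick].sum(axis=0)
        boots[b] = t / t.sum()
    lo = np.percentile(boots, 2.5, axis=0)
    hi = np.percentile(boots, 97.5, axis=0)
    return totals, lo, hi


# ---------------------------------------------------------------------------
# per-gene topology selection (JC69 likelihood + RELL support)
# ---------------------------------------------------------------------------
@dataclass
class TopologyTestResult:
    gene_id: str
    topologies: list[Topology]
    loglik: np.ndarray | None
    support: np.ndarray | None
    selected: int | None
    omitted: bool
    reason: str | None = None


def _jc69_p(t: float) -> np.ndarray:
    e = np.exp(-4.0 * t / 3.0)
    p_diff = 0.25 - 0.25 * e
    P = np.full((4, 4), p_diff)
    np.fill_diagonal(P, 0.25 + 0.75 * e)
    return P


def _site_logliks(pattern_bases: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Per-pattern log-likelihood of an unrooted quartet (a,b)|(c,d).

    ``pattern_bases`` is (4, n_pat) with rows in (a, b, c, d) order and -1
    for missing; ``lengths`` = (ta, tb, tc, td, t_internal).
    """
    n_pat = pattern_bases.shape[1]
    partials = []
    for row, t in zip(pattern_bases, lengths[:4]):
        P = _jc69_p(t)  # (anc, tip)
        L = np.ones((4, n_pat))
        obs = row >= 0
        L[:, obs] = P[:, row[obs]]
        partials.append(L)
    left = partials[0] * partials[1]  # (4, n_pat) indexed by left-node state
    right = partials[2] * partials[3]
    Pe = _jc69_p(lengths[4])
    lik = 0.25 * np.einsum("ip,ij,jp->p", left, Pe, right)
    return np.log(np.maximum(lik, 1e-300))


def _fit_quartet(pattern_bases: np.ndarray, counts: np.ndarray,
                 tol: float = 1e-6, max_sweeps: int = 60):
    """Coordinate-ascent JC69 branch-length fit; returns (lengths, per-site
    loglik vector, total loglik)."""
    lengths = np.full(5, 0.1)

    def total(ls):
        return float(counts @ _site_logliks(pattern_bases, ls))

    cur = total(lengths)
    for _ in range(max_sweeps):
        prev = cur
        for i in range(5):
            def neg(t, i=i):
                ls = lengths.copy()
                ls[i] = t
                return -total(ls)

            res = minimize_scalar(neg, bounds=(0.0, 10.0), method="bounded",
                                  options={"xatol": 1e-8})
            if -res.fun > cur:
                lengths[i] = float(res.x)
                cur = -res.fun
        if cur - prev < tol:
            break
    site_ll = _site_logliks(pattern_bases, lengths)
    return lengths, site_ll, cur


def gene_topology_test(aln: GeneAlignment, roles: dict[str, str],
                       n_rell: int = 10_000, seed: int = 0,
                       gene_id: str = "gene",
                       support_threshold: float = 0.95) -> TopologyTestResult:
    """Which of the three rooted topologies ((Pi,Pj),Pk),O fits a gene?

    Branch lengths are optimized per topology under JC69; support is the
    RELL bootstrap win proportion over ``n_rell`` site resamples; a topology
    is selected only when its support exceeds ``support_threshold``.  Genes
    where the three likelihoods are exactly tied (difference < 1e-9) are
    omitted, as are genes with no usable sites.
    """
    by_role = {}
    for name, role in roles.items():
        by_role[role] = name
    if set(by_role) != {"P1", "P2", "P3", "O"}:
        raise ConfigError("roles must assign exactly P1, P2, P3, O")
    topologies = enumerate_rooted_topologies(["P1", "P2", "P3"], "O")

    rows = np.stack([aln.codes[aln.names.index(by_role[r])]
                     for r in ("P1", "P2", "P3", "O")])  # (4, L)
    usable = np.any(rows >= 0, axis=0)
    rows = rows[:, usable]
    if rows.shape[1] == 0:
        return TopologyTestResult(gene_id, topologies, None, None, None,
                                  omitted=True, reason="no_signal")
    patterns, counts = np.unique(rows, axis=1, return_counts=True)
    counts = counts.astype(float)

    # map each rooted topology to its unrooted quartet row order:
    # ((Pi,Pj),Pk),O  <->  (Pi,Pj) | (Pk,O)
    role_row = {"P1": 0, "P2": 1, "P3": 2, "O": 3}
    site_lls = []
    totals = []
    for topo in topologies:
        (pair,) = [c for c in topo.clusters]
        pi, pj = sorted(pair)
        pk = next(iter({"P1", "P2", "P3"} - pair))
        order = (role_row[pi], role_row[pj], role_row[pk], 3)
        _, site_ll, tot = _fit_quartet(patterns[list(order)], counts)
        site_lls.append(site_ll)
        totals.append(tot)
    totals = np.array(totals)
    if totals.max() - totals.min() < 1e-9:
        return TopologyTestResult(gene_id, topologies, totals, None, None,
                                  omitted=True, reason="zero_likelihood_difference")

    rng = np.random.default_rng(seed)
    n_sites = counts.sum()
    probs = counts / n_sites
    resampled = rng.multinomial(int(n_sites), probs, size=n_rell)  # (B, n_pat)
    boot_ll = resampled @ np.stack(site_lls).T  # (B, 3)
    best = boot_ll.max(axis=1, keepdims=True)
    wins = boot_ll >= best - 1e-12
    support = (wins / wins.sum(axis=1, keepdims=True)).mean(axis=0)
    selected = int(np.argmax(support)) if support.max() > support_threshold else None
    return TopologyTestResult(gene_id, topologies, totals, support, selected,
                              omitted=False)
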