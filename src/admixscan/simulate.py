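"""Synthetic data with known truth for every pipeline stage.

The centerpiece is an exact structured coalescent for a four-taxon species
tree (((P1,P2)t1,P3)t2,O)t3 with a single backward-in-time introgression
pulse: at time tm (< t1) the P2 lineage is reassigned to the P3 population
with probability gamma.  Within each population interval, coalescence waits
are exponential with rate k(k-1)/2 for k resident lineages.  One mutation
per locus is placed uniformly on the genealogy's total branch length
(infinite sites), so each locus yields exactly one polarized biallelic
pattern; loci whose mutation lands on the outgroup's pendant branch are
emitted with O = 1 and all ingroup taxa 0.

All generators take an explicit seed and draw from a private
``numpy.random.Generator``; identical configurations are bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ValidationError
from .io import BASES, GeneAlignment, GeneInterval
from .tree import PhyloTree

__all__ = [
    "AdmixtureSimConfig", "SeqSimConfig", "LTRPair",
    "simulate_admixture_sites", "simulate_sequences_on_tree",
    "simulate_ltr_pair", "simulate_depth_tracks", "simulate_sv_callsets",
    "simulate_window_trees", "alignment_to_genotypes",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class AdmixtureSimConfig:
    """Species-tree times (coalescent units of 2N generations), pulse
    parameters, locus count and seed for the site-pattern simulator."""

    t1: float
    t2: float
    t3: float
    tm: float
    gamma: float
    n_loci: int
    seed: int
    spacing_bp: int = 2000  # distance between consecutive loci on the chromosome

    def __post_init__(self):
        if not (0.0 < self.tm < self.t1 < self.t2 < self.t3):
            raise ConfigError(
                f"need 0 < tm < t1 < t2 < t3, got tm={self.tm}, t1={self.t1}, "
                f"t2={self.t2}, t3={self.t3}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ConfigError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.n_loci < 1:
            raise ConfigError("n_loci must be >= 1")
        if self.spacing_bp < 1:
            raise ConfigError("spacing_bp must be >= 1")


@dataclass(frozen=True)
class SeqSimConfig:
    """Continuous-time sequence evolution along a tree with branch lengths
    in expected substitutions per site."""

    tree: PhyloTree
    length: int
    model: str = "JC69"
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.model not in {"JC69", "K2P"}:
            raise ConfigError(f"model must be JC69 or K2P, got {self.model}")
        if self.length < 1:
            raise ConfigError("length must be >= 1")
        if self.model == "K2P" and self.kappa <= 0:
            raise ConfigError("kappa must be > 0")
        for node in self.tree.preorder():
            if node.length is not None and node.length < 0:
                raise ConfigError("negative branch length")


@dataclass
class LTRPair:
    """Two LTR copies of one element plus the truth used to generate them."""

    element_id: str
    ltr5: str
    ltr3: str
    true_age_years: float


# ---------------------------------------------------------------------------
# four-taxon structured coalescent with one introgression pulse
# ---------------------------------------------------------------------------
def simulate_admixture_sites(cfg: AdmixtureSimConfig):
    """Simulate one polarized biallelic site per locus.

    Returns a :class:`~admixscan.dstat.PolarizedSiteTable` with taxa in
    (P1, P2, P3, O) order on a single synthetic chromosome, positions
    ``1, 1 + spacing, 1 + 2*spacing, ...`` so block-jackknife binning is
    exercised downstream.

    The genealogy per locus is encoded as three merge events over tip
    bitmasks (P1=1, P2=2, P3=4, O=8); everything is vectorized over loci.
    """
    from .dstat import PolarizedSiteTable

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_loci
    t1, t2, t3, tm, g = cfg.t1, cfg.t2, cfg.t3, cfg.tm, cfg.gamma

    # all randomness drawn with fixed shapes up front: reproducible and
    # independent of which branch each locus takes
    mig = rng.random(n) < g
    e_p1 = rng.exponential(size=n)
    e_p2 = rng.exponential(size=n)
    e_p3a = rng.exponential(size=n)
    r3 = rng.integers(0, 3, size=n)
    e_p3b = rng.exponential(size=n)
    e_p4a = rng.exponential(size=n)
    r6 = rng.integers(0, 6, size=n)
    e_p4b = rng.exponential(size=n)
    r3b = rng.integers(0, 3, size=n)
    r3c = rng.integers(0, 3, size=n)
    e_p4c = rng.exponential(size=n)
    u_mut = rng.random(n)

    e1_clade = np.zeros(n, np.int8)
    e1_time = np.zeros(n)
    e2_clade = np.zeros(n, np.int8)
    e2_time = np.zeros(n)
    root_time = np.zeros(n)

    # interval (tm, t1): P2 lineage migrated into P3 may coalesce with P3
    t_bc1 = tm + e_p1
    occ1 = mig & (t_bc1 < t1)
    # interval (t1, t2): either (P1,P2) in the merged population, or the
    # migrated P2 still with P3
    t_e2 = t1 + e_p2
    occ_ab = (~mig) & (t_e2 < t2)
    occ_bc2 = mig & ~occ1 & (t_e2 < t2)
    e1_clade[occ1] = 6
    e1_time[occ1] = t_bc1[occ1]
    e1_clade[occ_bc2] = 6
    e1_time[occ_bc2] = t_e2[occ_bc2]
    e1_clade[occ_ab] = 3
    e1_time[occ_ab] = t_e2[occ_ab]

    # interval (t2, t3): all ingroup lineages share one population
    have1 = e1_clade != 0
    k3 = ~have1  # three lineages, rate 3
    tA = t2 + e_p3a / 3.0
    occA = k3 & (tA < t3)
    first_pair = np.array([3, 5, 6], np.int8)  # (P1,P2), (P1,P3), (P2,P3)
    e1_clade[occA] = first_pair[r3[occA]]
    e1_time[occA] = tA[occA]
    tB = tA + e_p3b
    occB = occA & (tB < t3)
    e2_clade[occB] = 7
    e2_time[occB] = tB[occB]
    k2 = have1  # two lineages, rate 1 (reuse of e_p3a is valid: disjoint loci)
    tC = t2 + e_p3a
    occC = k2 & (tC < t3)
    e2_clade[occC] = 7
    e2_time[occC] = tC[occC]

    # beyond t3: the outgroup lineage joins
    have1 = e1_clade != 0
    have2 = e2_clade != 0
    ne2 = have1 & have2
    root_time[ne2] = t3 + e_p4a[ne2]
    ne1 = have1 & ~have2  # lineages: e1 clade, its ingroup complement, O
    tD = t3 + e_p4a / 3.0
    comp = (7 ^ e1_clade).astype(np.int8)
    u0 = np.where(r3b == 0, 7,
                  np.where(r3b == 1, e1_clade | 8, comp | 8)).astype(np.int8)
    e2_clade[ne1] = u0[ne1]
    e2_time[ne1] = tD[ne1]
    root_time[ne1] = tD[ne1] + e_p4b[ne1]
    ne0 = ~have1 & ~have2  # four free lineages
    tE = t3 + e_p4a / 6.0
    six_pairs = np.array([3, 5, 9, 6, 10, 12], np.int8)
    c1 = six_pairs[r6]
    e1_clade[ne0] = c1[ne0]
    e1_time[ne0] = tE[ne0]
    rem = (15 ^ c1).astype(np.int8)
    s1 = (rem & (-rem)).astype(np.int8)
    s2 = (rem ^ s1).astype(np.int8)
    second = np.where(r3c == 0, c1 | s1,
                      np.where(r3c == 1, c1 | s2, s1 | s2)).astype(np.int8)
    tF = tE + e_p4b / 3.0
    e2_clade[ne0] = second[ne0]
    e2_time[ne0] = tF[ne0]
    root_time[ne0] = tF[ne0] + e_p4c[ne0]

    # branch lengths: four pendant branches plus the two internal nodes
    tip_bits = np.array([1, 2, 4, 8], np.int8)
    in_e1 = (e1_clade[:, None] & tip_bits[None, :]) != 0
    in_e2 = (e2_clade[:, None] & tip_bits[None, :]) != 0
    tip_parent = np.where(in_e1, e1_time[:, None],
                          np.where(in_e2, e2_time[:, None], root_time[:, None]))
    e1_in_e2 = (e1_clade & e2_clade) == e1_clade
    e1_parent = np.where(e1_in_e2, e2_time, root_time)
    branches = np.concatenate(
        [tip_parent,
         (e1_parent - e1_time)[:, None],
         (root_time - e2_time)[:, None]], axis=1)  # (n, 6)
    clades = np.concatenate(
        [np.broadcast_to(tip_bits, (n, 4)),
         e1_clade[:, None], e2_clade[:, None]], axis=1)  # (n, 6)

    total = branches.sum(axis=1)
    cut = u_mut * total
    cum = np.cumsum(branches, axis=1)
    idx = np.argmax(cum >= cut[:, None], axis=1)
    derived = clades[np.arange(n), idx]
    codes = ((derived[:, None] >> np.arange(4)[None, :]) & 1).astype(np.int8)

    pos = 1 + np.arange(n, dtype=np.int64) * cfg.spacing_bp
    return PolarizedSiteTable(
        chrom=np.array(["chr1"] * n, dtype=object),
        pos=pos,
        codes=codes,
    )


# ---------------------------------------------------------------------------
# sequence evolution on a tree
# ---------------------------------------------------------------------------
def _k2p_probs(d: float, kappa: float) -> np.ndarray:
    """K2P transition matrix for branch length d (expected subs/site) with
    transition/transversion rate ratio kappa; kappa = 1 gives JC69."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (alpha + beta) * d)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    p_same = 1.0 - p_ts - 2.0 * p_tv
    # base order A, C, G, T; transitions are A<->G and C<->T
    P = np.full((4, 4), 0.0)
    for i in range(4):
        for j in range(4):
            if i == j:
                P[i, j] = p_same
            elif {i, j} in ({0, 2}, {1, 3}):
                P[i, j] = p_ts
            else:
                P[i, j] = p_tv
    return P


def _evolve(codes: np.ndarray, d: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    if d == 0:
        return codes.copy()
    P = _k2p_probs(d, kappa)
    cum = np.cumsum(P, axis=1)
    u = rng.random(codes.shape[0])
    return (cum[codes] < u[:, None]).sum(axis=1).astype(np.int8)


def simulate_sequences_on_tree(cfg: SeqSimConfig) -> GeneAlignment:
    """Evolve sequences root-to-tips under JC69 or K2P.

    The root sequence is uniform over {A,C,G,T}; rows follow the tree's tip
    label order.  Branches with absent lengths are treated as zero.
    """
    rng = np.random.default_rng(cfg.seed)
    kappa = 1.0 if cfg.model == "JC69" else cfg.kappa
    root_seq = rng.integers(0, 4, size=cfg.length).astype(np.int8)
    seqs: dict[str, np.ndarray] = {}

    def rec(node, seq):
        if node.is_leaf:
            seqs[node.label] = seq
            return
        for child in node.children:
            rec(child, _evolve(seq, child.length or 0.0, kappa, rng))

    rec(cfg.tree.root, root_seq)
    names = cfg.tree.tip_labels
    return GeneAlignment(names, np.stack([seqs[n] for n in names]))


# ---------------------------------------------------------------------------
# LTR pairs of known age
# ---------------------------------------------------------------------------
def simulate_ltr_pair(age_years: float, rate: float, length: int,
                      kappa: float = 2.0, seed: int = 0,
                      element_id: str = "ltr1") -> LTRPair:
    """Generate a 5'/3' LTR pair that diverged for ``age_years``.

    Each copy accumulates ``age_years * rate`` expected substitutions per
    site under K2P starting from a uniform ancestral LTR, mirroring the
    neutral divergence of the two initially identical terminal repeats.
    """
    if rate <= 0:
        raise ConfigError("rate must be > 0")
    if length < 100:
        raise ConfigError("length must be >= 100")
    if age_years < 0:
        raise ConfigError("age_years must be >= 0")
    rng = np.random.default_rng(seed)
    anc = rng.integers(0, 4, size=length).astype(np.int8)
    d = age_years * rate
    c5 = _evolve(anc, d, kappa, rng)
    c3 = _evolve(anc, d, kappa, rng)
    to_str = lambda c: "".join(BASES[x] for x in c)
    return LTRPair(element_id, to_str(c5), to_str(c3), age_years)


# ---------------------------------------------------------------------------
# depth tracks with deleted genes
# ---------------------------------------------------------------------------
def simulate_depth_tracks(genes: list[GeneInterval],
                          deleted: dict[str, set[str]],
                          mean_depth: float, seed: int = 0,
                          chrom_lengths: dict[str, int] | None = None):
    """Per-position Poisson(mean_depth) tracks, exactly zero inside each
    sample's deleted genes.  Returns ``{sample: DepthTrack}``."""
    from .coverage import DepthTrack

    by_id = {g.gene_id: g for g in genes}
    for sample, ids in deleted.items():
        unknown = set(ids) - set(by_id)
        if unknown:
            raise ValidationError(
                f"deleted gene ids not in gene list for {sample}: {sorted(unknown)}")
    if chrom_lengths is None:
        chrom_lengths = {}
        for g in genes:
            chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), g.end + 100)
    rng = np.random.default_rng(seed)
    tracks = {}
    for sample in sorted(deleted):
        depths = {c: rng.poisson(mean_depth, size=n).astype(np.float64)
                  for c, n in sorted(chrom_lengths.items())}
        for gid in sorted(deleted[sample]):
            g = by_id[gid]
            depths[g.chrom][g.start:g.end] = 0.0
        tracks[sample] = DepthTrack(sample=sample, depths=depths)
    return tracks


# ---------------------------------------------------------------------------
# dual-caller SV observations of a known PAV truth set
# ---------------------------------------------------------------------------
def simulate_sv_callsets(true_pavs, jitter_sd: float, fp_per_caller: int,
                         seed: int = 0, chrom_lengths: dict[str, int] | None = None):
    """Observe a non-overlapping PAV truth set through two noisy callers.

    Caller A mimics an assembly-based caller (point breakpoints, Gaussian
    jitter rounded to integers and truncated at +/-3 sd, so a 500-bp pad
    always covers sd <= 166); caller B mimics a read-based caller with the
    same jitter plus a read-support count >= 1.  Each call set gains
    ``fp_per_caller`` uniform false calls disjoint from the truth set.
    Returns ``(callset_a, callset_b)``.
    """
    from .sv import SVCall

    pavs = sorted(true_pavs, key=lambda c: (c.chrom, c.start))
    for a, b in zip(pavs, pavs[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValidationError("true PAVs must be non-overlapping")
    if chrom_lengths is None:
        chrom_lengths = {}
        for c in pavs:
            chrom_lengths[c.chrom] = max(chrom_lengths.get(c.chrom, 0),
                                         c.end + 200_000)
    rng = np.random.default_rng(seed)

    def jitter():
        if jitter_sd == 0:
            return 0
        j = rng.normal(0.0, jitter_sd)
        cap = 3.0 * jitter_sd
        return int(round(max(-cap, min(cap, j))))

    callset_a, callset_b = [], []
    for i, t in enumerate(pavs):
        js, je = jitter(), jitter()
        start_a = max(0, t.start + js)
        end_a = max(start_a + 1, t.end + je)
        callset_a.append(SVCall(
            chrom=t.chrom, start=start_a, end=end_a, svtype=t.svtype,
            size=end_a - start_a, source="assembly", breakpoint="point",
            call_id=f"a_true{i}"))
        js, je = jitter(), jitter()
        start_b = max(0, t.start + js)
        end_b = max(start_b + 1, t.end + je)
        callset_b.append(SVCall(
            chrom=t.chrom, start=start_b, end=end_b, svtype=t.svtype,
            size=end_b - start_b, read_support=int(1 + rng.poisson(19.0)),
            source="read", breakpoint="interval", call_id=f"b_true{i}"))

    def truth_overlap(chrom, start, end):
        return any(t.chrom == chrom and start < t.end + 1000 and t.start - 1000 < end
                   for t in pavs)

    for name, callset, source, bp in (("a", callset_a, "assembly", "point"),
                                      ("b", callset_b, "read", "interval")):
        placed = 0
        while placed < fp_per_caller:
            chrom = sorted(chrom_lengths)[int(rng.integers(0, len(chrom_lengths)))]
            size = int(rng.integers(50, 5000))
            start = int(rng.integers(0, max(1, chrom_lengths[chrom] - size)))
            if truth_overlap(chrom, start, start + size):
                continue
            callset.append(SVCall(
                chrom=chrom, start=start, end=start + size, svtype="deletion",
                size=size,
                read_support=None if source == "assembly" else int(1 + rng.poisson(19.0)),
                source=source, breakpoint=bp, call_id=f"{name}_fp{placed}"))
            placed += 1
    key = lambda c: (c.chrom, c.start, c.end)
    return sorted(callset_a, key=key), sorted(callset_b, key=key)


# ---------------------------------------------------------------------------
# multi-sample window genealogies (for topology weighting)
# ---------------------------------------------------------------------------
def simulate_window_trees(n_windows: int, tips_per_group: int,
                          t1: float, t2: float, t3: float,
                          gamma: float = 0.0, tm: float = 0.5,
                          seed: int = 0,
                          group_names: tuple[str, str, str, str] =
                          ("P1", "P2", "P3", "O")) -> list[PhyloTree]:
    """Independent coalescent genealogies with several tips per population.

    Uses msprime under the same species-tree-plus-pulse model as
    :func:`simulate_admixture_sites` (times in units of 2N generations,
    converted to msprime's scale internally).  Tips are labeled
    ``<group>_<i>``; the single outgroup population contributes
    ``tips_per_group`` tips as well.  Returns rooted trees.
    """
    import msprime

    p1, p2, p3, og = group_names
    demography = msprime.Demography()
    for name in (p1, p2, p3, og):
        demography.add_population(name=name, initial_size=1.0)
    demography.add_population(name="A12", initial_size=1.0)
    demography.add_population(name="A123", initial_size=1.0)
    demography.add_population(name="ROOT", initial_size=1.0)
    # with ploidy 1 and size 1 the pairwise coalescence rate is 1 per
    # generation, so msprime time equals coalescent units directly
    if gamma > 0:
        demography.add_mass_migration(time=tm, source=p2, dest=p3,
                                      proportion=gamma)
    demography.add_population_split(time=t1, derived=[p1, p2], ancestral="A12")
    demography.add_population_split(time=t2, derived=["A12", p3],
                                    ancestral="A123")
    demography.add_population_split(time=t3, derived=["A123", og],
                                    ancestral="ROOT")
    demography.sort_events()
    reps = msprime.sim_ancestry(
        samples={p1: tips_per_group, p2: tips_per_group,
                 p3: tips_per_group, og: tips_per_group},
        demography=demography, ploidy=1,
        num_replicates=n_windows, random_seed=max(1, seed % (2 ** 31 - 1)))
    from .tree import read_newick as _rn

    trees = []
    for ts in reps:
        labels = {}
        counts: dict[str, int] = {}
        for node in ts.samples():
            pop = ts.node(node).population
            name = ts.population(pop).metadata.get("name", str(pop))
            k = counts.get(name, 0)
            counts[name] = k + 1
            labels[node] = f"{name}_{k}"
        trees.append(_rn(ts.first().as_newick(node_labels=labels)))
    return trees


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------
def alignment_to_genotypes(aln: GeneAlignment, chrom: str = "chr1",
                           spacing_bp: int = 1, polymorphic_only: bool = True):
    """Convert a haploid alignment into a ploidy-1 GenotypeTable.

    Columns become sites (1-based positions at the given spacing); the first
    observed base is REF, remaining observed bases are ALTs; -1 codes stay
    missing.
    """
    from .io import GenotypeTable

    cols = []
    for j in range(aln.length):
        col = aln.codes[:, j]
        obs = sorted({int(c) for c in col if c >= 0})
        if polymorphic_only and len(obs) < 2:
            continue
        if not obs:
            continue
        cols.append((j, obs))
    chroms, pos, ref, alts, gts = [], [], [], [], []
    for rank, (j, obs) in enumerate(cols):
        remap = {b: i for i, b in enumerate(obs)}
        col = aln.codes[:, j]
        g = np.array([[remap.get(int(c), -1)] for c in col], dtype=np.int8)
        chroms.append(chrom)
        pos.append(1 + rank * spacing_bp)
        ref.append(BASES[obs[0]])
        alts.append(tuple(BASES[b] for b in obs[1:]))
        gts.append(g)
    genotypes = (np.stack(gts) if gts
                 else np.zeros((0, len(aln.names), 1), dtype=np.int8))
    return GenotypeTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=ref, alts=alts, genotypes=genotypes, samples=list(aln.names))
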