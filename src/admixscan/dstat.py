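"""Patterson's D (ABBA-BABA) with a weighted block jackknife.

Sites are polarized against an outgroup (ancestral = 0, derived = 1) for a
(P1, P2, P3, O) quartet.  ABBA sites carry the derived allele in P2 and P3,
BABA in P1 and P3; D = (nABBA - nBABA) / (nABBA + nBABA).  The standard
error comes from a delete-one weighted block jackknife over contiguous
genomic bins (default 100 kb), with block weights equal to the number of
informative (ABBA or BABA) sites, and significance is declared at |z| > 3.9
(p < 1e-4, two-sided normal).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, UndefinedStatisticError
from .io import GenotypeTable

ROLES = ("P1", "P2", "P3", "O")
Z_THRESHOLD = 3.9


@dataclass
class PolarizedSiteTable:
    """Biallelic sites coded 0 (outgroup/ancestral) or 1 (derived) for taxa
    in (P1, P2, P3, O) order."""

    chrom: np.ndarray  # (S,) str
    pos: np.ndarray  # (S,) int, 1-based
    codes: np.ndarray  # (S, 4) int8

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[1] != 4:
            raise ConfigError("codes must have shape (n_sites, 4)")

    @property
    def n_sites(self) -> int:
        return self.codes.shape[0]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "chrom": self.chrom, "pos": self.pos,
            "P1": self.codes[:, 0], "P2": self.codes[:, 1],
            "P3": self.codes[:, 2], "O": self.codes[:, 3]})


@dataclass
class BlockCounts:
    block_id: int
    chrom: str
    start: int  # 1-based inclusive bin start
    end: int  # inclusive bin end
    n_abba: int
    n_baba: int

    @property
    def informative(self) -> int:
        return self.n_abba + self.n_baba


@dataclass
class DStatResult:
    d: float
    se: float
    z: float
    n_abba_total: int
    n_baba_total: int
    n_blocks_used: int
    significant: bool
    degenerate_variance: bool = False


def polarize(gt: GenotypeTable, roles: dict[str, str]) -> tuple[
        PolarizedSiteTable, dict[str, int]]:
    """Polarize genotypes for the four taxa named in ``roles``.

    ``roles`` maps sample name -> one of P1/P2/P3/O, with exactly one
    outgroup.  Sites are kept only when biallelic across the quartet with
    the outgroup called and unambiguous; heterozygous diploid calls are
    treated as missing (the counting mode is binary, matching whole-genome
    assemblies used as taxa).  Returns the table plus per-reason drop
    counts.
    """
    by_role = {}
    for sample, role in roles.items():
        if role not in ROLES:
            raise ConfigError(f"unknown role {role!r}")
        if role in by_role:
            raise ConfigError(f"role {role} assigned twice")
        by_role[role] = sample
    if set(by_role) != set(ROLES):
        missing = set(ROLES) - set(by_role)
        raise ConfigError(f"missing role assignment: {sorted(missing)}")
    idx = [gt.samples.index(by_role[r]) for r in ROLES]

    G = gt.genotypes[:, idx, :]  # (S, 4, ploidy)
    S = G.shape[0]
    # haploid allele per taxon; heterozygous or missing -> -1
    first = G[:, :, 0]
    hom = np.all(G == first[:, :, None], axis=2) & (first >= 0)
    allele = np.where(hom, first, -1).astype(np.int16)

    reasons = {"outgroup_missing": 0, "missing": 0, "multiallelic": 0,
               "monomorphic": 0, "heterozygous": 0}
    keep = np.zeros(S, dtype=bool)
    codes = np.zeros((S, 4), dtype=np.int8)
    het = ~np.all(G == first[:, :, None], axis=2)
    for s in range(S):
        a = allele[s]
        if a[3] < 0:
            reasons["outgroup_missing"] += 1
            continue
        if np.any(a < 0):
            if np.any(het[s, :3]):
                reasons["heterozygous"] += 1
            else:
                reasons["missing"] += 1
            continue
        obs = set(int(x) for x in a)
        if len(obs) == 1:
            reasons["monomorphic"] += 1
            continue
        if len(obs) > 2:
            reasons["multiallelic"] += 1
            continue
        keep[s] = True
        codes[s] = (a != a[3]).astype(np.int8)
    table = PolarizedSiteTable(
        chrom=np.asarray(gt.chrom, dtype=object)[keep],
        pos=np.asarray(gt.pos)[keep],
        codes=codes[keep])
    return table, reasons


def _classify(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of ABBA (0,1,1,0) and BABA (1,0,1,0) sites."""
    c = codes
    abba = (c[:, 0] == 0) & (c[:, 1] == 1) & (c[:, 2] == 1) & (c[:, 3] == 0)
    baba = (c[:, 0] == 1) & (c[:, 1] == 0) & (c[:, 2] == 1) & (c[:, 3] == 0)
    return abba, baba


def count_patterns(sites: PolarizedSiteTable,
                   block_bp: int = 100_000) -> list[BlockCounts]:
    """Count ABBA and BABA sites per contiguous ``block_bp`` bin.

    Bins tile each chromosome from position 1; all other site patterns are
    ignored.  Bins with no sites at all are not emitted (they carry no
    information for the jackknife).
    """
    if sites.n_sites == 0:
        return []
    abba, baba = _classify(sites.codes)
    blocks: list[BlockCounts] = []
    block_id = 0
    for chrom in sorted(set(sites.chrom.tolist())):
        mask = sites.chrom == chrom
        pos = sites.pos[mask]
        ab, ba = abba[mask], baba[mask]
        bins = (pos - 1) // block_bp
        for b in np.unique(bins):
            inbin = bins == b
            blocks.append(BlockCounts(
                block_id=block_id, chrom=str(chrom),
                start=int(b) * block_bp + 1, end=(int(b) + 1) * block_bp,
                n_abba=int(ab[inbin].sum()), n_baba=int(ba[inbin].sum())))
            block_id += 1
    return blocks


def _pooled_d(n_abba: int, n_baba: int) -> float:
    if n_abba + n_baba == 0:
        raise UndefinedStatisticError("no informative (ABBA/BABA) sites")
    return (n_abba - n_baba) / (n_abba + n_baba)


def d_statistic(blocks: list[BlockCounts],
                z_threshold: float = Z_THRESHOLD) -> DStatResult:
    """Pooled-count D with delete-one weighted block jackknife SE.

    Blocks with zero informative sites are excluded.  The variance follows
    the weighted delete-m_j jackknife (Busing et al. 1999) with block
    weights m_j = informative sites per block, the convention standard for
    genome-scale D.  When every leave-one-out estimate coincides the SE is
    reported as 0 with a degenerate-variance warning.
    """
    used = [b for b in blocks if b.informative > 0]
    if len(used) < 2:
        raise UndefinedStatisticError(
            "need at least 2 blocks with informative sites")
    n_abba = sum(b.n_abba for b in used)
    n_baba = sum(b.n_baba for b in used)
    d = _pooled_d(n_abba, n_baba)

    m = np.array([b.informative for b in used], dtype=float)
    n = m.sum()
    g = len(used)
    loo = np.array([_pooled_d(n_abba - b.n_abba, n_baba - b.n_baba)
                    for b in used])
    h = n / m
    theta_j = g * d - np.sum((1.0 - m / n) * loo)
    var = np.sum((h * d - (h - 1.0) * loo - theta_j) ** 2 / (h - 1.0)) / g
    degenerate = bool(np.allclose(loo, loo[0], rtol=0, atol=0))
    if degenerate:
        warnings.warn("all leave-one-out D estimates identical; SE = 0")
        se = 0.0
    else:
        se = math.sqrt(max(var, 0.0))
    if se > 0:
        z = d / se
    else:
        z = 0.0 if d == 0 else math.copysign(math.inf, d)
    return DStatResult(
        d=d, se=se, z=z, n_abba_total=n_abba, n_baba_total=n_baba,
        n_blocks_used=g, significant=bool(abs(z) > z_threshold),
        degenerate_variance=degenerate)


def dstat_per_chromosome(sites: PolarizedSiteTable, block_bp: int = 100_000,
                         z_threshold: float = Z_THRESHOLD):
    """Genome-wide and per-chromosome D.

    Returns ``(genome_result, per_chrom)`` where ``per_chrom`` maps
    chromosome -> DStatResult or None when fewer than two informative
    blocks are available there.
    """
    blocks = count_patterns(sites, block_bp)
    genome = d_statistic(blocks, z_threshold)
    per_chrom: dict[str, DStatResult | None] = {}
    for chrom in sorted(set(b.chrom for b in blocks)):
        sub = [b for b in blocks if b.chrom == chrom]
        try:
            per_chrom[chrom] = d_statistic(sub, z_threshold)
        except UndefinedStatisticError:
            per_chrom[chrom] = None
    return genome, per_chrom
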