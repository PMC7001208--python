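"""Population-genotype filtering and window pruning.

Filters applied in order: (1) SNPs within 5 bp of an indel on the same
chromosome (boundary inclusive), (2) sites missing in more than 20% of
samples, (3) sites heterozygous in more than 5% of samples — "more than"
read strictly, so sites exactly at a threshold survive.  Pruning draws one
site uniformly at random per non-empty 200-kb bin anchored at position 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .io import GenotypeTable


@dataclass(frozen=True)
class FilterConfig:
    indel_flank_bp: int = 5
    max_missing_fraction: float = 0.20
    max_het_fraction: float = 0.05
    prune_window_bp: int = 200_000
    seed: int = 0

    def __post_init__(self):
        if self.indel_flank_bp < 0:
            raise ConfigError("indel_flank_bp must be >= 0")
        for name in ("max_missing_fraction", "max_het_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.prune_window_bp < 1:
            raise ConfigError("prune_window_bp must be >= 1")


def apply_population_filters(gt: GenotypeTable,
                             cfg: FilterConfig = FilterConfig()) -> tuple[
        GenotypeTable, dict[str, int]]:
    """Apply the three site filters; returns the surviving table plus an
    audit count of sites removed by each rule (applied in order, so each
    site is charged to the first rule that removes it)."""
    gt.validate_sorted()
    S = gt.n_sites
    keep = np.ones(S, dtype=bool)
    counts = {"snp_near_indel": 0, "missing": 0, "heterozygous": 0}

    # rule 1: SNPs within the flank of any indel on the same chromosome
    flank = cfg.indel_flank_bp
    for chrom in np.unique(gt.chrom):
        on = gt.chrom == chrom
        indel_pos = gt.pos[on & gt.is_indel]
        if len(indel_pos) == 0:
            continue
        snp_idx = np.flatnonzero(on & ~gt.is_indel)
        if len(snp_idx) == 0:
            continue
        dist = np.min(np.abs(gt.pos[snp_idx][:, None] - indel_pos[None, :]),
                      axis=1)
        hit = snp_idx[dist <= flank]
        counts["snp_near_indel"] += len(hit)
        keep[hit] = False

    # rule 2: missingness (a genotype is missing if any allele is missing)
    missing = np.any(gt.genotypes < 0, axis=2)  # (S, N)
    frac_missing = missing.mean(axis=1)
    hit = keep & (frac_missing > cfg.max_missing_fraction)
    counts["missing"] = int(hit.sum())
    keep &= ~hit

    # rule 3: heterozygosity
    first = gt.genotypes[:, :, 0]
    het = (~np.all(gt.genotypes == first[:, :, None], axis=2)) & ~missing
    frac_het = het.mean(axis=1)
    hit = keep & (frac_het > cfg.max_het_fraction)
    counts["heterozygous"] = int(hit.sum())
    keep &= ~hit

    return gt.subset_sites(keep), counts


def prune_by_window(gt: GenotypeTable, window_bp: int = 200_000,
                    seed: int = 0) -> GenotypeTable:
    """Keep exactly one site, drawn uniformly at random, per non-empty
    ``window_bp`` bin (bins anchored at position 1 per chromosome)."""
    gt.validate_sorted()
    rng = np.random.default_rng(seed)
    keep_idx: list[int] = []
    for chrom in sorted(np.unique(gt.chrom).tolist()):
        idx = np.flatnonzero(gt.chrom == chrom)
        bins = (gt.pos[idx] - 1) // window_bp
        for b in np.unique(bins):
            members = idx[bins == b]
            keep_idx.append(int(members[rng.integers(0, len(members))]))
    keep_idx.sort()
    return gt.subset_sites(np.array(keep_idx, dtype=int))
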