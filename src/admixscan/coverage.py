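"""Coverage-based gene-deletion calling and population deletion frequencies.

A gene is called deleted in a sample when its mean per-position read depth
is below 0.05x (strict); genes deleted in at least 30% of samples are
flagged for exclusion from downstream gene analysis, and genes never
deleted form the "core" set.  The 0.05x threshold is an absolute mean depth
in reads per base; a relative mode (threshold times the sample's
genome-wide mean) is available behind a flag.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GeneInterval

DELETION_THRESHOLD = 0.05
EXCLUSION_FREQUENCY = 0.3


@dataclass
class DepthTrack:
    """Per-position depth arrays for one sample, keyed by chromosome."""

    sample: str
    depths: dict[str, np.ndarray]

    def chrom_length(self, chrom: str) -> int:
        return len(self.depths[chrom])

    @property
    def genome_mean(self) -> float:
        total = sum(float(a.sum()) for a in self.depths.values())
        n = sum(len(a) for a in self.depths.values())
        return total / n if n else 0.0


@dataclass
class DeletionMatrix:
    """Boolean gene x sample deletion calls."""

    genes: list[str]
    samples: list[str]
    calls: np.ndarray  # (n_genes, n_samples) bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.genes, columns=self.samples)


def mean_gene_coverage(track: DepthTrack,
                       genes: list[GeneInterval]) -> dict[str, float]:
    """Arithmetic mean depth over [start, end) per gene."""
    out = {}
    for g in genes:
        if g.chrom not in track.depths:
            raise ValidationError(f"{g.gene_id}: no depth for {g.chrom}")
        arr = track.depths[g.chrom]
        if g.end > len(arr):
            raise ValidationError(
                f"{g.gene_id}: interval beyond end of {g.chrom} "
                f"({g.end} > {len(arr)})")
        out[g.gene_id] = float(arr[g.start:g.end].mean())
    return out


def call_gene_deletions(means: dict[str, float],
                        threshold: float = DELETION_THRESHOLD,
                        relative_to: float | None = None) -> dict[str, bool]:
    """Deleted iff mean coverage < threshold (strict).

    With ``relative_to`` set (e.g. the sample's genome-wide mean depth) the
    effective cutoff becomes ``threshold * relative_to``.
    """
    cut = threshold if relative_to is None else threshold * relative_to
    for gid, m in means.items():
        if m < 0:
            raise ValidationError(f"negative mean coverage for {gid}")
    return {gid: bool(m < cut) for gid, m in means.items()}


def deletion_matrix(tracks: dict[str, DepthTrack], genes: list[GeneInterval],
                    threshold: float = DELETION_THRESHOLD,
                    relative: bool = False) -> DeletionMatrix:
    """Call deletions for every sample and assemble the gene x sample matrix."""
    samples = sorted(tracks)
    gene_ids = [g.gene_id for g in genes]
    calls = np.zeros((len(genes), len(samples)), dtype=bool)
    for j, s in enumerate(samples):
        means = mean_gene_coverage(tracks[s], genes)
        rel = tracks[s].genome_mean if relative else None
        flags = call_gene_deletions(means, threshold, relative_to=rel)
        for i, gid in enumerate(gene_ids):
            calls[i, j] = flags[gid]
    return DeletionMatrix(gene_ids, samples, calls)


def deletion_frequency(matrix: DeletionMatrix,
                       exclusion_threshold: float = EXCLUSION_FREQUENCY
                       ) -> pd.DataFrame:
    """Per-gene deletion frequency with core/excluded flags.

    Frequency = deleted samples / total samples.  Genes at or above the
    exclusion threshold are flagged "excluded" (boundary inclusive); genes
    never deleted are "core"; the rest are "segregating".
    """
    if matrix.calls.shape[1] < 1:
        raise ValidationError("need at least one sample")
    freq = matrix.calls.mean(axis=1)
    flags = np.where(freq >= exclusion_threshold, "excluded",
                     np.where(freq == 0.0, "core", "segregating"))
    return pd.DataFrame({
        "gene": matrix.genes,
        "deletion_frequency": freq,
        "flag": flags,
    })
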