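"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; VCF (1-based) and the
1-based-inclusive SV table dialect are converted at the boundary.  Strand is
carried on intervals but never consulted by any computation.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .errors import ParseError, ValidationError
from .tree import PhyloTree, read_newick, write_newick  # re-exported  # noqa: F401

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class GeneInterval:
    """A gene (or any annotation) interval, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"interval {self.gene_id}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def read_intervals(path: str, fmt: str = "bed") -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open) or a 1-based
    inclusive TSV dialect (chrom, start, end[, id, strand])."""
    if fmt not in {"bed", "tsv"}:
        raise ValueError(f"unknown interval format: {fmt}")
    out: list[GeneInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            chrom, a, b = parts[0], int(parts[1]), int(parts[2])
            start, end = (a, b) if fmt == "bed" else (a - 1, b)
            name = parts[3] if len(parts) > 3 else f"iv{lineno}"
            strand = parts[5] if len(parts) > 5 else (
                parts[4] if len(parts) > 4 and parts[4] in "+-" else "+")
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start >= end")
            out.append(GeneInterval(name, chrom, start, end, strand))
    return out


def write_bed(intervals: list[GeneInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.gene_id}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------
@dataclass
class GenotypeTable:
    """Multi-sample genotypes at a sorted list of sites.

    ``genotypes`` has shape ``(n_sites, n_samples, ploidy)`` with allele
    indices into ``[ref] + alts`` and ``-1`` for missing.  Haploid call sets
    (single genome assemblies used as taxa) use ploidy 1.
    """

    chrom: np.ndarray  # (S,) str
    pos: np.ndarray  # (S,) int, 1-based
    ref: list[str]
    alts: list[tuple[str, ...]]
    genotypes: np.ndarray  # (S, N, ploidy) int8
    samples: list[str]
    is_indel: np.ndarray = field(default=None)  # (S,) bool
    phased: np.ndarray = field(default=None)  # (S, N) bool

    def __post_init__(self):
        S = len(self.pos)
        if self.is_indel is None:
            self.is_indel = np.array(
                [len(r) != 1 or any(len(a) != 1 for a in al)
                 for r, al in zip(self.ref, self.alts)], dtype=bool)
        if self.phased is None:
            self.phased = np.zeros((S, len(self.samples)), dtype=bool)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def ploidy(self) -> int:
        return self.genotypes.shape[2]

    @property
    def is_multiallelic(self) -> np.ndarray:
        return np.array([len(a) > 1 for a in self.alts], dtype=bool)

    def validate_sorted(self) -> None:
        """Positions must be strictly increasing within each chromosome."""
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValidationError(f"positions not strictly increasing on {c}")

    def subset_sites(self, index: np.ndarray) -> "GenotypeTable":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeTable(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=[self.ref[i] for i in index],
            alts=[self.alts[i] for i in index],
            genotypes=self.genotypes[index],
            samples=list(self.samples),
            is_indel=self.is_indel[index],
            phased=self.phased[index],
        )


def read_vcf(path: str) -> GenotypeTable:
    """Read a VCF v4.x (GT subset) into a :class:`GenotypeTable`.

    Multi-allelic records are retained (flagged via ``is_multiallelic``).
    A cheap structural pre-pass reports ragged records by line number before
    the real parse.
    """
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("##") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                n_cols = len(parts)
                continue
            if line.startswith("#"):
                continue
            if n_cols is None:
                raise ParseError(f"{path}:{lineno}: data before #CHROM header")
            if len(parts) != n_cols:
                raise ParseError(
                    f"{path}:{lineno}: ragged record ({len(parts)} columns, "
                    f"expected {n_cols})")
    if n_cols is None:
        raise ParseError(f"{path}: missing #CHROM header line")

    try:
        vcf = VCF(path)
    except Exception as exc:
        raise ParseError(f"{path}: malformed VCF header: {exc}") from exc
    samples = list(vcf.samples)
    chrom, pos, ref, alts, gts, phased = [], [], [], [], [], []
    for var in vcf:
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alts.append(tuple(var.ALT))
        g = np.array(var.genotypes, dtype=np.int16)  # (N, ploidy+1)
        gts.append(g[:, :-1].astype(np.int8))
        phased.append(g[:, -1].astype(bool))
    vcf.close()
    genotypes = (np.stack(gts) if gts
                 else np.zeros((0, len(samples), 2), dtype=np.int8))
    return GenotypeTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=ref,
        alts=alts,
        genotypes=genotypes,
        samples=samples,
        phased=(np.stack(phased) if phased
                else np.zeros((0, len(samples)), dtype=bool)),
    )


def write_vcf(table: GenotypeTable, path: str) -> None:
    """Write a minimal VCF v4.2 with GT-only FORMAT."""
    contigs = []
    for c in table.chrom:
        if c not in contigs:
            contigs.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            end = int(table.pos[table.chrom == c].max()) + 1000 if table.n_sites else 1000
            fh.write(f"##contig=<ID={c},length={end}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i in range(table.n_sites):
            alt = ",".join(table.alts[i]) if table.alts[i] else "."
            cols = [str(table.chrom[i]), str(int(table.pos[i])), ".",
                    table.ref[i], alt, ".", "PASS", ".", "GT"]
            for j in range(table.n_samples):
                sep = "|" if table.phased[i, j] else "/"
                alleles = table.genotypes[i, j]
                cols.append(sep.join("." if a < 0 else str(int(a)) for a in alleles))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# alignments / sequences
# ---------------------------------------------------------------------------
@dataclass
class GeneAlignment:
    """A multiple sequence alignment over {A,C,G,T} plus gap/ambiguity.

    ``codes`` is ``(n_seqs, length)`` int8 with 0..3 = A,C,G,T and -1 for
    gap/N; ``names`` gives row labels in order.
    """

    names: list[str]
    codes: np.ndarray

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def sequence(self, name: str) -> str:
        row = self.codes[self.names.index(name)]
        return "".join(BASES[c] if c >= 0 else "N" for c in row)

    @classmethod
    def from_strings(cls, names: list[str], seqs: list[str]) -> "GeneAlignment":
        if len({len(s) for s in seqs}) > 1:
            raise ValidationError("alignment rows differ in length")
        codes = np.full((len(seqs), len(seqs[0]) if seqs else 0), -1, dtype=np.int8)
        for i, s in enumerate(seqs):
            for j, ch in enumerate(s.upper()):
                codes[i, j] = _BASE_CODE.get(ch, -1)
        return cls(list(names), codes)


def read_fasta(path: str) -> GeneAlignment:
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        return GeneAlignment([], np.zeros((0, 0), dtype=np.int8))
    return GeneAlignment.from_strings(
        [r.id for r in records], [str(r.seq) for r in records])


def write_fasta(aln: GeneAlignment, path: str) -> None:
    records = [SeqRecord(Seq(aln.sequence(n)), id=n, description="")
               for n in aln.names]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# depth tracks (3-column TSV: chrom, 1-based pos, depth)
# ---------------------------------------------------------------------------
def read_depth_tsv(path: str, sample: str | None = None):
    """Read a per-position depth TSV into a :class:`~admixscan.coverage.DepthTrack`.

    Positions absent from the file get depth 0; chromosome length is taken as
    the maximum listed position.
    """
    from .coverage import DepthTrack

    per_chrom: dict[str, list[tuple[int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            per_chrom.setdefault(parts[0], []).append(
                (int(parts[1]), float(parts[2])))
    depths = {}
    for c, rows in per_chrom.items():
        n = max(p for p, _ in rows)
        arr = np.zeros(n, dtype=np.float64)
        for p, d in rows:
            arr[p - 1] = d
        depths[c] = arr
    name = sample or os.path.splitext(os.path.basename(path))[0]
    return DepthTrack(sample=name, depths=depths)


def write_depth_tsv(track, path: str) -> None:
    with open(path, "w") as fh:
        for c in sorted(track.depths):
            arr = track.depths[c]
            for i, d in enumerate(arr):
                fh.write(f"{c}\t{i + 1}\t{d:g}\n")
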