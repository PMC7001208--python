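"""Presence/absence-variant (PAV) call-set filtering, collapsing, matching
and density summaries.

Two call sources are reconciled: an assembly-based caller reporting point
breakpoints and a read-based caller reporting breakpoint intervals with a
read-support count.  Size limits are 50-100,000 bp inclusive; read calls
additionally require support strictly greater than 5.  Collapsing merges
calls whose reciprocal overlap is at least 70%; matching pads assembly
breakpoints by +/-500 bp and pairs calls greedily by decreasing overlap.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

SVTYPES = {"insertion", "deletion"}


@dataclass
class SVCall:
    chrom: str
    start: int  # 0-based half-open internally
    end: int
    svtype: str
    size: int
    read_support: int | None = None
    source: str = "assembly"  # "assembly" | "read"
    breakpoint: str = "point"  # "point" | "interval"
    call_id: str = ""
    members: int = 1  # calls merged into this one by collapse_overlaps

    def __post_init__(self):
        if self.svtype not in SVTYPES:
            raise ValidationError(f"bad svtype {self.svtype!r}")
        if self.size <= 0:
            raise ValidationError("size must be > 0")
        if self.start < 0 or self.end < self.start:
            raise ValidationError("bad coordinates")


def read_sv_table(path: str) -> list[SVCall]:
    """Read the TSV dialect (chrom, start, end, svtype, size, support,
    source), 1-based inclusive on disk."""
    calls = []
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chrom", "start", "end", "svtype", "size",
                            "support", "source"], header=None, dtype=str)
    for i, row in df.iterrows():
        support = None if row["support"] in (".", "", None) or pd.isna(row["support"]) \
            else int(row["support"])
        source = row["source"] if not pd.isna(row["source"]) else "assembly"
        calls.append(SVCall(
            chrom=row["chrom"], start=int(row["start"]) - 1, end=int(row["end"]),
            svtype=row["svtype"], size=int(row["size"]), read_support=support,
            source=source,
            breakpoint="interval" if source == "read" else "point",
            call_id=f"sv{i}"))
    return calls


def write_sv_table(calls: list[SVCall], path: str) -> None:
    with open(path, "w") as fh:
        for c in calls:
            support = "." if c.read_support is None else str(c.read_support)
            fh.write(f"{c.chrom}\t{c.start + 1}\t{c.end}\t{c.svtype}\t"
                     f"{c.size}\t{support}\t{c.source}\n")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------
def filter_sv_calls(calls: list[SVCall], min_size: int = 50,
                    max_size: int = 100_000,
                    min_read_support_exclusive: int = 5) -> list[SVCall]:
    """Keep calls with min_size <= size <= max_size (inclusive); read-based
    calls additionally need read_support strictly above the support bound."""
    out = []
    for c in calls:
        if not min_size <= c.size <= max_size:
            continue
        if c.source == "read":
            if c.read_support is None or c.read_support <= min_read_support_exclusive:
                continue
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# collapsing
# ---------------------------------------------------------------------------
def _reciprocal_overlap(a: SVCall, b: SVCall, frac: float,
                        one_way: bool = False) -> bool:
    if a.chrom != b.chrom:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    if one_way:
        return ov >= frac * min(a.end - a.start, b.end - b.start)
    return (ov >= frac * (a.end - a.start)) and (ov >= frac * (b.end - b.start))


def collapse_overlaps(calls: list[SVCall], min_reciprocal_frac: float = 0.70,
                      one_way: bool = False) -> list[SVCall]:
    """Collapse connected components of the reciprocal-overlap graph.

    Each component becomes one call spanning the coordinate union of its
    members, annotated with the member count.  The pass is repeated until
    no further merges occur, so the operation is idempotent: union spans
    that newly satisfy the reciprocal threshold are merged too.  Requires
    one svtype and one source (collapsing across them is not meaningful).
    """
    if not calls:
        return []
    if len({c.svtype for c in calls}) > 1 or len({c.source for c in calls}) > 1:
        raise ValidationError("collapse requires a single svtype and source")
    out = list(calls)
    while True:
        merged = _collapse_once(out, min_reciprocal_frac, one_way)
        if len(merged) == len(out):
            return merged
        out = merged


def _collapse_once(calls: list[SVCall], min_reciprocal_frac: float,
                   one_way: bool) -> list[SVCall]:
    order = sorted(range(len(calls)),
                   key=lambda i: (calls[i].chrom, calls[i].start, calls[i].end))
    parent = list(range(len(calls)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    # sweep: a call can only overlap calls starting before its end
    for a_pos, i in enumerate(order):
        ci = calls[i]
        for j in order[a_pos + 1:]:
            cj = calls[j]
            if cj.chrom != ci.chrom or cj.start >= ci.end:
                break
            if _reciprocal_overlap(ci, cj, min_reciprocal_frac, one_way):
                union(i, j)

    groups: dict[int, list[SVCall]] = {}
    for i, c in enumerate(calls):
        groups.setdefault(find(i), []).append(c)
    out = []
    for members in groups.values():
        start = min(c.start for c in members)
        end = max(c.end for c in members)
        rep = members[0]
        out.append(SVCall(
            chrom=rep.chrom, start=start, end=end, svtype=rep.svtype,
            size=end - start if rep.svtype == "deletion"
            else max(c.size for c in members),
            read_support=max((c.read_support for c in members
                              if c.read_support is not None), default=None),
            source=rep.source, breakpoint=rep.breakpoint,
            call_id=rep.call_id, members=sum(c.members for c in members)))
    out.sort(key=lambda c: (c.chrom, c.start, c.end))
    return out


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------
def match_callsets(assembly_calls: list[SVCall], read_calls: list[SVCall],
                   pad: int = 500):
    """Greedy one-to-one matching of assembly calls to read calls.

    An assembly call matches a read call when the svtypes agree and the
    assembly call's breakpoints, expanded by ``pad`` on both sides,
    intersect the read call's interval.  Candidate pairs are taken in order
    of decreasing overlap (ties broken by leftmost coordinates) and each
    call is used at most once.  Returns (matched_pairs, assembly_only,
    read_only).
    """
    candidates = []
    for i, a in enumerate(assembly_calls):
        a_lo, a_hi = a.start - pad, a.end + pad
        for j, r in enumerate(read_calls):
            if r.chrom != a.chrom or r.svtype != a.svtype:
                continue
            ov = min(a_hi, r.end) - max(a_lo, r.start)
            if ov > 0:
                candidates.append((-ov, a.chrom, min(a.start, r.start),
                                   a.start, r.start, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[SVCall, SVCall]] = []
    for *_, i, j in candidates:
        if i in used_a or j in used_r:
            continue
        used_a.add(i)
        used_r.add(j)
        pairs.append((assembly_calls[i], read_calls[j]))
    assembly_only = [a for i, a in enumerate(assembly_calls) if i not in used_a]
    read_only = [r for j, r in enumerate(read_calls) if j not in used_r]
    return pairs, assembly_only, read_only


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------
def pav_density(calls: list[SVCall], chrom_sizes: dict[str, int],
                window_bp: int = 500_000):
    """Per-window PAV counts and per-chromosome summary.

    Windows tile each chromosome; a call is counted in every window its
    span intersects.  Returns ``(window_df, chrom_df)`` DataFrames with
    per-window counts and per-chromosome mean/variance of window counts.
    """
    for c in calls:
        if c.chrom not in chrom_sizes:
            raise ValidationError(f"no chromosome size for {c.chrom}")
        if c.end > chrom_sizes[c.chrom]:
            raise ValidationError(
                f"call {c.call_id or c.start} beyond end of {c.chrom}")
    rows = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        n_windows = (size + window_bp - 1) // window_bp
        counts = np.zeros(n_windows, dtype=int)
        for c in calls:
            if c.chrom != chrom:
                continue
            first = c.start // window_bp
            last = (c.end - 1) // window_bp
            counts[first:last + 1] += 1
        for w in range(n_windows):
            rows.append({"chrom": chrom, "window_start": w * window_bp,
                         "window_end": min((w + 1) * window_bp, size),
                         "count": int(counts[w])})
    window_df = pd.DataFrame(rows)
    chrom_df = (window_df.groupby("chrom")["count"]
                .agg(mean_density="mean", var_density="var", n_windows="size")
                .reset_index())
    return window_df, chrom_df
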