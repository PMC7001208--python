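"""PAV filtering, collapsing, matching and density against brute force."""
import numpy as np
import pytest

from admixscan.errors import ValidationError
from admixscan.sv import (SVCall, collapse_overlaps, filter_sv_calls,
                          match_callsets, pav_density, read_sv_table,
                          write_sv_table)


def dele(start, end, support=None, source="assembly", call_id=""):
    return SVCall("chr1", start, end, "deletion", end - start,
                  read_support=support, source=source,
                  breakpoint="interval" if source == "read" else "point",
                  call_id=call_id)


# -- filtering --------------------------------------------------------------
def test_size_window_boundaries():
    assert filter_sv_calls([dele(0, 49)]) == []
    assert len(filter_sv_calls([dele(0, 50)])) == 1
    assert len(filter_sv_calls([dele(0, 100_000)])) == 1
    assert filter_sv_calls([dele(0, 100_001)]) == []


def test_read_support_strictly_greater_than_five():
    assert filter_sv_calls([dele(0, 100, support=5, source="read")]) == []
    assert len(filter_sv_calls([dele(0, 100, support=6, source="read")])) == 1
    # assembly calls carry no support requirement
    assert len(filter_sv_calls([dele(0, 100)])) == 1


def test_six_call_hand_fixture_retains_three():
    calls = [dele(0, 30), dele(100, 150), dele(1000, 1500),
             dele(10_000, 110_000), dele(200_000, 350_000),
             dele(500_000, 501_000, support=4, source="read")]
    kept = filter_sv_calls(calls)
    assert len(kept) == 3
    assert sorted(c.size for c in kept) == [50, 500, 100_000]


# -- collapsing -------------------------------------------------------------
def test_disjoint_calls_unchanged():
    calls = [dele(0, 100), dele(500, 600)]
    out = collapse_overlaps(calls)
    assert [(c.start, c.end) for c in out] == [(0, 100), (500, 600)]
    assert all(c.members == 1 for c in out)


def test_identical_calls_collapse():
    out = collapse_overlaps([dele(10, 110), dele(10, 110)])
    assert len(out) == 1
    assert out[0].members == 2


def test_below_reciprocal_threshold_not_collapsed():
    # overlap 60 of 100 = 60% < 70%
    out = collapse_overlaps([dele(0, 100), dele(40, 140)])
    assert len(out) == 2


def _oracle_components(calls, frac=0.70):
    """Brute-force all-pairs reciprocal-overlap graph + naive DFS
    component search; returns index components."""
    n = len(calls)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = calls[i], calls[j]
            if a.chrom != b.chrom:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov > 0 and ov >= frac * (a.end - a.start) \
                    and ov >= frac * (b.end - b.start):
                adj[i].add(j)
                adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        comp, stack = set(), [i]
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def _oracle_collapse_to_fixed_point(calls, frac=0.70):
    """Iterate the brute-force component collapse until stable, mirroring
    the operation's idempotence contract."""
    spans = [(c.start, c.end, 1) for c in calls]
    while True:
        as_calls = [dele(s, e, call_id=str(i)) for i, (s, e, _) in enumerate(spans)]
        comps = _oracle_components(as_calls, frac)
        merged = sorted(
            (min(spans[i][0] for i in comp), max(spans[i][1] for i in comp),
             sum(spans[i][2] for i in comp))
            for comp in comps)
        if len(merged) == len(spans):
            return merged
        spans = merged


def test_collapse_matches_brute_force_on_random_intervals(rng):
    calls = []
    for i in range(1000):
        start = int(rng.integers(0, 2_000_000))
        size = int(rng.integers(50, 5000))
        calls.append(dele(start, start + size, call_id=f"c{i}"))
    out = collapse_overlaps(calls)
    assert sum(c.members for c in out) == len(calls)
    got = sorted((c.start, c.end, c.members) for c in out)
    assert got == _oracle_collapse_to_fixed_point(calls)


def test_collapse_idempotent_and_order_invariant(rng):
    calls = []
    for i in range(200):
        start = int(rng.integers(0, 100_000))
        size = int(rng.integers(50, 3000))
        calls.append(dele(start, start + size, call_id=f"c{i}"))
    once = collapse_overlaps(calls)
    twice = collapse_overlaps(once)
    assert [(c.start, c.end) for c in twice] == [(c.start, c.end) for c in once]
    shuffled = [calls[i] for i in rng.permutation(len(calls))]
    other = collapse_overlaps(shuffled)
    assert [(c.start, c.end) for c in other] == [(c.start, c.end) for c in once]


def test_collapse_mixed_sources_rejected():
    with pytest.raises(ValidationError):
        collapse_overlaps([dele(0, 100), dele(0, 100, support=9, source="read")])


# -- matching ---------------------------------------------------------------
def test_identical_breakpoints_match():
    pairs, a_only, r_only = match_callsets(
        [dele(100, 200)], [dele(100, 200, support=9, source="read")])
    assert len(pairs) == 1 and not a_only and not r_only


def test_match_within_pad():
    # read interval starts 400 bp beyond the padded assembly end boundary
    pairs, *_ = match_callsets(
        [dele(100, 200)], [dele(600, 700, support=9, source="read")], pad=500)
    assert len(pairs) == 1
    pairs, a_only, r_only = match_callsets(
        [dele(100, 200)], [dele(701, 800, support=9, source="read")], pad=500)
    assert not pairs


def test_match_one_to_one_and_partition_counts(rng):
    truth_a = [dele(s, s + 1000, call_id=f"a{i}")
               for i, s in enumerate(range(0, 100_000, 5000))]
    truth_r = [dele(s + 100, s + 1100, support=9, source="read",
                    call_id=f"r{i}")
               for i, s in enumerate(range(0, 100_000, 5000))]
    extra_r = [dele(400_000, 401_000, support=9, source="read", call_id="fp")]
    pairs, a_only, r_only = match_callsets(truth_a, truth_r + extra_r)
    assert len(pairs) == len(truth_a)
    assert len(pairs) + len(r_only) == len(truth_r) + len(extra_r)
    assert len(pairs) + len(a_only) == len(truth_a)
    # one-to-one
    assert len({id(p[0]) for p in pairs}) == len(pairs)
    assert len({id(p[1]) for p in pairs}) == len(pairs)


def test_match_svtype_must_agree():
    ins = SVCall("chr1", 100, 101, "insertion", 300, source="assembly")
    del_read = dele(100, 400, support=9, source="read")
    pairs, a_only, r_only = match_callsets([ins], [del_read])
    assert not pairs and len(a_only) == 1 and len(r_only) == 1


def _oracle_greedy_match(assembly, reads, pad=500):
    """Independent max-overlap-first matcher: repeatedly take the best
    remaining pair."""
    cand = []
    for i, a in enumerate(assembly):
        for j, r in enumerate(reads):
            if a.chrom != r.chrom or a.svtype != r.svtype:
                continue
            ov = min(a.end + pad, r.end) - max(a.start - pad, r.start)
            if ov > 0:
                cand.append((ov, -min(a.start, r.start), -a.start, -r.start, i, j))
    pairs = []
    used_a, used_r = set(), set()
    while cand:
        cand.sort(reverse=True)
        ov, _, _, _, i, j = cand[0]
        pairs.append((i, j))
        used_a.add(i)
        used_r.add(j)
        cand = [c for c in cand if c[4] not in used_a and c[5] not in used_r]
    return set(pairs)


def test_match_equals_brute_force_on_simulated_callsets():
    from admixscan.simulate import simulate_sv_callsets

    truth = [dele(s, s + int(1000 + (s % 3) * 400), call_id=f"t{s}")
             for s in range(10_000, 2_500_000, 5000)][:500]
    a, b = simulate_sv_callsets(truth, jitter_sd=100, fp_per_caller=50, seed=21)
    pairs, a_only, r_only = match_callsets(a, b, pad=500)
    oracle = _oracle_greedy_match(a, b)
    got = {(a.index(p[0]), b.index(p[1])) for p in pairs}
    assert got == oracle
    # every true call pair is recovered; false calls fall in -only partitions
    true_a = {c.call_id for c in a if "true" in c.call_id}
    matched_a = {p[0].call_id for p in pairs}
    assert true_a <= matched_a
    assert all("fp" in c.call_id for c in a_only)
    assert all("fp" in c.call_id for c in r_only)


# -- density ----------------------------------------------------------------
def test_density_single_call_single_window():
    wdf, cdf = pav_density([dele(100, 200)], {"chr1": 2_000_000}, 500_000)
    assert wdf["count"].tolist() == [1, 0, 0, 0]


def test_density_boundary_spanning_call_counted_twice():
    wdf, _ = pav_density([dele(499_900, 500_100)], {"chr1": 1_000_000}, 500_000)
    assert wdf["count"].tolist() == [1, 1]


def test_density_matches_brute_force(rng):
    calls = []
    sizes = {"chr1": 3_000_000, "chr2": 1_500_000}
    for i in range(300):
        chrom = "chr1" if rng.random() < 0.7 else "chr2"
        start = int(rng.integers(0, sizes[chrom] - 10_000))
        end = start + int(rng.integers(50, 10_000))
        calls.append(SVCall(chrom, start, end, "deletion", end - start))
    wdf, _ = pav_density(calls, sizes, 500_000)
    for _, row in wdf.iterrows():
        expected = sum(1 for c in calls
                       if c.chrom == row["chrom"]
                       and c.start < row["window_end"]
                       and row["window_start"] < c.end)
        assert row["count"] == expected


def test_density_call_beyond_chrom_end_rejected():
    with pytest.raises(ValidationError):
        pav_density([dele(100, 200)], {"chr1": 150})


# -- table round trip -------------------------------------------------------
def test_sv_table_round_trip(tmp_path):
    calls = [dele(99, 200, call_id="x"),
             dele(1000, 1300, support=7, source="read", call_id="y")]
    path = str(tmp_path / "sv.tsv")
    write_sv_table(calls, path)
    back = read_sv_table(path)
    assert [(c.chrom, c.start, c.end, c.svtype, c.read_support, c.source)
            for c in back] == \
        [(c.chrom, c.start, c.end, c.svtype, c.read_support, c.source)
         for c in calls]
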