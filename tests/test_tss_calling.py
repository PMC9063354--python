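"""tss_calling: Poisson thresholds, run suppression, clustering, filtering."""

import warnings

import numpy as np
import pytest
from scipy import stats

from ernascape.io_core import GenomeLayout
from ernascape.signal_model import build_track, merge_replicates
from ernascape.tss_calling import (
    TssCall,
    TssCluster,
    call_tss,
    decile_groups,
    merge_clusters,
    poisson_count_threshold,
    quantify_tc,
    replicate_consistent,
)

from conftest import events_frame


def test_poisson_threshold_known_value():
    # lambda = 1, alpha = 1e-6: sf(8, 1) = 1.13e-6 > alpha, sf(9, 1) <= alpha,
    # so the smallest k with P(X >= k) <= alpha is 10.
    assert poisson_count_threshold(1000, 1000, 1e-6) == 10


def test_poisson_threshold_matches_definition():
    """k* is the smallest k with sf(k-1, lam) <= alpha, by direct scan."""
    rng = np.random.default_rng(5)
    for _ in range(40):
        total = float(rng.uniform(10, 1e5))
        glen = int(rng.integers(1000, 10_000_000))
        alpha = float(10.0 ** rng.uniform(-9, -2))
        lam = total / glen
        k = poisson_count_threshold(total, glen, alpha)
        assert stats.poisson.sf(k - 1, lam) <= alpha
        assert k == 1 or stats.poisson.sf(k - 2, lam) > alpha


def test_poisson_threshold_alpha_validation():
    with pytest.raises(ValueError):
        poisson_count_threshold(10, 100, 0.0)
    with pytest.raises(ValueError):
        poisson_count_threshold(10, 100, 1.0)


def _spike_events(spikes, filler=()):
    rows = []
    for chrom, pos, strand, n in spikes:
        rows += [(chrom, pos, strand)] * n
    rows += list(filler)
    return events_frame(rows)


def test_call_tss_min_count_floor(tiny_layout):
    # Sparse track: the Poisson threshold alone would call 3-count positions,
    # but min_count=5 must gate them out.
    ev = _spike_events([("chr1A", 100, "+", 3), ("chr1A", 5000, "+", 6)])
    t = build_track(ev, tiny_layout)
    calls = call_tss(t, alpha=1e-6, min_count=5)
    assert [(c.position, c.count) for c in calls] == [(5000, 6.0)]


def test_call_tss_run_suppression_keeps_leftmost_max(tiny_layout):
    # Three candidates within 50 bp; two tie at the max; leftmost wins.
    ev = _spike_events(
        [("chr1A", 100, "+", 8), ("chr1A", 130, "+", 9), ("chr1A", 160, "+", 9),
         ("chr1A", 300, "+", 7)]
    )
    t = build_track(ev, tiny_layout)
    calls = call_tss(t, alpha=1e-6, min_count=5)
    assert [(c.position, c.count) for c in calls] == [(130, 9.0), (300, 7.0)]


def test_call_tss_strands_independent(tiny_layout):
    ev = _spike_events([("chr1A", 100, "+", 8), ("chr1A", 120, "-", 8)])
    t = build_track(ev, tiny_layout)
    calls = call_tss(t, alpha=1e-6, min_count=5)
    assert {(c.strand, c.position) for c in calls} == {("+", 100), ("-", 120)}


def test_call_tss_rejects_empty_and_normalized(tiny_layout):
    from ernascape.signal_model import normalize

    empty = build_track(events_frame([]), tiny_layout)
    with pytest.raises(ValueError, match="empty"):
        call_tss(empty)
    t = normalize(build_track(_spike_events([("chr1A", 5, "+", 6)]), tiny_layout))
    with pytest.raises(ValueError, match="raw"):
        call_tss(t)


def _mk_calls(positions, chrom="c", strand="+"):
    return [TssCall(chrom, strand, p, 10.0) for p in positions]


def test_merge_clusters_chaining_is_single_linkage():
    # 0 -- 3000 -- 6000 chain (each gap == merge_dist) into one cluster even
    # though the ends are 6 kb apart; 9001 starts a new one.
    calls = _mk_calls([0, 3000, 6000, 9001])
    cl = merge_clusters(calls, merge_dist=3000)
    assert [(c.start, c.end) for c in cl] == [(0, 6001), (9001, 9002)]
    assert cl[0].id == "TC000001" and cl[1].id == "TC000002"


def test_merge_clusters_strand_and_chrom_separation():
    calls = _mk_calls([100], strand="+") + _mk_calls([200], strand="-") + _mk_calls(
        [150], chrom="d"
    )
    assert len(merge_clusters(calls)) == 3


def test_cluster_tss_is_five_prime_most():
    plus = merge_clusters(_mk_calls([100, 500]))[0]
    minus = merge_clusters(_mk_calls([100, 500], strand="-"))[0]
    assert plus.tss == 100
    assert minus.tss == 500


def _brute_merge(positions, merge_dist):
    """Oracle: clusters = connected components of the <=merge_dist chain."""
    positions = sorted(positions)
    out = [[positions[0]]]
    for p in positions[1:]:
        if p - out[-1][-1] <= merge_dist:
            out[-1].append(p)
        else:
            out.append([p])
    return [(g[0], g[-1] + 1) for g in out]


def test_merge_clusters_matches_bruteforce():
    rng = np.random.default_rng(21)
    for _ in range(100):
        n = int(rng.integers(1, 40))
        pos = sorted(int(p) for p in rng.choice(50_000, size=n, replace=False))
        d = int(rng.integers(1, 8000))
        got = [(c.start, c.end) for c in merge_clusters(_mk_calls(pos), merge_dist=d)]
        assert got == _brute_merge(pos, d)


def test_replicate_consistent_requires_all_replicates():
    clusters = merge_clusters(_mk_calls([100, 9000]))
    # cluster spans are [100,101) and [9000,9001); support needs a call inside
    rep1 = _mk_calls([100])
    rep2 = _mk_calls([100, 9000])
    kept = replicate_consistent(clusters, [rep1, rep2])
    assert [(c.start, c.end) for c in kept] == [(100, 101)]
    # same position, wrong strand: no support
    rep3 = _mk_calls([100], strand="-")
    assert replicate_consistent(clusters, [rep2, rep3]) == []


def test_replicate_consistent_single_replicate_passthrough():
    clusters = merge_clusters(_mk_calls([100]))
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        kept = replicate_consistent(clusters, [_mk_calls([999_999])])
    assert kept == clusters
    assert any("single replicate" in str(x.message) for x in w)
    with pytest.raises(ValueError):
        replicate_consistent(clusters, [])


def test_quantify_tc_window_and_strand(tiny_layout):
    ev = _spike_events(
        [("chr1A", 1000, "+", 10), ("chr1A", 1250, "+", 4), ("chr1A", 1251, "+", 4),
         ("chr1A", 1100, "-", 7)]
    )
    t = build_track(ev, tiny_layout)
    tc = TssCluster("TC1", "chr1A", "+", 1000, 1001)
    sig = quantify_tc(tc, t)
    # +/-250 window [750, 1251) includes 1000 and 1250 but not 1251; strand
    # restriction excludes the 7 minus-strand events.
    assert sig == pytest.approx((10 + 4) * 1e6 / 25)
    assert tc.signal_250 == sig


def test_decile_groups_sizes_and_order():
    tcs = []
    for i in range(23):
        tc = TssCluster(f"T{i}", "c", "+", i * 100, i * 100 + 1)
        tc.signal_250 = float(i)
        tcs.append(tc)
    groups = decile_groups(tcs, n_groups=10)
    assert [len(g) for g in groups] == [3, 3, 3, 2, 2, 2, 2, 2, 2, 2]
    flat = [tc.signal_250 for g in groups for tc in g]
    assert flat == sorted(flat, reverse=True)
    with pytest.raises(ValueError, match="quantify_tc"):
        decile_groups([TssCluster("x", "c", "+", 0, 1)])


def test_end_to_end_planted_spikes(tiny_layout):
    """Spikes planted well above background are recovered exactly through
    call -> merge -> replicate filter."""
    rng = np.random.default_rng(2)
    truth = [5_000, 20_000, 60_000]
    reps = []
    for _ in range(3):
        # concentrated spike: most reads at the mode, a few 1-2 bp downstream,
        # so every replicate's suppressed-run maximum lands on the mode
        rows = [("chr1A", p, "+") for p in truth for _ in range(25)]
        rows += [("chr1A", p + int(d), "+") for p in truth for d in rng.integers(1, 3, 5)]
        rows += [("chr1A", int(p), rng.choice(["+", "-"])) for p in rng.integers(0, 100_000, 50)]
        reps.append(build_track(events_frame(rows), tiny_layout))
    merged = merge_replicates(reps)
    rep_calls = [call_tss(t) for t in reps]
    clusters = replicate_consistent(merge_clusters(call_tss(merged)), rep_calls)
    tss = sorted(c.tss for c in clusters)
    assert len(tss) == 3
    for t_true, t_got in zip(truth, tss):
        assert abs(t_got - t_true) <= 2
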