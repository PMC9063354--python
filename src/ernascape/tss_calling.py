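"""TSS calling and TSS-cluster (TC) construction.

Detection treats the genome as a Poisson background: on each strand the
per-base rate is (strand events) / (genome length), and a position is called
when its raw event count reaches the smallest k whose Poisson upper tail
P(X >= k) falls at or below ``alpha`` — and is at least ``min_count``.
Candidate positions closer than 50 bp on one strand are collapsed to the
strongest one.  Calls within 3 kb of one another on a strand chain into TSS
clusters whose 5' end is the cluster TSS, and only clusters supported by
every replicate are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_core import Interval
from .signal_model import STRANDS, StrandTrack, window_signal

__all__ = [
    "TssCall",
    "TssCluster",
    "poisson_count_threshold",
    "call_tss",
    "merge_clusters",
    "replicate_consistent",
    "quantify_tc",
    "decile_groups",
]


@dataclass(frozen=True)
class TssCall:
    """One called transcription start position on one strand."""

    chrom: str
    strand: str
    position: int
    count: float
    replicate_id: str | None = None


@dataclass
class TssCluster:
    """A strand-specific transcription-initiation cluster (TC)."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    member_calls: list[TssCall] = field(default_factory=list)
    signal_250: float | None = None
    genomic_class: str | None = None  # genic_proximal | intergenic | masked
    element_id: str | None = None     # enhancer element containing this TC, if any

    @property
    def tss(self) -> int:
        """5' end of the cluster: leftmost base on +, rightmost on -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)


def poisson_count_threshold(total_events: float, genome_length: int, alpha: float) -> int:
    """Smallest k with P(X >= k | lambda = total_events/genome_length) <= alpha."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    lam = total_events / genome_length
    k = max(1, int(stats.poisson.ppf(1 - alpha, lam)))
    # ppf gives an approximate starting point; adjust to the exact boundary.
    while stats.poisson.sf(k - 1, lam) > alpha:
        k += 1
    while k > 1 and stats.poisson.sf(k - 2, lam) <= alpha:
        k -= 1
    return k


def call_tss(
    track: StrandTrack,
    alpha: float = 1e-6,
    min_count: int = 5,
    min_dist: int = 50,
    replicate_id: str | None = None,
) -> list[TssCall]:
    """Call TSS positions against a per-strand genome-wide Poisson background.

    Within any chain of candidate positions successively closer than
    ``min_dist`` on one strand, only the maximal-count position is kept
    (leftmost on ties).
    """
    if track.total_events == 0:
        raise ValueError("cannot call TSSs on an empty track")
    if track.normalized:
        raise ValueError("call_tss operates on raw event counts")
    genome_length = track.layout.total_length
    calls: list[TssCall] = []
    thresholds = {
        s: max(poisson_count_threshold(track.strand_total(s), genome_length, alpha), min_count)
        for s in STRANDS
        if track.strand_total(s) > 0
    }
    for (chrom, strand), (pos, vals) in sorted(track.data.items()):
        thr = thresholds.get(strand)
        if thr is None:
            continue
        keep = vals >= thr
        cpos = pos[keep]
        cval = vals[keep]
        if len(cpos) == 0:
            continue
        # chain candidates separated by < min_dist; keep the strongest of each run
        breaks = np.nonzero(np.diff(cpos) >= min_dist)[0] + 1
        for seg_pos, seg_val in zip(np.split(cpos, breaks), np.split(cval, breaks)):
            best = int(np.argmax(seg_val))  # argmax returns first (leftmost) max
            calls.append(
                TssCall(chrom, strand, int(seg_pos[best]), float(seg_val[best]), replicate_id)
            )
    calls.sort(key=lambda c: (c.chrom, c.strand, c.position))
    return calls


def merge_clusters(calls: list[TssCall], merge_dist: int = 3000) -> list[TssCluster]:
    """Single-linkage chaining of calls within ``merge_dist`` on one strand.

    Cluster span is [min position, max position + 1]; the cluster TSS is the
    5'-most member with respect to the strand.
    """
    ordered = sorted(calls, key=lambda c: (c.chrom, c.strand, c.position))
    clusters: list[TssCluster] = []
    current: list[TssCall] = []

    def flush() -> None:
        if current:
            clusters.append(
                TssCluster(
                    id="",
                    chrom=current[0].chrom,
                    strand=current[0].strand,
                    start=current[0].position,
                    end=current[-1].position + 1,
                    member_calls=list(current),
                )
            )

    for call in ordered:
        if (
            current
            and call.chrom == current[-1].chrom
            and call.strand == current[-1].strand
            and call.position - current[-1].position <= merge_dist
        ):
            current.append(call)
        else:
            flush()
            current = [call]
    flush()
    for i, cl in enumerate(clusters):
        cl.id = f"TC{i + 1:06d}"
    return clusters


def replicate_consistent(
    merged_clusters: list[TssCluster],
    replicate_calls: list[list[TssCall]],
) -> list[TssCluster]:
    """Keep merged-replicate clusters supported by every replicate.

    A replicate supports a cluster when it has at least one call inside the
    cluster span on the same strand.  With a single replicate the clusters
    pass through unchanged (with a warning).
    """
    if len(replicate_calls) == 0:
        raise ValueError("replicate_consistent needs at least one replicate call set")
    if len(replicate_calls) == 1:
        warnings.warn("single replicate: no cross-replicate filtering applied")
        return list(merged_clusters)
    # index replicate calls as sorted position arrays per (chrom, strand)
    indexes: list[dict[tuple[str, str], np.ndarray]] = []
    for calls in replicate_calls:
        idx: dict[tuple[str, str], list[int]] = {}
        for c in calls:
            idx.setdefault((c.chrom, c.strand), []).append(c.position)
        indexes.append({k: np.array(sorted(v)) for k, v in idx.items()})
    kept = []
    for cl in merged_clusters:
        ok = True
        for idx in indexes:
            pos = idx.get((cl.chrom, cl.strand))
            if pos is None:
                ok = False
                break
            lo, hi = np.searchsorted(pos, [cl.start, cl.end])
            if hi == lo:
                ok = False
                break
        if ok:
            kept.append(cl)
    return kept


def quantify_tc(tc: TssCluster, track: StrandTrack, flank: int = 250) -> float:
    """Strand-restricted normalized density within +/- ``flank`` bp of the TC
    TSS; stored on the cluster as ``signal_250``."""
    sig = window_signal(track, tc.chrom, tc.tss, flank, strand=tc.strand)
    tc.signal_250 = sig
    return sig


def decile_groups(tcs: list[TssCluster], n_groups: int = 10) -> list[list[TssCluster]]:
    """Split TCs into ``n_groups`` groups by descending signal_250.

    Group sizes are floor(n / n_groups) with the remainder spread over the top
    (strongest) groups; ties break deterministically by (chrom, tss).
    """
    if any(tc.signal_250 is None for tc in tcs):
        raise ValueError("quantify_tc must be run before decile_groups")
    n = len(tcs)
    if n < n_groups:
        warnings.warn(f"only {n} TCs for {n_groups} groups; returning {n} singleton groups")
        n_groups = max(n, 1)
    ranked = sorted(tcs, key=lambda tc: (-tc.signal_250, tc.chrom, tc.tss))
    base, rem = divmod(n, n_groups)
    groups: list[list[TssCluster]] = []
    i = 0
    for g in range(n_groups):
        size = base + (1 if g < rem else 0)
        groups.append(ranked[i : i + size])
        i += size
    return groups
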