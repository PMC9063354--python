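"""Transcribed-enhancer catalogs from chromatin states and intergenic TCs.

Enhancer-like elements are merged runs of chromatin-state 5–7 segments lying
at least 3 kb from the nearest gene body.  An element is *transcribed* when
at least one intergenic TC overlaps it; among transcribed elements the more
actively transcribed strand (by +/-250 bp density at the strongest TC's 5'
end) is the *primary* strand, and elements with called TCs on both strands
are bidirectional (BE), otherwise unidirectional (UE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import GeneModel, Interval, IntervalIndex
from .signal_model import StrandTrack, window_signal
from .tss_calling import TssCluster

__all__ = [
    "EnhancerElement",
    "define_enhancer_like",
    "assign_transcription",
    "classify_direction",
    "state_tc_counts",
]

DEFAULT_KEEP_STATES = frozenset({5, 6, 7})


@dataclass
class EnhancerElement:
    """A distal chromatin-state-derived element with transcription annotation."""

    id: str
    interval: Interval
    source_states: frozenset[int]
    distance_to_gene: float
    status: str = "untranscribed"        # transcribed | untranscribed
    primary_strand: str = "none"         # + | - | none
    signal_primary: float = 0.0
    signal_secondary: float = 0.0
    dir_class: str = "none"              # UE | BE | none
    supporting_tcs: list[str] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def define_enhancer_like(
    states: pd.DataFrame,
    genes: list[GeneModel],
    keep_states: frozenset[int] = DEFAULT_KEEP_STATES,
    min_gene_dist: int = 3000,
) -> list[EnhancerElement]:
    """Merge adjacent/overlapping kept-state segments and keep those at least
    ``min_gene_dist`` bp from the nearest gene body.

    ``states`` is a states-BED DataFrame (chrom, start, end, state_id) with
    non-overlapping segments per chromosome.
    """
    kept = states[states["state_id"].isin(list(keep_states))]
    gene_index = IntervalIndex([g.interval for g in genes])
    elements: list[EnhancerElement] = []
    for chrom, grp in kept.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        runs: list[tuple[int, int, set[int]]] = []
        for start, end, state in zip(grp["start"], grp["end"], grp["state_id"]):
            if runs and start <= runs[-1][1]:
                prev = runs[-1]
                runs[-1] = (prev[0], max(prev[1], int(end)), prev[2] | {int(state)})
            else:
                runs.append((int(start), int(end), {int(state)}))
        for start, end, src in runs:
            dist = gene_index.nearest_gap(chrom, start, end)
            if dist < min_gene_dist:
                continue
            elements.append(
                EnhancerElement(
                    id="",
                    interval=Interval(chrom, start, end),
                    source_states=frozenset(src),
                    distance_to_gene=dist,
                )
            )
    elements.sort(key=lambda e: (e.interval.chrom, e.interval.start))
    for i, el in enumerate(elements):
        el.id = f"ENH{i + 1:05d}"
    return elements


def assign_transcription(
    elements: list[EnhancerElement],
    intergenic_tcs: list[TssCluster],
) -> list[EnhancerElement]:
    """Mark elements transcribed when >= 1 intergenic TC overlaps (any strand);
    annotate each overlapping TC with its containing element id."""
    by_chrom: dict[str, list[EnhancerElement]] = {}
    for el in elements:
        el.status = "untranscribed"
        el.supporting_tcs = []
        by_chrom.setdefault(el.interval.chrom, []).append(el)
    starts = {
        chrom: np.array([e.interval.start for e in els])
        for chrom, els in by_chrom.items()
    }
    for tc in intergenic_tcs:
        tc.element_id = None
        els = by_chrom.get(tc.chrom)
        if not els:
            continue
        # elements are disjoint and start-sorted: every element overlapping the
        # TC span lies in a contiguous run ending at searchsorted(tc.end)
        i = int(np.searchsorted(starts[tc.chrom], tc.end, side="left")) - 1
        hit_ids: list[str] = []
        while i >= 0:
            el = els[i]
            if el.interval.end <= tc.start:
                break
            if el.interval.start < tc.end:
                el.status = "transcribed"
                el.supporting_tcs.append(tc.id)
                hit_ids.append(el.id)
                if el.interval.start <= tc.tss < el.interval.end:
                    tc.element_id = el.id
            i -= 1
        if hit_ids and tc.element_id is None:
            tc.element_id = hit_ids[-1]
    return elements


def classify_direction(
    element: EnhancerElement,
    track: StrandTrack,
    tcs: list[TssCluster],
) -> EnhancerElement:
    """Set primary strand, per-strand signals and the UE/BE class.

    Per strand, the signal is the +/-250 bp density around the 5' end of the
    strongest overlapping TC (by signal_250).  The primary strand is the one
    with higher signal (ties -> +); BE requires called TCs on both strands.
    """
    if element.status != "transcribed":
        raise ValueError(f"classify_direction on untranscribed element {element.id}")
    overlapping = [
        tc
        for tc in tcs
        if tc.chrom == element.chrom
        and tc.start < element.interval.end
        and tc.end > element.interval.start
    ]
    best_by_strand: dict[str, TssCluster] = {}
    for tc in overlapping:
        sig = tc.signal_250
        if sig is None:
            raise ValueError("TCs must be quantified (signal_250) before direction calls")
        cur = best_by_strand.get(tc.strand)
        if cur is None or sig > cur.signal_250:
            best_by_strand[tc.strand] = tc
    signals = {
        s: window_signal(track, tc.chrom, tc.tss, 250, strand=s)
        for s, tc in best_by_strand.items()
    }
    plus = signals.get("+", 0.0)
    minus = signals.get("-", 0.0)
    primary = "+" if plus >= minus else "-"
    element.primary_strand = primary
    element.signal_primary = max(plus, minus)
    element.signal_secondary = min(plus, minus)
    element.dir_class = "BE" if len(best_by_strand) == 2 else "UE"
    return element


def state_tc_counts(
    intergenic_tcs: list[TssCluster],
    states: pd.DataFrame,
) -> dict[int | str, int]:
    """Count TCs per chromatin state of the segment containing the TC TSS
    (5' end); TSSs in no segment fall in the ``"unassigned"`` bucket."""
    lookup: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in states.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        lookup[chrom] = (
            grp["start"].to_numpy(np.int64),
            grp["end"].to_numpy(np.int64),
            grp["state_id"].to_numpy(np.int64),
        )
    counts: dict[int | str, int] = {}
    for tc in intergenic_tcs:
        bucket: int | str = "unassigned"
        entry = lookup.get(tc.chrom)
        if entry is not None:
            starts, ends, state_ids = entry
            i = int(np.searchsorted(starts, tc.tss, side="right")) - 1
            if i >= 0 and tc.tss < ends[i]:
                bucket = int(state_ids[i])
        counts[bucket] = counts.get(bucket, 0) + 1
    return counts
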