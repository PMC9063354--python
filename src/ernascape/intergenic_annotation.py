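"""Genomic classification of TCs and of raw 5'-end events.

A TC is *genic-proximal* when its span overlaps any annotated gene body
(both confidence classes) extended by 1 kb on each side (strand-agnostic),
*masked* when it instead overlaps the coding-transcript mask, and
*intergenic* otherwise.  Raw events are partitioned into mutually exclusive
categories with priority exon > intron > TSS1K > TES1K > intergenic, where
TSS1K/TES1K are the strand-aware 1-kb regions upstream of the TSS and
downstream of the TES.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_core import GeneModel, GenomeLayout, merge_intervals
from .signal_model import STRANDS, StrandTrack
from .tss_calling import TssCluster

__all__ = ["classify_tcs", "read_category_fractions", "CATEGORIES"]

CATEGORIES = ("exon", "intron", "TSS1K", "TES1K", "intergenic")


def _merged_lookup(by_chrom: dict[str, list[tuple[int, int]]]):
    """Build per-chrom merged sorted arrays for point/interval membership."""
    out = {}
    for chrom, ivs in by_chrom.items():
        merged = merge_intervals(ivs)
        out[chrom] = (
            np.array([a for a, _ in merged], dtype=np.int64),
            np.array([b for _, b in merged], dtype=np.int64),
        )
    return out


def _overlaps(lookup, chrom: str, start: int, end: int) -> bool:
    entry = lookup.get(chrom)
    if entry is None:
        return False
    starts, ends = entry
    i = int(np.searchsorted(starts, end, side="left"))
    return i > 0 and ends[i - 1] > start


def _points_in(lookup, chrom: str, pos: np.ndarray) -> np.ndarray:
    entry = lookup.get(chrom)
    if entry is None:
        return np.zeros(len(pos), dtype=bool)
    starts, ends = entry
    i = np.searchsorted(starts, pos, side="right") - 1
    ok = i >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] < ends[i[ok]]
    return out


def classify_tcs(
    tcs: list[TssCluster],
    genes: list[GeneModel],
    coding_mask: pd.DataFrame | None,
    flank: int = 1000,
) -> list[TssCluster]:
    """Set ``genomic_class`` on every TC (in place; returns the same list)."""
    genic: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        genic.setdefault(g.chrom, []).append((max(0, g.start - flank), g.end + flank))
    genic_lookup = _merged_lookup(genic)
    mask_by: dict[str, list[tuple[int, int]]] = {}
    if coding_mask is not None:
        for chrom, start, end in zip(coding_mask["chrom"], coding_mask["start"], coding_mask["end"]):
            mask_by.setdefault(chrom, []).append((int(start), int(end)))
    mask_lookup = _merged_lookup(mask_by)
    for tc in tcs:
        if _overlaps(genic_lookup, tc.chrom, tc.start, tc.end):
            tc.genomic_class = "genic_proximal"
        elif _overlaps(mask_lookup, tc.chrom, tc.start, tc.end):
            tc.genomic_class = "masked"
        else:
            tc.genomic_class = "intergenic"
    return tcs


def read_category_fractions(
    track: StrandTrack,
    genes: list[GeneModel],
    layout: GenomeLayout | None = None,
    flank: int = 1000,
) -> dict[str, float]:
    """Fraction of 5'-end events in each genomic category.

    Each event is assigned exactly one category with priority
    exon > intron > TSS1K > TES1K > intergenic, so the fractions sum to 1.
    """
    layout = layout or track.layout
    exon_by: dict[str, list[tuple[int, int]]] = {}
    intron_by: dict[str, list[tuple[int, int]]] = {}
    tss1k_by: dict[str, list[tuple[int, int]]] = {}
    tes1k_by: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        exon_by.setdefault(g.chrom, []).extend(g.exons)
        intron_by.setdefault(g.chrom, []).extend(g.introns())
        if g.strand == "+":
            up = (g.start - flank, g.start)
            down = (g.end, g.end + flank)
        else:
            up = (g.end, g.end + flank)
            down = (g.start - flank, g.start)
        for target, (a, b) in ((tss1k_by, up), (tes1k_by, down)):
            a, b = layout.clip(g.chrom, a, b)
            if a < b:
                target.setdefault(g.chrom, []).append((a, b))
    lookups = [
        ("exon", _merged_lookup(exon_by)),
        ("intron", _merged_lookup(intron_by)),
        ("TSS1K", _merged_lookup(tss1k_by)),
        ("TES1K", _merged_lookup(tes1k_by)),
    ]
    totals = dict.fromkeys(CATEGORIES, 0.0)
    grand = 0.0
    for chrom in layout.chroms:
        for strand in STRANDS:
            pos, vals = track.arrays(chrom, strand)
            if len(pos) == 0:
                continue
            remaining = np.ones(len(pos), dtype=bool)
            for name, lookup in lookups:
                hit = remaining & _points_in(lookup, chrom, pos)
                totals[name] += float(vals[hit].sum())
                remaining &= ~hit
            totals["intergenic"] += float(vals[remaining].sum())
            grand += float(vals.sum())
    if grand == 0:
        raise ValueError("empty track: no events to categorize")
    return {k: v / grand for k, v in totals.items()}
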