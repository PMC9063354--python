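"""Strand-specific 5'-end coverage tracks.

A :class:`StrandTrack` stores, per (chromosome, strand), the sorted positions
where polymerase 5'-end events were observed and their event counts — the
primitive every quantification step reads from.  Densities are events per
million (the raw counts scaled by 1e6 / total_events), so replicates of
different depth are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import GenomeLayout, Interval, read_bed

__all__ = [
    "StrandTrack",
    "build_track",
    "normalize",
    "merge_replicates",
    "replicate_correlation",
    "window_signal",
    "metaprofile",
]

STRANDS = ("+", "-")


class StrandTrack:
    """Sparse per-base, per-strand 5'-end event track.

    ``data`` maps (chrom, strand) to a pair of aligned arrays
    ``(positions, values)`` with positions sorted and unique.  Values are raw
    integer counts unless ``normalized`` is True, in which case they are
    events-per-million densities.
    """

    def __init__(
        self,
        layout: GenomeLayout,
        data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] | None = None,
        total_events: int = 0,
        normalized: bool = False,
    ):
        self.layout = layout
        self.data = data or {}
        self.total_events = int(total_events)
        self.normalized = normalized

    # -- construction -----------------------------------------------------
    @classmethod
    def from_events(cls, events: pd.DataFrame, layout: GenomeLayout) -> "StrandTrack":
        """Accumulate single-base BED6-style event records into a track."""
        widths = events["end"].to_numpy() - events["start"].to_numpy()
        if len(widths) and (widths != 1).any():
            bad = int(np.argmax(widths != 1))
            raise ValueError(
                f"event record {bad} spans {widths[bad]} bp; 5'-end events must be "
                "single-base — pre-extract read 5' ends before building the track"
            )
        if len(events) and not events["strand"].isin(STRANDS).all():
            raise ValueError("events must be stranded (+ or -)")
        data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        total = 0
        for (chrom, strand), grp in events.groupby(["chrom", "strand"], sort=True):
            if chrom not in layout.lengths:
                raise ValueError(f"event on undeclared chromosome {chrom}")
            pos = grp["start"].to_numpy(dtype=np.int64)
            if (pos >= layout.lengths[chrom]).any():
                raise ValueError(f"event beyond end of {chrom}")
            upos, counts = np.unique(pos, return_counts=True)
            data[(chrom, strand)] = (upos, counts.astype(np.float64))
            total += int(counts.sum())
        return cls(layout, data, total_events=total, normalized=False)

    # -- basics -----------------------------------------------------------
    @property
    def norm_factor(self) -> float:
        """Events-per-million scale factor (1e6 / total events)."""
        if self.total_events == 0:
            raise ValueError("cannot normalize an empty track (total_events == 0)")
        return 1e6 / self.total_events

    def strand_total(self, strand: str) -> float:
        return float(
            sum(vals.sum() for (c, s), (_p, vals) in self.data.items() if s == strand)
        )

    def arrays(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        return self.data.get(
            (chrom, strand),
            (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.float64)),
        )

    def count_in(self, chrom: str, strand: str, start: int, end: int) -> float:
        """Sum of stored values with start <= position < end on one strand."""
        pos, vals = self.arrays(chrom, strand)
        lo, hi = np.searchsorted(pos, [start, end])
        return float(vals[lo:hi].sum())

    def density_in(self, chrom: str, start: int, end: int, strand: str | None = None) -> float:
        """Normalized (events-per-million) signal in [start, end)."""
        scale = 1.0 if self.normalized else self.norm_factor
        strands = STRANDS if strand is None else (strand,)
        return scale * sum(self.count_in(chrom, s, start, end) for s in strands)

    def binned(self, bin_size: int, stranded: bool = False) -> np.ndarray:
        """Genome-wide vector of normalized densities per fixed ``bin_size``
        tiling from position 0 (final partial bin included).  Strand-summed by
        default; with ``stranded`` the +/- vectors are concatenated."""
        scale = 1.0 if self.normalized else self.norm_factor
        per_strand: dict[str, list[np.ndarray]] = {s: [] for s in STRANDS}
        for chrom in self.layout.chroms:
            nbins = -(-self.layout.lengths[chrom] // bin_size)
            for s in STRANDS:
                vec = np.zeros(nbins)
                pos, vals = self.arrays(chrom, s)
                if len(pos):
                    np.add.at(vec, pos // bin_size, vals * scale)
                per_strand[s].append(vec)
        plus = np.concatenate(per_strand["+"])
        minus = np.concatenate(per_strand["-"])
        return np.concatenate([plus, minus]) if stranded else plus + minus


def build_track(events: "pd.DataFrame | str", layout: GenomeLayout) -> StrandTrack:
    """Build a raw-count track from an events DataFrame or a BED6 file of
    single-base 5'-end records."""
    if not isinstance(events, pd.DataFrame):
        events = read_bed(events, kind="bed6", layout=layout)
    return StrandTrack.from_events(events, layout)


def normalize(track: StrandTrack) -> StrandTrack:
    """Return a track whose values are events-per-million densities."""
    if track.normalized:
        return track
    f = track.norm_factor  # raises on empty track
    data = {k: (pos, vals * f) for k, (pos, vals) in track.data.items()}
    return StrandTrack(track.layout, data, track.total_events, normalized=True)


def merge_replicates(tracks: list[StrandTrack]) -> StrandTrack:
    """Position-wise sum of raw replicate counts (depths add)."""
    if not tracks:
        raise ValueError("merge_replicates needs at least one track")
    layout = tracks[0].layout
    for t in tracks:
        if t.normalized:
            raise ValueError("merge_replicates operates on raw-count tracks")
        if t.layout != layout:
            raise ValueError("replicate tracks disagree on genome layout")
    data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    keys = {k for t in tracks for k in t.data}
    for key in sorted(keys):
        allpos = np.concatenate([t.data[key][0] for t in tracks if key in t.data])
        allval = np.concatenate([t.data[key][1] for t in tracks if key in t.data])
        upos, inv = np.unique(allpos, return_inverse=True)
        summed = np.zeros(len(upos))
        np.add.at(summed, inv, allval)
        data[key] = (upos, summed)
    total = sum(t.total_events for t in tracks)
    return StrandTrack(layout, data, total_events=total, normalized=False)


def replicate_correlation(
    track_a: StrandTrack,
    track_b: StrandTrack,
    bin_size: int = 500,
    stranded: bool = False,
) -> float:
    """Pearson correlation of normalized densities over genome-wide bins
    (NaN if either binned vector has zero variance)."""
    if track_a.layout != track_b.layout:
        raise ValueError("tracks must share a genome layout")
    va = track_a.binned(bin_size, stranded=stranded)
    vb = track_b.binned(bin_size, stranded=stranded)
    if va.std() == 0 or vb.std() == 0:
        return float("nan")
    r, _ = stats.pearsonr(va, vb)
    return float(r)


def window_signal(
    track: StrandTrack,
    chrom: str,
    center: int,
    flank: int,
    strand: str | None = None,
) -> float:
    """Normalized density summed over [center - flank, center + flank + 1)
    (a symmetric window including the center base), clipped at chromosome
    edges.  ``strand`` restricts to one strand; None sums both."""
    start, end = track.layout.clip(chrom, center - flank, center + flank + 1)
    if start >= end:
        return 0.0
    return track.density_in(chrom, start, end, strand=strand)


def metaprofile(
    track: StrandTrack,
    anchors: list[tuple[str, int, str]],
    flank: int = 3000,
    nbins: int = 100,
    strand: str | None = None,
    order_by: np.ndarray | None = None,
) -> np.ndarray:
    """Anchor-centred signal matrix (rows = anchors, cols = ``nbins`` bins
    spanning [anchor - flank, anchor + flank)).

    Minus-strand anchors are orientation-flipped so that transcription
    downstream of the anchor always appears to the right of center.  Anchors
    off the chromosome give NaN rows.  ``order_by`` (one value per anchor)
    sorts rows descending.
    """
    scale = 1.0 if track.normalized else track.norm_factor
    width = 2 * flank
    binw = width / nbins
    mat = np.full((len(anchors), nbins), np.nan)
    for i, (chrom, pos, astrand) in enumerate(anchors):
        if chrom not in track.layout.lengths or not 0 <= pos < track.layout.lengths[chrom]:
            continue
        row = np.zeros(nbins)
        lo, hi = pos - flank, pos + flank
        strands = STRANDS if strand is None else (strand,)
        for s in strands:
            p, v = track.arrays(chrom, s)
            a, b = np.searchsorted(p, [lo, hi])
            if a == b:
                continue
            idx = np.minimum(((p[a:b] - lo) / binw).astype(int), nbins - 1)
            np.add.at(row, idx, v[a:b] * scale)
        if astrand == "-":
            row = row[::-1]
        mat[i] = row
    if order_by is not None:
        mat = mat[np.argsort(-np.asarray(order_by), kind="stable")]
    return mat
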