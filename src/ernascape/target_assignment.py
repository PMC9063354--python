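"""Enhancer -> target-gene assignment.

A transcribed enhancer is linked to a gene when three criteria hold
simultaneously: the gene body lies within the search range (500 kb, expanded
to 2 Mb only when no gene passes within 500 kb), the histone-peak signal
vectors of enhancer and promoter correlate at >= 0.7 across panel samples,
and at least one Hi-C read pair connects the two regions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enhancer_classification import EnhancerElement
from .io_core import GeneModel, GenomeLayout, Interval, read_bed

__all__ = [
    "PeakPanel",
    "EnhancerTargetLink",
    "promoter_of",
    "pair_correlation",
    "hic_support",
    "assign_targets",
    "target_expression_summary",
]

PRIMARY_DIST = 500_000
EXPANDED_DIST = 2_000_000


class PeakPanel:
    """A set of peaks for one mark, each carrying one signal value per panel
    sample (shared ordered sample list)."""

    def __init__(self, peaks: pd.DataFrame, signals: np.ndarray, samples: list[str]):
        if len(peaks) != signals.shape[0]:
            raise ValueError("one signal row per peak required")
        if signals.shape[1] != len(samples):
            raise ValueError("one signal column per sample required")
        if (signals < 0).any():
            raise ValueError("panel signals must be >= 0")
        self.peaks = peaks.reset_index(drop=True)
        self.signals = np.asarray(signals, dtype=float)
        self.samples = list(samples)
        self._by_chrom: dict[str, np.ndarray] = {
            chrom: grp.index.to_numpy()
            for chrom, grp in self.peaks.groupby("chrom", sort=True)
        }

    @classmethod
    def from_files(cls, peaks_bed: str, signals_tsv: str) -> "PeakPanel":
        """Load peaks (BED) and a row-aligned peak x sample signal matrix TSV."""
        peaks = read_bed(peaks_bed, kind="bed3")
        mat = pd.read_csv(signals_tsv, sep="\t", index_col=0)
        return cls(peaks, mat.to_numpy(dtype=float), list(mat.columns))

    def strongest_overlapping(self, iv: Interval) -> int | None:
        """Index of the max-mean-signal peak overlapping ``iv`` (None if none)."""
        idx = self._by_chrom.get(iv.chrom)
        if idx is None:
            return None
        starts = self.peaks.loc[idx, "start"].to_numpy()
        ends = self.peaks.loc[idx, "end"].to_numpy()
        hit = idx[(starts < iv.end) & (ends > iv.start)]
        if len(hit) == 0:
            return None
        means = self.signals[hit].mean(axis=1)
        return int(hit[int(np.argmax(means))])


@dataclass(frozen=True)
class EnhancerTargetLink:
    """One enhancer-gene link passing distance, correlation and Hi-C criteria."""

    enhancer_id: str
    gene_id: str
    distance: float
    correlation: float
    hic_pairs: int
    search_tier: str  # primary_500kb | expanded_2Mb


def promoter_of(gene: GeneModel, layout: GenomeLayout, up: int = 1000, down: int = 500) -> Interval:
    """Strand-aware promoter window around the annotated TSS (``up`` bp
    upstream, ``down`` bp downstream), clipped at chromosome edges."""
    tss = gene.tss
    if gene.strand == "+":
        start, end = tss - up, tss + down
    else:
        start, end = tss - down + 1, tss + up + 1
    start, end = layout.clip(gene.chrom, start, end)
    return Interval(gene.chrom, start, end)


def pair_correlation(enh: Interval, prom: Interval, panel: PeakPanel) -> float:
    """Pearson r across panel samples between the strongest peak overlapping
    the enhancer and the strongest peak overlapping the promoter.

    NaN when either side has no overlapping peak or a zero-variance vector.
    """
    if len(panel.samples) < 3:
        raise ValueError("pair_correlation needs >= 3 panel samples")
    ie = panel.strongest_overlapping(enh)
    ip = panel.strongest_overlapping(prom)
    if ie is None or ip is None:
        return float("nan")
    x, y = panel.signals[ie], panel.signals[ip]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def hic_support(enh: Interval, prom: Interval, contacts: pd.DataFrame) -> int:
    """Total read pairs over contacts with one anchor overlapping the enhancer
    and the other the promoter, in either orientation."""
    c1, s1, e1 = contacts["chrom1"], contacts["start1"], contacts["end1"]
    c2, s2, e2 = contacts["chrom2"], contacts["start2"], contacts["end2"]

    def _ov(c, s, e, iv: Interval):
        return (c == iv.chrom) & (s < iv.end) & (e > iv.start)

    fwd = _ov(c1, s1, e1, enh) & _ov(c2, s2, e2, prom)
    rev = _ov(c1, s1, e1, prom) & _ov(c2, s2, e2, enh)
    return int(contacts.loc[fwd | rev, "read_pairs"].sum())


def _gene_distance(el: EnhancerElement, gene: GeneModel) -> float:
    if gene.chrom != el.interval.chrom:
        return math.inf
    if gene.start < el.interval.end and el.interval.start < gene.end:
        return 0.0
    if gene.start >= el.interval.end:
        return float(gene.start - el.interval.end)
    return float(el.interval.start - gene.end)


def assign_targets(
    enhancers: list[EnhancerElement],
    genes: list[GeneModel],
    panel: PeakPanel,
    contacts: pd.DataFrame,
    layout: GenomeLayout,
    corr_cutoff: float = 0.7,
    primary_dist: int = PRIMARY_DIST,
    expanded_dist: int = EXPANDED_DIST,
) -> list[EnhancerTargetLink]:
    """Assign target genes to transcribed enhancers.

    For each enhancer, genes within ``primary_dist`` are tested; only when no
    primary-tier gene passes both the correlation cutoff and the >= 1 Hi-C
    read-pair requirement is the search expanded to ``expanded_dist``.
    Output order is deterministic (enhancer id, then gene id).
    """
    genes_sorted = sorted(genes, key=lambda g: g.gene_id)
    promoters = {g.gene_id: promoter_of(g, layout) for g in genes_sorted}
    links: list[EnhancerTargetLink] = []
    for el in sorted(enhancers, key=lambda e: e.id):
        if el.status != "transcribed":
            continue
        dists = [( _gene_distance(el, g), g) for g in genes_sorted]

        def _test(cands, tier):
            out = []
            for dist, g in cands:
                r = pair_correlation(el.interval, promoters[g.gene_id], panel)
                if not (r == r) or r < corr_cutoff:  # NaN fails
                    continue
                pairs = hic_support(el.interval, promoters[g.gene_id], contacts)
                if pairs < 1:
                    continue
                out.append(
                    EnhancerTargetLink(el.id, g.gene_id, dist, r, pairs, tier)
                )
            return out

        primary = _test([(d, g) for d, g in dists if d <= primary_dist], "primary_500kb")
        if primary:
            links.extend(primary)
        else:
            links.extend(
                _test(
                    [(d, g) for d, g in dists if primary_dist < d <= expanded_dist],
                    "expanded_2Mb",
                )
            )
    return links


def target_expression_summary(
    links: list[EnhancerTargetLink],
    expression: dict[str, float],
) -> pd.DataFrame:
    """Per-gene linked-enhancer counts joined with expression.

    Returns a DataFrame (gene_id, n_enhancers, expression) covering every
    gene in ``expression``; genes linked but absent from the expression map
    are excluded with a warning.
    """
    counts: dict[str, int] = {}
    for link in links:
        counts[link.gene_id] = counts.get(link.gene_id, 0) + 1
    missing = sorted(set(counts) - set(expression))
    if missing:
        warnings.warn(f"{len(missing)} linked genes missing from expression map; excluded")
    rows = [
        (gene, counts.get(gene, 0), level) for gene, level in expression.items()
    ]
    return pd.DataFrame(rows, columns=["gene_id", "n_enhancers", "expression"])
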