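"""Windowed nucleotide diversity, coverage saturation, and reporter scoring.

Diversity follows the vcftools ``--window-pi`` convention: per biallelic SNP,
pi_site = 2 j (n - j) / (n (n - 1)) with n called haplotypes and j ALT
haplotypes, and a 500-bp window's pi is the sum of site values divided by the
window length.  Reporter activity is the Fluc/Rluc ratio normalized to the
blank construct, positive at >= 2.0 (the negative control in the assay this
emulates sits at 1.6).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy import stats

from .io_core import GeneModel, GenomeLayout, Interval, merge_intervals

__all__ = [
    "DiversityWindow",
    "windowed_pi",
    "region_diversity_compare",
    "coverage_saturation",
    "reporter_score",
    "activity_signal_correlation",
]


@dataclass(frozen=True)
class DiversityWindow:
    interval: Interval
    pi: float
    n_variants: int
    all_missing: bool = False


def windowed_pi(
    vcf_path: str,
    layout: GenomeLayout,
    window: int = 500,
) -> pd.DataFrame:
    """Per-window nucleotide diversity across the genome.

    Non-biallelic or non-SNP records are skipped (the skipped count is
    attached as ``df.attrs['n_skipped']``).  Every window is reported; a
    window whose variants all have fully missing genotypes gets pi 0 and
    ``all_missing`` True.
    """
    sums: dict[str, np.ndarray] = {}
    nvar: dict[str, np.ndarray] = {}
    ncalled: dict[str, np.ndarray] = {}
    for chrom, length in layout.lengths.items():
        nbins = -(-length // window)
        sums[chrom] = np.zeros(nbins)
        nvar[chrom] = np.zeros(nbins, dtype=int)
        ncalled[chrom] = np.zeros(nbins, dtype=int)
    n_skipped = 0
    for rec in VCF(vcf_path):
        if rec.CHROM not in sums:
            continue
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        gts = np.asarray(rec.genotypes, dtype=int)[:, :2]
        called = gts >= 0
        n = int(called.sum())
        b = (rec.POS - 1) // window
        nvar[rec.CHROM][b] += 1
        if n < 2:
            continue
        j = int(gts[called].sum())
        ncalled[rec.CHROM][b] += 1
        sums[rec.CHROM][b] += 2 * j * (n - j) / (n * (n - 1))
    rows = []
    for chrom, length in layout.lengths.items():
        nbins = len(sums[chrom])
        for b in range(nbins):
            start = b * window
            end = min(length, start + window)
            rows.append(
                (
                    chrom,
                    start,
                    end,
                    sums[chrom][b] / window,
                    int(nvar[chrom][b]),
                    bool(nvar[chrom][b] > 0 and ncalled[chrom][b] == 0),
                )
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "pi", "n_variants", "all_missing"])
    df.attrs["n_skipped"] = n_skipped
    return df


def _intergenic_space(
    layout: GenomeLayout, genes: list[GeneModel], pad: int = 1000
) -> dict[str, list[tuple[int, int]]]:
    """Complement of gene bodies (+- pad) per chromosome."""
    out: dict[str, list[tuple[int, int]]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.chroms}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((max(0, g.start - pad), g.end + pad))
    for chrom, ivs in by_chrom.items():
        length = layout.lengths[chrom]
        gaps = []
        cur = 0
        for a, b in merge_intervals(ivs):
            if a > cur:
                gaps.append((cur, min(a, length)))
            cur = max(cur, b)
        if cur < length:
            gaps.append((cur, length))
        out[chrom] = gaps
    return out


def sample_random_intergenic(
    regions: list[Interval],
    layout: GenomeLayout,
    genes: list[GeneModel],
    rng: np.random.Generator,
) -> list[Interval]:
    """Length-matched uniform sample of intergenic intervals, one per input
    region (sampled anywhere in intergenic space, any chromosome)."""
    space = _intergenic_space(layout, genes)
    flat = [(chrom, a, b) for chrom, gaps in space.items() for a, b in gaps]
    out = []
    for region in regions:
        length = region.length
        eligible = [(c, a, b) for c, a, b in flat if b - a >= length]
        if not eligible:
            raise ValueError(
                f"no intergenic gap can hold a region of length {length}"
            )
        weights = np.array([b - a - length + 1 for _c, a, b in eligible], dtype=float)
        k = int(rng.choice(len(eligible), p=weights / weights.sum()))
        c, a, b = eligible[k]
        start = int(rng.integers(a, b - length + 1))
        out.append(Interval(c, start, start + length))
    return out


def _region_mean_pi(windows: pd.DataFrame, region: Interval) -> float:
    sel = windows[
        (windows["chrom"] == region.chrom)
        & (windows["start"] < region.end)
        & (windows["end"] > region.start)
    ]
    if len(sel) == 0:
        return float("nan")
    return float(sel["pi"].mean())


def region_diversity_compare(
    windows: pd.DataFrame,
    regions: list[Interval],
    layout: GenomeLayout,
    genes: list[GeneModel],
    seed: int = 0,
) -> pd.DataFrame:
    """Mean window-pi of each region vs a length-matched random intergenic
    control region (seeded), with per-subgenome labels for breakdowns.

    Returns a DataFrame with one row per region: region_pi, random_pi,
    subgenome.
    """
    rng = np.random.default_rng(seed)
    controls = sample_random_intergenic(regions, layout, genes, rng)
    rows = []
    for region, ctrl in zip(regions, controls):
        rows.append(
            (
                region.chrom,
                region.start,
                region.end,
                layout.subgenome_of(region.chrom),
                _region_mean_pi(windows, region),
                _region_mean_pi(windows, ctrl),
            )
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "subgenome", "region_pi", "random_pi"]
    )


def coverage_saturation(
    events: pd.DataFrame,
    layout: GenomeLayout,
    subsample_sizes: list[int],
    bin_size: int = 10_000,
    cutoff: int = 5,
    seed: int = 0,
    nested: bool = True,
) -> pd.DataFrame:
    """Covered-bin fraction as a function of subsample size.

    A bin counts as covered at >= ``cutoff`` records.  With ``nested``
    (default) smaller subsamples are prefixes of larger ones under a single
    seeded shuffle, making the curve monotone by construction.  Requested
    sizes beyond the available records are capped with a warning.
    """
    total_bins = sum(-(-l // bin_size) for l in layout.lengths.values())
    offsets = {}
    off = 0
    for chrom, length in layout.lengths.items():
        offsets[chrom] = off
        off += -(-length // bin_size)
    bin_ids = (
        events["start"].to_numpy(np.int64) // bin_size
        + events["chrom"].map(offsets).to_numpy(np.int64)
    )
    rng = np.random.default_rng(seed)
    navail = len(bin_ids)
    order = rng.permutation(navail)
    rows = []
    for size in subsample_sizes:
        if size > navail:
            warnings.warn(f"requested subsample {size} > available {navail}; capped")
            size = navail
        if nested:
            take = bin_ids[order[:size]]
        else:
            take = bin_ids[rng.choice(navail, size=size, replace=False)]
        counts = np.bincount(take, minlength=total_bins)
        rows.append((size, float((counts >= cutoff).sum() / total_bins)))
    return pd.DataFrame(rows, columns=["subsample_size", "covered_fraction"])


def reporter_score(
    measurements: pd.DataFrame,
    blank_id: str,
    cutoff: float = 2.0,
) -> pd.DataFrame:
    """Score dual-luciferase reporter constructs.

    ``measurements`` needs columns construct_id, fluc, rluc.  Relative
    expression is fluc/rluc; relative intensity is that value normalized to
    the blank construct, and a construct is positive at >= ``cutoff``.
    """
    df = measurements.copy()
    if (df["rluc"] <= 0).any():
        raise ValueError("rluc must be > 0 for every construct")
    if blank_id not in set(df["construct_id"]):
        raise ValueError(f"blank construct {blank_id!r} not present")
    df["relative_expression"] = df["fluc"] / df["rluc"]
    blank = float(df.loc[df["construct_id"] == blank_id, "relative_expression"].iloc[0])
    df["relative_intensity"] = df["relative_expression"] / blank
    df["is_positive"] = df["relative_intensity"] >= cutoff
    return df


def mad_outlier_mask(x: np.ndarray, k: float = 3.0) -> np.ndarray:
    """True for points within median +- k*MAD (all True when MAD is 0)."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.ones(len(x), dtype=bool)
    return np.abs(x - med) <= k * mad


def activity_signal_correlation(
    activities: np.ndarray,
    densities: np.ndarray,
    mad_k: float = 3.0,
) -> tuple[float, np.ndarray]:
    """Pearson r between reporter activities and region signal densities
    after removing points outside median +- ``mad_k``*MAD on either variable.

    Returns (r, kept_mask); r is NaN when < 3 points survive or a variable is
    constant.
    """
    activities = np.asarray(activities, dtype=float)
    densities = np.asarray(densities, dtype=float)
    keep = mad_outlier_mask(activities, mad_k) & mad_outlier_mask(densities, mad_k)
    if keep.sum() < 3:
        return float("nan"), keep
    x, y = activities[keep], densities[keep]
    if x.std() == 0 or y.std() == 0:
        return float("nan"), keep
    r, _ = stats.pearsonr(x, y)
    return float(r), keep
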