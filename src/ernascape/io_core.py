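"""Genomic data model, format readers/writers, and interval arithmetic.

All internal coordinates are 0-based half-open on a declared chromosome set
(:class:`GenomeLayout`).  GFF3 is converted on read (1-based closed -> 0-based
half-open); BED passes through unchanged.  Overlap everywhere means ">= 1
shared base"; gene distances are edge-to-edge gaps between an interval and
gene bodies (both confidence classes).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "Interval",
    "GenomeLayout",
    "GeneModel",
    "ChromatinStateSegment",
    "IntervalIndex",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "read_homoeolog_map",
    "read_expression",
    "merge_intervals",
    "nearest_gene_distance",
]

VALID_STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """Raised for malformed input files (carries line context where known)."""


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class GenomeLayout:
    """Chromosome names, lengths and subgenome labels for one assembly."""

    def __init__(self, lengths: dict[str, int], subgenomes: dict[str, str] | None = None):
        if len(lengths) == 0:
            raise ValueError("empty genome layout")
        for name, length in lengths.items():
            if length <= 0:
                raise ValueError(f"chrom {name} has non-positive length {length}")
        self.lengths: dict[str, int] = dict(lengths)
        self.subgenomes: dict[str, str] = dict(subgenomes or {})

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def subgenome_of(self, chrom: str) -> str | None:
        return self.subgenomes.get(chrom)

    def validate_interval(self, iv: Interval) -> None:
        if iv.chrom not in self.lengths:
            raise ValueError(f"unknown chromosome {iv.chrom}")
        if iv.end > self.lengths[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chrom length "
                f"{self.lengths[iv.chrom]}"
            )

    def clip(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Clip [start, end) to the chromosome bounds."""
        length = self.lengths[chrom]
        return max(0, start), min(length, end)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GenomeLayout)
            and self.lengths == other.lengths
            and self.subgenomes == other.subgenomes
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GenomeLayout({len(self.lengths)} chroms, {self.total_length} bp)"


@dataclass
class GeneModel:
    """A gene body with exons, confidence class and homoeolog annotation."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    confidence: str = "high"
    homoeolog_group: str | None = None
    subgenome: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: need 0 <= start < end")
        if self.confidence not in {"high", "low"}:
            raise ValueError(f"gene {self.gene_id}: confidence must be high|low")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = self.start
        for (a, b) in self.exons:
            if a < self.start or b > self.end:
                raise ValueError(f"gene {self.gene_id}: exon [{a},{b}) outside gene span")
            if a >= b:
                raise ValueError(f"gene {self.gene_id}: empty exon [{a},{b})")
            if a < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = b

    @property
    def tss(self) -> int:
        """Position of the annotated transcription start site (0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Position of the annotated transcription end site (0-based)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (a0, b0), (a1, _b1) in zip(self.exons, self.exons[1:]):
            if b0 < a1:
                out.append((b0, a1))
        return out


@dataclass(frozen=True)
class ChromatinStateSegment:
    """One segment of a 15-state chromatin segmentation."""

    interval: Interval
    state_id: int

    def __post_init__(self) -> None:
        if not 1 <= self.state_id <= 15:
            raise ValueError(f"state_id must be in [1, 15], got {self.state_id}")


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals: list[tuple[int, int]], gap: int = 0) -> list[tuple[int, int]]:
    """Merge intervals whose gap is <= ``gap`` (0 merges touching/overlapping)."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


class IntervalIndex:
    """Per-chromosome sorted-array index supporting overlap and nearest-gap queries.

    Handles arbitrarily overlapping input intervals via a running prefix
    maximum of ends in start order.
    """

    def __init__(self, intervals: list[Interval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._idx: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            starts = np.array([p[0] for p in pairs], dtype=np.int64)
            ends = np.array([p[1] for p in pairs], dtype=np.int64)
            prefix_max_end = np.maximum.accumulate(ends)
            sorted_ends = np.sort(ends)
            self._idx[chrom] = (starts, ends, prefix_max_end, sorted_ends)

    def overlaps_any(self, chrom: str, start: int, end: int) -> bool:
        entry = self._idx.get(chrom)
        if entry is None:
            return False
        starts, _ends, prefix_max_end, _ = entry
        i = int(np.searchsorted(starts, end, side="left"))
        return i > 0 and int(prefix_max_end[i - 1]) > start

    def nearest_gap(self, chrom: str, start: int, end: int) -> float:
        """Minimal edge-to-edge gap to any indexed interval; 0 if overlapping;
        +inf if the chromosome holds no intervals."""
        entry = self._idx.get(chrom)
        if entry is None:
            return math.inf
        if self.overlaps_any(chrom, start, end):
            return 0.0
        starts, _ends, _pme, sorted_ends = entry
        best = math.inf
        # closest interval entirely to the right: smallest start >= end
        i = int(np.searchsorted(starts, end, side="left"))
        if i < len(starts):
            best = min(best, float(starts[i] - end))
        # closest interval entirely to the left: largest end <= start
        j = int(np.searchsorted(sorted_ends, start, side="right"))
        if j > 0:
            best = min(best, float(start - sorted_ends[j - 1]))
        return best


def nearest_gene_distance(iv: Interval, genes: "list[GeneModel] | IntervalIndex") -> float:
    """Edge-to-edge gap between ``iv`` and the nearest gene body on its
    chromosome (strand-agnostic; 0 if overlapping; +inf if the chromosome has
    no genes)."""
    if isinstance(genes, IntervalIndex):
        index = genes
    else:
        index = IntervalIndex([g.interval for g in genes])
    return index.nearest_gap(iv.chrom, iv.start, iv.end)


# ---------------------------------------------------------------------------
# Readers / writers (gz-transparent)
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Read a ``name<TAB>length[<TAB>subgenome]`` table into a GenomeLayout."""
    lengths: dict[str, int] = {}
    subgenomes: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 columns")
            name = parts[0]
            if name in lengths:
                raise FormatError(f"{path}:{lineno}: duplicate chrom {name}")
            lengths[name] = int(parts[1])
            if len(parts) >= 3:
                subgenomes[name] = parts[2]
    return GenomeLayout(lengths, subgenomes)


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for name, length in layout.lengths.items():
            sub = layout.subgenomes.get(name, "")
            fh.write(f"{name}\t{length}\t{sub}".rstrip("\t") + "\n")


def read_gff3(
    path: str | Path,
    layout: GenomeLayout | None = None,
    confidence_attr: str = "confidence",
) -> list[GeneModel]:
    """Parse gene/mRNA/exon features from GFF3 into :class:`GeneModel` records.

    Coordinates are converted from GFF3 1-based closed to 0-based half-open.
    Confidence is read from the ``confidence_attr`` attribute (``HC``/``high``
    -> high, ``LC``/``low`` -> low; absent -> high).
    """
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"failed to parse GFF3 {path}: {exc}") from exc
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = []
        for ex in db.children(g, featuretype="exon", order_by="start"):
            exons.append((ex.start - 1, ex.end))
        conf_raw = g.attributes.get(confidence_attr, ["HC"])[0].lower()
        confidence = "high" if conf_raw in {"hc", "high"} else "low"
        sub = None
        if layout is not None:
            sub = layout.subgenome_of(g.seqid)
        try:
            gene = GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                exons=exons,
                confidence=confidence,
                subgenome=sub,
            )
        except ValueError as exc:
            raise FormatError(f"{path}: gene {g.id}: {exc}") from exc
        if layout is not None:
            layout.validate_interval(gene.interval)
        genes.append(gene)
    return genes


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon features (inverse of :func:`read_gff3`)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x.chrom, x.start, x.gene_id)):
            conf = "HC" if g.confidence == "high" else "LC"
            fh.write(
                f"{g.chrom}\ternascape\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};confidence={conf}\n"
            )
            mrna_id = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\ternascape\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (a, b) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\ternascape\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )


_BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path, kind: str = "auto", layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Read BED3/BED6(+) into a DataFrame with canonical column names.

    ``kind``: ``bed3``, ``bed6``, ``auto`` (by column count) or ``states``
    (BED4 with an integer state label in column 4).  Strand ``.`` denotes
    unstranded.  Extra columns beyond BED6 are kept as ``extra_1``, ...
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    ncol = df.shape[1]
    if kind == "states":
        if ncol < 4:
            raise FormatError(f"{path}: states BED needs 4 columns")
        df = df.iloc[:, :4].copy()
        df.columns = ["chrom", "start", "end", "state_id"]
        df["state_id"] = df["state_id"].astype(int)
    else:
        want = 3 if kind == "bed3" else (6 if kind == "bed6" else min(ncol, 6))
        if ncol < want:
            raise FormatError(f"{path}: expected >= {want} columns, got {ncol}")
        cols = _BED6_COLS[:want] + [f"extra_{i}" for i in range(1, ncol - want + 1)]
        df.columns = cols[:ncol]
        if "strand" not in df.columns:
            df["strand"] = "."
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        raise FormatError(f"{path}: line {bad[0] + 1}: need 0 <= start < end")
    if "strand" in df.columns:
        badstrand = ~df["strand"].isin(list(VALID_STRANDS))
        if badstrand.any():
            raise FormatError(f"{path}: invalid strand value {df.loc[badstrand, 'strand'].iloc[0]!r}")
    if layout is not None:
        for chrom, end in zip(df["chrom"], df["end"]):
            if chrom not in layout.lengths or end > layout.lengths[chrom]:
                raise FormatError(f"{path}: interval off declared genome ({chrom}:{end})")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path: str | Path) -> pd.DataFrame:
    """Read BEDPE with a read-pair count column (column 8 if 8+ columns,
    else column 7)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    ncol = df.shape[1]
    if ncol < 7:
        raise FormatError(f"{path}: BEDPE needs >= 7 columns (6 coords + count)")
    base = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    if ncol >= 8:
        cols = base + ["name", "read_pairs"] + [f"extra_{i}" for i in range(1, ncol - 7)]
    else:
        cols = base + ["read_pairs"]
    df.columns = cols[:ncol]
    df["read_pairs"] = df["read_pairs"].astype(np.int64)
    if (df["read_pairs"] < 1).any():
        raise FormatError(f"{path}: read_pairs must be >= 1")
    return df


def read_homoeolog_map(path: str | Path) -> pd.DataFrame:
    """Read a homoeolog map TSV: ``group_id`` plus one gene-id column per
    subgenome (e.g. gene_A, gene_B, gene_D)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "group_id" not in df.columns or df.shape[1] < 3:
        raise FormatError(f"{path}: expected columns group_id + >=2 gene columns")
    return df


def read_expression(path: str | Path) -> dict[str, float]:
    """Read a two-column ``gene<TAB>level`` expression table."""
    df = pd.read_csv(path, sep="\t")
    gene_col, level_col = df.columns[:2]
    levels = df[level_col].astype(float)
    if (levels < 0).any():
        raise FormatError(f"{path}: negative expression level")
    return dict(zip(df[gene_col].astype(str), levels))
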