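"""Synthetic hexaploid toy genome with planted ground truth.

Generates every input the pipeline consumes — chromosome layout, gene models
arranged as 1:1:1 homoeolog triads on three subgenomes, a chromatin-state
segmentation with planted distal enhancer-like elements, strand-specific
5'-end read events with TSS-proximal pausing and exon-biased gene bodies,
histone peak panels correlated at true enhancer–promoter pairs, Hi-C
contacts supporting true pairs, a diploid population VCF with reduced
diversity inside eRNA regions, and reporter measurements — together with a
machine-readable truth record for every planted feature.

All randomness flows from ``SimConfig.seed`` through named child streams, so
the same config always produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (
    GeneModel,
    GenomeLayout,
    Interval,
    write_bed,
    write_chrom_sizes,
    write_gff3,
)
from .subgenome_bias import HomoeologPairRecord
from .target_assignment import PeakPanel, promoter_of

__all__ = [
    "SimConfig",
    "SimulatedGenome",
    "RegulatoryLandscape",
    "simulate_genome",
    "simulate_regulatory_landscape",
    "simulate_nascent_reads",
    "simulate_variants",
    "simulate_reporter",
    "simulate_pair_outcomes",
    "simulate_tss_tracks",
    "solve_category_probs",
    "write_all",
]

SUBGENOMES = ("A", "B", "D")


@dataclass
class SimConfig:
    """Study conditions for the toy hexaploid simulation.

    Defaults give 3 subgenomes x 1 chromosome x 5 Mb with 100 triads and 200
    enhancer-like elements: large enough for stable recovery statistics,
    small enough to generate in well under a minute.
    """

    seed: int = 0
    n_chroms_per_subgenome: int = 1
    chrom_length: int = 5_000_000
    n_triads: int = 100
    n_enhancers: int = 200
    frac_transcribed: float = 0.5
    frac_bidirectional: float = 0.35
    frac_expansion_tier: float = 0.05
    n_masked_units: int = 8
    n_free_units: int = 12
    genic_read_depth: float = 120.0      # mean reads per gene per replicate
    erna_read_depth: float = 30.0        # primary-strand reads per transcribed enhancer per replicate
    secondary_depth_frac: float = 0.8
    pausing_peak_weight: float = 0.4
    spike_mode_mass: float = 0.9
    background_rate: float = 0.002       # events / bp / strand / replicate
    n_replicates: int = 4
    planted_or: float = 1.5
    balanced_frac: float = 0.7
    target_expression_boost: float = 2.0
    panel_size: int = 8
    panel_noise_sd: float = 0.0
    hic_pairs_true: float = 5.0
    hic_pairs_false: float = 0.0
    n_vcf_samples: int = 20
    diversity_baseline: float = 0.002    # expected per-bp pi genome-wide
    erna_reduction: float = 0.5

    def validate(self) -> None:
        fracs = [
            self.frac_transcribed,
            self.frac_bidirectional,
            self.frac_expansion_tier,
            self.balanced_frac,
            self.spike_mode_mass,
            self.secondary_depth_frac,
            self.pausing_peak_weight,
            self.erna_reduction,
        ]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        rates = [
            self.genic_read_depth,
            self.erna_read_depth,
            self.background_rate,
            self.hic_pairs_true,
            self.hic_pairs_false,
            self.diversity_baseline,
            self.panel_noise_sd,
        ]
        if any(r < 0 for r in rates):
            raise ValueError("rates must be >= 0")
        if self.planted_or <= 0:
            raise ValueError("planted_or must be > 0")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def child_rng(self, *tag: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, *tag]))


@dataclass
class SimulatedGenome:
    layout: GenomeLayout
    genes: list[GeneModel]
    homoeolog_map: pd.DataFrame  # group_id, gene_A, gene_B, gene_D
    base_expression: dict[str, float]


@dataclass
class RegulatoryLandscape:
    states: pd.DataFrame                  # chrom, start, end, state_id
    coding_mask: pd.DataFrame             # chrom, start, end
    enhancers: list[dict]                 # planted-enhancer truth records
    other_units: list[dict]               # planted non-enhancer intergenic units
    panel: PeakPanel
    contacts: pd.DataFrame                # BEDPE columns + read_pairs
    expression: dict[str, float]          # final per-gene levels (after planting)
    gene_enh_flag: dict[str, bool]        # truth: gene targeted by transcribed enhancer
    pair_truth: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(cfg: SimConfig) -> SimulatedGenome:
    """Three subgenomes of jitter-syntenic 1:1:1 homoeolog triads."""
    cfg.validate()
    rng = cfg.child_rng(1)
    lengths: dict[str, int] = {}
    subs: dict[str, str] = {}
    for sub in SUBGENOMES:
        for i in range(1, cfg.n_chroms_per_subgenome + 1):
            name = f"chr{i}{sub}"
            lengths[name] = cfg.chrom_length
            subs[name] = sub
    layout = GenomeLayout(lengths, subs)

    per_chrom = -(-cfg.n_triads // cfg.n_chroms_per_subgenome)
    spacing = (cfg.chrom_length - 100_000) / (per_chrom + 1)
    if spacing < 25_000:
        raise ValueError(
            "gene density too high for non-overlapping placement; lower n_triads "
            "or increase chrom_length"
        )
    genes: list[GeneModel] = []
    map_rows = []
    for t in range(cfg.n_triads):
        chrom_i = t % cfg.n_chroms_per_subgenome + 1
        rank = t // cfg.n_chroms_per_subgenome
        base = 50_000 + (rank + 1) * spacing
        group = f"T{t + 1:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(2_000, 8_001))
        n_ex = int(rng.integers(2, 7))
        row: dict[str, str] = {"group_id": group}
        for sub in SUBGENOMES:
            chrom = f"chr{chrom_i}{sub}"
            jitter = int(rng.integers(-5_000, 5_001))
            start = int(base) + jitter
            end = start + length
            gene_id = f"G{t + 1:03d}{sub}"
            exons = _make_exons(rng, start, end, n_ex)
            conf = "high" if rng.random() < 0.9 else "low"
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    confidence=conf,
                    homoeolog_group=group,
                    subgenome=sub,
                )
            )
            row[f"gene_{sub}"] = gene_id
        map_rows.append(row)
    # validate non-overlap per chrom
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gl in by_chrom.items():
        gl.sort(key=lambda g: g.start)
        for g0, g1 in zip(gl, gl[1:]):
            if g1.start < g0.end:
                raise ValueError(f"gene placement overlap on {chrom}")
    expr_rng = cfg.child_rng(2)
    base_expression = {
        g.gene_id: float(expr_rng.lognormal(mean=math.log(5.0), sigma=1.0))
        for g in genes
    }
    return SimulatedGenome(layout, genes, pd.DataFrame(map_rows), base_expression)


def _make_exons(rng: np.random.Generator, start: int, end: int, n_ex: int) -> list[tuple[int, int]]:
    """Split [start, end) into n_ex exons separated by introns, first and last
    blocks exonic."""
    n_blocks = 2 * n_ex - 1
    w = rng.dirichlet(np.ones(n_blocks)) * (end - start)
    w = np.maximum(w, 20.0)
    w = w / w.sum() * (end - start)
    bounds = np.concatenate([[0], np.cumsum(w)]).astype(int) + start
    bounds[-1] = end
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(0, n_blocks, 2)]


# ---------------------------------------------------------------------------
# regulatory landscape
# ---------------------------------------------------------------------------

def solve_category_probs(planted_or: float, balanced_frac: float) -> tuple[float, float]:
    """Probabilities (enhancer-side dominant, free-side dominant) such that the
    mirrored 2x2 table (a, n-a, c, n-c) has expected odds ratio ``planted_or``
    with a ``balanced_frac`` share of balanced pairs."""
    s = 1.0 - balanced_frac
    w = planted_or
    if s <= 0:
        raise ValueError("balanced_frac must be < 1")
    if abs(w - 1.0) < 1e-12:
        return s / 2, s / 2
    A = 1.0 - w
    B = (1.0 + w) - s * (1.0 - w)
    C = -s * w
    disc = B * B - 4 * A * C
    p = (-B + math.sqrt(disc)) / (2 * A)
    if not 0 < p < s:
        p = (-B - math.sqrt(disc)) / (2 * A)
    r = s - p
    if not (0 < p < s and 0 < r < s):
        raise ValueError(f"no valid category probabilities for OR={w}, balanced={balanced_frac}")
    return p, r


def _safe_gaps(layout: GenomeLayout, genes: list[GeneModel], margin: int) -> dict[str, list[tuple[int, int]]]:
    gaps: dict[str, list[tuple[int, int]]] = {}
    by_chrom: dict[str, list[GeneModel]] = {c: [] for c in layout.chroms}
    for g in genes:
        by_chrom[g.chrom].append(g)
    for chrom, gl in by_chrom.items():
        gl.sort(key=lambda g: g.start)
        length = layout.lengths[chrom]
        cur = 5_000
        out = []
        for g in gl:
            a, b = cur, g.start - margin
            if b - a >= 4_000:
                out.append((a, b))
            cur = max(cur, g.end + margin)
        if length - 5_000 - cur >= 4_000:
            out.append((cur, length - 5_000))
        gaps[chrom] = out
    return gaps


def simulate_regulatory_landscape(cfg: SimConfig, genome: SimulatedGenome) -> RegulatoryLandscape:
    """Chromatin states, planted enhancers, peak panel, Hi-C and expression."""
    rng = cfg.child_rng(3)
    layout, genes = genome.layout, genome.genes
    gaps = _safe_gaps(layout, genes, margin=3_500)
    chroms = layout.chroms

    # --- reserve distinct safe gaps for enhancers / masked units / free units
    gap_pool = [(chrom, a, b) for chrom in chroms for a, b in gaps[chrom]]
    order = rng.permutation(len(gap_pool))
    needed = cfg.n_enhancers + cfg.n_masked_units + cfg.n_free_units
    if needed > len(gap_pool):
        raise ValueError(
            f"not enough intergenic space: need {needed} gaps, have {len(gap_pool)}; "
            "lower n_enhancers or raise chrom_length"
        )
    chosen = [gap_pool[i] for i in order[:needed]]
    enh_gaps = chosen[: cfg.n_enhancers]
    masked_gaps = chosen[cfg.n_enhancers : cfg.n_enhancers + cfg.n_masked_units]
    free_gaps = chosen[cfg.n_enhancers + cfg.n_masked_units :]

    # --- planted enhancers
    enhancers: list[dict] = []
    n_trans = int(round(cfg.frac_transcribed * cfg.n_enhancers))
    trans_flags = np.zeros(cfg.n_enhancers, dtype=bool)
    trans_flags[:n_trans] = True
    rng.shuffle(trans_flags)
    state_rows: list[tuple[str, int, int, int]] = []
    for k, ((chrom, a, b), is_trans) in enumerate(zip(enh_gaps, trans_flags)):
        length = int(rng.integers(500, 2_001))
        start = int(rng.integers(a + 500, b - 500 - length + 1))
        end = start + length
        # emit the element as 1-3 adjacent kept-state segments
        n_seg = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(start + 50, end - 50), size=n_seg - 1, replace=False)) if n_seg > 1 else np.array([], dtype=int)
        bounds = [start, *cuts.tolist(), end]
        for i in range(n_seg):
            state_rows.append((chrom, int(bounds[i]), int(bounds[i + 1]), int(rng.choice([5, 6, 7]))))
        rec: dict = {
            "id": f"T_ENH{k + 1:04d}",
            "chrom": chrom,
            "start": start,
            "end": end,
            "transcribed": bool(is_trans),
        }
        if is_trans:
            primary = "+" if rng.random() < 0.5 else "-"
            tss_p = int(rng.integers(start + 100, end - 100))
            rec["primary_strand"] = primary
            rec["tss_primary"] = tss_p
            rec["bidirectional"] = bool(rng.random() < cfg.frac_bidirectional)
            if rec["bidirectional"]:
                lo, hi = start + 60, end - 60
                tss_s = int(rng.integers(lo, hi))
                rec["tss_secondary"] = tss_s
        enhancers.append(rec)

    # --- planted non-enhancer intergenic units (masked + free)
    other_units: list[dict] = []
    for tag, gap_list in (("masked", masked_gaps), ("free", free_gaps)):
        for chrom, a, b in gap_list:
            pos = int(rng.integers(a + 500, b - 500))
            strand = "+" if rng.random() < 0.5 else "-"
            other_units.append({"kind": tag, "chrom": chrom, "tss": pos, "strand": strand})

    # --- coding-transcript mask covers the masked units
    mask_rows = [
        (u["chrom"], u["tss"] - 300, u["tss"] + 300)
        for u in other_units
        if u["kind"] == "masked"
    ]
    coding_mask = pd.DataFrame(mask_rows, columns=["chrom", "start", "end"])

    # --- near-gene kept-state decoys (must be discarded by the 3-kb rule)
    #     and other-state decoys anywhere
    segs_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for chrom, s, e, _st in state_rows:
        segs_by_chrom[chrom].append((s, e))
    gene_sample = rng.choice(len(genes), size=min(20, len(genes)), replace=False)
    for gi in gene_sample:
        g = genes[int(gi)]
        s = g.end + int(rng.integers(500, 1_500))
        e = s + int(rng.integers(400, 1_000))
        if e < layout.lengths[g.chrom] - 5_000 and not _conflicts(segs_by_chrom[g.chrom], s, e):
            state_rows.append((g.chrom, s, e, int(rng.choice([5, 6, 7]))))
            segs_by_chrom[g.chrom].append((s, e))
    other_states = [st for st in range(1, 16) if st not in (5, 6, 7)]
    for _ in range(2 * cfg.n_enhancers):
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(5_000, layout.lengths[chrom] - 10_000))
        e = s + int(rng.integers(500, 3_000))
        if not _conflicts(segs_by_chrom[chrom], s, e):
            state_rows.append((chrom, s, e, int(rng.choice(other_states))))
            segs_by_chrom[chrom].append((s, e))
    states = (
        pd.DataFrame(state_rows, columns=["chrom", "start", "end", "state_id"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )

    # --- target genes for transcribed enhancers
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for gl in genes_by_chrom.values():
        gl.sort(key=lambda g: g.start)
    for rec in enhancers:
        if not rec["transcribed"]:
            rec["targets"] = []
            continue
        cands = genes_by_chrom[rec["chrom"]]
        dists = np.array(
            [_edge_dist(rec["start"], rec["end"], g.start, g.end) for g in cands]
        )
        expansion = rng.random() < cfg.frac_expansion_tier
        far = np.nonzero((dists > 500_000) & (dists <= 2_000_000))[0]
        near = np.nonzero(dists <= 500_000)[0]
        if expansion and len(far) > 0:
            pick = rng.choice(far, size=1, replace=False)
            rec["tier"] = "expanded_2Mb"
        else:
            n_t = min(int(rng.integers(1, 3)), len(near))
            pick = rng.choice(near, size=n_t, replace=False)
            rec["tier"] = "primary_500kb"
        rec["targets"] = sorted(cands[int(i)].gene_id for i in pick)

    gene_enh_flag = {g.gene_id: False for g in genes}
    for rec in enhancers:
        for gid in rec.get("targets", []):
            gene_enh_flag[gid] = True  # targets are always on the enhancer's chromosome

    # --- peak panel: one peak per enhancer + one per gene promoter;
    #     connected components of the true-link graph share a latent vector
    panel_rng = cfg.child_rng(4)
    comp = _link_components(enhancers, genes)
    n_comp = max(comp.values(), default=-1) + 1
    latents = panel_rng.uniform(1.0, 10.0, size=(n_comp, cfg.panel_size))
    peak_rows = []
    signal_rows = []
    for rec in enhancers:
        peak_rows.append((rec["chrom"], rec["start"], rec["end"]))
        signal_rows.append(_panel_vector(panel_rng, comp.get(("E", rec["id"])), latents, cfg))
    for g in sorted(genes, key=lambda g: g.gene_id):
        prom = promoter_of(g, layout)
        peak_rows.append((prom.chrom, prom.start, prom.end))
        signal_rows.append(_panel_vector(panel_rng, comp.get(("G", g.gene_id)), latents, cfg))
    panel = PeakPanel(
        pd.DataFrame(peak_rows, columns=["chrom", "start", "end"]),
        np.vstack(signal_rows),
        [f"sample{i + 1}" for i in range(cfg.panel_size)],
    )

    # --- Hi-C: every true pair carries >= 1 read pair; false contacts optional
    hic_rng = cfg.child_rng(5)
    gene_lookup = {g.gene_id: g for g in genes}
    contact_rows = []
    for rec in enhancers:
        for gid in rec.get("targets", []):
            prom = promoter_of(gene_lookup[gid], layout)
            pairs = 1 + int(hic_rng.poisson(max(0.0, cfg.hic_pairs_true - 1.0)))
            contact_rows.append(
                (rec["chrom"], rec["start"], rec["end"], prom.chrom, prom.start, prom.end,
                 f"{rec['id']}:{gid}", pairs)
            )
    if cfg.hic_pairs_false > 0:
        true_pairs = {(r["id"], gid) for r in enhancers for gid in r.get("targets", [])}
        for rec in enhancers:
            cands = genes_by_chrom[rec["chrom"]]
            for g in cands:
                if (rec["id"], g.gene_id) in true_pairs:
                    continue
                if _edge_dist(rec["start"], rec["end"], g.start, g.end) > 2_000_000:
                    continue
                k = int(hic_rng.poisson(cfg.hic_pairs_false))
                if k >= 1:
                    prom = promoter_of(g, layout)
                    contact_rows.append(
                        (rec["chrom"], rec["start"], rec["end"], prom.chrom, prom.start,
                         prom.end, f"noise:{rec['id']}:{g.gene_id}", k)
                    )
    contacts = pd.DataFrame(
        contact_rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "read_pairs"],
    )

    # --- expression: base levels, target boost, then planted dominance for
    #     discordant homoeolog pairs at the configured odds ratio
    expression = dict(genome.base_expression)
    for gid, flag in gene_enh_flag.items():
        if flag:
            expression[gid] *= cfg.target_expression_boost
    pair_truth = _plant_dominance(cfg, genome, gene_enh_flag, expression)

    return RegulatoryLandscape(
        states=states,
        coding_mask=coding_mask,
        enhancers=enhancers,
        other_units=other_units,
        panel=panel,
        contacts=contacts,
        expression=expression,
        gene_enh_flag=gene_enh_flag,
        pair_truth=pair_truth,
    )


def _conflicts(segments: list[tuple[int, int]], s: int, e: int) -> bool:
    return any(s < b and a < e for a, b in segments)


def _edge_dist(s1: int, e1: int, s2: int, e2: int) -> float:
    if s1 < e2 and s2 < e1:
        return 0.0
    return float(s2 - e1) if s2 >= e1 else float(s1 - e2)


def _link_components(enhancers: list[dict], genes: list[GeneModel]) -> dict[tuple[str, str], int]:
    """Union-find over the true enhancer-gene link graph; returns node -> component."""
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for rec in enhancers:
        find(("E", rec["id"]))
        for gid in rec.get("targets", []):
            union(("E", rec["id"]), ("G", gid))
    roots: dict[tuple[str, str], int] = {}
    out = {}
    for node in parent:
        r = find(node)
        if r not in roots:
            roots[r] = len(roots)
        out[node] = roots[r]
    return out


def _panel_vector(
    rng: np.random.Generator,
    comp_id: int | None,
    latents: np.ndarray,
    cfg: SimConfig,
) -> np.ndarray:
    """Latent-plus-noise signal vector; unlinked nodes get independent vectors.

    The noise draw is consumed unconditionally so that sweeping
    ``panel_noise_sd`` under one seed reuses identical noise realizations
    (common random numbers).
    """
    eps = rng.standard_normal(cfg.panel_size)
    indep = rng.uniform(1.0, 10.0, cfg.panel_size)
    if comp_id is None:
        return indep
    return np.clip(latents[comp_id] + cfg.panel_noise_sd * eps, 0.0, None)


def _plant_dominance(
    cfg: SimConfig,
    genome: SimulatedGenome,
    gene_enh_flag: dict[str, bool],
    expression: dict[str, float],
) -> list[dict]:
    """Rewrite expression of discordant homoeolog pairs so that the
    enhancer-bearing side is dominant with the probability implied by
    ``planted_or`` (mirrored-table construction, ``balanced_frac`` balanced)."""
    rng = cfg.child_rng(6)
    p_enh, p_free = solve_category_probs(cfg.planted_or, cfg.balanced_frac)
    pinned: set[str] = set()
    truth = []
    pairs = [(a, b) for a, b in (("A", "B"), ("A", "D"), ("B", "D"))]
    for _, row in genome.homoeolog_map.iterrows():
        for sa, sb in pairs:
            ga, gb = row[f"gene_{sa}"], row[f"gene_{sb}"]
            fa, fb = gene_enh_flag[ga], gene_enh_flag[gb]
            if fa == fb:
                continue
            u = rng.random()
            if u < p_enh:
                category = "enh_dominant"
            elif u < p_enh + p_free:
                category = "free_dominant"
            else:
                category = "balanced"
            enh_gene, free_gene = (ga, gb) if fa else (gb, ga)
            base = math.sqrt(expression[enh_gene] * expression[free_gene])
            fold = math.sqrt(float(rng.uniform(2.5, 6.0)))
            if enh_gene in pinned and free_gene in pinned:
                truth.append({"pair": (ga, gb), "category": "unset", "subgenomes": (sa, sb)})
                continue
            if category == "enh_dominant":
                hi, lo = enh_gene, free_gene
                _set_pair(expression, pinned, hi, lo, base, fold)
            elif category == "free_dominant":
                hi, lo = free_gene, enh_gene
                _set_pair(expression, pinned, hi, lo, base, fold)
            else:
                ratio = math.sqrt(float(rng.uniform(0.7, 1.4)))
                if enh_gene not in pinned:
                    ref = expression[free_gene]
                    expression[enh_gene] = ref * ratio
                else:
                    expression[free_gene] = expression[enh_gene] * ratio
                pinned.update((enh_gene, free_gene))
            truth.append({"pair": (ga, gb), "category": category, "subgenomes": (sa, sb)})
    return truth


def _set_pair(expression, pinned, hi, lo, base, fold) -> None:
    if hi in pinned:
        expression[lo] = expression[hi] / (fold * fold)
    elif lo in pinned:
        expression[hi] = expression[lo] * (fold * fold)
    else:
        expression[hi] = base * fold
        expression[lo] = base / fold
    pinned.update((hi, lo))


# ---------------------------------------------------------------------------
# nascent reads
# ---------------------------------------------------------------------------

def _spike_positions(
    rng: np.random.Generator, n: int, mode: int, strand: str, mode_mass: float, spread: int
) -> np.ndarray:
    """n 5'-end positions: ``mode_mass`` at the mode, the rest geometric decay
    downstream of the mode with respect to ``strand``."""
    at_mode = rng.random(n) < mode_mass
    offs = np.minimum(rng.geometric(0.1, size=n), spread)
    offs[at_mode] = 0
    if strand == "-":
        offs = -offs
    return mode + offs


def simulate_nascent_reads(
    cfg: SimConfig,
    genome: SimulatedGenome,
    landscape: RegulatoryLandscape,
    n_replicates: int | None = None,
) -> list[pd.DataFrame]:
    """Per-replicate single-base 5'-end event BED6 frames.

    Genic reads mix a TSS-proximal pausing spike with body reads at a 3:1
    exon:intron per-bp density ratio on the gene strand; transcribed
    enhancers get a primary-strand spike at the planted eRNA TSS (plus a
    secondary-strand spike when bidirectional); both strands carry uniform
    Poisson background.  Replicates are independent draws from shared
    expected rates.
    """
    n_replicates = n_replicates or cfg.n_replicates
    layout = genome.layout
    mean_expr = float(np.mean(list(landscape.expression.values())))
    frames = []
    for rep in range(n_replicates):
        rng = cfg.child_rng(7, rep)
        chroms: list[np.ndarray] = []
        rows_chrom: list[str] = []
        rows_pos: list[np.ndarray] = []
        rows_strand: list[str] = []

        def emit(chrom: str, pos: np.ndarray, strand: str) -> None:
            if len(pos):
                pos = np.clip(pos, 0, layout.lengths[chrom] - 1)
                rows_chrom.append(chrom)
                rows_pos.append(pos.astype(np.int64))
                rows_strand.append(strand)

        # background
        for chrom, length in layout.lengths.items():
            for strand in ("+", "-"):
                n_bg = rng.poisson(cfg.background_rate * length)
                emit(chrom, rng.integers(0, length, size=n_bg), strand)
        # genic
        for g in genome.genes:
            lam = cfg.genic_read_depth * landscape.expression[g.gene_id] / mean_expr
            n = rng.poisson(lam)
            if n == 0:
                continue
            m = rng.binomial(n, cfg.pausing_peak_weight)
            emit(g.chrom, _spike_positions(rng, m, g.tss, g.strand, cfg.spike_mode_mass, 150), g.strand)
            body = n - m
            if body:
                exon_len = sum(b - a for a, b in g.exons)
                intron_len = (g.end - g.start) - exon_len
                p_exon = 3 * exon_len / (3 * exon_len + intron_len) if intron_len else 1.0
                in_exon = rng.random(body) < p_exon
                pos = np.empty(body, dtype=np.int64)
                if in_exon.any():
                    pos[in_exon] = _uniform_in(rng, g.exons, int(in_exon.sum()))
                if (~in_exon).any():
                    introns = g.introns() or g.exons
                    pos[~in_exon] = _uniform_in(rng, introns, int((~in_exon).sum()))
                emit(g.chrom, pos, g.strand)
        # eRNA at transcribed enhancers
        for rec in landscape.enhancers:
            if not rec["transcribed"]:
                continue
            primary = rec["primary_strand"]
            n_p = rng.poisson(cfg.erna_read_depth)
            emit(rec["chrom"], _spike_positions(rng, n_p, rec["tss_primary"], primary, cfg.spike_mode_mass, 50), primary)
            if rec["bidirectional"]:
                secondary = "-" if primary == "+" else "+"
                n_s = rng.poisson(cfg.erna_read_depth * cfg.secondary_depth_frac)
                emit(rec["chrom"], _spike_positions(rng, n_s, rec["tss_secondary"], secondary, cfg.spike_mode_mass, 50), secondary)
        # planted non-enhancer intergenic units
        for u in landscape.other_units:
            n_u = rng.poisson(cfg.erna_read_depth)
            emit(u["chrom"], _spike_positions(rng, n_u, u["tss"], u["strand"], cfg.spike_mode_mass, 50), u["strand"])

        chrom_col = np.concatenate(
            [np.repeat(c, len(p)) for c, p in zip(rows_chrom, rows_pos)]
        )
        pos_col = np.concatenate(rows_pos)
        strand_col = np.concatenate(
            [np.repeat(s, len(p)) for s, p in zip(rows_strand, rows_pos)]
        )
        df = pd.DataFrame(
            {
                "chrom": chrom_col,
                "start": pos_col,
                "end": pos_col + 1,
                "name": ".",
                "score": 0,
                "strand": strand_col,
            }
        ).sort_values(["chrom", "start", "strand"], kind="stable").reset_index(drop=True)
        frames.append(df)
    return frames


def _uniform_in(rng: np.random.Generator, intervals: list[tuple[int, int]], n: int) -> np.ndarray:
    lens = np.array([b - a for a, b in intervals], dtype=float)
    starts = np.array([a for a, _ in intervals])
    which = rng.choice(len(intervals), size=n, p=lens / lens.sum())
    offs = (rng.random(n) * lens[which]).astype(np.int64)
    return starts[which] + offs


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def simulate_variants(cfg: SimConfig, genome: SimulatedGenome, landscape: RegulatoryLandscape, path: str | Path) -> Path:
    """Write a diploid multi-sample VCF with expected per-bp pi equal to
    ``diversity_baseline`` genome-wide and ``baseline * (1 - erna_reduction)``
    inside transcribed (eRNA) enhancer regions."""
    rng = cfg.child_rng(8)
    layout = genome.layout
    # E[2 f (1 - f)] for f ~ Uniform(0.05, 0.5)
    mean_het = 0.365
    site_rate = cfg.diversity_baseline / mean_het
    erna_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for rec in landscape.enhancers:
        if rec["transcribed"]:
            erna_by_chrom.setdefault(rec["chrom"], []).append((rec["start"], rec["end"]))
    samples = [f"S{i + 1:02d}" for i in range(cfg.n_vcf_samples)]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in layout.lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for chrom, length in layout.lengths.items():
            n_sites = rng.poisson(site_rate * length)
            pos = np.sort(rng.choice(length, size=n_sites, replace=False))
            keep = np.ones(len(pos), dtype=bool)
            for a, b in erna_by_chrom.get(chrom, []):
                inside = (pos >= a) & (pos < b)
                keep[inside] &= rng.random(int(inside.sum())) >= cfg.erna_reduction
            pos = pos[keep]
            freqs = rng.uniform(0.05, 0.5, size=len(pos))
            alleles = rng.random((len(pos), cfg.n_vcf_samples, 2)) < freqs[:, None, None]
            bases = np.array(["A", "C", "G", "T"])
            for i, p in enumerate(pos):
                ref, alt = rng.choice(4, size=2, replace=False)
                gts = "\t".join(f"{int(a)}/{int(b)}" for a, b in alleles[i])
                fh.write(
                    f"{chrom}\t{int(p) + 1}\t.\t{bases[ref]}\t{bases[alt]}\t.\tPASS\t.\tGT\t{gts}\n"
                )
    return path


# ---------------------------------------------------------------------------
# reporter assay
# ---------------------------------------------------------------------------

def simulate_reporter(
    cfg: SimConfig,
    landscape: RegulatoryLandscape,
    n_constructs: int = 36,
    activity_slope: float = 2.5,
    activity_noise_sd: float = 0.3,
) -> pd.DataFrame:
    """Dual-luciferase measurements for a sample of enhancer candidates.

    Planted activity (relative intensity) rises linearly with the planted
    eRNA depth signal, so activity correlates with enhancer transcription;
    includes a blank (intensity 1) and a negative control (intensity 1.6).
    """
    rng = cfg.child_rng(9)
    enh = list(landscape.enhancers)
    order = rng.permutation(len(enh))[:n_constructs]
    rows = []
    blank_rel = 2.0
    for i in order:
        rec = enh[int(i)]
        signal = 1.0 if rec["transcribed"] else 0.0
        intensity = max(
            0.1, 0.9 + activity_slope * signal + float(rng.normal(0, activity_noise_sd))
        )
        rluc = float(rng.uniform(0.8, 1.2))
        rows.append((rec["id"], intensity * blank_rel * rluc, rluc, "candidate", signal))
    for cid, intensity in (("blank", 1.0), ("negative", 1.6)):
        rluc = 1.0
        rows.append((cid, intensity * blank_rel * rluc, rluc, cid, 0.0))
    return pd.DataFrame(rows, columns=["construct_id", "fluc", "rluc", "role", "planted_signal"])


# ---------------------------------------------------------------------------
# focused generators for estimator-level checks
# ---------------------------------------------------------------------------

def simulate_pair_outcomes(
    n_pairs: int,
    planted_or: float,
    balanced_frac: float,
    rng: np.random.Generator,
) -> list[HomoeologPairRecord]:
    """Discordant homoeolog pair records drawn directly from the planted
    three-category model (enhancer-side dominant / free-side dominant /
    balanced), for estimator calibration at scale."""
    p_enh, p_free = solve_category_probs(planted_or, balanced_frac)
    u = rng.random(n_pairs)
    records = []
    for i in range(n_pairs):
        if u[i] < p_enh:
            ea, eb = 4.0, 1.0
        elif u[i] < p_enh + p_free:
            ea, eb = 1.0, 4.0
        else:
            ea, eb = 3.0, 3.0
        records.append(
            HomoeologPairRecord(
                gene_a=f"a{i}", gene_b=f"b{i}", expr_a=ea, expr_b=eb,
                enh_a=True, enh_b=False,
            )
        )
    return records


def simulate_tss_tracks(
    n_tss: int = 200,
    depth: float = 25.0,
    background_rate: float = 0.01,
    n_replicates: int = 4,
    genome_length: int = 5_000_000,
    seed: int = 0,
    mode_mass: float = 0.9,
) -> tuple[GenomeLayout, list[pd.DataFrame], list[tuple[str, int, str]]]:
    """Planted-TSS tracks on a single-chromosome genome for detection checks.

    Returns (layout, per-replicate event frames, truth (chrom, pos, strand)).
    Planted sites are spaced > 10 kb apart so each maps to its own cluster.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    chrom = "chrT"
    layout = GenomeLayout({chrom: genome_length}, {chrom: "A"})
    spacing = (genome_length - 20_000) // n_tss
    if spacing <= 10_000:
        raise ValueError("genome too small for requested TSS count")
    truth = []
    for i in range(n_tss):
        pos = 10_000 + i * spacing + int(rng.integers(0, spacing // 2))
        strand = "+" if rng.random() < 0.5 else "-"
        truth.append((chrom, pos, strand))
    frames = []
    for _rep in range(n_replicates):
        pos_list, strand_list = [], []
        for strand in ("+", "-"):
            n_bg = rng.poisson(background_rate * genome_length)
            pos_list.append(rng.integers(0, genome_length, size=n_bg))
            strand_list.extend([strand] * n_bg)
        for chrom_t, pos, strand in truth:
            n = rng.poisson(depth)
            pos_list.append(_spike_positions(rng, n, pos, strand, mode_mass, 50))
            strand_list.extend([strand] * n)
        allpos = np.clip(np.concatenate(pos_list), 0, genome_length - 1).astype(np.int64)
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "start": allpos,
                "end": allpos + 1,
                "name": ".",
                "score": 0,
                "strand": np.array(strand_list),
            }
        ).sort_values(["start", "strand"], kind="stable").reset_index(drop=True)
        frames.append(df)
    return layout, frames, truth


# ---------------------------------------------------------------------------
# file emission + truth manifest
# ---------------------------------------------------------------------------

def write_all(cfg: SimConfig, outdir: str | Path) -> dict:
    """Generate the full dataset and write every pipeline input plus
    ``truth.json`` and ``manifest.json`` to ``outdir``.  Returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(cfg)
    landscape = simulate_regulatory_landscape(cfg, genome)
    reads = simulate_nascent_reads(cfg, genome, landscape)

    write_chrom_sizes(genome.layout, outdir / "chrom.sizes")
    write_gff3(genome.genes, outdir / "genes.gff3")
    genome.homoeolog_map.to_csv(outdir / "homoeologs.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(landscape.expression.items()), columns=["gene_id", "level"]
    ).to_csv(outdir / "expression.tsv", sep="\t", index=False)
    write_bed(landscape.states, outdir / "states.bed")
    write_bed(landscape.coding_mask, outdir / "mask.bed")
    read_files = []
    for i, df in enumerate(reads, 1):
        fn = outdir / f"reads.rep{i}.bed"
        write_bed(df, fn)
        read_files.append(fn.name)
    write_bed(landscape.panel.peaks, outdir / "panel.bed")
    pd.DataFrame(
        landscape.panel.signals,
        columns=landscape.panel.samples,
        index=[f"peak{i + 1}" for i in range(len(landscape.panel.peaks))],
    ).to_csv(outdir / "panel.tsv", sep="\t")
    write_bed(landscape.contacts, outdir / "contacts.bedpe")
    simulate_variants(cfg, genome, landscape, outdir / "variants.vcf")
    simulate_reporter(cfg, landscape).to_csv(outdir / "reporter.tsv", sep="\t", index=False)

    truth = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "enhancers": landscape.enhancers,
        "other_units": landscape.other_units,
        "gene_enh_flag": landscape.gene_enh_flag,
        "pair_truth": [
            {"pair": list(t["pair"]), "category": t["category"], "subgenomes": list(t["subgenomes"])}
            for t in landscape.pair_truth
        ],
        "expression": landscape.expression,
    }
    _check_truth_consistency(truth, landscape)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "files": sorted(
            ["chrom.sizes", "genes.gff3", "homoeologs.tsv", "expression.tsv",
             "states.bed", "mask.bed", "panel.bed", "panel.tsv", "contacts.bedpe",
             "variants.vcf", "reporter.tsv", "truth.json"] + read_files
        ),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _check_truth_consistency(truth: dict, landscape: RegulatoryLandscape) -> None:
    ids = [e["id"] for e in truth["enhancers"]]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate planted enhancer ids")
    gene_ids = set(truth["gene_enh_flag"])
    for e in truth["enhancers"]:
        for gid in e.get("targets", []):
            if gid not in gene_ids:
                raise ValueError(f"planted target {gid} is not a simulated gene")
    n_links = sum(len(e.get("targets", [])) for e in truth["enhancers"])
    if n_links != len([c for c in landscape.contacts["name"] if not str(c).startswith("noise")]):
        raise ValueError("planted links and true Hi-C contacts disagree")
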