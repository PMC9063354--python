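"""End-to-end orchestration: reads -> tracks -> TCs -> enhancers -> targets -> OR.

Thin glue over the stage modules, used by the CLI and by recovery tests.
Each stage is also usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .enhancer_classification import (
    EnhancerElement,
    assign_transcription,
    classify_direction,
    define_enhancer_like,
)
from .intergenic_annotation import classify_tcs
from .io_core import (
    GeneModel,
    GenomeLayout,
    read_bed,
    read_bedpe,
    read_chrom_sizes,
    read_expression,
    read_gff3,
    read_homoeolog_map,
)
from .signal_model import StrandTrack, build_track, merge_replicates
from .subgenome_bias import (
    HomoeologPairRecord,
    OddsRatioResult,
    bias_call,
    build_pairs,
    contingency,
    merged_dominance_or,
    odds_ratio,
)
from .target_assignment import EnhancerTargetLink, PeakPanel, assign_targets
from .tss_calling import (
    TssCluster,
    call_tss,
    merge_clusters,
    quantify_tc,
    replicate_consistent,
)

SUBGENOME_PAIRS = (("A", "B"), ("A", "D"), ("B", "D"))


@dataclass
class NascentResult:
    """Outputs of the track -> TC -> enhancer stages."""

    merged_track: StrandTrack
    tcs: list[TssCluster]
    intergenic_tcs: list[TssCluster]
    elements: list[EnhancerElement]


@dataclass
class FullResult(NascentResult):
    links: list[EnhancerTargetLink] = field(default_factory=list)
    pair_records: dict[tuple[str, str], list[HomoeologPairRecord]] = field(default_factory=dict)
    per_pair_or: dict[tuple[str, str], OddsRatioResult] = field(default_factory=dict)
    merged_or: OddsRatioResult | None = None


def run_nascent_stages(
    layout: GenomeLayout,
    genes: list[GeneModel],
    replicate_events: list[pd.DataFrame],
    states: pd.DataFrame,
    coding_mask: pd.DataFrame | None,
    alpha: float = 1e-6,
    min_count: int = 5,
    merge_dist: int = 3000,
) -> NascentResult:
    """Replicate tracks through replicate-consistent, classified, quantified
    TCs and direction-classified enhancer elements."""
    tracks = [build_track(ev, layout) for ev in replicate_events]
    merged = merge_replicates(tracks)
    rep_calls = [
        call_tss(t, alpha=alpha, min_count=min_count, replicate_id=str(i + 1))
        for i, t in enumerate(tracks)
    ]
    merged_calls = call_tss(merged, alpha=alpha, min_count=min_count, replicate_id="merged")
    clusters = merge_clusters(merged_calls, merge_dist=merge_dist)
    consistent = replicate_consistent(clusters, rep_calls)
    for tc in consistent:
        quantify_tc(tc, merged)
    classify_tcs(consistent, genes, coding_mask)
    intergenic = [tc for tc in consistent if tc.genomic_class == "intergenic"]
    elements = define_enhancer_like(states, genes)
    assign_transcription(elements, intergenic)
    for el in elements:
        if el.status == "transcribed":
            classify_direction(el, merged, intergenic)
    return NascentResult(merged, consistent, intergenic, elements)


def run_full_pipeline(
    layout: GenomeLayout,
    genes: list[GeneModel],
    replicate_events: list[pd.DataFrame],
    states: pd.DataFrame,
    coding_mask: pd.DataFrame | None,
    panel: PeakPanel,
    contacts: pd.DataFrame,
    expression: dict[str, float],
    fc_threshold: float = 2.0,
    min_expr: float = 0.5,
    **kwargs,
) -> FullResult:
    """Nascent stages plus target assignment and the homoeolog OR analysis."""
    nas = run_nascent_stages(layout, genes, replicate_events, states, coding_mask, **kwargs)
    links = assign_targets(nas.elements, genes, panel, contacts, layout)
    enh_chroms = {el.id: el.chrom for el in nas.elements}
    result = FullResult(
        merged_track=nas.merged_track,
        tcs=nas.tcs,
        intergenic_tcs=nas.intergenic_tcs,
        elements=nas.elements,
        links=links,
    )
    for pair in SUBGENOME_PAIRS:
        records = build_pairs(genes, expression, links, enh_chroms, pair)
        for r in records:
            bias_call(r, fc_threshold=fc_threshold, min_expr=min_expr)
        result.pair_records[pair] = records
        if records:
            result.per_pair_or[pair] = odds_ratio(contingency(records), paired=True)
    nonempty = [r for r in result.pair_records.values() if r]
    if nonempty:
        result.merged_or = merged_dominance_or(nonempty, fc_threshold=fc_threshold, min_expr=min_expr)
    return result


def load_simulated_inputs(indir: str | Path) -> dict:
    """Load a `write_all` output directory into in-memory pipeline inputs."""
    indir = Path(indir)
    layout = read_chrom_sizes(indir / "chrom.sizes")
    genes = read_gff3(indir / "genes.gff3", layout=layout)
    homoeologs = read_homoeolog_map(indir / "homoeologs.tsv")
    by_id = {g.gene_id: g for g in genes}
    for _, row in homoeologs.iterrows():
        for col in homoeologs.columns:
            if col.startswith("gene_") and row[col] in by_id:
                by_id[row[col]].homoeolog_group = row["group_id"]
                by_id[row[col]].subgenome = col.removeprefix("gene_")
    reads = sorted(indir.glob("reads.rep*.bed"))
    return {
        "layout": layout,
        "genes": genes,
        "replicate_events": [read_bed(p, kind="bed6", layout=layout) for p in reads],
        "states": read_bed(indir / "states.bed", kind="states"),
        "coding_mask": read_bed(indir / "mask.bed", kind="bed3"),
        "panel": PeakPanel.from_files(str(indir / "panel.bed"), str(indir / "panel.tsv")),
        "contacts": read_bedpe(indir / "contacts.bedpe"),
        "expression": read_expression(indir / "expression.tsv"),
    }
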