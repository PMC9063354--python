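"""Homoeolog expression bias versus enhancer association: 2x2 odds ratios.

For each pair of subgenomes, 1:1 homoeolog pairs are restricted to the
*discordant* set — one homoeolog associated with >= 1 transcribed enhancer on
its own chromosome, the other not.  Each pair is then called for expression
dominance (fold-change gate), and the association between "carries the
enhancer" and "is the dominant copy" is summarised as an odds ratio with a
95% CI on the log scale.

The table rows are mirrored classifications of the same n pairs
(a = enhancer-side dominant, b = n - a; c = enhancer-free-side dominant,
d = n - c), so the Woolf variance 1/a+1/b+1/c+1/d understates Var(log OR);
``paired=True`` adds the multinomial delta-method cross term 2n/(b*d), which
is exact in the no-balanced-pairs limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_core import GeneModel
from .target_assignment import EnhancerTargetLink

__all__ = [
    "HomoeologPairRecord",
    "OddsRatioResult",
    "build_pairs",
    "bias_call",
    "contingency",
    "odds_ratio",
    "merged_dominance_or",
]


@dataclass
class HomoeologPairRecord:
    """A 1:1 homoeolog pair; by construction gene_a carries the enhancer flag
    asymmetry of interest only after discordance filtering."""

    gene_a: str
    gene_b: str
    expr_a: float
    expr_b: float
    enh_a: bool
    enh_b: bool
    bias: str | None = None  # a_higher | b_higher | balanced

    def __post_init__(self) -> None:
        if self.expr_a < 0 or self.expr_b < 0:
            raise ValueError("expression levels must be >= 0")


@dataclass
class OddsRatioResult:
    table: tuple[float, float, float, float]
    or_value: float
    log_or_se: float
    ci95: tuple[float, float]
    correction_applied: bool
    n_pairs: int


def build_pairs(
    genes: list[GeneModel],
    expression: dict[str, float],
    links: list[EnhancerTargetLink],
    enhancer_chroms: dict[str, str],
    subgenome_pair: tuple[str, str],
) -> list[HomoeologPairRecord]:
    """Discordant homoeolog pairs between two subgenomes.

    A gene's enhancer flag is set only by links whose enhancer lies on the
    gene's own chromosome (``enhancer_chroms`` maps enhancer id -> chrom).
    Homoeolog groups without exactly one gene per requested subgenome are
    skipped.  Only discordant pairs (flag XOR) are returned, oriented so that
    gene_a belongs to ``subgenome_pair[0]``.
    """
    flagged: dict[str, bool] = {}
    by_gene: dict[str, GeneModel] = {g.gene_id: g for g in genes}
    for link in links:
        gene = by_gene.get(link.gene_id)
        if gene is None:
            continue
        if enhancer_chroms.get(link.enhancer_id) == gene.chrom:
            flagged[link.gene_id] = True
    groups: dict[str, dict[str, list[GeneModel]]] = {}
    for g in genes:
        if g.homoeolog_group is None or g.subgenome not in subgenome_pair:
            continue
        groups.setdefault(g.homoeolog_group, {}).setdefault(g.subgenome, []).append(g)
    records: list[HomoeologPairRecord] = []
    for _group, by_sub in sorted(groups.items()):
        ga = by_sub.get(subgenome_pair[0], [])
        gb = by_sub.get(subgenome_pair[1], [])
        if len(ga) != 1 or len(gb) != 1:
            continue  # not a 1:1 correspondence
        a, b = ga[0], gb[0]
        if a.gene_id not in expression or b.gene_id not in expression:
            continue
        enh_a = flagged.get(a.gene_id, False)
        enh_b = flagged.get(b.gene_id, False)
        if enh_a == enh_b:
            continue  # concordant pair: carries no directional information
        records.append(
            HomoeologPairRecord(
                gene_a=a.gene_id,
                gene_b=b.gene_id,
                expr_a=expression[a.gene_id],
                expr_b=expression[b.gene_id],
                enh_a=enh_a,
                enh_b=enh_b,
            )
        )
    return records


def bias_call(
    record: HomoeologPairRecord,
    fc_threshold: float = 2.0,
    min_expr: float = 0.5,
) -> str:
    """Dominance call for one pair: ``a_higher`` when expr_a >= fc * expr_b
    and expr_a >= min_expr (symmetrically for b), else ``balanced``.

    The min_expr gate handles zero denominators: a pair (1, 0) is a_higher
    whenever 1 >= min_expr.
    """
    if fc_threshold <= 0 or min_expr <= 0:
        raise ValueError("thresholds must be > 0")
    a, b = record.expr_a, record.expr_b
    if a >= fc_threshold * b and a >= min_expr:
        record.bias = "a_higher"
    elif b >= fc_threshold * a and b >= min_expr:
        record.bias = "b_higher"
    else:
        record.bias = "balanced"
    return record.bias


def contingency(records: list[HomoeologPairRecord]) -> tuple[int, int, int, int]:
    """Mirrored 2x2 table over discordant pairs with bias calls.

    a = pairs where the enhancer-bearing homoeolog is the dominant one,
    b = pairs where it is not (balanced pairs fall here),
    c = pairs where the enhancer-free homoeolog is dominant,
    d = pairs where it is not.
    """
    if not records:
        raise ValueError("contingency of an empty record set")
    a = c = 0
    for r in records:
        if r.bias is None:
            raise ValueError("bias_call must be computed on every record")
        if not (r.enh_a ^ r.enh_b):
            raise ValueError("contingency expects discordant pairs only")
        enh_side_higher = (r.bias == "a_higher") if r.enh_a else (r.bias == "b_higher")
        free_side_higher = (r.bias == "b_higher") if r.enh_a else (r.bias == "a_higher")
        a += enh_side_higher
        c += free_side_higher
    n = len(records)
    return (a, n - a, c, n - c)


def odds_ratio(
    table: tuple[float, float, float, float],
    haldane: bool = True,
    paired: bool = False,
) -> OddsRatioResult:
    """OR = (a/b)/(c/d) with a Wald 95% CI on log OR.

    With ``haldane`` the Haldane–Anscombe 0.5 is added to all cells when any
    cell is zero.  ``paired`` applies the mirrored-table variance correction
    (+ 2n/(b d), n = a + b) appropriate for tables built by
    :func:`contingency`.
    """
    a, b, c, d = (float(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be >= 0")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    corrected = False
    if haldane and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    if min(a, b, c, d) == 0:
        raise ValueError("zero cell without Haldane correction: OR undefined")
    or_value = (a / b) / (c / d)
    var = 1 / a + 1 / b + 1 / c + 1 / d
    n = a + b
    if paired:
        var += 2 * n / (b * d)
    se = math.sqrt(var)
    log_or = math.log(or_value)
    ci = (math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se))
    return OddsRatioResult(
        table=(a, b, c, d),
        or_value=or_value,
        log_or_se=se,
        ci95=ci,
        correction_applied=corrected,
        n_pairs=int(round(n)),
    )


def merged_dominance_or(
    record_sets: list[list[HomoeologPairRecord]],
    fc_threshold: float = 2.0,
    min_expr: float = 0.5,
    paired: bool = True,
) -> OddsRatioResult:
    """Pool discordant pairs from all subgenome pairings and compute one OR."""
    pooled: list[HomoeologPairRecord] = [r for rs in record_sets for r in rs]
    for r in pooled:
        if r.bias is None:
            bias_call(r, fc_threshold=fc_threshold, min_expr=min_expr)
    table = contingency(pooled)
    return odds_ratio(table, paired=paired)
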