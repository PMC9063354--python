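"""target_assignment: promoters, panel correlation, Hi-C, link assignment."""

import math

import numpy as np
import pandas as pd
import pytest

from ernascape.enhancer_classification import EnhancerElement
from ernascape.io_core import GeneModel, GenomeLayout, Interval
from ernascape.target_assignment import (
    EnhancerTargetLink,
    PeakPanel,
    assign_targets,
    hic_support,
    pair_correlation,
    promoter_of,
    target_expression_summary,
)

LAYOUT = GenomeLayout({"c": 5_000_000})


def _panel(peaks, signals, samples=None):
    df = pd.DataFrame(peaks, columns=["chrom", "start", "end"])
    sig = np.asarray(signals, dtype=float)
    return PeakPanel(df, sig, samples or [f"s{i}" for i in range(sig.shape[1])])


def _enh(eid, start, end, status="transcribed"):
    el = EnhancerElement(eid, Interval("c", start, end), frozenset({5}), 10_000.0)
    el.status = status
    return el


def _contacts(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "read_pairs"],
    )


def test_promoter_of_both_strands():
    plus = GeneModel("g", "c", "+", 10_000, 20_000)
    p = promoter_of(plus, LAYOUT, up=1000, down=500)
    assert (p.start, p.end) == (9_000, 10_500)
    minus = GeneModel("g", "c", "-", 10_000, 20_000)  # TSS at 19_999
    p = promoter_of(minus, LAYOUT, up=1000, down=500)
    # mirrored window: 500 bp downstream (left), 1000 bp upstream (right)
    assert (p.start, p.end) == (19_500, 21_000)
    edge = GeneModel("g", "c", "+", 200, 5_000)
    p = promoter_of(edge, LAYOUT)
    assert p.start == 0  # clipped


def test_panel_validation_and_strongest_overlap():
    with pytest.raises(ValueError, match="signal row"):
        _panel([("c", 0, 10)], [[1, 2], [3, 4]])
    with pytest.raises(ValueError, match=">= 0"):
        _panel([("c", 0, 10)], [[1, -2]])
    panel = _panel(
        [("c", 0, 100), ("c", 50, 150), ("c", 400, 500)],
        [[1, 1, 1], [5, 5, 5], [9, 9, 9]],
    )
    # both first peaks overlap [60, 80); the higher-mean one wins
    assert panel.strongest_overlapping(Interval("c", 60, 80)) == 1
    assert panel.strongest_overlapping(Interval("c", 200, 300)) is None
    assert panel.strongest_overlapping(Interval("x", 0, 10)) is None


def test_pair_correlation_values_and_nans():
    panel = _panel(
        [("c", 0, 100), ("c", 1000, 1100), ("c", 2000, 2100)],
        [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [5.0, 5.0, 5.0]],
    )
    enh = Interval("c", 10, 20)
    assert pair_correlation(enh, Interval("c", 1050, 1060), panel) == pytest.approx(1.0)
    # flat promoter vector -> NaN
    assert math.isnan(pair_correlation(enh, Interval("c", 2050, 2060), panel))
    # no peak at the promoter -> NaN
    assert math.isnan(pair_correlation(enh, Interval("c", 3000, 3010), panel))
    two_sample = _panel([("c", 0, 100)], [[1.0, 2.0]])
    with pytest.raises(ValueError, match="3 panel samples"):
        pair_correlation(enh, enh, two_sample)


def test_hic_support_orientations_and_sums():
    enh = Interval("c", 1000, 2000)
    prom = Interval("c", 50_000, 51_000)
    contacts = _contacts(
        [
            ("c", 1500, 1600, "c", 50_200, 50_300, 3),   # forward
            ("c", 50_100, 50_150, "c", 1100, 1200, 2),   # reversed anchors
            ("c", 1500, 1600, "c", 90_000, 90_100, 7),   # wrong promoter
            ("x", 1500, 1600, "c", 50_200, 50_300, 7),   # wrong chromosome
        ]
    )
    assert hic_support(enh, prom, contacts) == 5
    assert hic_support(enh, Interval("c", 200_000, 201_000), contacts) == 0


def _brute_hic(enh, prom, contacts):
    total = 0
    for _, r in contacts.iterrows():
        a1 = (r.chrom1 == enh.chrom and r.start1 < enh.end and r.end1 > enh.start)
        a2 = (r.chrom2 == prom.chrom and r.start2 < prom.end and r.end2 > prom.start)
        b1 = (r.chrom1 == prom.chrom and r.start1 < prom.end and r.end1 > prom.start)
        b2 = (r.chrom2 == enh.chrom and r.start2 < enh.end and r.end2 > enh.start)
        if (a1 and a2) or (b1 and b2):
            total += r.read_pairs
    return total


def test_hic_support_matches_bruteforce():
    rng = np.random.default_rng(17)
    for _ in range(20):
        rows = []
        for _ in range(60):
            s1, s2 = rng.integers(0, 100_000, 2)
            rows.append(
                (rng.choice(["c", "x"]), int(s1), int(s1) + int(rng.integers(1, 500)),
                 rng.choice(["c", "x"]), int(s2), int(s2) + int(rng.integers(1, 500)),
                 int(rng.integers(1, 10)))
            )
        contacts = _contacts(rows)
        for _ in range(10):
            es = int(rng.integers(0, 100_000))
            ps = int(rng.integers(0, 100_000))
            enh = Interval("c", es, es + 800)
            prom = Interval("c", ps, ps + 800)
            assert hic_support(enh, prom, contacts) == _brute_hic(enh, prom, contacts)


def _link_setup(gene_start, corr_ok=True, hic_ok=True):
    """One enhancer at [0, 1000), one plus-strand gene; both criteria tunable."""
    gene = GeneModel("g1", "c", "+", gene_start, gene_start + 2_000)
    enh = _enh("E1", 0, 1_000)
    prom = promoter_of(gene, LAYOUT)
    enh_sig = [1.0, 2.0, 3.0, 4.0]
    prom_sig = [1.0, 2.0, 3.0, 4.0] if corr_ok else [4.0, 1.0, 3.0, 2.0]
    panel = _panel(
        [("c", 0, 1_000), ("c", prom.start, prom.end)], [enh_sig, prom_sig]
    )
    contacts = _contacts(
        [("c", 100, 200, "c", prom.start + 10, prom.start + 20, 2)] if hic_ok else []
    )
    return enh, gene, panel, contacts


def test_assign_targets_requires_all_three_criteria():
    enh, gene, panel, contacts = _link_setup(100_000)
    links = assign_targets([enh], [gene], panel, contacts, LAYOUT)
    assert len(links) == 1
    link = links[0]
    assert (link.enhancer_id, link.gene_id, link.search_tier) == ("E1", "g1", "primary_500kb")
    assert link.distance == 99_000 and link.hic_pairs == 2
    for kwargs in (dict(corr_ok=False), dict(hic_ok=False)):
        enh, gene, panel, contacts = _link_setup(100_000, **kwargs)
        assert assign_targets([enh], [gene], panel, contacts, LAYOUT) == []


def test_assign_targets_untranscribed_skipped():
    enh, gene, panel, contacts = _link_setup(100_000)
    enh.status = "untranscribed"
    assert assign_targets([enh], [gene], panel, contacts, LAYOUT) == []


def test_assign_targets_expansion_only_when_primary_empty():
    # gene beyond 500 kb: linked only through the expanded tier
    enh, far_gene, panel, contacts = _link_setup(800_000)
    links = assign_targets([enh], [far_gene], panel, contacts, LAYOUT)
    assert [l.search_tier for l in links] == ["expanded_2Mb"]
    # adding a passing primary-tier gene suppresses the expanded search
    near_gene = GeneModel("g0", "c", "+", 100_000, 102_000)
    near_prom = promoter_of(near_gene, LAYOUT)
    panel2 = _panel(
        [("c", 0, 1_000), ("c", near_prom.start, near_prom.end),
         ("c", promoter_of(far_gene, LAYOUT).start, promoter_of(far_gene, LAYOUT).end)],
        [[1.0, 2.0, 3.0, 4.0]] * 3,
    )
    contacts2 = _contacts(
        [
            ("c", 100, 200, "c", near_prom.start + 10, near_prom.start + 20, 1),
            ("c", 100, 200, "c", 800_000, 800_010, 1),
        ]
    )
    links = assign_targets([enh], [near_gene, far_gene], panel2, contacts2, LAYOUT)
    assert [(l.gene_id, l.search_tier) for l in links] == [("g0", "primary_500kb")]
    # beyond 2 Mb: never linked
    enh, very_far, panel, contacts = _link_setup(2_600_000)
    assert assign_targets([enh], [very_far], panel, contacts, LAYOUT) == []


def test_target_expression_summary_counts_and_missing_warning():
    links = [
        EnhancerTargetLink("E1", "g1", 1.0, 0.9, 2, "primary_500kb"),
        EnhancerTargetLink("E2", "g1", 1.0, 0.9, 2, "primary_500kb"),
        EnhancerTargetLink("E3", "g_missing", 1.0, 0.9, 2, "primary_500kb"),
    ]
    with pytest.warns(UserWarning, match="missing from expression"):
        df = target_expression_summary(links, {"g1": 5.0, "g2": 1.0})
    assert df.set_index("gene_id").loc["g1", "n_enhancers"] == 2
    assert df.set_index("gene_id").loc["g2", "n_enhancers"] == 0
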