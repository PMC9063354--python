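"""synthetic_data: determinism, structural invariants, planted-truth checks."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from ernascape.io_core import read_chrom_sizes, read_gff3
from ernascape.subgenome_bias import bias_call, contingency
from ernascape.synthetic_data import (
    SimConfig,
    simulate_genome,
    simulate_pair_outcomes,
    simulate_regulatory_landscape,
    simulate_reporter,
    simulate_tss_tracks,
    simulate_variants,
    solve_category_probs,
    write_all,
)


def test_config_validation():
    with pytest.raises(ValueError, match="fractions"):
        SimConfig(frac_transcribed=1.5).validate()
    with pytest.raises(ValueError, match="rates"):
        SimConfig(background_rate=-1).validate()
    with pytest.raises(ValueError, match="planted_or"):
        SimConfig(planted_or=0).validate()
    assert SimConfig().config_hash() != SimConfig(seed=1).config_hash()


def test_genome_structure(small_sim):
    cfg, genome, _landscape, _reads = small_sim
    assert set(genome.layout.chroms) == {"chr1A", "chr1B", "chr1D"}
    assert len(genome.genes) == 3 * cfg.n_triads
    assert len(genome.homoeolog_map) == cfg.n_triads
    # 1:1:1 triads with matching group ids and subgenome-consistent chroms
    by_group = {}
    for g in genome.genes:
        by_group.setdefault(g.homoeolog_group, []).append(g)
        assert g.chrom.endswith(g.subgenome)
        assert g.exons[0][0] == g.start and g.exons[-1][1] == g.end
    assert all(len(v) == 3 for v in by_group.values())
    # non-overlapping placement per chromosome
    for chrom in genome.layout.chroms:
        gl = sorted((g for g in genome.genes if g.chrom == chrom), key=lambda g: g.start)
        assert all(a.end <= b.start for a, b in zip(gl, gl[1:]))


def test_genome_determinism(small_cfg):
    g1 = simulate_genome(small_cfg)
    g2 = simulate_genome(small_cfg)
    assert [(g.gene_id, g.start, g.end, tuple(g.exons)) for g in g1.genes] == [
        (g.gene_id, g.start, g.end, tuple(g.exons)) for g in g2.genes
    ]
    assert g1.base_expression == g2.base_expression
    g3 = simulate_genome(SimConfig(**{**small_cfg.__dict__, "seed": 2}))
    assert g1.base_expression != g3.base_expression


def test_solve_category_probs_reproduces_or():
    """The planted category probabilities must make the *expected* mirrored
    table reproduce the requested odds ratio exactly."""
    for w in (1.0, 1.3, 1.5, 2.0, 3.0):
        for bal in (0.0, 0.3, 0.7):
            p, r = solve_category_probs(w, bal)
            assert p >= 0 and r >= 0 and p + r == pytest.approx(1 - bal)
            implied = (p / (1 - p)) / (r / (1 - r))
            assert implied == pytest.approx(w, rel=1e-9)
    with pytest.raises(ValueError):
        solve_category_probs(1.5, 1.0)


def test_landscape_invariants(small_sim):
    cfg, genome, landscape, _reads = small_sim
    assert len(landscape.enhancers) == cfg.n_enhancers
    n_trans = sum(e["transcribed"] for e in landscape.enhancers)
    assert n_trans == round(cfg.frac_transcribed * cfg.n_enhancers)
    # state segments per chromosome are non-overlapping
    for chrom, grp in landscape.states.groupby("chrom"):
        grp = grp.sort_values("start")
        assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()
    gene_iv = {
        chrom: [(g.start, g.end) for g in genome.genes if g.chrom == chrom]
        for chrom in genome.layout.chroms
    }
    for e in landscape.enhancers:
        # planted enhancers are >= 3 kb from every gene body
        for gs, ge in gene_iv[e["chrom"]]:
            if gs < e["end"] and e["start"] < ge:
                gap = 0
            else:
                gap = gs - e["end"] if gs >= e["end"] else e["start"] - ge
            assert gap >= 3_000
        if e["transcribed"]:
            assert e["start"] <= e["tss_primary"] < e["end"]
            for gid in e["targets"]:
                # planted targets share the enhancer's chromosome
                assert gid.endswith(e["chrom"][-1])
    # every true link has Hi-C support; no noise contacts at the default 0 rate
    n_links = sum(len(e["targets"]) for e in landscape.enhancers if e["transcribed"])
    assert len(landscape.contacts) == n_links
    assert (landscape.contacts["read_pairs"] >= 1).all()


def test_panel_correlation_at_true_links(small_sim):
    cfg, genome, landscape, _reads = small_sim
    from ernascape.target_assignment import pair_correlation, promoter_of
    from ernascape.io_core import Interval

    by_gene = {g.gene_id: g for g in genome.genes}
    checked = 0
    for e in landscape.enhancers:
        for gid in e.get("targets", []):
            enh_iv = Interval(e["chrom"], e["start"], e["end"])
            prom = promoter_of(by_gene[gid], genome.layout)
            r = pair_correlation(enh_iv, prom, landscape.panel)
            assert r == pytest.approx(1.0)  # zero panel noise: shared latent
            checked += 1
    assert checked > 0


def test_panel_noise_sweep_uses_common_random_numbers(small_cfg):
    """Regenerating the landscape with a different panel_noise_sd must leave
    everything except the panel signal matrix unchanged (common random
    numbers), and noise must only perturb signals additively."""
    genome = simulate_genome(small_cfg)
    base = simulate_regulatory_landscape(small_cfg, genome)
    noisy_cfg = SimConfig(**{**small_cfg.__dict__, "panel_noise_sd": 1.0})
    noisy = simulate_regulatory_landscape(noisy_cfg, genome)
    assert base.expression == noisy.expression
    pd.testing.assert_frame_equal(base.contacts, noisy.contacts)
    assert [e["id"] for e in base.enhancers] == [e["id"] for e in noisy.enhancers]
    diff = np.abs(base.panel.signals - noisy.panel.signals)
    assert diff.max() > 0


def test_plant_dominance_matches_planted_or_in_expectation(small_sim):
    cfg, genome, landscape, _reads = small_sim
    # categories recorded in truth should be recoverable from the final
    # expression table for non-"unset" pairs
    expr = landscape.expression
    for t in landscape.pair_truth:
        if t["category"] == "unset":
            continue
        ga, gb = t["pair"]
        ea, eb = expr[ga], expr[gb]
        fa = landscape.gene_enh_flag[ga]
        if t["category"] == "balanced":
            assert max(ea, eb) / min(ea, eb) < 2.0
        else:
            enh_expr, free_expr = (ea, eb) if fa else (eb, ea)
            if t["category"] == "enh_dominant":
                assert enh_expr >= 2.0 * free_expr
            else:
                assert free_expr >= 2.0 * enh_expr


def test_simulate_pair_outcomes_estimator_recovers_or():
    rng = np.random.default_rng(0)
    records = simulate_pair_outcomes(5_000, planted_or=1.5, balanced_frac=0.7, rng=rng)
    for r in records:
        bias_call(r)
    a, b, c, d = contingency(records)
    est = (a / b) / (c / d)
    assert est == pytest.approx(1.5, rel=0.25)


def test_nascent_reads_shape_and_determinism(small_sim):
    cfg, genome, landscape, reads = small_sim
    assert len(reads) == cfg.n_replicates
    for df in reads:
        assert list(df.columns) == ["chrom", "start", "end", "name", "score", "strand"]
        assert (df["end"] - df["start"] == 1).all()
        assert df["strand"].isin(["+", "-"]).all()
    from ernascape.synthetic_data import simulate_nascent_reads

    again = simulate_nascent_reads(cfg, genome, landscape)
    pd.testing.assert_frame_equal(reads[0], again[0])
    # replicates differ from one another
    assert not reads[0].equals(reads[1])


def test_nascent_reads_concentrate_at_planted_tss(small_sim):
    cfg, genome, landscape, reads = small_sim
    df = reads[0]
    hits = 0
    total = 0
    for e in landscape.enhancers:
        if not e["transcribed"]:
            continue
        total += 1
        sel = df[
            (df["chrom"] == e["chrom"])
            & (df["strand"] == e["primary_strand"])
            & (df["start"] >= e["tss_primary"] - 60)
            & (df["start"] <= e["tss_primary"] + 60)
        ]
        if len(sel) >= 5:
            hits += 1
    assert hits / total > 0.95


def test_simulate_variants_diversity_levels(tmp_path, small_sim):
    cfg, genome, landscape, _reads = small_sim
    from ernascape.auxiliary_stats import windowed_pi

    vcf = simulate_variants(cfg, genome, landscape, tmp_path / "v.vcf")
    windows = windowed_pi(str(vcf), genome.layout, window=500)
    genome_pi = float(windows["pi"].mean())
    assert genome_pi == pytest.approx(cfg.diversity_baseline, rel=0.15)
    # eRNA regions depleted roughly by erna_reduction
    erna_pi = []
    for e in landscape.enhancers:
        if not e["transcribed"]:
            continue
        sel = windows[
            (windows["chrom"] == e["chrom"])
            & (windows["start"] < e["end"])
            & (windows["end"] > e["start"])
        ]
        erna_pi.append(float(sel["pi"].mean()))
    ratio = float(np.mean(erna_pi)) / genome_pi
    assert ratio < 0.85


def test_simulate_reporter_controls(small_sim):
    cfg, _genome, landscape, _reads = small_sim
    from ernascape.auxiliary_stats import reporter_score

    df = simulate_reporter(cfg, landscape)
    scored = reporter_score(df, blank_id="blank").set_index("construct_id")
    assert scored.loc["blank", "relative_intensity"] == pytest.approx(1.0)
    assert scored.loc["negative", "relative_intensity"] == pytest.approx(1.6)
    assert not scored.loc["negative", "is_positive"]
    cands = scored[scored["role"] == "candidate"]
    # planted transcribed candidates mostly positive, untranscribed mostly not
    pos_rate_trans = cands[cands["planted_signal"] > 0]["is_positive"].mean()
    pos_rate_untrans = cands[cands["planted_signal"] == 0]["is_positive"].mean()
    assert pos_rate_trans > 0.8 > pos_rate_untrans


def test_simulate_tss_tracks_contract():
    layout, frames, truth = simulate_tss_tracks(
        n_tss=20, depth=25, genome_length=1_000_000, n_replicates=2, seed=0
    )
    assert len(frames) == 2 and len(truth) == 20
    positions = sorted(p for _c, p, _s in truth)
    assert all(b - a > 10_000 for a, b in zip(positions, positions[1:]))
    for df in frames:
        assert (df["end"] - df["start"] == 1).all()


def test_write_all_roundtrip(tmp_path, small_cfg):
    outdir = tmp_path / "sim"
    manifest = write_all(small_cfg, outdir)
    for fn in manifest["files"]:
        assert (outdir / fn).exists(), fn
    layout = read_chrom_sizes(outdir / "chrom.sizes")
    genes = read_gff3(outdir / "genes.gff3", layout=layout)
    assert len(genes) == 3 * small_cfg.n_triads
    with open(outdir / "truth.json") as fh:
        truth = json.load(fh)
    assert len(truth["enhancers"]) == small_cfg.n_enhancers
    assert truth["seed"] == small_cfg.seed
    # written expression table matches the in-memory truth
    expr = pd.read_csv(outdir / "expression.tsv", sep="\t")
    assert dict(zip(expr["gene_id"], expr["level"])) == pytest.approx(truth["expression"])
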