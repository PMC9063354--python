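# Methods

This document states the statistical model behind each pipeline stage, every
default parameter with its rationale, and the scope and limits of the
synthetic-data generator. Coordinates are 0-based half-open throughout;
GFF3/VCF inputs are converted on read.

## 1. Signal model

Input reads are reduced to single-base 5′-end events (the track builder
rejects multi-base records rather than silently taking an endpoint). A
`StrandTrack` stores, per (chromosome, strand), sorted unique positions and
event counts. Densities are *events per million*: raw counts scaled by
`1e6 / total_events`, making replicates of different depth comparable.
Replicate merging sums raw counts position-wise; replicate agreement is the
Pearson correlation of normalized densities in fixed genome-wide bins
(default 500 bp), NaN when a binned vector has zero variance.

## 2. TSS calling and TSS clusters

Detection models each strand as a homogeneous Poisson background with rate
λ = (strand events) / (genome length). A position is a TSS candidate when its
raw count reaches the smallest k with P(X ≥ k | λ) ≤ α (default α = 1e-6,
computed exactly from the Poisson survival function with a boundary-adjusted
`ppf` start) and at least `min_count = 5` — the floor guards shallow tracks
where the Poisson threshold alone would admit 2–3-read positions. Within any
chain of candidates successively closer than 50 bp on one strand, only the
maximal-count position survives (leftmost on ties).

Calls within 3 kb on one strand chain into TSS clusters (TCs) by single
linkage; the cluster TSS is the 5′-most member with respect to strand. A
merged-replicate cluster is retained only when **every** replicate has ≥ 1
call inside the cluster span on the same strand (with a single replicate the
filter passes through with a warning). Each TC is quantified as the
strand-restricted normalized density within ± 250 bp of its TSS
(`signal_250`), used for signal-ranked decile groups and for enhancer
direction calls.

Consequence of the design worth noting: run suppression reduces an isolated
initiation site to one position, so its cluster span is 1 bp, and replicate
support then requires each replicate's suppressed maximum to fall on the same
base. This is the intended regime for 5′-end data with a dominant initiation
mode; diffuse initiation spread uniformly over several bases can fail the
filter.

## 3. Genomic annotation

A TC is *genic-proximal* when its span overlaps any gene body extended by
1 kb on each side, strand-agnostically (divergent upstream transcription
belongs to the gene's regulatory neighborhood regardless of strand);
otherwise *masked* when it overlaps the coding-transcript mask; otherwise
*intergenic*. Read 5′-end categories are mutually exclusive with priority
exon > intron > TSS1K > TES1K > intergenic, where TSS1K/TES1K are the
strand-aware 1-kb windows upstream of the TSS and downstream of the TES, so
the five fractions sum to one.

## 4. Enhancer-like elements and direction classes

Enhancer-like elements are maximal runs of touching/overlapping
chromatin-state segments with state ∈ {5, 6, 7}, kept only when the
edge-to-edge distance to the nearest gene body is ≥ 3 kb. An element is
*transcribed* when ≥ 1 intergenic TC overlaps it (any strand). For
transcribed elements, the per-strand signal is the ± 250 bp density at the
5′ end of the strongest overlapping TC on that strand; the higher-signal
strand is *primary* (ties → +). An element with called TCs on both strands is
bidirectional (BE), otherwise unidirectional (UE). BE requires called TCs —
not merely nonzero secondary-strand signal — so the direction call reuses the
replicate-filtered detection machinery instead of introducing a separate
secondary-signal threshold.

## 5. Target assignment

A transcribed enhancer links to a gene when three criteria hold jointly:

* **distance** — gene body within 500 kb (edge-to-edge);
* **panel correlation** — Pearson r ≥ 0.7 across panel samples between the
  strongest (max mean signal) histone peak overlapping the enhancer and the
  strongest peak overlapping the gene promoter (1 kb upstream to 500 bp
  downstream of the TSS, strand-aware); pairs with no overlapping peak or a
  zero-variance vector fail;
* **contact** — ≥ 1 Hi-C read pair with one anchor overlapping the enhancer
  and the other the promoter, in either anchor orientation.

Only when *no* gene passes all three criteria within 500 kb is the distance
window expanded to 2 Mb (genes in (500 kb, 2 Mb]); expansion-tier links are
labeled as such. Output order is deterministic (enhancer id, then gene id).

## 6. Homoeolog dominance odds ratio

For a subgenome pair (e.g. A–B), homoeolog groups with exactly one gene per
subgenome form candidate pairs; a gene carries the *enhancer flag* when some
transcribed enhancer on the gene's own chromosome links to it. Only
*discordant* pairs (exactly one flagged side) are informative and retained.
Each pair receives a dominance call: side X dominant when
expr_X ≥ 2.0 · expr_Y and expr_X ≥ 0.5 (the `min_expr` gate handles zero
denominators); otherwise balanced. "Significantly higher" is operationalized
as this fold-change gate rather than a per-pair test because replicate-level
expression is not an input at this stage.

The 2 × 2 table is the mirrored classification of the same n pairs:
a = enhancer-side dominant, b = n − a, c = enhancer-free-side dominant,
d = n − c, and OR = (a/b)/(c/d). When any cell is zero the Haldane–Anscombe
0.5 is added to all cells. Because the two rows are not independent samples,
the Woolf variance 1/a + 1/b + 1/c + 1/d understates Var(log OR); for tables
built this way the package adds the multinomial delta-method cross term
2n/(b·d) (`paired=True`), which is exact in the no-balanced-pairs limit.
Monte-Carlo checks in the test suite confirm the paired SE tracks the
empirical SD of log OR and that 95% CI coverage lands in [92%, 98%], while
plain Woolf is anticonservative (~91–93% coverage) on mirrored tables.
Per-subgenome-pair ORs and a pooled (merged) OR over all three pairings are
reported.

## 7. Auxiliary statistics

**Windowed π.** Per biallelic SNP, π_site = 2j(n−j)/(n(n−1)) with n called
haplotypes and j ALT haplotypes (the unbiased per-site heterozygosity); a
window's π is the sum of its site values divided by the window length
(default 500 bp), the `--window-pi` convention of vcftools. Non-SNP or
multi-allelic records are skipped and counted. Region-versus-control
comparisons draw length-matched intervals uniformly from intergenic space
(gene bodies ± 1 kb excluded), weighted by gap capacity, under a caller-
provided seed.

**Coverage saturation.** The covered fraction of fixed bins (default 10 kb,
covered at ≥ 5 records) as a function of subsample size. Subsamples are
nested prefixes of one seeded shuffle, so the curve is monotone by
construction and converges to the full-data value.

**Reporter scoring.** Relative expression is Fluc/Rluc; relative intensity
normalizes to the blank construct (blank → 1.0); a construct is positive at
≥ 2.0. The threshold is set with reference to an empirical negative-control
level of 1.6, which must score non-positive. Activity–signal correlations
first drop points outside median ± 3·MAD on either variable.

## 8. Synthetic data generator

Scope: the generator produces *analysis-level* inputs (events, segments,
peaks, contacts, variant genotypes), not sequence-level data — no FASTA,
motifs, or read qualities. Default problem size (3 subgenomes × 1 chromosome
× 5 Mb, 100 triads, 200 enhancer-like elements, 4 replicates) is a package
choice: large enough for stable recovery statistics, small enough to generate
and analyze in seconds on one CPU.

All randomness flows from `SimConfig.seed` through named `SeedSequence`
child streams (genome, expression, landscape, panel, Hi-C, dominance, reads
per replicate, variants, reporter), so a config reproduces byte-identical
outputs, and changing one component's parameters leaves the other components'
draws untouched. In particular the panel-noise draw is consumed whether or
not noise is applied, so sweeping `panel_noise_sd` under one seed is a
common-random-numbers experiment in which only peak signal values change.

Key constructions:

* **Genome** — jitter-syntenic triads with Dirichlet-split exon/intron
  structure; placement spacing is validated so genes never overlap.
* **Landscape** — each planted enhancer occupies its own intergenic gap
  (margin 3.5 kb from genes) and is emitted as 1–3 adjacent state-5/6/7
  segments; near-gene kept-state decoys (which the 3-kb rule must discard)
  and non-kept-state decoys are added. Planted targets are same-chromosome
  genes within 500 kb (or, for a configurable fraction, only beyond 500 kb to
  exercise the expansion tier).
* **Panel** — connected components of the true link graph share a latent
  signal vector, giving r = 1 at true pairs when noise is zero; unlinked
  peaks get independent vectors.
* **Hi-C** — every true pair carries 1 + Poisson(rate − 1) read pairs (a
  planted link without physical support would contradict the link
  definition); false contacts are Poisson with default rate 0.
* **Reads** — genic events mix a TSS pausing spike (weight 0.4, 90% of its
  mass on the mode base) with body reads at a 3:1 exon:intron per-bp ratio;
  transcribed enhancers get a primary-strand spike (mean 30 reads/replicate)
  and, when bidirectional, a secondary-strand spike at 0.8 × depth; both
  strands carry uniform Poisson background (0.002 events/bp/strand/
  replicate). The 0.9 mode mass and these depths put planted sites far above
  the min-count 5 detection floor, which is what makes ≥ 0.99 recovery an
  expected property rather than a tuned outcome.
* **Dominance planting** — discordant pairs draw one of three categories
  (enhancer-side dominant / free-side dominant / balanced). The category
  probabilities (p, r) solve p + r = 1 − balanced_frac together with
  (p/(1−p))/(r/(1−r)) = planted_or, i.e. the quadratic
  (1−w)p² + [(1+w) − s(1−w)]p − sw = 0 with s = 1 − balanced_frac, so the
  *expected* mirrored table reproduces the planted OR exactly. (The simpler
  rule p = OR/(OR+1) would plant OR² under this table construction.)
  Expression rewrites respect previously pinned genes across the three
  subgenome pairings; chained constraints can occasionally leave a pair's
  category "unset" in the truth record.
* **Variants** — SNP positions are Poisson with per-bp rate
  diversity_baseline / 0.365 (0.365 = E[2f(1−f)] for f ~ U(0.05, 0.5)), so
  expected window π equals the configured baseline; sites inside transcribed
  enhancers are thinned by `erna_reduction` (default 0.5). Genotypes are
  independent draws per haplotype (no linkage).

Limits: no linkage disequilibrium, no overdispersion beyond Poisson, uniform
background, one peak per element/promoter in the panel, and enhancers never
share a gap — deliberate simplifications that make planted-truth recovery
checks exact while still exercising every decision rule in the pipeline.

Estimation noise at the default scale: a single dataset yields only
~100–200 discordant pairs, so the dataset-level merged OR scatters around the
planted value with SE(log OR) ≈ 0.35–0.4. Estimator calibration is therefore
checked with a dedicated pair-outcome generator at n = 5,000 pairs × 200
simulations per planted OR (bias ≤ 5%, CI coverage within [92%, 98%]), and a
40-seed landscape-level check confirms the full planting path is unbiased
(mean OR 1.48 at planted 1.5, SE of the mean 0.10).
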