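# Methods

`barseqfit` analyzes pooled-fitness experiments in which a randomly barcoded
transposon mutant library of *Caulobacter crescentus* is passaged daily
through medium containing submerged cheesecloth. Adhesive (holdfast-bearing)
cells attach to the cloth and are removed from the planktonic phase, so
mutants that cannot adhere enrich over passages, hyperadhesive mutants
deplete, and sequencing the transposon barcodes (BarSeq) after each passage
yields a temporal fitness profile per gene. A parallel passage series without
cloth controls for growth effects. This note records the model, the defaults,
and the design choices; every number quoted here is computed by the test
suite or by `scripts/acceptance.py`.

## Strain and gene fitness

Let `n_is` be the reads of barcode *i* in sample *s*, `D_s` the sample depth,
and `B` the number of pool barcodes. The reference is the pooled first
control passage (sum over its three replicates, counts `n0_i`, depth `D0`).
Strain fitness is the pseudocounted log2 frequency ratio

    f_is = log2((n_is + ps) / (D_s + ps·B)) − log2((n0_i + ps) / (D0 + ps·B))

with `ps = 0.5` by default (a Jeffreys-style half count; `ps = 0` is allowed
and gives exact log ratios). The pseudocount enters the depth as `ps·B` so
pseudocounted frequencies still sum to one. A strain is *usable* when
`n0_i ≥ 3`; weaker reference representation makes the ratio unstable.

Gene fitness averages usable strains whose insertion lies in the central
80 % of the ORF (`orf_fraction` in [0.10, 0.90], endpoints inclusive —
insertions in the outer 10 % often leave partial function). The default
weight is the delta-method inverse variance of a log count ratio,
`w_i = 1/(1/(n_is+ps) + 1/(n0_i+ps))`; `reference_count` (`w = n0+ps`) and
`uniform` weightings are selectable for sensitivity analysis. Note that the
precision weight is a function of the same sample count as the fitness
value, which introduces a small positive bias for strains near zero counts;
the reference-count weighting avoids this at some cost in variance. Genes
whose strains are all unusable or peripheral carry no value — never 0.

Per-sample median centering (default) removes the arbitrary renormalization
constant that pooled competition imposes on every log ratio in a sample; it
assumes most genes are phenotypically neutral, which holds in genome-wide
libraries.

## Temporal profiles, filtering, normalization, ranking

Samples are grouped into the (condition × passage) grid — 10 cells in the
default 2 × 5 design — and gene fitness is summarized per cell as the
replicate mean and sample SD (n−1 denominator; unbiased at n = 3). By the
pooled-reference convention the control passage-1 cell is 0/0 by definition.

A gene is eliminated when its largest SD across the grid exceeds its largest
absolute mean fitness — a signature of pure replicate noise. Removal uses a
strict inequality, so an all-zero gene survives, and genes missing any SD
are kept but flagged. The filter acts on raw per-condition summaries, before
normalization; both per-gene maxima are written out so the alternative
(filtering on normalized values) is auditable.

Normalized profiles subtract the control mean from the cheesecloth mean at
each passage, `g_t = m_cheese(t) − m_control(t)`, cancelling
condition-independent growth effects in expectation (exactly so in the
sampling-free recursion; see the simulator section). Genes are ranked by
`max_t |g_t|` (ties broken by locus identifier) and the top k = 250 enter
clustering.

## Clustering, cofitness, archetypes

Selected profiles are clustered agglomeratively (default Euclidean distance,
Ward linkage, tree cut to k = 6: four archetype shapes, the mild class, and
a leftover group); genes are processed in lexicographic order so results do
not depend on input order. Cofitness is the Pearson correlation between two
genes' profiles; zero-variance profiles get correlation 0 (distance 1) with
a flag rather than an exception, keeping matrices total.

Because cluster groups in experiments of this kind are typically curated by
eye, explicit first-match rules assign each profile a temporal archetype as
a reproducible surrogate (thresholds in log2 units: strong = 2.0,
mild = 0.5, negative dip = −1.0, floor = −0.5, rebound = 1.5):

1. **recovery** — early dip `min(g1,g2) ≤ −1`, rebound `g5 − min ≥ 1.5`,
   final `g5 ≥ −0.5` (the smooth-LPS shape: transient hyperadhesion);
2. **hyperadhesive** — dips to −1 and finishes at or below −0.5
   (polar-appendage-mutant shape, no recovery phase);
3. **biosynthesis** — `g5 ≥ 2` and never below the floor (strong adhesion
   loss, the holdfast-synthesis shape);
4. **modification** — `g5` in [0.5, 2) and never below the floor (modest
   adhesion defect, the holdfast-modification shape);
5. **unclassified** otherwise.

Recovery precedes hyperadhesive deliberately: dip-then-rise profiles satisfy
rule 2's antecedent and would otherwise be swallowed by it.

## The simulator

The generator realizes the study design as a composition-only process.
A pool of 1000 genes receives zero-truncated Poisson(3) insertions each,
plus intergenic strains making up 15 % of the library; every strain gets a
unique random 20-nt barcode and an ORF position uniform on (0,1). Classes
are planted per gene: neutral 90 %, strongly nonadhesive 3 %, mildly
nonadhesive 2 %, hyperadhesive 2 %, recovery 2 %, growth-defect confounder
1 %.

Each passage, strain frequency in the cheesecloth condition is thinned by a
per-cycle capture probability `a` (wild-type-like cells: 0.6), then all
strains grow by `2^(3.9·(1+penalty))` (3.9 ≈ log2 of the ~15-fold daily
dilution) and the composition is renormalized — growth to saturation tracked
as composition only, since BarSeq observes nothing else. Capture is a single
per-cycle thinning factor; any within-cycle attachment schedule is absorbed
into the effective `a`, which keeps the model identifiable and analytically
checkable: a fully nonadhesive strain gains exactly
`−log2(1−0.6) = 1.3219` log2 units per passage relative to wild-type-like
strains, and a pure growth defect cancels exactly in `g_t`. Sequencing is
multinomial per sample (200 000 reads), with optional Dirichlet-multinomial
overdispersion (off by default — the simplest model consistent with pooled
amplicon counting). Initial abundances are log-normal (σ = 0.8) and shared
between the two conditions of a replicate, as both start from the same
thawed aliquot.

Class capture defaults are calibrated jointly with the archetype thresholds
so each planted class realizes its intended shape: strong nonadhesive
`a = 0` (profile ramps to ≈ +6.6 by passage 5), mild `a = 0.5`, just below
wild type (ramps to ≈ +1.6, inside the modification band), hyperadhesive
`a = 0.85` (≈ −7 by passage 5), and recovery uses the schedule
(0.9, 0.7, 0.4, 0.1, 0.0), yielding ≈ (−2, −2.4, −1.8, −0.7, +0.7) — strong
early capture relaxing to below wild type, the dip-then-recover shape
reported for smooth-LPS mutants. The recovery class is phenomenological: it
reproduces the shape via a time-varying capture probability, not a
mechanism, because no mechanism for the recovery is established. Reads can
optionally be emitted as FASTQ (4-nt random stagger + 18-nt pre-flank +
barcode + 7-nt post-flank + random tail, constant Phred+33 quality, optional
per-base substitution errors) for end-to-end testing of extraction.

What the simulator does *not* model: rosette formation, cloth saturation,
spatial structure, PCR duplicates/chimeras, indel sequencing errors, or
batch effects between replicates. Passing tests therefore demonstrate that
the analysis recovers planted signal under multinomial counting noise — not
that it is robust to every artifact of real sequencing data.

## Numerical and degenerate-input conventions

* Barcode extraction: leftmost valid flank placement wins; per-flank Hamming
  budget, no indels; ambiguous (non-ACGT) barcodes are discarded and counted
  in QC. Absence of a barcode is a value, not an error.
* The top-percentile QC statistic uses `ceil(p/100·B)` barcodes with
  lexicographic tie-break, so it is deterministic.
* Count tables carry all pool barcodes zero-filled, keeping pseudocount
  arithmetic well defined.
* All stochastic stages draw from seeded generators with per-replicate /
  per-sample derived substreams; a rerun with the same configuration is
  byte-identical in every TSV artifact.
* Ties in ranking, cofitness ordering, and cluster relabeling are broken by
  gene identifier.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the full default design
(1000 genes, ≈ 3800 strains, 30 samples × 200 000 reads) for planted-class
recovery, and scaled-down experiments for the FASTQ round trip (100 genes,
5000 reads/sample) and the mode-equivalence check (60 genes), which exercise
identical code paths on smaller read sets.

## Known limitations

* At 200 000 reads/sample, classes that are strongly depleted by passage 5
  (growth-defect strains fall ~7.5-fold in both conditions while enriched
  nonadhesive mutants dilute everyone else ~3-fold in the cheesecloth arm)
  are measured from only a few reads per strain; their per-gene |g_5| is
  shot-noise-dominated (≈ 0.4 in log2 units) even though the class-mean bias
  is small (≲ 0.2, pseudocount shrinkage asymmetry) and exactly zero in the
  noise-free recursion.
* The SD filter is aggressive on genome-wide null genes (an SD estimate from
  three replicates is noisy), which is its purpose; with 1000 genes the
  top-250 selection is then rarely binding.
* Archetype thresholds are calibrated to the simulator's effect sizes; real
  datasets with weaker selection may need rescaled thresholds.
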