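# Methods

This note documents the statistical model, the conventions and defaults,
the synthetic-data generator, and the design choices made where the
underlying analysis left details open.

## Coordinates, sites and the count matrix

All internal coordinates are 0-based half-open; CGmap and Bismark
coverage positions (1-based) and GTF intervals (1-based inclusive) are
converted at the file boundary.  CpG sites are keyed by the cytosine
position on its own strand; the two cytosines of a symmetric CpG dyad are
*not* merged (strand-specific calls, as produced by read-1-only
methylation calling, are analysed as-is).  Non-CG contexts parse but are
dropped at ingest.

The central object is the CpG count matrix: sites × samples methylated
and total read counts, with a sample→group design.  Only sites covered by
at least `min_cov` reads in **every** sample are retained ("coexisting"
sites), so every downstream statistic is computed on one shared site
universe.  Defaults: `min_cov = 5` for levels/profiles/DMRs and
`min_cov = 8` for DMC testing.

A site's level is m/t.  A **group level is the arithmetic mean of
replicate levels**, not the pooled-count ratio; pooling is reserved for
the Fisher tests (below), where a 2×2 table needs one count pair per
group.  A region level is the unweighted mean over the retained CpGs it
contains; a region without CpGs is missing, never zero.

Level histograms are left-closed right-open with the last bin closed
(so level 0.2 falls in [0.2, 0.5) and 1.0 in the top bin); per-replicate
masses therefore sum to one and group summaries are mean ± standard
error over the biological replicates (n = 3).  Genome windows tile from
coordinate 0 at 1 Mb with the trailing partial window kept; DMC density
per window is normalized by the window's retained-CpG count.

## CpG-island detection and annotation layers

Islands follow the classic sequence criteria: length strictly greater
than 200 bp, GC fraction > 0.5, and observed/expected CpG ratio > 0.6
with expected density (GC/2)².  The algorithm slides a 200 bp window in
1 bp steps, merges overlapping qualifying windows, then re-tests each
merged region and symmetrically trims one base from each end until the
region itself satisfies all three criteria (regions that shrink to
≤ 200 bp are dropped).  Only the three thresholds are part of the
analysis definition; the window/merge/trim procedure is the package's
concrete implementation of the classic region-growing approach, and the
test suite pins it against a brute-force oracle that tests every
substring window directly.

The CGI layer assigns CGI > shore > shelf > none, shores being the 2 kb
flanks outside islands and shelves the 2 kb outside shores, clipped at
chromosome ends.  The gene layer is a strict partition into upstream
(5 kb 5' of the TSS), exon, intron, downstream (5 kb 3' of the TES) and
intergenic, with precedence exon > intron > upstream > downstream >
intergenic applied jointly across genes — the exon-first convention is
what makes per-category detected-CpG counts sum exactly to the total.
A CGI is classified by the genic feature covering strictly more than
half its length; failing that, the largest overlap wins with ties broken
by the same precedence.

Promoter CpG-content classes score the (TSS−1000, TSS+500) window
(transcription-oriented, clipped) by the same observed/expected formula;
HCP at ratio ≥ 0.48, else LCP.  Both the window and the threshold are
configurable because the class boundary is not standardized across
studies, and an externally supplied gene→class table can bypass the
computation entirely.

## Dynamics classification

Over three ordered stage levels per site: HyperC requires ≥ 0.8 in all
stages, HypoC ≤ 0.2 in all stages, IncrmC a rise ≥ 0.2 at *each* step,
DecrmC the mirror.  The four classes are mutually exclusive by
arithmetic (a monotone site moving ≥ 0.4 in total cannot stay inside a
0.2-wide consistency band).  Comparisons of float levels use plain
`>=`; levels that sit exactly on a threshold only behave predictably
when exactly representable, which the tests respect.

## DMC calling

Per site, replicate counts are summed within each group and the 2×2
table (meth_A, unmeth_A; meth_B, unmeth_B) is tested with a two-tailed
Fisher exact test — the sum of all hypergeometric outcomes with the
observed margins whose probability does not exceed the observed table's
(relative tolerance 1e−7 on the comparison).  Benjamini–Hochberg
adjustment runs across all tested sites.  A DMC requires q ≤ 0.05 and a
pooled level change strictly greater than 0.2, on sites covered ≥ 8× in
every sample.

**Replicate pooling is the key inferential choice**: a 2×2 exact test
admits one count pair per group, and summing the three replicates is the
natural mapping.  It ignores between-replicate overdispersion, so the
synthetic benchmark deliberately draws beta-binomial (not binomial)
counts; at the default mild overdispersion (concentration 100) the
caller holds empirical FDR ≈ 0.02–0.03 at q ≤ 0.05 with recall ≈ 0.9 for
Δ = 0.3 at 30× — adequate, but a dispersion-aware model would be needed
for noisier replicates (out of scope).  A `delta_method="replicate_mean"`
flag computes the delta gate from replicate-mean levels instead of
pooled levels.

The DMC delta gate is strict (> 0.2) while the DMR gate is inclusive
(≥ 0.2), following the asymmetric wording of the two definitions.

## DMR calling (dynamic fragmentation)

1. Retained CpGs (≥ 5× everywhere) are chained into fragments wherever
   the inter-CpG gap is ≤ `max_gap` (default 300 bp).
2. Within a fragment, walking 5'→3' with a running mean of the per-CpG
   inter-group level difference, a CpG whose difference has the opposite
   strict sign to the running mean starts a new sub-fragment (zeros
   never split), yielding direction-coherent sub-fragments.
3. Sub-fragments with ≥ `min_cpgs` (default 5) CpGs are tested by the
   same pooled Fisher machinery on region-summed counts; BH runs across
   all tested sub-fragments.
4. A DMR requires q ≤ 0.05 and |mean per-site level difference| ≥ 0.2.
   The delta uses the mean of per-site pooled-level differences (the
   literal "mean level difference"); the Fisher table uses the
   region-summed counts.

`max_gap` and `min_cpgs` are not part of the source analysis definition
and are exposed as configuration; absolute DMR counts are therefore not
comparable across parameterizations, and the package validates the
caller by planted-block recovery and null control rather than by any
fixed count.

## Enrichment statistic

Relative enrichment of a selected site class (DMCs, HyperCs, …) in a
region category is the **inside/outside rate ratio**
`(k_r/n_r) / ((K−k_r)/(N−n_r))` — not the Fisher odds ratio.  The
identification was verified by recomputation: from the published
per-region detected/DMC summary counts, only the rate-ratio definition
reproduces the printed values (e.g. shores 1.74, shelves 2.04, CGI 0.30
for the first stage comparison, agreeing to two decimals in every named
cell, with the known downstream cell off by 0.01).  Fisher's exact test
on the same table supplies the p-value only, reported exactly rather
than floored at 2.22 × 10⁻¹⁶.  A region equal to the whole universe has
no outside rate and is an error; a region containing every selected site
has outside rate zero and infinite enrichment.

## Synthetic data

The generator lays each chromosome out in 30 kb slots cycling through:
gene with upstream island, gene with exonic island, lone intergenic
island, gene with intronic island, gene with downstream island, gene
with upstream island, island-free gene — so all five genic features,
all five genic CGI classes, both strands, and both promoter classes are
guaranteed.  The background is AT-biased (GC 0.35) with 90 % of CG
dinucleotides deaminated away, so background observed/expected ≈ 0.1 and
the island detector finds nothing off-plan; islands are CG-token
sequences with GC ≈ 0.76 and observed/expected ≈ 1.4.

Counts: depth ~ negative binomial (mean 30, size 8); replicate-level
true levels ~ Beta around the group truth (concentration 100, mild
overdispersion); meth ~ Binomial(depth, replicate level).  Baselines are
bimodal — Beta mean 0.05 for CpGs in islands or upstream regions, 0.85
elsewhere (concentration 30).  Planted signals overwrite baselines:
5 % of sites shift the middle stage by 0.3 (DMCs), four 10-CpG blocks
shift by 0.5 (DMRs), and 40 sites per class get canonical dynamics
triples (0.92/0.92/0.92, 0.04/0.04/0.04, 0.10→0.40→0.70 and its
mirror — steps of 0.3 leave 0.1 of margin over the 0.2 rule so the
planted classes survive moderate sampling noise).  Truth tables record
true group levels, roles and block ids; all randomness flows from one
seed and outputs are byte-identical under it.

What the generator does *not* emulate: read-level artifacts (bisulfite
conversion error, M-bias, mapping bias), MspI fragment size selection
(real RRBS coverage is concentrated near MspI sites), linked
hypo/hypermethylation structure beyond the island/upstream rule, and
chromosome-scale covariates.  Passing tests therefore demonstrate
algorithmic correctness and calibration under the stated noise model,
not performance on any particular tissue's data.

## Problem sizes and numerics

The default simulated study is 2 × 400 kb chromosomes (≈ 7,000 CpGs,
22 genes, 23 islands), and the caller benchmarks use 10,000 sites (DMC)
and 5 planted blocks with 10 null repeats (DMR) — sizes chosen so the
entire validation runs in seconds while every code path (both strands,
all categories, all planted classes) is exercised.  Fisher p-values are
computed in log space via `lgamma`; when the tail criterion includes the
whole support the p-value is returned as exactly 1.  BH q-values use the
standard step-up with a stable argsort.  Empty matrices, empty regions,
all-N promoter windows and categories without detected CpGs are explicit
missing/error states rather than silent zeros.
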