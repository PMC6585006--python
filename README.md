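# methdyn

Reduced-representation bisulfite sequencing (RRBS) yields, per sample,
methylated/total read counts at individual CpG cytosines.  `methdyn` is a
tested, reusable pipeline for studying how such methylomes change across an
ordered series of biological stages (its motivating design: ovarian tissue
across three pubertal stages — Pre, In, Post — with three biological
replicates each).  It takes per-CpG count files, a genome FASTA and gene
models, and produces:

* **annotation layers** — CpG islands (CGIs) detected from sequence
  (length > 200 bp, GC > 0.5, observed/expected CpG > 0.6 with expected
  density (GC/2)²), their ±2 kb *shores* and ±2 kb *shelves*; and a strict
  five-way genic partition (upstream 5 kb / exon / intron / downstream
  5 kb / intergenic, precedence exon > intron > upstream > downstream >
  intergenic), plus high/low-CpG-content promoter (HCP/LCP) gene classes;
* **methylation levels** — per site *m/t*, per group the mean of replicate
  levels, per region the mean over contained CpGs, restricted to CpGs
  covered ≥ 5× in *every* sample; level histograms and 1 Mb window tracks;
* **meta-profiles** — 20/40/20-bin metagene and 20/20/20-bin CGI profiles
  per group, strand-oriented, equal feature weighting;
* **dynamics** — consistently hyper-/hypomethylated CpGs (level ≥ 0.8 /
  ≤ 0.2 in all stages) and monotonically increasing/decreasing CpGs
  (≥ 0.2 change at each step); differentially methylated CpGs (DMCs:
  ≥ 8× everywhere, group-pooled two-tailed Fisher exact test,
  Benjamini–Hochberg q ≤ 0.05, |Δ| > 0.2) and regions (DMRs: dynamic
  fragmentation of ≥ 5× CpG chains into direction-coherent fragments,
  pooled Fisher, q ≤ 0.05, |Δ| ≥ 0.2);
* **enrichment** — per-region relative enrichment of DMCs or site labels,
  defined as the DMC rate inside the region over the rate outside,
  `(k_r/n_r) / ((K−k_r)/(N−n_r))`, with a Fisher exact p-value — plus the
  two-sample Student t-test and the 2^−ΔΔCt qPCR fold change.

A fully seeded synthetic-data generator (`methdyn.synthetic_data`) emits a
self-contained study — genome, genes, islands, nine CGmap count files —
with beta-binomial replicate noise, a bimodal level distribution
(hypomethylated islands/promoters, hypermethylated background), and planted
DMCs, DMR blocks and dynamics labels, together with truth tables for
scoring every caller.

## Worked example

```python
from methdyn import (SimConfig, simulate_genome, simulate_counts,
                     build_annotation, build_matrix, call_dmcs,
                     classify_dynamics, enrichment_report)

cfg = SimConfig(seed=1)                       # 2 chromosomes, 9 samples
genome = simulate_genome(cfg)
counts = simulate_counts(cfg, genome)
annot = build_annotation(genome.sequences, genome.genes)
matrix = build_matrix(counts.sample_sites, cfg.design, min_cov=5,
                      group_order=list(cfg.groups))
print(f"{matrix.n_sites} CpGs covered >=5x in all {len(matrix.samples)} samples")

labels = classify_dynamics(matrix.group_levels())
dmc = call_dmcs(matrix, "Pre", "In", min_cov=8, delta=0.2, q_max=0.05)
print(f"{dmc.n_dmc} DMCs of {dmc.n_tested} tested ({100*dmc.fraction:.2f}%)")
```

prints

```
6793 CpGs covered >=5x in all 9 samples
412 DMCs of 6484 tested (6.35%)
```

6,793 of the simulated CpG sites survive the ≥ 5× coexistence filter;
6,484 still reach ≥ 8× everywhere and enter the Fisher test, and 412
(6.35 %) are called DMCs — the generator plants level shifts at 5 % of
sites plus additional shifted DMR blocks and monotone sites, so a call
rate slightly above 5 % with high precision is the expected outcome.  The
label counts (`classify_dynamics`) are dominated by HypoC island CpGs and
HyperC background CpGs, mirroring the bimodal level distribution.  The
same objects feed `enrichment_report(annot, matrix, dmc_tables=...)`,
which tabulates detected/DMC counts and relative enrichment per CGI-layer
and gene-layer category.

The shell interface mirrors the library: `methdyn simulate`, `methdyn
annotate`, `methdyn levels`, `methdyn profile`, `methdyn dynamics`,
`methdyn dmc`, `methdyn dmr`, `methdyn enrich`, and `methdyn run-all
--config config.yaml`, which runs every stage and writes a manifest of
thresholds, input hashes and row counts (re-running unchanged is a no-op).

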