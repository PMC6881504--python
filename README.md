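# acylprofiler

Downstream analysis of histone-acylation ChIP-seq data, built around the
genome-wide profiling of histone lysine butyrylation (Kbu) in rice
(*Oryza sativa*). Starting from a peak caller's output (broadPeak /
narrowPeak / BED), a gene annotation (GFF3), coverage tracks (bedGraph),
expression tables (FPKM) and qPCR Ct tables, the package computes:

- **Genomic distribution of a mark** — each peak is assigned to exactly one
  of six feature categories (promoter = 1 kb upstream of the TSS, 5′UTR,
  CDS, 3′UTR, intron, intergenic) by maximal base-pair overlap, with
  genebody/exon rollups.
- **Mark-related genes** — genes whose body overlaps ≥ 1 bp of a peak —
  and exact set comparisons between samples or cultivars (shared/specific
  counts, percentages).
- **Pairwise mark co-occurrence** — the percentage of query peaks touching
  at least one subject peak (query-anchored, hence asymmetric), including
  the restriction to intergenic peaks vs DNase-hypersensitive sites.
- **Expression-stratified metagene profiles** — mean read density in
  20 bp bins across TSS ± 1 kb, in reads per kilobase per million mapped
  reads, over six expression classes (five FPKM quintiles plus a silent
  FPKM = 0 class).
- **Combination-expression testing** — genes partitioned by presence of
  two marks (both / one / other / neither) and compared by the two-sample
  Kolmogorov–Smirnov test, with the R-style "< 2.2e-16" display floor.
- **ChIP-qPCR validation** — qPCR2 = Ct(input) − Ct(ChIP), with input as
  its own reference (qPCR1 ≡ 0); a site is enriched when qPCR2 > 1 cycle.
- **High-confidence peaks and GO enrichment** — strict score filters
  (fold enrichment > 10 and −log10 q > 100 by default), then one-sided
  hypergeometric term over-representation with Benjamini–Hochberg FDR.

A seed-deterministic synthetic-data generator (`acylprofiler.synthetic_data`)
produces toy genomes, peak sets with a controlled category mix and
controlled pairwise co-occurrence, coverage tracks, FPKM tables coupled to
peak density, and Ct tables with a known input-vs-ChIP shift — so the whole
pipeline is testable end to end without any downloads.

## Worked example

Run the shipped demo configuration (a 2-chromosome, 400-gene simulated
genome with four marks) through every stage:

```sh
acylprofiler run-all --config examples/demo_config.yaml --outdir demo_out
```

`demo_out/summary.json` then contains, among other things:

```
"category_percent": {"cds": 37.75, "five_prime_utr": 6.63, "intron": 27.25,
                     "three_prime_utr": 3.38, "promoter": 12.88, "intergenic": 12.13}
"rollups":          {"exon_pct": 47.75, "genebody_pct": 75.0}
"overlap_percent" ("Kbu" row): {"H3K9ac": 80.0, "H3K23ac": 84.13, "DHS": 60.0}
"intergenic_dhs_percent": 59.79
"qpcr": {"n_enriched": {"peak": 11, "non_peak": 0}}
```

Reading: three quarters of the simulated Kbu peaks fall in gene bodies
(matching the generator's category mix, which defaults to the distribution
observed for this mark in rice); the Kbu peak set overlaps the two
acetylation marks at the configured 80%/84% rates and open chromatin at
60%, also when restricted to intergenic peaks; and the noise-free part of
the simulated ΔCt shift (1.5 cycles) drives 11 of 12 true peak sites over
the 1-cycle enrichment threshold.

Every stage is also available separately (`simulate`, `annotate`,
`cooccur`, `profile`, `combine`, `qpcr`, `go`) and as plain library
functions; see `docs/methods.md` for the underlying definitions and the
design decisions.

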