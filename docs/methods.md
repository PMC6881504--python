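# Methods

This note records what the package computes, the conventions and defaults
it uses, and the design decisions taken where more than one reading was
defensible. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and annotation model

All interval arithmetic uses one convention: 0-based, half-open
`[start, end)` (the BED convention). GFF3 input (1-based, closed) is
converted on read and restored on write; the round trip is exact and
tested. Two intervals overlap when they share ≥ 1 bp; bookended intervals
(`[0,100)` and `[100,200)`) do not overlap but do merge at `max_gap = 0`,
matching the BEDTools defaults the original analysis chain relied on.

Gene features are modelled per gene, not per transcript: when a gene has
several transcripts, the longest one is the representative and its
5′UTR/CDS/intron/3′UTR structure defines the gene's features (longest is
deterministic; the analyses here never need isoform resolution). Introns
are defined as the gaps between consecutive exons. When an annotation has
CDS records but no explicit UTR records, exonic sequence outside the CDS
span is classified as UTR by position relative to the CDS, 5′ vs 3′ by
strand. For non-coding genes the exonic span is kept under the `cds`
label so the feature partition of the transcript span stays complete.

The TSS is the first transcribed base (`start` on +, `end − 1` on −). The
promoter is the `promoter_flank` bp (default 1000, the definition used in
the source study) directly upstream of the TSS, strand-aware, truncated at
chromosome boundaries. Intergenic space is the complement of gene bodies
and promoters.

## Peak classification and distribution report

Each peak is assigned to exactly one of six categories — promoter, 5′UTR,
CDS, 3′UTR, intron, intergenic — by maximal base-pair overlap with the
merged per-category interval sets. Ties are broken by a fixed precedence,
`cds > five_prime_utr > three_prime_utr > intron > promoter > intergenic`.
The published analysis reports disjoint percentages summing to ~100% but
does not state its resolution rule; maximal overlap with a fixed tie order
is deterministic, oracle-checkable (a per-base mask oracle reproduces it
in the tests), and yields a true partition. Percentages are reported to
two decimals with half-up rounding. Rollups are computed on unrounded
shares: exon% = 5′UTR% + CDS% + 3′UTR%, genebody% = exon% + intron%.

Mark-related genes are genes whose body overlaps ≥ 1 bp of any peak; an
`include_promoter` flag extends the rule to promoters (off by default —
the source analysis counts genes that *contain* peaks). Transposable-
element genes are handled by an explicit exclusion list supplied by the
caller rather than a built-in heuristic.

## Co-occurrence

`overlap_fraction(query, subject)` is the percentage of query peaks that
touch ≥ 1 bp of any subject peak. It is query-anchored and intentionally
asymmetric; the full matrix stores every ordered pair. Common peaks can be
reported in the query frame (default), the subject frame, or as the merged
union of both overlapping subsets. The intergenic variant first classifies
the query peaks and keeps only the intergenic ones — the construction used
to compare intergenic peaks with DNase-hypersensitive sites. No overlap
significance testing (permutation or Jaccard nulls) is attempted; the
source analysis reports raw percentages only.

## Expression groups and metagene profiles

Expression classes follow the six-way split used for the stratified
profiles: genes with FPKM exactly 0 form a "silent" class and the
remaining genes are cut into five equal-size groups by descending FPKM
(top 20%, 20–40%, …, 80–100%), ties broken by gene id for determinism.
The six-class reading ("top 20% to the bottom 0%") is ambiguous in the
source description; five quantiles plus silent reproduces a six-way split
with the stated 20% steps and is the default, with `k` configurable.
The expressed/silent threshold for *expressed-fraction* statistics is
FPKM ≥ 1.

The metagene profile covers TSS ± 1 kb in 100 bins of 20 bp, oriented in
the direction of transcription (minus-strand windows are mirrored; a
genome-mirroring equivariance test pins this down). The per-bin read
count is estimated as the mean per-base depth over the bin, and the
density is count / 0.02 kb / (total_mapped / 10⁶) — reads per kilobase
per million mapped reads. Genes are aggregated per group by the mean
(the default of the profiling tool used in the source analysis), not the
median. Genes within 1 kb of a chromosome end contribute only the covered
part of each bin; fully off-chromosome bins are excluded from the group
mean rather than zero-filled. A `total_mapped` of zero is an error; the
bedGraph reader takes the library size explicitly or from a
`#total_mapped=` header comment written by this package's writer.

## Kolmogorov–Smirnov testing

`ks_two_sample` computes the exact supremum ECDF distance D by a sorted
sweep and the p-value from the asymptotic Kolmogorov distribution at
√(mn/(m+n))·D. The tail is evaluated by an explicit pair of series — the
Jacobi theta form below x = 1.18 and the alternating exponential series
above — truncated far below double precision; the tests verify agreement
with an independent implementation to < 1e-9. No exact small-sample
enumeration is performed: the source analysis reports only the R-style
floor "< 2.2e-16", which this package mirrors in display and uses as the
significance flag for the combination analysis. The combination analysis
partitions the gene universe into both/one-mark/other-mark/neither and
tests (both vs each single-mark class) and (single-mark vs neither).

## ChIP-qPCR enrichment

Input DNA is its own reference, so its normalised threshold cycle
(qPCR1) is 0 by definition; qPCR2 = Ct(input) − Ct(ChIP) in cycles.
A site is called enriched when qPCR2 > 1 cycle, with a *strict*
inequality, as stated in the source method. Replicate Ct columns are
averaged before subtraction (replicate handling is not specified in the
source; the mean is the conventional choice). Applying the stated strict
rule to the 24 published validation loci yields 8 of 12 peak sites and 2
of 12 non-peak sites enriched; the source text says "nine out of 12"
peak sites, which the printed values do not support under any threshold
between 1.03 and 1.18 — the package implements the stated rule and
surfaces the full per-site table rather than guessing an alternative.
The shipped table reconstructs raw Ct columns from the printed ΔCt values
with a nominal 25-cycle input baseline (only the difference is ever used).

## High-confidence peaks and GO enrichment

The confidence filter keeps peaks with fold enrichment > 10 **and**
−log10(q) > 100, both strict, both configurable; peaks missing either
score are dropped with a logged count. Term over-representation is the
one-sided hypergeometric upper tail (equivalent to one-sided Fisher),
BH-FDR-corrected across tested terms at α = 0.05. Only over-representation
is tested (the source reports enriched terms, never depletion). The
background defaults to all annotated genes minus any exclusion list and is
overridable — the original analysis used an external web service whose
background and DAG-closure behaviour are opaque, so no ancestor closure
over the GO graph is applied unless the supplied term map already encodes
it.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of `SimConfig`; one global seed feeds a
named substream per generator, so adding a generator never perturbs the
draws of existing ones.

Default study conditions: 4 chromosomes × 5 Mb, 1200 genes of 1.5–4 kb
with 2–6 exons, ≥ 1 kb spacing (so promoters never run into neighbouring
genes), 2000 peaks per mark of 150–400 bp, category mix
{CDS .39, 5′UTR .07, 3′UTR .03, intron .26, promoter .12, intergenic .13}
(echoing the distribution observed for the butyrylation mark in rice),
co-occurrence targets Kbu→H3K9ac 0.80, Kbu→H3K23ac 0.84, Kbu→DHS 0.60
(echoing the strongest observed mark overlaps), expression coupling 2.0
on log2(FPKM+1) per gene-body peak with N(0,1) noise and a 20% silent
fraction, 20 bp reads at 0.002 background starts/bp plus ~30 extra reads
per peak, and a 1.5 ± 0.3-cycle ΔCt shift at truly enriched qPCR sites.
Genome sizes here are chosen so that chance peak overlap is negligible
relative to the controlled co-occurrence; the tests and the acceptance
script use these conditions as-is.

Placement details that matter for recovery: each peak is placed wholly
inside an interval of its drawn category (length clamped to the interval),
so the classifier recovers the mix up to multinomial noise. Peaks of one
mark never overlap each other, as with a real peak caller's merged
output. Co-occurrence is generated conditionally: the anchor mark (Kbu)
is placed freely by the mix; for each subject mark, a fraction f of the
anchor peaks — selected at random, stratified by feature category so the
rate holds within every category, including intergenic — each receives
one subject peak nested inside it, and the remaining subject peaks are
placed by the mix under rejection against the unselected anchor peaks.
The net effect is that the configured target *is* the realised overlap
fraction, not merely its expectation; a mark may not be both anchor and
subject.

What the generator does not emulate: read-level data (no FASTQ/BAM, no
mappability structure, no duplicates), sequence content, peak-length and
score distributions of any real caller (lengths are uniform; scores are
log-normal/exponential with configurable parameters), correlated
biological replicates, and silencing that is linked to peak absence (the
silent fraction is drawn independently of peak count, so a silent gene
can still carry peaks). Consequently, passing the recovery tests shows
the *analysis* is correct and well-calibrated on data with the assumed
structure; it says nothing about alignment, peak calling, or annotation
quality on real libraries.

## Orchestration and determinism

`run-all` chains simulate → annotate → cooccur → profile → combine → qpcr
→ go on one YAML config with full defaulting (promoter 1 kb, FPKM
threshold 1, six expression groups, 20 bp bins, fold enrichment > 10,
−log10 q > 100, qPCR2 > 1). All randomness flows from the single config
seed; summaries are JSON with sorted keys and no timestamps, so repeated
runs are byte-identical (tested). A failing stage aborts with the stage
named and partial outputs preserved.

## Known limitations

- Read-level statistics of the source study (e.g. the fraction of *peak
  reads* shared between replicate libraries) are not reconstructible from
  peak files and are not implemented.
- The exon subcategory percentages printed in the source (CDS + 5′UTR +
  3′UTR = 48.11%) do not sum to its exon total (50.41%); the residual
  class is undefined there. This package's rollups are internally exact
  by construction instead.
- The genome-scale results of the source study depend on multi-gigabyte
  external sequencing data and are covered here by the worked-example
  arithmetic plus generator-recovery testing, not by reprocessing.
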