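# Demonstration run: a small simulated dataset through every stage.
seed: 42
simulate:
  n_chroms: 2
  chrom_length: 2000000
  n_genes: 400
  n_peaks: 800
params:
  promoter_flank: 1000
  expressed_threshold: 1.0
  n_expression_groups: 6
  min_fold_enrichment: 10.0
  min_neg_log10_q: 100.0
  qpcr_threshold: 1.0
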