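# Synthetic stand-in for a 26-variant cis instrument table (IL6R +/- 300 kb,
# CRP-increasing alleles). Generated by the package's own simulator at the
# summary level: per-variant F statistics log-uniform in [31, 2033] at an
# exposure GWAS sample size of 575,531; MAFs uniform on [0.05, 0.5];
# companion LD matrix realized from 20,000 simulated individuals with
# AR(1)-correlated haplotypes (all pairwise r^2 < 0.1).
# NOT real data; positions are placeholders inside the gene window.
kind: synthetic
seed: 424242
n_variants: 26
exposure_sample_size: 575531
f_range: [31, 2033]
genome_build: unknown
region:
  chrom: "1"
  gene_start: 154377669
  gene_end: 154441926
  flank_bp: 300000
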