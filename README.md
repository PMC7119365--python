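# silknet

A tested, reusable pipeline for comparative two-condition silk-gland
transcriptomics and population genetics:

- **Quantification** (`silknet.quant`): TMM scaling factors
  (doubly-trimmed, inverse-variance-weighted mean of log ratios), FPKM,
  replicate averaging, low-expression (FPKM < 1 in more than 10 samples) and
  non-varying gene filters, expression-band tallies.
- **Differential expression** (`silknet.de`): per-stage negative-binomial
  exact test (counts rescaled to a common library size, conditioned on the
  total), method-of-moments common dispersion, Benjamini–Hochberg adjustment
  within each stage, and the dual DEG rule (|log2FC| > 1 with adjusted
  p < 0.05 for replicated stages, p < 0.01 for single-sample stages).
- **Co-expression networks** (`silknet.coexpr`): unsigned |Pearson|
  similarity, soft-threshold adjacency (`a = s^beta`, default beta = 16 or
  scale-free auto-selection), topological overlap (TOM), average-linkage
  module detection on 1−TOM with a static cut, and cross-condition consensus
  modules (quantile-scaled element-wise minimum).
- **Differential co-expression** (`silknet.diffcoex`): edge weight fold
  change (> 1.5 rule), condition-specific networks of seed genes
  (Fib-H/Fib-L/P25/Sericin1-3 by default) and their DEG partners, seed degree
  tables, pruning by selection-signature genes.
- **Selection scan** (`silknet.popgen`): two-population VCF reading
  (cyvcf2), sliding-window nucleotide diversity and Fst (Weir–Cockerham
  ratio-of-sums, Hudson optional), compound 5%/95% empirical-quantile
  outlier calling, and gene overlap.
- **Enrichment** (`silknet.enrich`): hypergeometric over-representation with
  BH, and the cross-stage functional-shift comparison of up- vs
  down-regulated sets.
- **Synthetic data** (`silknet.simulate`): seeded generators with planted
  ground truth — co-expression modules (latent stage trajectories),
  condition-specific edges, DE genes, two-population genotype panels with
  planted sweeps, and annotations with planted enriched terms. The design
  mirrors a 2-condition × 7-stage study (replicates at 0p/1p/2p/3p/5p,
  single samples at 4p and w).

All interchange formats are plain text (TSV, VCF v4.2, BED-like, JSON).
Genomic intervals are 0-based half-open; VCF positions are 1-based.

## CLI

```sh
silknet simulate --seed 1 --out study/          # synthetic study + truth.json
silknet quantify --counts study/counts.tsv --samples study/samples.tsv \
    --gene-models study/gene_models.tsv --out out/
silknet de --counts study/counts.tsv --samples study/samples.tsv --out out/
silknet network --expression out/expression.tsv --condition domestic \
    --beta 16 --out out/
silknet sweepscan --vcf study/variants.vcf --popmap study/populations.tsv \
    --gene-models study/gene_models.tsv --out out/
silknet run-all -c config.yaml                  # everything from one config
```

A `run-all` config is a YAML mapping with `inputs` (paths to counts,
samples, gene_models, annotation, seed_genes, and optionally vcf + popmap —
omitting the VCF disables the selection stages), optional `params` overrides
per stage (see `silknet.pipeline.DEFAULT_PARAMS`), and `outdir`. Reruns with
identical inputs are byte-identical.

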