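# spongelnc

Long non-coding RNAs (lncRNAs) evolve so fast that orthologues usually
cannot be found by sequence comparison, which makes it hard to say whether
lncRNA-based developmental regulation is ancient or repeatedly reinvented.
`spongelnc` implements an analysis strategy for this problem in sponges, the
oldest-diverging animal lineage with good transcriptome data: lncRNA
conservation is inferred *indirectly*, through the protein-coding genes a
lncRNA is co-expressed with. The package is aimed at comparative
transcriptomics work on non-model animals where counts, annotations and a
coding-gene homology table are available, but nothing downstream is.

## What it computes

1. **Cell-type expression analysis.** Samples with fewer than 10⁶ total
   reads are discarded; counts are normalized by median-of-ratios size
   factors; every pair of cell types (archeocyte, choanocyte, pinacocyte in
   the sponge setting) is tested gene-by-gene with a negative binomial Wald
   test (method-of-moments dispersion, t reference with n₁+n₂−2 df);
   p-values are Benjamini–Hochberg adjusted per contrast and genes with
   Q < 0.05 are assigned a Venn-style enrichment category. lncRNA expression
   is additionally binned into global quartiles Q1–Q4 (zero counts
   discarded, per-gene median of nonzero normalized counts, pooled
   25/50/75th-percentile breakpoints).
2. **Genomic context.** Each lncRNA is classified as *intergenic*,
   *cis-antisense* (≥1 exon overlapping a coding exon on the opposite
   strand) or *genic-other*, and lncRNA sets are compared on length, exon
   count and class proportions with exact Mann–Whitney U and Fisher tests.
3. **Co-expression networks.** Over a developmental time course, an edge
   connects two differentially expressed genes when the Pearson correlation
   of their log2(normalized+1) profiles satisfies r ≥ 0.95 or r ≤ −0.95
   (inclusive) with p < 0.05 (strict). A *module* is a lncRNA hub plus the
   coding genes in its ego network.
4. **Cross-species conservation.** Given coding-gene homology pairs
   (BLASTp-style table, E-value < 10⁻⁵ strict), a module pair — one hub per
   species — is called *putatively evolutionarily conserved* when at least
   one homologous pair links their member sets. An optional permutation
   test quantifies how easily the observed sharing arises by chance.

A synthetic two-species generator (`simulate_bundle`) produces count
matrices, annotations and homology tables with planted truth (modules,
conserved pairs, DE genes, positional classes), so the whole pipeline is
testable without any download.

## Worked example

The package ships the published table of homologous coding genes shared by
three sponge lncRNA modules (*AmqTCONS_00003141*, *AmqTCONS_00001337-9*,
*AmqTCONS_00003502*, demosponge side; scigt-prefixed calcisponge partners):

```python
>>> import spongelnc as sl
>>> mods_a, mods_b, hom = sl.load_published_example()
>>> matches = sl.match_modules(mods_a, mods_b, hom)
>>> summary = sl.conservation_summary(matches, mods_a, mods_b)
>>> summary["n_conserved_modules_a"]
3
>>> summary["shared_pairs_per_match"]["AmqTCONS_00001337-9|SciLnc_AmqTCONS_00001337-9"]
14
>>> print(sl.report_conserved(matches).splitlines()[0])
module_a	module_b	gene_pair	description
```

All three module headings are flagged conserved under the
"at-least-one-homologue" rule; the *AmqTCONS_00003141* block carries 7
distinct homologous pairs, including the tgf-beta receptor type-1 pair
scigt000612–Aqu2.1.41568_001.

A full synthetic run:

```bash
spongelnc simulate --seed 1 --outdir sim
spongelnc qc-de --counts sim/counts_celltype_A.tsv --meta sim/meta_celltype_A.tsv --outdir out
spongelnc network --counts sim/counts_dev_A.tsv --species A --outdir out
```

The qc-de step prints a log line reporting that 8 of 39 samples fall below
the read threshold (leaving 31), and writes `de_results.tsv`,
`enrichment.tsv` and `quartiles.tsv`.

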