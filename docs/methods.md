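# Methods

This note documents the statistical models, parameter defaults and design
choices behind `spongelnc`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Sample QC and normalization

Samples are filtered on total sequenced reads with an exclusive lower
threshold (default 10⁶: a sample with exactly one million reads is kept,
"fewer than one million" are discarded). Normalization is median-of-ratios:
the size factor of sample *j* is the median, over genes with nonzero counts
in every sample, of count/geometric-mean. When no such reference gene
exists, the code falls back to library-size factors scaled to geometric
mean one and logs a warning. Normalized counts are raw counts divided by
the size factor.

## Differential expression

Each pair of groups is tested per gene with a negative binomial Wald test
built from summary moments:

* group means μ̂ₐ, μ̂ᵦ on normalized counts;
* a pooled method-of-moments dispersion
  α̂ = Σ (nₖ−1)·α̂ₖ / (nₐ+nᵦ−2) with α̂ₖ = (s²ₖ − μ̂ₖ)/μ̂ₖ², floored at
  10⁻⁸ (no shrinkage);
* the statistic is log2 fold change over its delta-method standard error,
  with NB variance μ + αμ² per sample and a 0.5 pseudocount stabilising
  the log at low counts;
* the reference distribution is Student t with nₐ+nᵦ−2 degrees of freedom.
  The t reference (rather than normal) was chosen from a pre-build null
  simulation: with method-of-moments dispersion at the replicate numbers
  used here (15/10/6 per cell type, or 5 vs 5), the normal reference
  rejects at 6–10% for nominal 5%, while the t reference holds 5.0–5.9%.

Genes with zero raw counts in all samples of both groups get p = NA and do
not enter the multiple-testing adjustment. Benjamini–Hochberg is applied
per contrast (pairwise comparisons are reported separately); pooling across
contrasts is possible by concatenating p-value vectors before adjustment.

The test is deliberately simple — no dispersion shrinkage, no GLM fitting,
no outlier handling. It is *calibrated*, not equivalent to heavier DE
machinery; on real data with few replicates and strong mean–dispersion
trends a shrinkage estimator would have more power at small fold changes.

### Enrichment categories

A gene is differentially expressed when Q < 0.05 in at least one contrast.
A cell type joins the gene's Venn category when the gene's normalized mean
in that type exceeds its mean in every type it was significantly compared
against; singleton categories are reported as "X-enriched". This assignment
rule is the package's own choice — any rule consistent with per-contrast
significance and mean ordering would do; this one is deterministic and
never produces an empty category for a significant gene.

### Expression quartiles

Per gene, the summary value is the median of its *nonzero* normalized
counts across all samples; genes never observed are unassigned. The pooled
25/50/75th percentiles (linear interpolation) of summary values define
global breakpoints; within each group, the gene's group-mean normalized
count is binned against those breakpoints (values equal to a breakpoint
fall in the lower bin). The summary-value definition admits several
readings; the per-gene median of nonzero values was adopted because it is
robust to the strongly skewed nonzero distributions of tag-count data.

## Genomic context

Internal coordinates are 0-based half-open everywhere; GFF3 is converted on
input (1-based closed), BED12 read natively. Classification priority is:

1. *antisense_exon_overlap* — any lncRNA exon overlaps any coding exon on
   the opposite strand of the same contig;
2. *intergenic* — the lncRNA span overlaps no coding gene span on either
   strand;
3. *genic_other* — the residual class (intronic, same-strand overlap, …).

The classes are mutually exclusive and exhaustive by construction.

### Exact tests

The Mann–Whitney U statistic counts pairs with xᵢ > yⱼ plus half the ties.
For combined n ≤ 12 the null distribution is enumerated exhaustively over
all C(n, n₁) group assignments of the pooled values (tie-aware); the
two-sided p is the doubled smaller tail, capped at one (conventions for
two-sided exact p differ; the doubled-tail definition is used because it
reduces to the familiar 2·k/C(n,n₁) in the untied case). Larger samples use
the normal approximation with tie correction and 0.5 continuity correction.

Fisher's exact test sums hypergeometric probabilities (fixed margins) of
all tables no more probable than the observed one (with a 1+10⁻⁷ relative
guard against floating-point ties). The reported odds ratio is the sample
odds ratio ad/bc, not the conditional MLE.

## Co-expression networks

Profiles are log2(normalized + 1) across developmental stages; Pearson
correlation is the default (Spearman is a switch — the upstream method
this mirrors does not pin down the choice, and on the synthetic data the
two give nearly identical edge sets at |r| ≥ 0.95). Edge p-values come from
the t transform with n−2 df and are *nominal*: no multiple-testing
correction, matching a strict-threshold network definition where the
correlation cutoff, not the p-value, does the real work. Thresholds are
inclusive for r (≥ 0.95 / ≤ −0.95) and strict for p (< 0.05). Constant
profiles are skipped with a counted warning.

A module is the ego network of a lncRNA hub restricted to coding
neighbours. lncRNA–lncRNA edges stay in the edge table but create no
members; two hubs may share members. Connected-component modules were
rejected because they merge distinct hubs through shared neighbours, losing
the per-lncRNA interpretation the conservation step needs.

## Cross-species conservation

Homology rows are filtered at E-value < 10⁻⁵ (strict) on load, tolerant of
unicode minus and `1 × 10⁻⁵`-style notation; symmetric duplicates collapse
to the best E-value; many-to-many maps are allowed, and any-hit (not
best-hit) matching is the default, with `best_hit_only` available. A module
pair is conserved when ≥ 1 homologous pair links the member sets
(`min_shared_pairs` raises the bar). The optional permutation test redraws
species-B memberships as uniform same-size gene sets from the species-B
member universe and reports the add-one-smoothed fraction of permutations
reaching the observed sharing; because of smoothing its value approaches,
but never exactly equals, the exact enumeration probability.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
any particular organism's sequence content.

* **Counts** are gamma-Poisson (negative binomial, var = μ + αμ²);
  cell-type dispersion defaults to 0.05 and developmental dispersion to
  0.01 (tag-counting protocols at these depths are close to Poisson).
* **Cell-type design:** 15/10/6 retained replicates for
  archeocyte/choanocyte/pinacocyte plus 5+3 planted sub-threshold libraries
  (150–950k reads), so 39 raw samples filter to 31. Retained library sizes
  are uniform on 2–12 million reads and scale the per-sample expected
  counts. 10% of genes carry a 4-fold change in one cell type; 2% are
  silent.
* **Developmental design:** one library per stage, 16 stages by default
  (the stage count is a config knob, not a claim about any real series),
  with ±20% depth variation.
* **Planted modules:** each module has a unit-norm shared stage profile ẑ;
  member latents are √ρ·ẑ + √(1−ρ)·ε̂⊥ with ε̂⊥ orthonormalized against ẑ,
  so the *realized* hub–member latent correlation is exactly √ρ and
  member–member correlation is ρ up to O(n⁻¹ᐟ²) residual cross-terms. Plain
  mixture draws satisfy the same property only in expectation, and at 16
  stages the sampling spread of realized correlations is large enough to
  blur the planted structure the generator exists to plant. Negative-edge
  members are sign-flipped. Latents enter the mean as
  base·exp(a·l − a²/2) with amplitude a = 1.0 and base mean 1000 — a
  regime where log-scale count noise (≈ 0.15 sd) is small against the
  signal (≈ 1.4 sd), i.e. the count layer is a faithful readout of the
  latent profiles. The default module set is three conserved modules
  (8 coding members per species, one negative member) plus one private
  module per species.
* **Annotation:** coding genes with two exons at a 10 kb pitch, 50 per
  contig, alternating strands; each lncRNA is placed against a partner
  coding gene to force its class (50% intergenic, 20% antisense, 30%
  intronic by default — proportions in the range reported for sponge
  lncRNA complements).
* **Homology:** conserved-module members pair index-to-index with one
  extra many-to-many hit per module; 50% of background coding genes get
  orthologs; spurious pairs are added at `homology_noise` (default 0.5%)
  of the true table and recorded in the truth; five rows above the E-value
  cutoff exercise loader filtering.

What passing the synthetic suite shows: the pipeline recovers structure it
is statistically entitled to recover, the tests hold their nominal error
rates, and every published threshold is applied with the stated boundary
semantics. What it does not show: performance on real data with
mean–dispersion trends, batch effects, shared-pathway correlation between
"background" genes, assembly artifacts in annotations, or paralog-rich
homology tables — all of which make the real problem harder than the
planted one.

## Numerical and degenerate-input conventions

* BH adjustment passes NA p-values through and enforces step-up
  monotonicity; Q ≥ p always.
* All-zero genes: p = NA in DE, unassigned in quartiles.
* Constant profiles: correlation undefined → pair skipped, warning counted
  in the run manifest.
* Dispersion floor 10⁻⁸ prevents a negative method-of-moments estimate
  from producing a sub-Poisson variance model.
* All writers emit deterministic row/column order; every stochastic step
  takes an explicit seed, and a rerun with the same seed reproduces every
  artifact byte-for-byte.

## Problem sizes

The default generator produces 340 genes × 39 cell-type samples and
340 genes × 16 stages per species; calibration checks use 2,000 genes.
These sizes give Monte-Carlo error well inside the asserted margins while
keeping any single check in the test suite under a few seconds.
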