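# Methods

## The question and the design

Two inbred strains differ in thousands of molecular phenotypes. With
matched polyA RNA-seq ("RNA-seq1"), rRNA-depleted total RNA-seq
("RNA-seq2") and ribosome profiling ("Ribo-seq") from the same animals,
one can ask, per gene, whether a strain difference arises at
transcription and is *forwarded* to translation, is *buffered* away at
the ribosome, or is *reinforced* — created or amplified at the
translational level. Two independent RNA assays are used so that a
"Ribo-only" call cannot be explained by the idiosyncrasies of a single
RNA library protocol. The package implements that partition and the
satellite analyses that interrogate its mechanism: protein-level
confirmation through conditional-independence tests, miRNA target
enrichment, eQTL overlap, and 3'UTR SNP/motif analysis.

## Count model and differential expression

Counts are modelled as negative binomial in the mean/dispersion
parameterization, Var = μ + αμ². Per assay, the model is a log-link GLM
with a strain indicator and fixed offsets log s_j, where s_j are
median-of-ratios size factors rescaled to geometric mean 1. Because the
design is a two-group comparison, the MLE reduces to one log-mean per
group, solved by Fisher scoring vectorized across genes; the Wald
statistic is β̂/SE with SE from the Fisher information at the optimum.

Dispersion is estimated per gene by method of moments on normalized
counts, α̂ = max((pooled within-strain variance − mean)/mean², 1e−8).
With five replicates per strain this raw estimator is noisy enough to
cost real power, so the pipeline moderates it: a robust least-squares
trend α(μ) = a₀ + a₁/μ is fit across genes, and log-dispersions are
shrunk toward the trend with weights given by the sampling variance of a
log-dispersion estimate (approximated by trigamma(df/2), df = samples −
groups) versus the excess spread of gene estimates around the trend
(MAD-based, floored at 0.25²). Genes at the variance floor carry no
dispersion information and fall back to the trend. Fold-change shrinkage
(as in DESeq2's lfcShrink) is deliberately not applied: classification
needs unbiased log2 fold changes for the downstream slope analysis.

Multiple testing uses Bonferroni at adjusted p ≤ 0.01 by default, with
Benjamini–Hochberg available; both appear in the field's practice for
this analysis and neither is hard-coded. Genes that are not testable
(all-zero counts, undefined dispersion) are excluded from both the
numerator and denominator of every classification proportion.

## Depth matching and Ribo-seq QC

Sequencing technologies differ systematically in depth. Within each
animal, all libraries are downsampled to the smallest library's total by
multivariate-hypergeometric sampling — reads are physical items drawn
without replacement, so column totals match exactly and per-gene counts
keep their relative composition in expectation. A `--global` scope
matches to the minimum over all samples instead.

Ribo-seq quality is summarized by triplet periodicity: 5' read starts
are shifted by a configurable P-site offset (default +12, consistent
with the −12 nt start-codon peak of 29-mers from initiating ribosomes)
and binned by codon frame; the modal unshifted start offset is reported
as the start peak.

## Classification and its quantification

The class of a gene is a pure function of its three DE flags (table in
the README). Patterns that fit none of the four canonical rows (e.g.
significant in exactly one RNA assay) are labelled `discordant` rather
than merged, for auditability.

The degree of translational regulation per class is the standardized
major-axis slope of ribo log2FC on RNA log2FC (RNA = average of the two
RNA assays). SMA is the right line when both axes carry comparable
error; its slope is sign(r)·sd(y)/sd(x) and its CI uses the standard
pivot b·(√(B+1) ± √B), B = F₁₋α(1, n−2)(1−r²)/(n−2). Classes are
compared by a likelihood-ratio test of a shared slope: under a
bivariate-normal model the constraint "SMA slope = b" is σ_yy = b²σ_xx,
whose profile likelihood has a closed form per group (the constrained
correlation is ρ* = 2b·s_xy/(b²s_xx + s_yy)); the common slope is
profiled numerically (bounded scalar minimization on log|b|, both signs)
and Λ = −2(ℓ_common − Σℓ_group) is referred to χ² with (groups − 1) df.
The test's size and power are verified by simulation in the test suite
rather than against any external implementation.

Translational efficiency is mean Ribo FPKM over mean RNA FPKM, computed
on the CDS (UTR lengths must not enter, since ribosome footprints are
CDS-confined) after averaging across samples; genes under 1 FPKM in
either layer are undefined. Note that library-depth normalization makes
TE a *relative* quantity — only contrasts across genes or classes are
meaningful, which is how it is used (e.g. buffered genes translate at
lower efficiency).

## Proteome information flow

For three gene-level variables per strain — log RNA, log Ribo, log
protein — conditional independence under a joint Gaussian model is
equivalent to a zero partial correlation. ρ_xy·z is computed by
correlating the residuals of x|z and y|z (and cross-checked in tests
against the inverse-covariance formula), with t = ρ√(df/(1−ρ²)),
df = n−3. If translation mediates the transcript→protein path,
ρ(RNA, protein | Ribo) ≈ 0 while ρ(Ribo, protein | RNA) stays large;
generating protein from RNA instead reverses the pattern, and both
behaviors are exercised in the tests. Protein-level confirmation of
reinforced genes splits RIBO_only genes by the direction of their Ribo
fold change and applies a one-sided Mann–Whitney test to their protein
log-ratios (concordance); a label-permutation variant is available.

## miRNA, eQTL and 3'UTR layers

**miRNA.** Libraries are normalized by upper-quartile scaling over
nonzero counts (each library's UQ brought to the geometric mean of UQs,
counts rounded back to integers). DE uses a quasi-Poisson GLM — for a
two-group log-link design the closed form (group means; Pearson
dispersion φ̂ = X²/(n−2); t reference with φ̂-inflated SE) equals the
IRLS fit, verified against `statsmodels` in the tests. Enrichment
cross-tabulates RIBO_only vs RNA+RIBO genes against membership in the
union of DE-miRNA target sets, reporting Fisher's exact and χ² tests per
tissue and Fisher's combination −2Σln p ~ χ²(2k) across tissues.

**eQTL.** For each gene and marker over a recombinant-inbred panel, the
likelihood ratio compares NB models with and without the genotype
indicator, at fixed per-gene dispersion (estimated across the panel;
conservative under true genotype effects) with size-factor offsets.
Significance of the per-gene max-over-markers LR uses strain-label
permutations — permuting whole expression vectors preserves marker
linkage disequilibrium exactly — with p = (1 + #{perm max ≥ obs})/
(n_perm + 1) and BH across genes. Class enrichment is a per-class 2×2
χ² (Fisher fallback when an expected count < 1).

**3'UTR variants.** Per-gene SNP density (SNPs per kb of UTR) is
compared between classes by Mann–Whitney. The effect of a SNP on an
RBP motif is scored with the TRAP biophysical model: per window,
mismatch energy E = (1/λ)Σ ln(p_max/p_base), occupancy
R0·e^(−E)/(1 + R0·e^(−E)), summed over both strands (λ = 0.7,
R0 = exp(0.584·w − 5.66) by default; N bases contribute the column
mean). Binding p-values are empirical against mononucleotide-
composition-preserving shuffles of the 101-base SNP context (shared
shuffle order for the two alleles of a SNP, a paired design that
cancels shuffle noise in the impact |ln p_ref − ln p_alt|). A
shuffle-based null was chosen over a fitted parametric null: the
class-level comparison consumes only ranks of impacts, which are robust
to the calibration of the individual p-values. Per PWM, impacts in
RIBO_only versus RNA+RIBO genes are compared one-sided (Mann–Whitney)
and BH-adjusted across PWMs.

**ORA.** Over-representation of a gene set in user-supplied pathway
sets is an upper-tail hypergeometric test, requiring ≥ 2 overlapping
genes per pathway, Bonferroni-adjusted over tested pathways.

## The synthetic-data generator

`riboflow.sim` emulates the study's statistical structure with full
ground truth. Defaults describe a clearly powered design: 6,000 genes,
two strains × 5 replicates × 3 assays, ~2e6 reads per library, NB
dispersion 0.05, lognormal baseline expression (sd 1 on the log scale),
and per-gene |log2 effects| drawn from N(2.0, 0.5) truncated at 1 with
random sign, applied half-up/half-down so the per-gene strain ratio is
exactly 2^β while library totals stay balanced. Class proportions are
50% unregulated and one-sixth each forwarded/buffered/reinforced.

The class archetypes are generated in their pure forms: buffered genes
have their entire RNA effect erased at the ribosome
(`buffering_slope = 0`) and reinforced genes carry an RNA-side component
of β/8 (`reinforcement_slope = 8`), which a design power analysis places
safely below the detection threshold of the default design — as the
class definitions require (RIBO_only differences are, by definition,
undetectable in both RNA assays). Intermediate slope values emulate the
partial buffering/amplification seen in real tissues. Buffered genes
also translate at half efficiency by default (`te_class_factor`),
mirroring the low TE observed for such genes.

Auxiliary layers: protein is generated from the *measured* Ribo layer
(log-linear plus Gaussian noise, default sd 0.3), which makes the
RNA→Ribo→protein chain hold exactly in the simulation; miRNAs (300, 4v4
replicates at 1e5 reads, dispersion 0.02 — chosen by power analysis so
2-fold effects are detectable at BH 0.05 with df = 6) target reinforced
genes with 4-fold higher odds; the RI panel has 30 strains and 20
markers in correlated blocks, with 2.8-fold eQTL effects injected into
half of the RNA-driven (forwarded/buffered) genes; 3'UTRs are lognormal-
length random sequences where reinforced genes carry a planted consensus
site of the first PWM, twice the SNP rate, and motif-disrupting alleles
for half of their SNPs. Every layer draws from its own RNG stream split
from the master seed, so enabling one layer never changes another.

What the generator does *not* emulate: positional read structure beyond
start-offset lists, sequence-dependent count biases, polyA-vs-total RNA
protocol offsets (the two RNA assays differ only by sampling noise
unless configured otherwise), batch effects, correlated genes, or
realistic UTR base composition. Passing the validation therefore shows
that the estimators recover the structure they assume, at realistic
depths and replicate numbers — not that the assumptions hold in any
particular real data set.

One internal consequence of the NB model worth noting: library totals
concentrate around the target depth with a standard deviation governed
by α·Σμ² (≈0.5% relative at defaults), not by √depth; the tests check
totals at that scale.

## Numerical choices and degenerate inputs

- Dispersion floor 1e−8; all-zero genes are "not testable" and excluded
  from multiple-testing denominators.
- Newton/Fisher-scoring steps are clipped at ±5 on the log scale; empty
  groups yield −∞ log-means and NaN test results rather than crashes.
- SMA requires n ≥ 3 and positive variances; |r| < 0.05 triggers an
  instability warning. The common-slope profile is optimized to xatol
  1e−12 so that identical groups give Λ = 0 exactly (to float).
- Mann–Whitney tests are exact for combined n ≤ 50 without ties, normal
  approximation with tie correction otherwise.
- Permutation p-values use the add-one estimator, never returning 0.
- Degenerate conditioning (a variable linear in the conditioning
  variable) raises rather than returning a meaningless coefficient.
- TRAP scoring of an allele whose stated reference base contradicts the
  UTR sequence raises "reference mismatch".

## Problem sizes used in validation

The test suite validates at the default study scale (6,000 genes) for
classification recovery and at reduced scales elsewhere: 1,000–2,000
Monte Carlo replicates for estimator calibration (SMA CI coverage and
test size, partial-correlation level, quasi-Poisson level), 500 genes ×
200 permutations for eQTL null uniformity, 200-SNP × 5-PWM batches for
the motif layer, and a 1,000-gene end-to-end pipeline determinism check.
`scripts/acceptance.py` reports quantities from the default-scale run
plus 250-replicate Monte Carlo for the conditional-independence rates.

## Known limitations

- The Wald test with moderated dispersions is slightly conservative at
  five replicates; no Cox–Reid adjustment is applied.
- The common-slope LR test assumes bivariate normality of fold-change
  pairs within a class; heavy tails inflate its size (the permutation
  route in `class_metric_compare` is the robust alternative).
- TE and all count-derived quantities are relative (composition-
  normalized); absolute translational efficiency is not identifiable
  from counts alone.
- The eQTL scan fits one marker at a time; linked causal variants and
  multi-QTL architectures are out of scope.
- Shuffle-based binding p-values have resolution 1/(n_shuffles+1);
  ranks, not magnitudes, should be interpreted.
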