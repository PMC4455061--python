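# riboflow

Tools for partitioning strain-specific gene expression differences into
transcriptional and translational regulation from matched RNA-seq and
ribosome-profiling (Ribo-seq) count data, with downstream links to the
proteome, miRNAs, eQTLs and 3'UTR sequence variants.

Ribo-seq counts ribosome-protected mRNA fragments and so measures
translation, while RNA-seq measures transcript abundance. Given a
two-strain design (e.g. the hypertensive SHR/Ola rat versus the BN-*Lx*
reference) with biological replicates and three assays per animal —
polyA-selected RNA-seq, rRNA-depleted total RNA-seq, and Ribo-seq —
`riboflow` classifies each gene by where the strain difference acts:

| class       | RNA-seq1 | RNA-seq2 | Ribo-seq | interpretation              |
|-------------|----------|----------|----------|-----------------------------|
| `RNA+RIBO`  | DE       | DE       | DE       | forwarded (transcriptional) |
| `RNA_only`  | DE       | DE       | —        | translationally buffered    |
| `RIBO_only` | —        | —        | DE       | translationally reinforced  |
| `none`      | —        | —        | —        | unregulated                 |

Any other flag pattern is labelled `discordant` rather than silently merged.

## Methods at a glance

* **Differential expression.** Per assay, gene counts $K_{gj}$ are modelled
  as NB($\mu_{gj}, \alpha_g$) with $\mathrm{Var} = \mu + \alpha\mu^2$,
  $\mu_{gj} = s_j q_g e^{\beta_g x_j}$ (median-of-ratios size factors
  $s_j$, strain indicator $x_j$). $\beta_g$ is tested with a Wald test;
  dispersions come from a method-of-moments estimator with optional
  empirical-Bayes shrinkage toward an $a_0 + a_1/\mu$ trend. Bonferroni
  (default) or BH adjustment at $p \le 0.01$.
* **Depth matching.** Within each animal, all libraries are downsampled
  without replacement (multivariate hypergeometric) to the smallest
  library, removing depth differences between sequencing technologies.
* **Quantifying translational regulation.** Standardized major-axis (SMA)
  regression of Ribo-seq on RNA-seq log2 fold changes per class,
  $b = \mathrm{sign}(r)\,s_y/s_x$; classes are compared with a
  likelihood-ratio test of a common SMA slope (profile likelihood under
  bivariate normality, $\chi^2_{k-1}$ reference). Translational
  efficiency is the ratio of Ribo-seq to RNA-seq FPKM over the CDS.
* **Information flow.** Partial correlations $\rho_{xy\cdot z}$ across
  genes test conditional independence in the chain
  RNA $\to$ translation $\to$ protein (t reference, $df = n-3$).
* **miRNA / eQTL / 3'UTR layers.** Quasi-Poisson GLM for miRNA DE after
  upper-quartile scaling; NB trait–marker likelihood-ratio scans with
  strain-label permutations over a recombinant-inbred panel; TRAP-style
  biophysical PWM affinity scoring of 3'UTR SNP alleles with
  shuffle-based binding p-values; hypergeometric over-representation for
  user-supplied gene sets.
* **Synthetic studies.** `riboflow.sim` generates all layers with known
  ground truth (gene classes, effect sizes, miRNA targets, causal
  markers, motif-disrupting SNPs), which is how the whole pipeline is
  validated.

## Worked example

```python
from riboflow.sim import SimConfig, simulate_counts
from riboflow.prep import match_depth
from riboflow.de import run_de, classify_genes
from riboflow.regulation import sma_fit

cfg = SimConfig(n_genes=2000, seed=1)
rna1, rna2, ribo, truth = simulate_counts(cfg)
rna1, rna2, ribo = match_depth([rna1, rna2, ribo], seed=1)
classes = classify_genes(run_de(rna1), run_de(rna2), run_de(ribo))
print(classes["class_label"].value_counts().to_string())
for name, label in [("forwarded", "RNA+RIBO"), ("buffered", "RNA_only"),
                    ("reinforced", "RIBO_only")]:
    sub = classes[classes.class_label == label]
    fit = sma_fit(sub.rna_fc, sub.ribo_fc)
    print(f"{name} SMA slope: {fit.slope:.2f}"
          f"  (95% CI {fit.ci[0]:.2f}-{fit.ci[1]:.2f}, n={fit.n})")
```

prints

```
class_label
none          1008
RIBO_only      326
RNA_only       323
RNA+RIBO       318
discordant      25
forwarded SMA slope: 1.00  (95% CI 0.99-1.02, n=318)
buffered SMA slope: 0.11  (95% CI 0.10-0.13, n=323)
reinforced SMA slope: 7.00  (95% CI 6.61-7.41, n=326)
```

Forwarded genes fall on the diagonal (slope ≈ 1: RNA differences carried
1:1 into translation); buffered genes have their RNA differences erased
at the ribosome (slope ≪ 1); reinforced genes show translation-level
differences far exceeding any RNA signal (slope ≫ 1).

A command-line interface mirrors the library
(`riboflow simulate|downsample|qc-periodicity|de|classify|slopes|te|protflow|mirna|eqtl|motif|ora|run`);
`riboflow run --n-genes 6000 --seed 0 --out-dir out/` executes every stage
on a synthetic study and writes result tables plus a deterministic
manifest.

## Documentation

`docs/methods.md` describes the generative model, the estimators, their
assumptions and numerical details, and what the synthetic validation does
and does not demonstrate about real data.
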