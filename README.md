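# grace-coexpression

Copy-number-adjusted co-expression analysis for tumor transcriptomes
(GRACE: genomic regression analysis of co-expression).

## The problem

Somatic copy number alterations (SCNAs) amplify or delete chromosomal
segments spanning many contiguous genes, moving their expression up and
down together through a dosage effect. Co-expression rankings computed
on raw tumor expression are therefore dominated by the query gene's
chromosomal neighbors rather than by genes sharing its regulation or
function. This package removes that bias: for each gene *j* it fits the
simple linear regression

    y_ij = b0_j + b1_j · x_ij + e_ij

of expression *y* on gene-level relative copy number *x* across samples
*i* (ordinary least squares), and uses the residual

    r_ij = y_ij − b̂0_j − b̂1_j · x_ij

as the copy-number-adjusted expression value. Spearman rank correlation
of residual profiles then ranks co-expression partners. The residual
correlation approximates the correlation of two genes conditional on
both copy numbers (the partial correlation the package's oracle computes
exactly from the precision matrix) at a tiny fraction of the cost of
joint inference over all gene pairs.

It is intended for computational biologists working with paired
expression / copy-number cohorts (TCGA-style RSEM + GISTIC2 gene-level
tables, cell-line panels) and for anyone who wants a seeded, fully
synthetic test bed for SCNA-confounded co-expression methods.

Included beyond the core adjustment:

* the gene filters used with such data (zero-expression in over 10% of
  samples for RNA-seq or 50% for microarray; copy-number saturation in
  over 5% of samples; missing values), all with strict "over" rules;
* neighbor-bias diagnostics: genomic autocorrelation profiles (gaps
  0–40), same-chromosome counts among top-10 partners with a simulated
  random baseline, pooled intra-/inter-chromosomal rho;
* hypergeometric gene-set enrichment with Benjamini–Hochberg control;
* association of RNA or residual profiles with orthogonal per-sample
  features (Spearman for protein/metabolite, Pearson for drug response)
  and the one-sided Wilcoxon signed-rank comparison of the two methods;
* a seeded simulator of segment-structured SCNA (arm-level and
  whole-chromosome events) plus latent-factor co-regulation modules,
  with ground truth for recovery benchmarks.

## Worked example

```python
from grace import SimulationConfig, simulate_dataset, GraceModel

cfg = SimulationConfig(n_genes=300, n_samples=120, n_chromosomes=8, seed=7)
expr, cn, truth = simulate_dataset(cfg)

results = GraceModel(expr, cn, annotation=truth.annotation).fit()
print(results.summary())
```

```
     Copy-number-adjusted co-expression fit
===============================================
-----------------------------------------------
samples analyzed                            120
genes analyzed                              300
genes degenerate (constant CN)                0
median dosage slope b1                   1.0241
IQR dosage slope b1            [0.8285, 1.2217]
genes removed: underexpressed                 0
genes removed: saturated_cn                   0
genes removed: missing                        0
-----------------------------------------------
```

The median fitted dosage slope is close to the simulated effect of 1,
and no genes were lost to the filters on this clean synthetic dataset.
The neighbor-bias diagnostic shows the adjustment at work — adjacent
genes correlate strongly in the raw data because they share copy-number
events, and barely at all after residualization:

```python
raw = results.autocorrelation_profile(method="standard")
adj = results.autocorrelation_profile(method="grace")
print(f"gap-0 autocorrelation: raw {raw.mean_r[0]:.3f}, adjusted {adj.mean_r[0]:.3f}")
```

```
gap-0 autocorrelation: raw 0.158, adjusted 0.010
```

Partner tables report Spearman rho with chromosomal locations; on
residuals the top partners of `G0000` come from other chromosomes (its
co-regulation module) instead of its physical neighbors:

```python
print(results.top_coexpressed("G0000", k=3, method="grace").table.to_string(index=False))
```

```
partner      rho chromosome cytoband  rank
  G0200 0.559678       chr6    p13.2     1
  G0069 0.548823       chr2    q13.5     2
  G0114 0.539336       chr4    p11.1     3
```

## Command line

The same workflows are available as the `grace` console script:

```sh
grace simulate --out-prefix sim/                      # synthetic dataset + truth
grace residualize --expr expr.tsv --cn cn.tsv --out out/
grace coexpress --expr expr.tsv --cn cn.tsv --annotation ann.tsv \
      --gene TP53 --method grace --top-n 10 --gmt sets.gmt --out out/
grace diagnose --expr expr.tsv --cn cn.tsv --annotation ann.tsv --out out/
grace enrich --genes genes.txt --gmt sets.gmt --universe universe.txt --out enr.tsv
grace assoc --matrix residuals.tsv --kind residual --feature amax.tsv \
      --feature-kind drug_response --fdr 0.001 --out assoc.tsv
grace validate-approximation --seed 1 --out validation/
```

All inputs are tab-separated gene × sample tables (genes in the first
column, sample ids in the header; `NA` for missing), a six-column gene
annotation (`gene_id`, `chromosome`, `start`, `end`, `arm`, `cytoband`;
0-based half-open coordinates) and standard GMT gene sets. Every run
writes a `manifest.json` with inputs, seed and thresholds. Exit codes:
0 success, 2 validation error, 3 data error.

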