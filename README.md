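# methclass

Methylation-based tumor subclass discovery and downstream immune
characterization, packaged as a tested, reusable pipeline.

Cervical cancer is classically split into squamous (CSCC) and
adenocarcinoma (CA) histologies, but 450K-array DNA methylation profiles
reveal finer structure: consensus clustering of beta values separates an
adenocarcinoma-like hypermethylated class from two squamous subclasses,
one of which is specifically hypomethylated at immune-gene promoters,
expresses an immune module more highly, carries more inferred immune
infiltrate, and shows favorable survival associations that track predicted
neo-epitope burden. `methclass` implements the full analysis chain behind
that kind of study so it can be run, audited and stress-tested end to end
on cohorts with known ground truth.

## What it implements

- **Subtype discovery** — top-*n* probe selection by median absolute
  deviation (MAD) of beta values, then consensus clustering: repeated
  subsampling of samples (`pItem = 0.9`) and probes (`pFeature = 0.9`),
  Ward linkage on `1 − r` (Pearson) distance, consensus matrix
  `M_ij = #co-clustered / #co-sampled`, final labels from hierarchical
  clustering of `1 − M`.
- **Differential methylation** — SAM-style moderated statistic
  `d = (mean_B − mean_A)/(s + s0)` with label-permutation q-values; probes
  called highly/lowly methylated at beta fold change > 1.05 / < 0.95 with
  q < 0.01, and promoter-gene mapping that excludes genes carrying both
  call directions.
- **Enrichment** — strand-aware region assignment (promoter = TSS ± 1500
  bp, 5′UTR/exon/intron/3′UTR/intergenic), two-sided Fisher exact tests
  with Benjamini–Hochberg adjustment, and the pseudocount fold enrichment
  `log2(((k+1)/(K+1)) / ((n+1)/(N+1)))` for TF target-set collections.
- **Differential expression** — median-of-ratios size factors,
  method-of-moments NB dispersions with an `a0 + a1/μ` trend
  (max-of-dispersions policy), exact conditional NB test on group sums;
  genes called at |log2FC| > 1 and adjusted p < 0.001; promoter-beta
  integration and methylation/expression concordance tables.
- **Immune deconvolution** — reference-based constrained projection:
  nonnegative least squares with fractions summing to at most 1 over
  marker-probe beta signatures, with per-class comparisons.
- **Prognostic screening** — quartile expression grouping (high > 75th,
  low < 25th percentile), Kaplan–Meier curves, log-rank (Mantel–Cox)
  tests, BH adjustment, Cox proportional-hazards HR with Wald 95% CI.
- **Neo-epitope association** — Spearman correlation of gene expression
  with per-sample neo-epitope counts and a 1000-iteration random-gene
  resampling null whose FDR is the fraction of iterations in which the
  target panel fails to beat the random panel (mean p smaller and t-test
  p < 0.001).
- **Synthetic cohorts** — a generator producing beta matrices with three
  latent classes, promoter-coupled NB expression, immune-linked survival
  and neo-epitope counts, plus TF sets with a known enriched member, so
  every stage is testable against ground truth.

## Worked example

The package ships the published 24-gene immune prognostic screen for
cervical squamous carcinoma as a validation table. Reproducing its
adjusted p-value column is two lines:

```python
import pandas as pd
from methclass.datasets import immune_prognostic_screen
from methclass.survival_prognosis import bh_adjust

table = immune_prognostic_screen()
table["logrank_padj"] = bh_adjust(table["logrank_p"])
print(table[["logrank_p", "logrank_padj"]].sort_values("logrank_p").head(5).round(5))
```

```
         logrank_p  logrank_padj
gene
SELL       0.00070       0.01675
KLRK1      0.00449       0.05388
CD3E       0.00900       0.06120
IL18RAP    0.01020       0.06120
PTPRC      0.01750       0.08040
```

SELL's adjusted value 0.01675 (printed as 0.0168) is its raw log-rank p
times 24/1; CD3E and IL18RAP share 0.0612 because the step-up minimum is
attained at rank 4. Every gene in the table keeps HR < 1 with p < 0.1 —
the screen's "favorable" criterion.

Running the whole pipeline on a simulated cohort:

```bash
cat > run.yaml <<'YAML'
out_dir: demo_run
seed: 11
simulate:
  n_samples_per_class: [12, 20, 22]
  n_probes: 3000
  n_genes: 400
  immune_module_size: 40
n_top_probes: 1500
n_resamplings: 30
n_fdr_iterations: 50
YAML
methclass run-all --config run.yaml
```

The summary JSON reports, among other things, the per-class global mean
beta (class 1 highest, class 3 lowest), the promoter as the top-enriched
region for class-3 hypomethylated probes, the designated TF set recovered
at q < 0.05, class 3 with the highest immune cell fraction, most immune
module genes flagged favorable (HR < 1), and a resampling FDR near 0 for
their neo-epitope correlation. Rerunning with the same config and seed
reproduces every output byte for byte.

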