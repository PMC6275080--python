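# Methods

This note documents the statistical procedures, the design choices made
where conventions genuinely diverge, the synthetic-cohort model the test
suite relies on, and the limits of what the tests demonstrate.

## Consensus clustering

Probes are ranked by unscaled MAD (median absolute deviation from the
probe median across samples, missing values dropped per probe); the
1.4826 normal-consistency factor is omitted since ranking is
scale-invariant. Each resampling draws `⌈pItem·n⌉` samples and
`⌈pFeature·p⌉` probes without replacement, computes pairwise sample
distance `1 − r` (Pearson; not `1 − |r|`, the standard consensus-
clustering choice), and cuts a Ward dendrogram at each requested k. A
pair's consensus entry is its co-clustering count divided by its
co-sampling count; pairs never co-sampled get 0 and the diagonal is 1.
Ward linkage operates on the precomputed distance through SciPy's
Lance–Williams update (Ward.D2-equivalent on a Euclidean embedding). A
sample with zero variance on the drawn probes has undefined correlations;
its distances are set to the metric's maximum, 2. Final labels per k come
from hierarchical clustering (average linkage by default, configurable)
of `1 − consensus`, with cluster ids renumbered by lowest sample index so
results are reproducible across orderings. The number of clusters is a
user decision; the module reports the area under each k's consensus CDF
and its successive deltas but never auto-selects k. Global methylation is
compared by computing each sample's mean beta first, then two-sided
two-sample t-tests between classes on those per-sample means.

## SAM-style differential methylation

For comparison "A vs B", `d = (mean_B − mean_A)/(s + s0)` per probe,
where `s` is the pooled standard error
`sqrt((1/n_A + 1/n_B) · (SS_A + SS_B)/(n_A + n_B − 2))`. The fudge
factor `s0` is chosen by the classic grid rule: candidates at the
percentiles {0, 5, …, 100} of `s`, picking the candidate minimizing the
coefficient of variation of a robust spread (MAD/0.64) of `d` across
s-quantile bins; a cheap `median-s` policy is also offered. Significance
uses label permutations (100 by default; exhaustive enumeration of group
assignments is available and used by the oracle tests): a probe's q is
the median across permutations of the count of null |d| at or above its
observed |d|, divided by the number of observed |d| at or above it,
capped at 1 and made monotone non-increasing in |d|. Fold change is the
raw ratio of beta means (second class over first) with no offset; probes
whose denominator mean is zero are excluded and reported. Calls: high if
FC > 1.05 and q < 0.01, low if FC < 0.95 and q < 0.01. Promoter-gene
mapping assigns a gene the direction of its promoter probes' calls and
drops genes whose promoter carries both directions.

## Region assignment and enrichment

Coordinates are 1-based fully-closed throughout (Illumina MAPINFO
convention). The promoter is `[TSS − 1500, TSS + 1500]`, strand-aware
and boundary-inclusive. A probe receives every region label it overlaps
(promoter, 5′UTR, exon, 3′UTR; intron when inside a transcript extent
but in none of that chromosome's exons); a probe overlapping nothing —
including probes on chromosomes absent from the gene models — is
intergenic. Enrichment uses the two-sided Fisher exact test (sidedness
unstated in common usage; two-sided matches standard defaults and the
conclusions are insensitive to it) on `[[k, n−k], [K−k, N−K−n+k]]`,
reporting the unconditional sample odds ratio `k(N−K−n+k)/((n−k)(K−k))`
rather than the conditional MLE — a reproducible closed form. Region
tests use all array probes as background; gene-set tests use the union
of the collection's genes (non-redundant target genes) as the universe,
with an explicit-background override. BH adjustment is applied within
one query's family of categories. The pseudocount fold enrichment
`log2(((k+1)/(K+1))/((n+1)/(N+1)))` is finite for all valid margins and
strictly increasing in k.

## Negative-binomial differential expression

Classic count-based exact-test semantics (rather than shrinkage-based
GLMs, so behavior is a deterministic closed procedure): size factors by
median-of-ratios against the per-gene geometric mean over samples (only
genes positive in every sample contribute); per-gene method-of-moments
dispersion on normalized counts pooled within class, corrected by the
Poisson sampling term `mean(1/s_j)·μ`; a parametric trend
`α(μ) = a0 + a1/μ` fitted by least squares across informative genes; the
working dispersion is the maximum of gene-wise and fitted values
(conservative policy), floored at 1e−8. The exact test conditions on the
two-group count sums: each group sum is modelled as NB with
moment-matched mean `q̂0·Σs_j` and variance `mean + α·q̂0²·Σs_j²`
(Poisson when the matched variance is not above the mean), and the
two-sided p sums the probabilities of all splits no more likely than the
observed one, normalized over all splits. log2 fold changes use
normalized class means with a 0.5 pseudocount on each side; genes with
zero counts throughout both classes are dropped. Calls require
|log2FC| > 1 and BH-adjusted p < 0.001.

One caveat surfaced by testing: the textbook "multiplying one sample by
c multiplies its size factor by c" only holds for factor *ratios*,
because the geometric-mean reference absorbs `c^(1/m)`; the property
tests assert the ratio form.

## Immune deconvolution

Each sample's marker beta vector `y` is fitted as `y ≈ R·f` with
`f ≥ 0` and `Σf ≤ 1` (Houseman-style constrained projection; the mode
name is recorded in the output). The solver runs NNLS first and only
invokes SLSQP when the simplex constraint is active, so noiseless
identifiable mixtures are recovered to solver tolerance. At least 10
shared marker probes are required; within a sample, missing markers are
dropped. The immune fraction is the sum over immune-flagged cell types.
A 200-marker, 2-immune + 2-non-immune synthetic reference generator is
included (block-structured hypo/hyper marker panels, the geometry real
references have); real references load from the same TSV layout.

## Survival screening

Expression grouping uses linear-interpolation (type-7) quantiles: high
strictly above the 0.75 quantile, low strictly below the 0.25 quantile,
ties at a cut excluded with the middle. ("Fourth/second quantile" is
read as the 75th/25th percentile; both cuts are configurable since the
wording that motivates them is ambiguous.) Kaplan–Meier uses the
product-limit form with events processed before censorings at tied
times. The two-group log-rank test (hypergeometric variance, 1 df,
two-sided) and the Cox model (Efron ties, Newton–Raphson, Wald 95% CI)
are delegated to lifelines; complete separation is flagged and the fit
falls back to a minuscule ridge penalty. The screen runs per gene:
grouping → log-rank → BH across genes → Cox on the high-vs-low
indicator, flagging genes favorable when HR < 1 with log-rank p < 0.1.
Both arm sizes and per-arm death counts are reported since "events"
columns are defined differently across publications.

## Neo-epitope association

Spearman rho uses average ranks; its two-tailed p uses the
t-approximation `t = ρ·sqrt((n−2)/(1−ρ²))` for n ≥ 10 and exact
permutation enumeration for n ≤ 9. The resampling null draws, in each of
1000 iterations (configurable), a random gene set matching the target
panel's size from all non-constant genes — targets included by default,
exclusion available — computes both panels' correlation p-values against
the neo-epitope counts, and flags the iteration significant when the
targets' mean p is smaller and a two-sided t-test on the two p-vectors
gives p < 0.001. The FDR is the fraction of non-significant iterations —
the only reading under which a strong panel yields a small value like
0.005 over 1000 draws. Each iteration also records how many target rhos
exceed the random panel's mean rho (the "vs mean" convention; pairwise
and vs-max variants would be easy to add but are not).

## Synthetic cohort model

Defaults: three classes of 50/120/130 samples, 20,000 probes (35% placed
in promoters, cycling genes so every promoter is covered), 2,000 genes
on one synthetic chromosome with three exons and UTRs each, 30%
informative probes. Informative probes split 60/40: a class-1
hypermethylated block (Beta(8,2) in class 1 vs the probe's baseline
elsewhere — the adenocarcinoma-like global shift) and a class-3
hypomethylated block (Beta(2,8) in class 3), which contains all immune
gene promoter probes and whose remainder is drawn with a 70% promoter
bias so the class-3 hypomethylation signature concentrates in promoters.
Uninformative promoter probes get gene-specific baselines
(Beta(m_g·10, (1−m_g)·10), m_g ~ Beta(2,2)), giving promoters realistic
between-gene spread; other probes are Beta(5,5). Expression is NB
(dispersion 0.2) with gene means log-linear in the class-expected mean
promoter beta (natural-log slope −2.0, centered at 0.5) and an extra
+1.5 log2-fold for the 100 immune-module genes in class 3; library
depths are log-normal (σ = 0.25). The per-sample immune score is the
standardized mean log2 depth-normalized immune-gene expression. Survival
is exponential with hazard `3e−4·exp(−0.7·score)` per day and
administrative censoring at the horizon giving ~40% censoring at
baseline; histology is CA with probability 0.9 in class 1 and CSCC with
probability 0.95 elsewhere; neo-epitope counts are Poisson with log-mean
`log 30 + 0.5·score`. One TF set is seeded with 60% of the immune module
plus decoys; 49 others are random. All randomness flows through a single
seeded generator, so cohorts are bit-reproducible.

What the generator deliberately omits: probe-type (I/II) chemistry,
batch and purity effects, correlated probe blocks within CpG islands,
HPV status, and covariate-structured censoring. Passing tests therefore
demonstrate correctness of the statistical machinery and sensible
behavior under the assumed generative structure — not performance on
real 450K data, where noise is heavier-tailed and class boundaries are
softer.

## Problem sizes used by tests and the acceptance script

Oracle and calibration checks run at the sizes stated in their tests:
the complete Fisher sweep over all margins ≤ 12; 1000 random
fold-enrichment cases; consensus clustering on the default cohort using
the top 5,000 MAD probes and 30 resamplings (the 1000-resampling,
30,000-probe defaults remain the production configuration; recovery is
already exact at the reduced setting); the SAM global null on 20,000
probes with 50 permutations; 2,000-gene NB and 2,000-replicate log-rank
null simulations; 200-iteration resampling-FDR runs; and an end-to-end
determinism check on a 54-sample, 2,500-probe simulate config — chosen
as the smallest sizes at which each property is stable and informative.

## Known limitations

- The SAM q-value is the classic plug-in FDR estimate; it is not a
  per-probe posterior and can be conservative at small permutation
  counts.
- The NB exact test enumerates all splits of the conditioned total, so
  its cost grows linearly with group-sum magnitude; very deep cohorts
  would want an asymptotic switch that is not implemented.
- The deconvolution reference must be linearly independent across cell
  types; collinear references return one feasible solution without
  warning.
- BH adjustment is not idempotent (re-adjusting adjusted values can
  inflate them); adjusted columns should be computed once from raw
  p-values.
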