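"""Negative-binomial differential expression with exact-test semantics.

The workflow mirrors the classic count-based NB test: median-of-ratios
size factors, per-gene method-of-moments dispersions with a fitted
``a0 + a1/mu`` trend (taking the maximum of gene-wise and fitted values),
and a two-sided exact conditional test on the per-group count sums.
Genes are called differentially expressed when |log2 fold change| exceeds
a threshold and the Benjamini-Hochberg adjusted p-value is below another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_enrichment import bh_qvalues

_DISPERSION_FLOOR = 1e-8


@dataclass
class DEConfig:
    lfc_threshold: float = 1.0  # log2
    padj_threshold: float = 0.001
    dispersion_policy: str = "conservative"  # max(gene-wise, fitted trend)

    def validate(self) -> None:
        if self.lfc_threshold <= 0 or not 0 < self.padj_threshold < 1:
            raise ValueError("invalid DE thresholds")


@dataclass
class DEResult:
    table: pd.DataFrame  # base_mean_a, base_mean_b, log2_fold_change, p, padj, call
    size_factors: pd.Series
    dispersions: pd.Series


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    The reference is the per-gene geometric mean over samples; only genes
    with nonzero counts in every sample contribute.
    """
    arr = counts.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; filter the matrix first"
        )
    log_arr = np.log(arr[all_pos])
    log_geo = log_arr.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_arr - log_geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersions(
    counts: pd.DataFrame,
    labels: pd.Series,
    sf: pd.Series,
    policy: str = "conservative",
) -> pd.Series:
    """Per-gene NB dispersion alpha (variance = mu + alpha * mu^2).

    Gene-wise values come from a method-of-moments estimate on normalized
    counts pooled within class; a parametric trend ``alpha(mu) = a0 + a1/mu``
    is then fitted across genes and, under the "conservative" policy, each
    gene receives the maximum of its own estimate and the trend value.
    """
    labels = labels.loc[counts.columns]
    sf = sf.loc[counts.columns]
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    classes = sorted(labels.unique())
    var_within = np.zeros(norm.shape[0])
    df = 0
    for c in classes:
        cols = (labels == c).to_numpy()
        if cols.sum() < 2:
            raise ValueError(f"class {c!r} needs >= 2 samples")
        var_within += norm[:, cols].var(axis=1, ddof=1) * (cols.sum() - 1)
        df += cols.sum() - 1
    var_within /= df
    base_mean = norm.mean(axis=1)
    # bias term: sampling variance of normalized counts under Poisson
    xi = float(np.mean(1.0 / sf.to_numpy()))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var_within - xi * base_mean) / base_mean**2
    raw = np.where(np.isfinite(raw), raw, 0.0)
    genewise = np.maximum(raw, _DISPERSION_FLOOR)
    if policy == "gene-wise":
        return pd.Series(genewise, index=counts.index, name="dispersion")
    # fit alpha = a0 + a1/mu on genes with informative estimates
    use = (base_mean > 0) & (raw > 0)
    fitted = np.full_like(genewise, _DISPERSION_FLOOR)
    if use.sum() >= 10:
        X = np.column_stack([np.ones(use.sum()), 1.0 / base_mean[use]])
        coef, *_ = np.linalg.lstsq(X, raw[use], rcond=None)
        with np.errstate(divide="ignore"):
            fitted = coef[0] + coef[1] / base_mean
        fitted = np.where(np.isfinite(fitted), fitted, _DISPERSION_FLOOR)
    else:  # degenerate fit: fall back to gene-wise values
        import warnings

        warnings.warn("too few informative genes for a dispersion trend fit")
        fitted = genewise
    final = np.maximum(np.maximum(genewise, fitted), _DISPERSION_FLOOR)
    return pd.Series(final, index=counts.index, name="dispersion")


def _nb_logpmf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    """NB log-pmf parameterized by mean/variance; Poisson when var <= mean."""
    if var <= mean * (1 + 1e-8):
        return stats.poisson.logpmf(x, mean)
    size = mean**2 / (var - mean)
    return stats.nbinom.logpmf(x, size, size / (size + mean))


def nb_exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    sf_a: np.ndarray,
    sf_b: np.ndarray,
    dispersion: float,
) -> float:
    """Two-sided exact conditional NB test on the group sums.

    Conditions on the total ``k = ka + kb``: sums all splits ``(a, k-a)``
    whose joint probability does not exceed the observed one, normalized
    by the total over all splits.  Group sums are modelled as NB with
    moment-matched mean/variance under a common per-count rate.
    """
    ka, kb = int(np.sum(counts_a)), int(np.sum(counts_b))
    k = ka + kb
    if k == 0:
        return 1.0
    sa, sb = float(np.sum(sf_a)), float(np.sum(sf_b))
    q0 = k / (sa + sb)
    mean_a, mean_b = q0 * sa, q0 * sb
    var_a = mean_a + dispersion * q0**2 * float(np.sum(np.square(sf_a)))
    var_b = mean_b + dispersion * q0**2 * float(np.sum(np.square(sf_b)))
    a = np.arange(k + 1)
    logp = _nb_logpmf(a, mean_a, var_a) + _nb_logpmf(k - a, mean_b, var_b)
    logp_obs = logp[ka]
    log_total = np.logaddexp.reduce(logp)
    keep = logp <= logp_obs + 1e-10  # tolerate float ties
    p = float(np.exp(np.logaddexp.reduce(logp[keep]) - log_total))
    return min(p, 1.0)


def call_de_genes(
    counts: pd.DataFrame,
    labels: pd.Series,
    pair: tuple,
    config: DEConfig | None = None,
) -> DEResult:
    """Differential expression for ``pair[0] vs pair[1]``.

    log2 fold change is the size-factor-normalized mean of the second
    class over the first, with a pseudocount of 0.5 on each side.  Genes
    with zero counts in every sample of both classes are dropped.
    """
    cfg = config or DEConfig()
    cfg.validate()
    labels = labels.loc[counts.columns]
    first, second = pair
    keep_cols = labels.isin([first, second]).to_numpy()
    sub = counts.loc[:, keep_cols]
    sub_labels = labels[keep_cols]
    sf = size_factors(counts).loc[sub.columns]
    expressed = (sub.to_numpy() > 0).any(axis=1)
    sub = sub.loc[expressed]
    disp = estimate_dispersions(
        sub, sub_labels, sf, policy=cfg.dispersion_policy
    )
    a_cols = (sub_labels == first).to_numpy()
    b_cols = (sub_labels == second).to_numpy()
    arr = sub.to_numpy(dtype=float)
    sf_arr = sf.to_numpy()
    norm = arr / sf_arr[None, :]
    mean_a = norm[:, a_cols].mean(axis=1)
    mean_b = norm[:, b_cols].mean(axis=1)
    lfc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    pvals = np.array(
        [
            nb_exact_test(
                arr[i, a_cols], arr[i, b_cols],
                sf_arr[a_cols], sf_arr[b_cols], disp.iloc[i],
            )
            for i in range(arr.shape[0])
        ]
    )
    padj = bh_qvalues(pvals)
    call = np.where(
        (np.abs(lfc) > cfg.lfc_threshold) & (padj < cfg.padj_threshold),
        np.where(lfc > 0, "up", "down"),
        "none",
    )
    table = pd.DataFrame(
        {
            "base_mean_a": mean_a,
            "base_mean_b": mean_b,
            "log2_fold_change": lfc,
            "p": pvals,
            "padj": padj,
            "call": call,
        },
        index=sub.index,
    )
    return DEResult(table=table, size_factors=sf, dispersions=disp)


def promoter_beta_of_gene_sets(
    gene_sets: dict[str, list[str]],
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    gene_models: pd.DataFrame,
    labels: pd.Series,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, list[str]]:
    """Mean promoter beta per gene per class for each gene set, with t-tests.

    Returns (per-set gene x class mean-beta tables, a t-test table with one
    row per set and class pair, genes skipped for lack of promoter probes).
    """
    from .annotation_enrichment import probes_to_promoter_genes

    labels = labels.loc[beta.columns]
    classes = sorted(labels.unique())
    probe_genes = probes_to_promoter_genes(beta.index, annotation, gene_models)
    gene_probes: dict[str, list[str]] = {}
    for probe, genes in probe_genes.items():
        for g in genes:
            gene_probes.setdefault(g, []).append(probe)

    all_genes = set().union(*[set(g) for g in gene_sets.values()])
    if not all_genes & set(gene_probes):
        raise ValueError("no query gene has promoter probes in the beta matrix")

    per_set: dict[str, pd.DataFrame] = {}
    skipped: list[str] = []
    rows = []
    for name, genes in gene_sets.items():
        if len(genes) == 0:
            raise ValueError(f"gene set {name!r} is empty")
        usable = [g for g in genes if g in gene_probes]
        skipped.extend(g for g in genes if g not in gene_probes)
        per_gene = {}
        for g in usable:
            sub = beta.loc[gene_probes[g]]
            per_gene[g] = sub.mean(axis=0).groupby(labels).mean()
        tbl = pd.DataFrame(per_gene).T
        tbl.columns.name = "class"
        per_set[name] = tbl
        for i, a in enumerate(classes):
            for b in classes[i + 1:]:
                if a in tbl.columns and b in tbl.columns and len(tbl) >= 2:
                    res = stats.ttest_ind(tbl[a], tbl[b])
                    rows.append(
                        dict(set=name, class_a=a, class_b=b,
                             mean_a=tbl[a].mean(), mean_b=tbl[b].mean(),
                             p=res.pvalue)
                    )
    tests = pd.DataFrame(rows)
    return per_set, tests, skipped


def dm_de_overlap(
    dm_high: set[str], dm_low: set[str], de: DEResult
) -> tuple[pd.DataFrame, float, float]:
    """2x2 methylation-direction x expression-direction concordance.

    Returns (count table, Fisher odds ratio, p) where an excess of
    hypo+up and hyper+down genes drives the odds ratio above 1.
    """
    up = set(de.table.index[de.table["call"] == "up"])
    down = set(de.table.index[de.table["call"] == "down"])
    tbl = pd.DataFrame(
        {
            "up": [len(dm_low & up), len(dm_high & up)],
            "down": [len(dm_low & down), len(dm_high & down)],
        },
        index=["hypo", "hyper"],
    )
    odds_ratio, p = stats.fisher_exact(
        [[tbl.loc["hypo", "up"], tbl.loc["hypo", "down"]],
         [tbl.loc["hyper", "up"], tbl.loc["hyper", "down"]]]
    )
    return tbl, float(odds_ratio), float(p)
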