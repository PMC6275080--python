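"""Neo-epitope burden correlations and the random-gene resampling null.

Spearman correlation links each gene's expression to the per-sample
neo-epitope count.  The significance of a target gene panel (e.g. the 24
prognostic immune genes) is assessed against a resampling null: in each
of ``n_iterations`` draws, an equal-sized random gene set is sampled, the
two p-value vectors are compared by a two-sided t-test, and the draw is
flagged significant when the target genes' mean p is smaller with t-test
p < 0.001.  The false discovery rate of the panel is the fraction of
draws that fail that conjunction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EXACT_PERMUTATION_MAX_N = 9


def _spearman_t_pvalue(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _exact_permutation_pvalue(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """P(|rho_perm| >= |rho|) over all permutations of y's ranks (n <= 9)."""
    import itertools

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx_c = rx - rx.mean()
    denom_x = np.sqrt(np.sum(rx_c**2))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        ryp = ry[list(perm)]
        ryp_c = ryp - ryp.mean()
        denom = denom_x * np.sqrt(np.sum(ryp_c**2))
        r = np.dot(rx_c, ryp_c) / denom
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with a two-tailed p-value.

    The p-value uses the t-distribution approximation except for n <= 9,
    where the exact permutation null is enumerated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant vector: Spearman correlation undefined")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if x.size <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_pvalue(x, y, rho)
    else:
        p = _spearman_t_pvalue(rho, x.size)
    return rho, p


def _rank_matrix(expr: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, expr)


def _bulk_spearman(
    expr_ranks: np.ndarray, neo_ranks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman rho and t-approximation p against one rank vector."""
    n = neo_ranks.size
    xc = expr_ranks - expr_ranks.mean(axis=1, keepdims=True)
    yc = neo_ranks - neo_ranks.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    rho = (xc @ yc) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    return rho, p


def gene_burden_correlations(
    expr: pd.DataFrame, neo_counts: pd.Series, gene_list
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene Spearman correlation of expression with neo-epitope burden.

    Returns (records with rho, p and a significance flag at p < 0.05,
    genes skipped because absent from ``expr``).
    """
    shared = expr.columns.intersection(neo_counts.index)
    if len(shared) < 4:
        raise ValueError("fewer than 4 samples shared between inputs")
    skipped = [g for g in gene_list if g not in expr.index]
    genes = [g for g in gene_list if g in expr.index]
    sub = expr.loc[genes, shared].to_numpy(dtype=float)
    ranks = _rank_matrix(sub)
    neo_ranks = stats.rankdata(neo_counts.loc[shared].to_numpy(dtype=float))
    rho, p = _bulk_spearman(ranks, neo_ranks)
    table = pd.DataFrame(
        {"rho": rho, "p": p, "significant": p < 0.05},
        index=pd.Index(genes, name="gene"),
    )
    return table, skipped


@dataclass
class ResamplingFdrResult:
    n_iterations: int
    fdr: float
    iterations: pd.DataFrame  # mean_p_target, mean_p_random, ttest_p,
    #                           significant, n_target_rho_above
    target_table: pd.DataFrame
    seed: int


def resampling_fdr(
    expr: pd.DataFrame,
    neo_counts: pd.Series,
    target_genes,
    n_iterations: int = 1000,
    seed: int = 0,
    exclude_targets_from_pool: bool = False,
) -> ResamplingFdrResult:
    """Random-gene resampling null for a target panel's burden correlations.

    Each iteration draws ``len(target_genes)`` genes without replacement
    from all (non-constant) genes in ``expr`` and is flagged significant
    when the target panel's mean correlation p-value is below the random
    set's with a two-sided t-test p < 0.001.  ``fdr`` is the fraction of
    iterations that are not significant.  Also recorded per iteration: the
    number of target genes whose rho exceeds the random set's mean rho.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    target_genes = list(target_genes)
    missing = [g for g in target_genes if g not in expr.index]
    if missing:
        raise ValueError(f"target genes absent from expression: {missing}")
    shared = expr.columns.intersection(neo_counts.index)
    if len(shared) < 4:
        raise ValueError("fewer than 4 samples shared between inputs")
    sub = expr.loc[:, shared]
    neo_ranks = stats.rankdata(neo_counts.loc[shared].to_numpy(dtype=float))
    # pool excludes constant genes (undefined rho)
    variable = sub.nunique(axis=1) > 1
    pool = sub.index[variable]
    if exclude_targets_from_pool:
        pool = pool.difference(target_genes)
    pool_arr = np.asarray(pool)

    all_ranks = _rank_matrix(sub.loc[pool].to_numpy(dtype=float))
    rho_all, p_all = _bulk_spearman(all_ranks, neo_ranks)
    rho_by_gene = pd.Series(rho_all, index=pool)
    p_by_gene = pd.Series(p_all, index=pool)

    target_rho = rho_by_gene.loc[target_genes].to_numpy()
    target_p = p_by_gene.loc[target_genes].to_numpy()
    target_table = pd.DataFrame(
        {"rho": target_rho, "p": target_p},
        index=pd.Index(target_genes, name="gene"),
    )

    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iterations):
        picked = rng.choice(pool_arr, size=len(target_genes), replace=False)
        rand_p = p_by_gene.loc[picked].to_numpy()
        rand_rho = rho_by_gene.loc[picked].to_numpy()
        tt = stats.ttest_ind(target_p, rand_p)
        significant = bool(
            target_p.mean() < rand_p.mean() and tt.pvalue < 0.001
        )
        rows.append(
            dict(
                mean_p_target=target_p.mean(),
                mean_p_random=rand_p.mean(),
                ttest_p=float(tt.pvalue),
                significant=significant,
                n_target_rho_above=int((target_rho > rand_rho.mean()).sum()),
            )
        )
    iterations = pd.DataFrame(rows)
    fdr = float((~iterations["significant"]).mean())
    return ResamplingFdrResult(
        n_iterations=n_iterations, fdr=fdr, iterations=iterations,
        target_table=target_table, seed=seed,
    )
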