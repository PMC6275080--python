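"""Genomic-region assignment and Fisher-based enrichment statistics.

A probe is assigned every region label whose interval it overlaps:
promoter (TSS +/- 1500 bp, strand-aware, closed interval), 5'UTR, exon,
intron (inside the transcript extent but in no exon of that gene), 3'UTR.
A probe overlapping nothing is intergenic.  Enrichment of a query set
against a background uses Fisher's exact test (two-sided) with the sample
odds ratio, Benjamini-Hochberg adjustment across categories, and a
pseudocount log2 fold enrichment
``log2(((k+1)/(K+1)) / ((n+1)/(N+1)))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PROMOTER_FLANK = 1500
REGION_LABELS = ("promoter", "5UTR", "exon", "intron", "3UTR", "intergenic")


@dataclass
class EnrichmentRecord:
    name: str
    k: int  # hits in query
    K: int  # category size in background
    n: int  # query size
    N: int  # background size
    odds_ratio: float
    p: float
    q: float
    log2_fold_enrichment: float


def _interval_hits(
    starts: np.ndarray, ends: np.ndarray, pos: np.ndarray
) -> np.ndarray:
    """Boolean: does each position overlap any [start, end] (closed)?"""
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    # running maximum of ends lets a binary search bound the candidates
    run_max = np.maximum.accumulate(ends)
    idx = np.searchsorted(starts, pos, side="right")
    hit = np.zeros(len(pos), dtype=bool)
    for i, (p, j) in enumerate(zip(pos, idx)):
        lo = j
        while lo > 0 and run_max[lo - 1] >= p:
            if starts[lo - 1] <= p <= ends[lo - 1]:
                hit[i] = True
                break
            lo -= 1
    return hit


def _collect_intervals(gene_models: pd.DataFrame, chrom: str):
    """Per-label interval arrays for one chromosome, plus per-gene extents."""
    sub = gene_models[gene_models["chrom"] == chrom]
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tss = sub["tss"].to_numpy()
    out["promoter"] = (tss - PROMOTER_FLANK, tss + PROMOTER_FLANK)
    for label, col in (("5UTR", "utr5"), ("exon", "exons"), ("3UTR", "utr3")):
        starts, ends = [], []
        for ivs in sub[col]:
            for lo, hi in ivs:
                starts.append(lo)
                ends.append(hi)
        out[label] = (np.asarray(starts, dtype=np.int64),
                      np.asarray(ends, dtype=np.int64))
    out["_tx"] = (sub["tx_start"].to_numpy(), sub["tx_end"].to_numpy())
    return out


def assign_regions(
    annotation: pd.DataFrame, gene_models: pd.DataFrame
) -> pd.DataFrame:
    """Boolean probe x region-label matrix (one probe may carry several)."""
    flags = pd.DataFrame(
        False, index=annotation.index, columns=list(REGION_LABELS)
    )
    known_chroms = set(gene_models["chrom"].unique())
    for chrom, grp in annotation.groupby("chrom"):
        pos = grp["pos"].to_numpy()
        if chrom not in known_chroms:
            flags.loc[grp.index, "intergenic"] = True
            continue
        ivs = _collect_intervals(gene_models, chrom)
        hit_any = np.zeros(len(pos), dtype=bool)
        for label in ("promoter", "5UTR", "exon", "3UTR"):
            h = _interval_hits(*ivs[label], pos)
            flags.loc[grp.index, label] = h
            hit_any |= h
        in_tx = _interval_hits(*ivs["_tx"], pos)
        in_exon = flags.loc[grp.index, "exon"].to_numpy()
        intron = in_tx & ~in_exon
        flags.loc[grp.index, "intron"] = intron
        hit_any |= in_tx
        flags.loc[grp.index, "intergenic"] = ~hit_any
    return flags


def promoter_probe_ids(
    annotation: pd.DataFrame, gene_models: pd.DataFrame
) -> pd.Index:
    regions = assign_regions(annotation, gene_models)
    return regions.index[regions["promoter"]]


def probes_to_promoter_genes(
    probe_ids, annotation: pd.DataFrame, gene_models: pd.DataFrame
) -> dict[str, list[str]]:
    """Map probe id -> list of gene symbols whose promoter it overlaps."""
    sub = annotation.loc[annotation.index.intersection(pd.Index(probe_ids))]
    out: dict[str, list[str]] = {p: [] for p in sub.index}
    for chrom, grp in sub.groupby("chrom"):
        genes = gene_models[gene_models["chrom"] == chrom]
        if genes.empty:
            continue
        tss = genes["tss"].to_numpy()
        syms = genes.index.to_numpy()
        order = np.argsort(tss)
        tss, syms = tss[order], syms[order]
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(tss, pos - PROMOTER_FLANK, side="left")
        hi = np.searchsorted(tss, pos + PROMOTER_FLANK, side="right")
        for probe, a, b in zip(grp.index, lo, hi):
            out[probe] = list(syms[a:b])
    return out


def fisher_enrichment(
    k: int, K: int, n: int, N: int, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Sample odds ratio and Fisher exact p for the 2x2 enrichment table.

    Table: [[k, n-k], [K-k, N-K-n+k]] — query hits, query misses,
    background-only hits, neither.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and N - K - n + k >= 0):
        raise ValueError(f"inconsistent margins k={k} K={K} n={n} N={N}")
    table = np.array([[k, n - k], [K - k, N - K - n + k]])
    odds_ratio, p = stats.fisher_exact(table, alternative=alternative)
    return float(odds_ratio), float(p)


def fold_enrichment(k: int, K: int, n: int, N: int) -> float:
    """Pseudocount log2 fold enrichment of the query hit rate."""
    return float(np.log2(((k + 1) / (K + 1)) / ((n + 1) / (N + 1))))


def bh_qvalues(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _records(
    names, ks, Ks, n: int, N: int
) -> list[EnrichmentRecord]:
    raw = [fisher_enrichment(k, K, n, N) for k, K in zip(ks, Ks)]
    qs = bh_qvalues([p for _, p in raw])
    return [
        EnrichmentRecord(
            name=name, k=int(k), K=int(K), n=n, N=N,
            odds_ratio=orr, p=p, q=float(q),
            log2_fold_enrichment=fold_enrichment(k, K, n, N),
        )
        for name, k, K, (orr, p), q in zip(names, ks, Ks, raw, qs)
    ]


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(set=r.name, k=r.k, K=r.K, n=r.n, N=r.N, odds_ratio=r.odds_ratio,
                 p=r.p, q=r.q, log2_fold_enrichment=r.log2_fold_enrichment)
            for r in records
        ]
    ).set_index("set")


def region_enrichment(
    dm_probes, all_probes, regions: pd.DataFrame
) -> list[EnrichmentRecord]:
    """One Fisher test per region label; background = all array probes."""
    dm_probes = pd.Index(dm_probes)
    all_probes = pd.Index(all_probes)
    if len(dm_probes) == 0:
        raise ValueError("empty query probe set")
    if not dm_probes.isin(all_probes).all():
        raise ValueError("query probes must be a subset of the background")
    sub = regions.loc[all_probes]
    n, N = len(dm_probes), len(all_probes)
    names = list(REGION_LABELS)
    Ks = [int(sub[label].sum()) for label in names]
    ks = [int(sub.loc[dm_probes, label].sum()) for label in names]
    return _records(names, ks, Ks, n, N)


def geneset_enrichment(
    query_genes,
    collection: dict[str, list[str]],
    background=None,
) -> list[EnrichmentRecord]:
    """Fisher enrichment of a gene list in each set of a GMT collection.

    The default background universe N is the union of all genes in the
    collection (non-redundant target genes); pass ``background`` to use an
    explicit universe instead.  The query is intersected with the universe
    first.
    """
    if len(query_genes) == 0:
        raise ValueError("empty query gene list")
    if background is not None:
        universe = set(background)
    else:
        universe = set()
        for genes in collection.values():
            universe.update(genes)
    query = set(query_genes) & universe
    if not query:
        import warnings

        warnings.warn("query does not intersect the collection universe")
    n, N = len(query), len(universe)
    names = list(collection)
    Ks = [len(set(collection[s]) & universe) for s in names]
    ks = [len(set(collection[s]) & query) for s in names]
    return _records(names, ks, Ks, n, N)
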