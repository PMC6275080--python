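"""MAD probe selection and consensus clustering of beta-value profiles.

The clustering follows the resampling scheme of consensus clustering:
repeatedly subsample items (samples) and features (probes), cluster each
subsample with Ward linkage on 1 - Pearson distance, and record for every
sample pair the fraction of co-sampled iterations in which the pair
co-clusters.  Final labels come from hierarchical clustering of
1 - consensus.  The number of clusters is a user decision; per-k consensus
CDF areas are reported to support it but never auto-selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .annotation_enrichment import promoter_probe_ids


@dataclass
class ClusteringConfig:
    n_top_probes: int = 30_000
    promoter_only: bool = False
    n_resamplings: int = 1000
    p_item: float = 0.9
    p_feature: float = 0.9
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    final_linkage: str = "average"  # linkage used on 1 - consensus
    seed: int = 0

    def validate(self, n_samples: int | None = None) -> None:
        if not (0 < self.p_item <= 1 and 0 < self.p_feature <= 1):
            raise ValueError("p_item and p_feature must lie in (0, 1]")
        if n_samples is not None and any(
            not 2 <= k <= n_samples - 1 for k in self.k_range
        ):
            raise ValueError("every k must satisfy 2 <= k <= n_samples - 1")


@dataclass
class ConsensusResult:
    samples: list[str]
    consensus: dict[int, np.ndarray]  # k -> sample x sample consensus matrix
    co_sampled: np.ndarray  # sample x sample co-sampling counts
    labels: dict[int, pd.Series]  # k -> final labels (1..k)
    cdf_area: dict[int, float] = field(default_factory=dict)


def select_top_mad_probes(
    beta: pd.DataFrame,
    n: int,
    promoter_only: bool = False,
    annotation: pd.DataFrame | None = None,
    gene_models: pd.DataFrame | None = None,
) -> pd.Index:
    """Return the ``n`` probes with the highest (unscaled) MAD of beta.

    MAD is the median absolute deviation from the probe's median across
    samples, missing values ignored per probe.  With ``promoter_only`` the
    candidate pool is restricted to probes within TSS +/- 1500 bp.
    """
    pool = beta
    if promoter_only:
        if annotation is None or gene_models is None:
            raise ValueError("promoter_only needs annotation and gene_models")
        prom = promoter_probe_ids(annotation, gene_models)
        pool = beta.loc[beta.index.intersection(prom)]
    if n > pool.shape[0]:
        raise ValueError(
            f"requested {n} probes but only {pool.shape[0]} are eligible"
        )
    arr = pool.to_numpy()
    med = np.nanmedian(arr, axis=1, keepdims=True)
    mad = np.nanmedian(np.abs(arr - med), axis=1)
    order = np.argsort(-mad, kind="stable")[:n]
    return pool.index[np.sort(order)]


def _pearson_distance(x: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r between rows; undefined correlations -> 2."""
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    d = 1.0 - r
    bad = (sd == 0) | ~np.isfinite(sd)
    d[bad, :] = 2.0
    d[:, bad] = 2.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _ward_cut(dist: np.ndarray, ks: tuple[int, ...]) -> dict[int, np.ndarray]:
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method="ward")
    return {k: fcluster(z, t=k, criterion="maxclust") for k in ks}


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Renumber cluster labels 1..k in order of first (lowest-index) appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def consensus_cluster(
    beta_subset: pd.DataFrame, config: ClusteringConfig | None = None
) -> ConsensusResult:
    """Consensus clustering of samples (columns) over the given probes."""
    cfg = config or ClusteringConfig()
    samples = list(beta_subset.columns)
    n_samples = len(samples)
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    cfg.validate(n_samples)
    x = beta_subset.to_numpy().T  # samples x probes
    if np.isnan(x).all(axis=1).any():
        raise ValueError("a sample has all-missing beta values")
    n_probes = x.shape[1]
    n_item = int(np.ceil(cfg.p_item * n_samples))
    n_feat = int(np.ceil(cfg.p_feature * n_probes))
    rng = np.random.default_rng(cfg.seed)

    ks = tuple(cfg.k_range)
    co_cluster = {k: np.zeros((n_samples, n_samples)) for k in ks}
    co_sampled = np.zeros((n_samples, n_samples))
    for _ in range(cfg.n_resamplings):
        items = np.sort(rng.choice(n_samples, size=n_item, replace=False))
        feats = rng.choice(n_probes, size=n_feat, replace=False)
        co_sampled[np.ix_(items, items)] += 1.0
        dist = _pearson_distance(x[np.ix_(items, feats)])
        for k, lab in _ward_cut(dist, ks).items():
            same = lab[:, None] == lab[None, :]
            co_cluster[k][np.ix_(items, items)] += same

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = {
            k: np.where(co_sampled > 0, co_cluster[k] / co_sampled, 0.0)
            for k in ks
        }
    for k in ks:
        np.fill_diagonal(consensus[k], 1.0)

    labels: dict[int, pd.Series] = {}
    cdf_area: dict[int, float] = {}
    for k in ks:
        d = 1.0 - consensus[k]
        np.fill_diagonal(d, 0.0)
        z = linkage(squareform(d, checks=False), method=cfg.final_linkage)
        raw = fcluster(z, t=k, criterion="maxclust")
        labels[k] = pd.Series(_canonical_labels(raw), index=samples, name="label")
        tri = consensus[k][np.triu_indices(n_samples, k=1)]
        # area under the empirical consensus CDF on [0, 1]
        cdf_area[k] = float(np.mean(1.0 - tri))
    return ConsensusResult(
        samples=samples, consensus=consensus, co_sampled=co_sampled,
        labels=labels, cdf_area=cdf_area,
    )


def cdf_area_deltas(result: ConsensusResult) -> dict[int, float]:
    """Relative change in consensus-CDF area between successive k."""
    ks = sorted(result.cdf_area)
    deltas = {ks[0]: result.cdf_area[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        a_prev = result.cdf_area[prev]
        deltas[k] = (result.cdf_area[k] - a_prev) / a_prev if a_prev > 0 else 0.0
    return deltas


def compare_global_methylation(
    beta: pd.DataFrame, labels: pd.Series
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-class mean beta and pairwise two-sided t-tests on sample means.

    The per-sample mean beta over all probes is computed first; classes are
    then compared by a two-sample t-test on those per-sample means.
    """
    labels = labels.loc[beta.columns]
    sample_means = beta.mean(axis=0, skipna=True)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
    class_means = sample_means.groupby(labels).mean()
    pvals = pd.DataFrame(np.nan, index=classes, columns=classes, dtype=float)
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            res = stats.ttest_ind(
                sample_means[labels == a], sample_means[labels == b]
            )
            pvals.loc[a, b] = pvals.loc[b, a] = res.pvalue
    return class_means, pvals


def crosstab_histology(labels: pd.Series, clinical: pd.DataFrame) -> pd.DataFrame:
    """Class x histology contingency table; missing histology -> 'unknown'."""
    shared = labels.index.intersection(clinical.index)
    if len(shared) == 0:
        raise ValueError("labels and clinical table share no samples")
    hist = clinical.loc[shared, "histology"].fillna("unknown")
    return pd.crosstab(labels.loc[shared], hist)
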