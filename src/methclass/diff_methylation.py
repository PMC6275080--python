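"""SAM-style two-class permutation differential methylation on beta values.

For a comparison "A vs B" each probe gets the moderated statistic
``d = (mean_B - mean_A) / (s + s0)`` where ``s`` is the pooled standard
error of the unpaired two-class SAM statistic and ``s0`` a fudge factor
estimated from the data.  Significance comes from label permutations:
the q-value of a probe is the median, across permutations, of the number
of null |d| values at or above its observed |d|, divided by the number of
observed |d| at or above it, capped at 1 and made monotone in |d|.

Probes are called highly methylated when the beta-mean fold change
(second class over first) exceeds ``fc_high`` with q below threshold,
lowly methylated symmetrically below ``fc_low``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DiffMethylConfig:
    fc_high: float = 1.05
    fc_low: float = 0.95
    q_threshold: float = 0.01
    n_permutations: int = 100
    s0_policy: str = "tusher"  # or "median-s"
    seed: int = 0

    def validate(self) -> None:
        if not self.fc_low < 1 < self.fc_high:
            raise ValueError("need fc_low < 1 < fc_high")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class DiffMethylResult:
    table: pd.DataFrame  # mean_a, mean_b, fold_change, d, q, call
    s0: float
    excluded: list[str] = field(default_factory=list)


def _mean_and_se(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise mean, within-group sum of squares and counts, NaN-aware."""
    cnt = np.sum(~np.isnan(values), axis=1)
    mean = np.nanmean(values, axis=1)
    ss = np.nansum((values - mean[:, None]) ** 2, axis=1)
    return mean, ss, cnt


def sam_statistics(
    values_a: np.ndarray, values_b: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized SAM d and pooled-SE s for probe rows of two groups."""
    mean_a, ss_a, n_a = _mean_and_se(np.atleast_2d(values_a))
    mean_b, ss_b, n_b = _mean_and_se(np.atleast_2d(values_b))
    if np.any(n_a < 2) or np.any(n_b < 2):
        raise ValueError("each group needs >= 2 non-missing values per probe")
    pooled = (ss_a + ss_b) / (n_a + n_b - 2)
    s = np.sqrt((1.0 / n_a + 1.0 / n_b) * pooled)
    d = (mean_b - mean_a) / (s + s0)
    return d, s


def sam_statistic(values_a, values_b, s0: float) -> float:
    """Scalar convenience wrapper for a single probe."""
    d, _ = sam_statistics(
        np.asarray(values_a, dtype=float)[None, :],
        np.asarray(values_b, dtype=float)[None, :],
        s0,
    )
    return float(d[0])


def estimate_s0(r: np.ndarray, s: np.ndarray, policy: str = "tusher") -> float:
    """Fudge factor from per-probe numerators ``r`` and SE terms ``s``.

    ``median-s`` returns the median SE.  ``tusher`` scans s0 candidates at
    the percentiles {0, 5, ..., 100} of ``s`` and picks the one minimizing
    the coefficient of variation of a robust spread of d across s-quantile
    bins (the classic SAM tuning rule).
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 probes to estimate s0")
    if policy == "median-s":
        return float(np.median(s))
    if policy != "tusher":
        raise ValueError(f"unknown s0 policy {policy!r}")
    percentiles = np.arange(0, 101, 5)
    candidates = np.unique(np.percentile(s, percentiles))
    n_bins = min(100, max(2, r.size // 10))
    edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
    best_s0, best_cv = candidates[0], np.inf
    for s0 in candidates:
        d = r / (s + s0)
        spreads = []
        for b in range(n_bins):
            db = d[bins == b]
            if db.size >= 2:
                spreads.append(np.median(np.abs(db - np.median(db))) / 0.64)
        spreads = np.asarray(spreads)
        mean = spreads.mean()
        if mean <= 0:
            continue
        cv = spreads.std(ddof=0) / mean
        if cv < best_cv:
            best_cv, best_s0 = cv, s0
    return float(best_s0)


def _all_group_assignments(n_total: int, n_a: int):
    """All distinct ways of choosing which samples form group A."""
    for combo in itertools.combinations(range(n_total), n_a):
        yield np.asarray(combo, dtype=np.intp)


def _q_from_null(
    d_obs: np.ndarray, null_counts: np.ndarray
) -> np.ndarray:
    """q per probe from per-permutation exceedance counts.

    ``null_counts[perm, i]`` is the number of null |d| >= |d_obs| of the
    probe ranked ``i`` by decreasing |d|.
    """
    m = d_obs.size
    order = np.argsort(-np.abs(d_obs), kind="stable")
    med_false = np.median(null_counts, axis=0)  # per rank, decreasing |d|
    called = np.arange(1, m + 1)
    q_sorted = np.minimum(med_false / called, 1.0)
    q_sorted = np.maximum.accumulate(q_sorted)  # monotone non-increasing in |d|
    q = np.empty(m)
    q[order] = q_sorted
    return q


def permutation_qvalues(
    beta_subset: pd.DataFrame,
    labels: pd.Series,
    config: DiffMethylConfig | None = None,
    exhaustive: bool = False,
) -> tuple[pd.Series, pd.Series, float]:
    """SAM permutation q-values for a two-class comparison.

    Returns (q per probe, d per probe, s0).  With ``exhaustive`` every
    distinct assignment of samples to the two groups is used instead of
    random permutations.
    """
    cfg = config or DiffMethylConfig()
    cfg.validate()
    labels = labels.loc[beta_subset.columns]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    a_mask = (labels == classes[0]).to_numpy()
    n_a = int(a_mask.sum())
    n_total = len(labels)
    if n_a < 3 or n_total - n_a < 3:
        import warnings

        warnings.warn("class sizes < 3: permutation null is coarse")
    x = beta_subset.to_numpy()
    _, s = sam_statistics(x[:, a_mask], x[:, ~a_mask], 0.0)
    r = np.nanmean(x[:, ~a_mask], axis=1) - np.nanmean(x[:, a_mask], axis=1)
    s0 = estimate_s0(r, s, cfg.s0_policy)
    d_obs, _ = sam_statistics(x[:, a_mask], x[:, ~a_mask], s0)

    order = np.argsort(-np.abs(d_obs), kind="stable")
    thresholds = np.abs(d_obs)[order]
    if exhaustive:
        assignments = list(_all_group_assignments(n_total, n_a))
    else:
        rng = np.random.default_rng(cfg.seed)
        assignments = [
            rng.permutation(n_total)[:n_a] for _ in range(cfg.n_permutations)
        ]
    null_counts = np.empty((len(assignments), d_obs.size))
    for j, idx_a in enumerate(assignments):
        mask = np.zeros(n_total, dtype=bool)
        mask[idx_a] = True
        d_null, _ = sam_statistics(x[:, mask], x[:, ~mask], s0)
        abs_null = np.sort(np.abs(d_null))
        # count of null |d| >= threshold, for each observed threshold
        null_counts[j] = abs_null.size - np.searchsorted(
            abs_null, thresholds, side="left"
        )
    q = _q_from_null(d_obs, null_counts)
    return (
        pd.Series(q, index=beta_subset.index, name="q"),
        pd.Series(d_obs, index=beta_subset.index, name="d"),
        s0,
    )


def call_dm_probes(
    beta: pd.DataFrame,
    labels: pd.Series,
    pair: tuple,
    config: DiffMethylConfig | None = None,
) -> DiffMethylResult:
    """Call highly/lowly methylated probes for the comparison ``pair[0] vs pair[1]``.

    Fold change is the mean beta of the second class over the first, so a
    "low" call means the probe is hypomethylated in the second class.
    """
    cfg = config or DiffMethylConfig()
    cfg.validate()
    labels = labels.loc[beta.columns]
    first, second = pair
    for c in (first, second):
        if c not in set(labels):
            raise ValueError(f"class {c!r} absent from labels")
    keep = labels.isin([first, second])
    sub = beta.loc[:, keep.to_numpy()]
    sub_labels = labels[keep]
    # order classes so that "A" is the first of the pair
    ordered = sub_labels.map({first: 0, second: 1})
    mean_a = sub.loc[:, (ordered == 0).to_numpy()].mean(axis=1, skipna=True)
    mean_b = sub.loc[:, (ordered == 1).to_numpy()].mean(axis=1, skipna=True)
    excluded = list(sub.index[mean_a == 0])
    valid = mean_a > 0
    q, d, s0 = permutation_qvalues(sub.loc[valid], ordered, cfg)
    fc = mean_b[valid] / mean_a[valid]
    call = pd.Series("none", index=fc.index, name="call")
    call[(fc > cfg.fc_high) & (q < cfg.q_threshold)] = "high"
    call[(fc < cfg.fc_low) & (q < cfg.q_threshold)] = "low"
    table = pd.DataFrame(
        {
            "mean_a": mean_a[valid],
            "mean_b": mean_b[valid],
            "fold_change": fc,
            "d": d,
            "q": q,
            "call": call,
        }
    )
    return DiffMethylResult(table=table, s0=s0, excluded=excluded)


def map_dm_probes_to_genes(
    dm: DiffMethylResult,
    annotation: pd.DataFrame,
    gene_models: pd.DataFrame,
) -> tuple[set[str], set[str], set[str]]:
    """Promoter-gene sets from DM calls: (high, low, excluded-both).

    A gene is "high" when at least one probe in its promoter is called
    high and none low (symmetrically for "low"); genes whose promoter
    carries both calls are excluded and returned separately.
    """
    from .annotation_enrichment import probes_to_promoter_genes

    called = dm.table[dm.table["call"] != "none"]
    probe_genes = probes_to_promoter_genes(called.index, annotation, gene_models)
    high_genes: set[str] = set()
    low_genes: set[str] = set()
    for probe, row_call in called["call"].items():
        for gene in probe_genes.get(probe, []):
            (high_genes if row_call == "high" else low_genes).add(gene)
    both = high_genes & low_genes
    return high_genes - both, low_genes - both, both
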