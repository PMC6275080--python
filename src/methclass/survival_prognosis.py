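"""Quantile-based prognostic screening of gene expression.

For each candidate gene, samples are split into high (above the 75th
percentile of expression) and low (below the 25th) groups; the middle is
excluded.  Group survival is compared by the Kaplan-Meier estimator and
the log-rank (Mantel-Cox) test, log-rank p-values are Benjamini-Hochberg
adjusted across genes, and a Cox proportional-hazards model on the
high-vs-low indicator yields the hazard ratio with its Wald 95% CI.
A gene is flagged favorable when HR < 1 with a log-rank p below the
screen's significance level (0.1 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .annotation_enrichment import bh_qvalues

bh_adjust = bh_qvalues  # Benjamini-Hochberg step-up, shared across modules


@dataclass
class SurvivalGrouping:
    groups: pd.Series  # 'high' / 'low' / 'excluded'
    cut_high: float
    cut_low: float


@dataclass
class ScreenConfig:
    hi_q: float = 0.75
    lo_q: float = 0.25
    alpha: float = 0.1  # screen significance on the adjusted log-rank p


@dataclass
class PrognosticRecord:
    gene: str
    n_high: int
    n_low: int
    deaths_high: int
    deaths_low: int
    logrank_p: float
    logrank_padj: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    favorable: bool
    separation_flag: bool = False


def quantile_groups(
    values: pd.Series, hi_q: float = 0.75, lo_q: float = 0.25
) -> SurvivalGrouping:
    """Split samples at linear-interpolation quantiles, strict inequalities.

    Samples tied exactly with a cut point fall in the excluded middle.
    """
    values = values.astype(float)
    if len(values) < 4:
        raise ValueError("need at least 4 samples")
    if values.nunique() == 1:
        raise ValueError("all values identical: no grouping possible")
    cut_high = float(np.quantile(values, hi_q))  # type-7 / linear
    cut_low = float(np.quantile(values, lo_q))
    groups = pd.Series("excluded", index=values.index, name="group")
    groups[values > cut_high] = "high"
    groups[values < cut_low] = "low"
    return SurvivalGrouping(groups=groups, cut_high=cut_high, cut_low=cut_low)


def km_estimate(times, events) -> list[tuple[float, float]]:
    """Kaplan-Meier product-limit curve as (event time, survival) pairs.

    At tied times, events are processed before censorings (a subject
    censored at an event time is still at risk for that event).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("negative times")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    out: list[tuple[float, float]] = []
    s = 1.0
    n_at_risk = times.size
    for t in np.unique(times):
        here = times == t
        d = int(events[here].sum())
        if d > 0:
            s *= 1.0 - d / n_at_risk
            out.append((float(t), s))
        n_at_risk -= int(here.sum())
    return out


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic and two-sided p (1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size != 2:
        raise ValueError("exactly two groups required")
    if events.sum() == 0:
        raise ValueError("no events in either group")
    a = groups == uniq[0]
    res = _lifelines_logrank(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


def cox_ph(times, events, covariate) -> tuple[float, float, float, float, bool]:
    """Cox PH fit (Efron ties): (HR, ci_low, ci_high, p, separation_flag)."""
    covariate = np.asarray(covariate, dtype=float)
    if np.unique(covariate).size < 2:
        raise ValueError("covariate is constant")
    df = pd.DataFrame(
        {"time": np.asarray(times, dtype=float),
         "event": np.asarray(events, dtype=int),
         "x": covariate}
    )
    cph = CoxPHFitter()
    separation = False
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception:
            separation = True
            cph = CoxPHFitter(penalizer=1e-6)
            cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    if not np.isfinite(se) or se > 50:
        separation = True
    hr = float(np.exp(coef))
    ci_low = float(np.exp(coef - 1.959963984540054 * se))
    ci_high = float(np.exp(coef + 1.959963984540054 * se))
    p = float(cph.summary.loc["x", "p"])
    return hr, ci_low, ci_high, p, separation


def prognostic_screen(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    gene_list,
    config: ScreenConfig | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene survival screen over ``gene_list``.

    ``expr`` is a gene x sample matrix of (normalized) expression values.
    Returns (records table, genes skipped because absent from ``expr``).
    """
    cfg = config or ScreenConfig()
    shared = expr.columns.intersection(clinical.index)
    if len(shared) == 0:
        raise ValueError("expression and clinical tables share no samples")
    expr = expr.loc[:, shared]
    clin = clinical.loc[shared]
    skipped = [g for g in gene_list if g not in expr.index]
    genes = [g for g in gene_list if g in expr.index]
    rows = []
    for gene in genes:
        grouping = quantile_groups(expr.loc[gene], cfg.hi_q, cfg.lo_q)
        mask = grouping.groups != "excluded"
        sub_groups = grouping.groups[mask]
        sub_clin = clin.loc[sub_groups.index]
        stat, p = logrank_test(
            sub_clin["time"], sub_clin["event"], sub_groups
        )
        indicator = (sub_groups == "high").astype(float)
        hr, lo, hi, _, sep = cox_ph(
            sub_clin["time"], sub_clin["event"], indicator
        )
        high, low = sub_groups == "high", sub_groups == "low"
        rows.append(
            dict(
                gene=gene,
                n_high=int(high.sum()), n_low=int(low.sum()),
                deaths_high=int(sub_clin.loc[high.to_numpy(), "event"].sum()),
                deaths_low=int(sub_clin.loc[low.to_numpy(), "event"].sum()),
                logrank_p=p, hazard_ratio=hr, ci_low=lo, ci_high=hi,
                separation_flag=sep,
            )
        )
    table = pd.DataFrame(rows).set_index("gene")
    table["logrank_padj"] = bh_adjust(table["logrank_p"].to_numpy())
    table["favorable"] = (table["hazard_ratio"] < 1) & (
        table["logrank_p"] < cfg.alpha
    )
    return table, skipped
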