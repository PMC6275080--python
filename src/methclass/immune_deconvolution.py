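"""Reference-based methylation deconvolution of immune cell fractions.

Each bulk sample's marker-probe beta vector is modelled as a convex-ish
mixture of reference cell-type profiles: fractions are estimated by
constrained least squares (fractions >= 0, sum <= 1, Houseman-style
constrained projection).  The immune cell fraction of a sample is the sum
of fractions over the immune-flagged cell types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

MIN_SHARED_MARKERS = 10


@dataclass
class ReferenceSignature:
    profiles: pd.DataFrame  # marker probe x cell type, beta values
    immune_types: tuple[str, ...]

    def validate(self) -> None:
        arr = self.profiles.to_numpy()
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("reference beta values must lie in [0, 1]")
        if self.profiles.shape[1] < 2:
            raise ValueError("need at least 2 cell types")
        missing = set(self.immune_types) - set(self.profiles.columns)
        if missing:
            raise ValueError(f"immune types absent from reference: {missing}")


@dataclass
class CellFractions:
    fractions: pd.DataFrame  # sample x cell type
    immune_fraction: pd.Series
    mode: str = "constrained-projection"


def _solve_fractions(y: np.ndarray, R: np.ndarray) -> np.ndarray:
    """min ||y - R f|| subject to f >= 0 and sum(f) <= 1."""
    k = R.shape[1]
    f0, _ = optimize.nnls(R, y)
    if f0.sum() <= 1.0 + 1e-12:
        return np.clip(f0, 0.0, None)
    res = optimize.minimize(
        lambda f: 0.5 * np.sum((R @ f - y) ** 2),
        x0=f0 / f0.sum(),
        jac=lambda f: R.T @ (R @ f - y),
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "ineq", "fun": lambda f: 1.0 - f.sum(),
                      "jac": lambda f: -np.ones(k)}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    f = np.clip(res.x, 0.0, None)
    total = f.sum()
    if total > 1.0:
        f /= total
    return f


def estimate_fractions(
    beta: pd.DataFrame, reference: ReferenceSignature
) -> CellFractions:
    """Cell-type fractions per sample by constrained projection.

    Markers missing from the cohort are ignored; within a sample, markers
    with missing beta are dropped before solving.
    """
    reference.validate()
    shared = beta.index.intersection(reference.profiles.index)
    if len(shared) < MIN_SHARED_MARKERS:
        raise ValueError(
            f"only {len(shared)} marker probes shared with the reference "
            f"(need >= {MIN_SHARED_MARKERS})"
        )
    R_full = reference.profiles.loc[shared].to_numpy()
    B = beta.loc[shared].to_numpy()
    out = np.empty((beta.shape[1], R_full.shape[1]))
    for j in range(beta.shape[1]):
        y = B[:, j]
        ok = ~np.isnan(y)
        if ok.sum() < MIN_SHARED_MARKERS:
            raise ValueError(
                f"sample {beta.columns[j]!r} has fewer than "
                f"{MIN_SHARED_MARKERS} non-missing markers"
            )
        out[j] = _solve_fractions(y[ok], R_full[ok])
    fractions = pd.DataFrame(
        out, index=beta.columns, columns=reference.profiles.columns
    )
    immune = fractions[list(reference.immune_types)].sum(axis=1)
    return CellFractions(
        fractions=fractions, immune_fraction=immune.rename("immune_fraction")
    )


def fraction_subset_variants(
    beta: pd.DataFrame, reference: ReferenceSignature, probe_subset
) -> CellFractions:
    """Same estimator restricted to markers inside ``probe_subset``."""
    subset = pd.Index(probe_subset)
    markers = reference.profiles.index.intersection(subset)
    if len(markers) == 0:
        raise ValueError("probe subset contains no reference markers")
    restricted = ReferenceSignature(
        profiles=reference.profiles.loc[markers],
        immune_types=reference.immune_types,
    )
    return estimate_fractions(beta, restricted)


def compare_fractions(
    fractions: CellFractions, labels: pd.Series
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-class mean immune fraction and pairwise two-sided t-test p-values."""
    labels = labels.loc[fractions.immune_fraction.index]
    classes = sorted(labels.unique())
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    means = fractions.immune_fraction.groupby(labels).mean()
    pvals = pd.DataFrame(np.nan, index=classes, columns=classes, dtype=float)
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            res = stats.ttest_ind(
                fractions.immune_fraction[labels == a],
                fractions.immune_fraction[labels == b],
            )
            pvals.loc[a, b] = pvals.loc[b, a] = res.pvalue
    return means, pvals


def make_synthetic_reference(
    n_markers: int = 200, seed: int = 0
) -> ReferenceSignature:
    """Small synthetic reference: 2 immune + 2 non-immune cell types.

    Marker betas are drawn so that each cell type has a block of markers
    where it differs strongly from the others, the usual structure of
    reference-based deconvolution panels.  Synthetic stand-in for a real
    450K reference; real references load through the same TSV format.
    """
    rng = np.random.default_rng(seed)
    types = ["Tcell", "Bcell", "Epithelial", "Fibroblast"]
    markers = [f"ref{i:05d}" for i in range(n_markers)]
    base = rng.beta(5, 5, size=(n_markers, len(types)))
    block = n_markers // len(types)
    for t in range(len(types)):
        rows = slice(t * block, (t + 1) * block)
        base[rows, t] = rng.beta(2, 18, size=block)  # hypo in the marked type
        others = [u for u in range(len(types)) if u != t]
        base[rows][:, others] = rng.beta(18, 2, size=(block, len(others)))
    profiles = pd.DataFrame(base, index=pd.Index(markers, name="probe"),
                            columns=types)
    return ReferenceSignature(profiles=profiles, immune_types=("Tcell", "Bcell"))


def read_reference(path, immune_types: tuple[str, ...]) -> ReferenceSignature:
    profiles = pd.read_csv(path, sep="\t", index_col=0)
    ref = ReferenceSignature(profiles=profiles, immune_types=tuple(immune_types))
    ref.validate()
    return ref


def write_reference(reference: ReferenceSignature, path) -> None:
    reference.profiles.to_csv(path, sep="\t", index_label="probe")
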