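"""Synthetic 450K-style cohort generator with known ground truth.

Emulates the statistical structure of a TCGA-like cervical-cancer cohort:

* a probe x sample beta matrix with three latent subclasses — class 1
  (adenocarcinoma-like) globally hypermethylated, class 3 specifically
  hypomethylated at the promoter probes of an immune gene module;
* RNA-seq-like negative-binomial counts whose gene means decrease
  log-linearly with the gene's mean promoter beta, plus an explicit
  expression boost for immune-module genes in class 3;
* immune-linked clinical structure: exponential survival times whose
  hazard decreases with a sample's immune-module expression score,
  administrative censoring, histology labels associated with class;
* per-sample neo-epitope counts Poisson-linked to the same immune score;
* a TF target-set collection in which one designated set is enriched for
  the immune-module genes.

Every stochastic choice flows through one :class:`numpy.random.Generator`
seeded from ``config.seed``, so identical configs give bit-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import data_io

#: per-probe Beta-distribution means implied by the default shape pairs
_GENE_SPACING = 20_000
_TX_LENGTH = 4_000


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults follow the cohort geometry used throughout the test-suite:
    three classes of 50/120/130 samples, 20,000 probes of which 30% carry
    class signal, and a 2,000-gene transcriptome with a 100-gene immune
    module boosted by 1.5 log2-fold in class 3.
    """

    n_samples_per_class: tuple[int, int, int] = (50, 120, 130)
    n_probes: int = 20_000
    frac_informative: float = 0.30
    frac_promoter_probes: float = 0.35
    beta_shape_hyper: tuple[float, float] = (8.0, 2.0)
    beta_shape_hypo: tuple[float, float] = (2.0, 8.0)
    beta_shape_mid: tuple[float, float] = (5.0, 5.0)
    n_genes: int = 2_000
    coupling_strength: float = 2.0  # natural-log slope of mean on promoter beta
    nb_dispersion: float = 0.2
    immune_module_size: int = 100
    immune_effect_lfc: float = 1.5  # log2, added in class 3
    baseline_hazard: float = 3e-4  # events per day
    protective_loghr: float = -0.7  # per SD of immune score
    neo_link_slope: float = 0.5  # log-scale, per SD of immune score
    n_tf_sets: int = 50
    seed: int = 7

    def validate(self) -> None:
        if any(n <= 0 for n in self.n_samples_per_class):
            raise ValueError("each class needs at least one sample")
        if self.n_probes <= 0 or self.n_genes <= 0:
            raise ValueError("n_probes and n_genes must be positive")
        for frac in (self.frac_informative, self.frac_promoter_probes):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for pair in (self.beta_shape_hyper, self.beta_shape_hypo, self.beta_shape_mid):
            if min(pair) <= 0:
                raise ValueError("Beta shapes must be positive")
        if self.immune_module_size > self.n_genes:
            raise ValueError("immune_module_size cannot exceed n_genes")
        if self.nb_dispersion <= 0 or self.baseline_hazard <= 0:
            raise ValueError("nb_dispersion and baseline_hazard must be positive")


@dataclass
class SyntheticCohort:
    beta: pd.DataFrame
    annotation: pd.DataFrame
    gene_models: pd.DataFrame
    counts: pd.DataFrame
    clinical: pd.DataFrame
    neo_counts: pd.Series
    tf_sets: dict[str, list[str]]
    truth: dict = field(default_factory=dict)
    config: SimulationConfig | None = None


def _make_gene_models(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    symbols = [f"G{i:05d}" for i in range(cfg.n_genes)]
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    rows = []
    for i, (sym, strand) in enumerate(zip(symbols, strands)):
        tx_start = 10_000 + i * _GENE_SPACING
        tx_end = tx_start + _TX_LENGTH - 1
        tss = tx_start if strand == "+" else tx_end
        # three exons with fixed internal geometry; UTRs at the transcript ends
        e1 = (tx_start, tx_start + 499)
        e2 = (tx_start + 1500, tx_start + 1999)
        e3 = (tx_end - 499, tx_end)
        if strand == "+":
            utr5 = [(tx_start, tx_start + 199)]
            utr3 = [(tx_end - 199, tx_end)]
        else:
            utr5 = [(tx_end - 199, tx_end)]
            utr3 = [(tx_start, tx_start + 199)]
        rows.append(
            dict(chrom="chr1", strand=strand, tss=tss, tx_start=tx_start,
                 tx_end=tx_end, exons=[e1, e2, e3], utr5=utr5, utr3=utr3)
        )
    return pd.DataFrame(rows, index=pd.Index(symbols, name="symbol"))


def _shape_mean(shape: tuple[float, float]) -> float:
    return shape[0] / (shape[0] + shape[1])


def generate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Draw a fully labelled cohort from ``config`` (defaults if omitted)."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n1, n2, n3 = cfg.n_samples_per_class
    n_samples = n1 + n2 + n3
    samples = [f"S{i:04d}" for i in range(n_samples)]
    labels = pd.Series(
        np.repeat([1, 2, 3], [n1, n2, n3]), index=samples, name="label"
    )

    gene_models = _make_gene_models(cfg, rng)
    genes = gene_models.index.to_numpy()
    immune_genes = rng.choice(genes, size=cfg.immune_module_size, replace=False)
    immune_mask = pd.Series(np.isin(genes, immune_genes), index=genes)

    # ---- probe placement -------------------------------------------------
    probes = [f"cg{i:06d}" for i in range(cfg.n_probes)]
    n_promoter = int(round(cfg.frac_promoter_probes * cfg.n_probes))
    chrom_len = 10_000 + cfg.n_genes * _GENE_SPACING
    pos = np.empty(cfg.n_probes, dtype=np.int64)
    # promoter probes cycle through genes so every gene's promoter is covered
    promoter_gene_idx = np.arange(n_promoter) % cfg.n_genes
    rng.shuffle(promoter_gene_idx)
    tss = gene_models["tss"].to_numpy()
    pos[:n_promoter] = tss[promoter_gene_idx] + rng.integers(
        -1500, 1501, size=n_promoter
    )
    pos[n_promoter:] = rng.integers(1, chrom_len + 1, size=cfg.n_probes - n_promoter)
    probe_gene = np.full(cfg.n_probes, "", dtype=object)
    probe_gene[:n_promoter] = genes[promoter_gene_idx]
    annotation = pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "gene": probe_gene},
        index=pd.Index(probes, name="probe"),
    )

    # ---- informative probe sets ------------------------------------------
    n_informative = int(round(cfg.frac_informative * cfg.n_probes))
    is_promoter_of_immune = np.zeros(cfg.n_probes, dtype=bool)
    is_promoter_of_immune[:n_promoter] = immune_mask.to_numpy()[promoter_gene_idx]
    informative = np.zeros(cfg.n_probes, dtype=bool)
    class1_hyper = np.zeros(cfg.n_probes, dtype=bool)
    class3_hypo = np.zeros(cfg.n_probes, dtype=bool)
    if n_informative > 0:
        n_hypo = int(round(0.4 * n_informative))
        # class-3 hypomethylated set: immune-gene promoter probes first
        immune_prom_idx = np.flatnonzero(is_promoter_of_immune)
        take = immune_prom_idx[: min(len(immune_prom_idx), n_hypo)]
        class3_hypo[take] = True
        # remaining class-3 hypo probes are promoter-biased: the class-3
        # hypomethylation signature concentrates in promoter regions
        n_extra = n_hypo - take.size
        rem_prom = np.flatnonzero(~class3_hypo[:n_promoter])
        rem_other = n_promoter + np.flatnonzero(~class3_hypo[n_promoter:])
        n_extra_prom = min(int(round(0.7 * n_extra)), rem_prom.size)
        extra = np.concatenate([
            rng.choice(rem_prom, size=n_extra_prom, replace=False),
            rng.choice(rem_other, size=n_extra - n_extra_prom, replace=False),
        ])
        class3_hypo[extra] = True
        # class-1 hypermethylated (CA-like) set from the rest
        pool = np.flatnonzero(~class3_hypo)
        hyper = rng.choice(pool, size=n_informative - n_hypo, replace=False)
        class1_hyper[hyper] = True
        informative = class1_hyper | class3_hypo

    # ---- beta matrix ------------------------------------------------------
    # per-gene baseline promoter methylation, spread so that promoter beta
    # varies across genes (drives the expression coupling)
    gene_baseline = rng.beta(2.0, 2.0, size=cfg.n_genes)
    concentration = 10.0
    base_a = np.full(cfg.n_probes, cfg.beta_shape_mid[0])
    base_b = np.full(cfg.n_probes, cfg.beta_shape_mid[1])
    prom_base = gene_baseline[promoter_gene_idx]
    base_a[:n_promoter] = prom_base * concentration
    base_b[:n_promoter] = (1.0 - prom_base) * concentration

    class_a = np.tile(base_a, (3, 1))
    class_b = np.tile(base_b, (3, 1))
    class_a[0, class1_hyper] = cfg.beta_shape_hyper[0]
    class_b[0, class1_hyper] = cfg.beta_shape_hyper[1]
    class_a[2, class3_hypo] = cfg.beta_shape_hypo[0]
    class_b[2, class3_hypo] = cfg.beta_shape_hypo[1]

    beta_vals = np.empty((cfg.n_probes, n_samples))
    class_of_sample = labels.to_numpy() - 1
    for cls in range(3):
        cols = np.flatnonzero(class_of_sample == cls)
        beta_vals[:, cols] = rng.beta(
            class_a[cls][:, None], class_b[cls][:, None],
            size=(cfg.n_probes, cols.size),
        )
    beta = pd.DataFrame(beta_vals, index=annotation.index, columns=samples)

    # ---- expression counts -------------------------------------------------
    # expected promoter beta per gene per class, from the Beta means
    prom_mean = np.empty((3, cfg.n_probes))
    for cls in range(3):
        prom_mean[cls] = class_a[cls] / (class_a[cls] + class_b[cls])
    gene_prom_beta = np.full((3, cfg.n_genes), 0.5)
    for cls in range(3):
        sums = np.zeros(cfg.n_genes)
        cnts = np.zeros(cfg.n_genes)
        np.add.at(sums, promoter_gene_idx, prom_mean[cls, :n_promoter])
        np.add.at(cnts, promoter_gene_idx, 1.0)
        has = cnts > 0
        gene_prom_beta[cls, has] = sums[has] / cnts[has]

    base_log_mean = rng.normal(np.log(200.0), 0.7, size=cfg.n_genes)
    log_mu = (
        base_log_mean[None, :]
        - cfg.coupling_strength * (gene_prom_beta - 0.5)
    )
    log_mu[2, immune_mask.to_numpy()] += cfg.immune_effect_lfc * np.log(2.0)
    mu_class = np.exp(log_mu)  # class x gene

    depth = np.exp(rng.normal(0.0, 0.25, size=n_samples))
    mu = mu_class[class_of_sample, :].T * depth[None, :]  # gene x sample
    nb_n = 1.0 / cfg.nb_dispersion
    counts_vals = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))
    counts = pd.DataFrame(
        counts_vals.astype(np.int64),
        index=gene_models.index.rename("gene"), columns=samples,
    )

    # ---- immune score, survival, neo-epitopes -----------------------------
    norm = counts.to_numpy() / depth[None, :]
    immune_expr = np.log2(1.0 + norm[immune_mask.to_numpy(), :]).mean(axis=0)
    score = (immune_expr - immune_expr.mean()) / immune_expr.std(ddof=0)

    hazard = cfg.baseline_hazard * np.exp(cfg.protective_loghr * score)
    latent_t = rng.exponential(1.0 / hazard)
    horizon = -np.log(0.4) / cfg.baseline_hazard  # ~40% censoring at baseline
    event = (latent_t <= horizon).astype(int)
    time = np.minimum(latent_t, horizon)

    histology = np.where(
        class_of_sample == 0,
        np.where(rng.random(n_samples) < 0.9, "CA", "CSCC"),
        np.where(rng.random(n_samples) < 0.95, "CSCC", "CA"),
    )
    clinical = pd.DataFrame(
        {"time": time, "event": event, "histology": histology},
        index=pd.Index(samples, name="sample"),
    )

    neo_mu = np.exp(np.log(30.0) + cfg.neo_link_slope * score)
    neo_counts = pd.Series(
        rng.poisson(neo_mu), index=pd.Index(samples, name="sample"),
        name="neo_count", dtype=np.int64,
    )

    # ---- TF target sets ----------------------------------------------------
    tf_sets: dict[str, list[str]] = {}
    n_immune_in_set = int(round(0.6 * cfg.immune_module_size))
    designated = list(rng.choice(immune_genes, size=n_immune_in_set, replace=False))
    others = genes[~immune_mask.to_numpy()]
    designated += list(rng.choice(others, size=n_immune_in_set // 3, replace=False))
    tf_sets["TF_IMMUNE"] = sorted(designated)
    lo = min(50, max(2, cfg.n_genes // 4))
    hi = min(200, cfg.n_genes)
    for i in range(cfg.n_tf_sets - 1):
        size = int(rng.integers(lo, hi + 1))
        tf_sets[f"TF{i:03d}"] = sorted(rng.choice(genes, size=size, replace=False))

    truth = {
        "labels": labels,
        "immune_genes": pd.Index(sorted(immune_genes)),
        "informative_probes": pd.Series(informative, index=annotation.index),
        "class1_hyper_probes": pd.Series(class1_hyper, index=annotation.index),
        "class3_hypo_probes": pd.Series(class3_hypo, index=annotation.index),
        "immune_score": pd.Series(score, index=samples),
        "designated_tf_set": "TF_IMMUNE",
    }
    return SyntheticCohort(
        beta=beta, annotation=annotation, gene_models=gene_models,
        counts=counts, clinical=clinical, neo_counts=neo_counts,
        tf_sets=tf_sets, truth=truth, config=cfg,
    )


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, str]:
    """Write every component in the pipeline's native TSV/GMT formats.

    Returns a name -> path manifest.  Files round-trip losslessly through
    the :mod:`methclass.data_io` readers.
    """
    from pathlib import Path

    if cohort.beta.shape[1] == 0:
        raise ValueError("cannot write an empty cohort (0 samples)")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": directory / "beta.tsv",
        "manifest": directory / "probe_manifest.tsv",
        "gene_models": directory / "gene_models.tsv",
        "counts": directory / "counts.tsv",
        "clinical": directory / "clinical.tsv",
        "neo_counts": directory / "neo_counts.tsv",
        "tf_sets": directory / "tf_sets.gmt",
        "truth_labels": directory / "truth_labels.tsv",
    }
    data_io.write_beta_matrix(cohort.beta, paths["beta"])
    data_io.write_probe_manifest(cohort.annotation, paths["manifest"])
    data_io.write_gene_models(cohort.gene_models, paths["gene_models"])
    data_io.write_counts(cohort.counts, paths["counts"])
    data_io.write_clinical(cohort.clinical, paths["clinical"])
    data_io.write_neo_counts(cohort.neo_counts, paths["neo_counts"])
    data_io.write_gmt(cohort.tf_sets, paths["tf_sets"])
    data_io.write_labels(cohort.truth["labels"], paths["truth_labels"])
    return {k: str(v) for k, v in paths.items()}


def make_cohort_reference(
    cohort: SyntheticCohort, n_markers: int = 200, seed: int = 0
):
    """Reference signature aligned with a synthetic cohort's probes.

    Emulates the situation of a real deconvolution panel: immune cell
    types are hypomethylated at the cohort's immune-linked probes, so
    samples with genuine immune infiltration signal (class 3) draw larger
    immune fractions.  Half the markers come from the class-3
    hypomethylated probe set, half from uninformative non-promoter probes
    that separate the two non-immune types.
    """
    from .immune_deconvolution import ReferenceSignature

    rng = np.random.default_rng(seed)
    hypo = cohort.truth["class3_hypo_probes"]
    informative = cohort.truth["informative_probes"]
    is_promoter = cohort.annotation["gene"] != ""
    hypo_pool = hypo.index[hypo].to_numpy()
    neutral_pool = informative.index[
        (~informative) & (~is_promoter)
    ].to_numpy()
    n_half = n_markers // 2
    if len(hypo_pool) < n_half or len(neutral_pool) < n_markers - n_half:
        raise ValueError("cohort too small for the requested marker panel")
    m_imm = rng.choice(hypo_pool, size=n_half, replace=False)
    m_neu = rng.choice(neutral_pool, size=n_markers - n_half, replace=False)
    markers = np.concatenate([m_imm, m_neu])
    types = ["Tcell", "Bcell", "Epithelial", "Fibroblast"]
    prof = np.full((n_markers, 4), 0.5)
    half_imm = n_half // 2
    prof[:half_imm] = [0.1, 0.3, 0.6, 0.6]  # T-cell-discriminating block
    prof[half_imm:n_half] = [0.3, 0.1, 0.6, 0.6]  # B-cell block
    prof[n_half:] = [0.5, 0.5, 0.3, 0.7]  # separates the non-immune types
    prof = np.clip(prof + rng.normal(0.0, 0.01, size=prof.shape), 0.0, 1.0)
    profiles = pd.DataFrame(prof, index=pd.Index(markers, name="probe"),
                            columns=types)
    return ReferenceSignature(profiles=profiles, immune_types=("Tcell", "Bcell"))


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a (YAML-loaded) mapping, tolerating lists for tuples."""
    kwargs = dict(d)
    for key in ("n_samples_per_class", "beta_shape_hyper", "beta_shape_hypo",
                "beta_shape_mid"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
    return d
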