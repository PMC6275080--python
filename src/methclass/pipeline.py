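"""End-to-end orchestration of the subclass-discovery pipeline.

``run_all`` executes: simulate (optional) -> MAD probe selection and
consensus clustering -> SAM differential methylation for every class
pair -> genomic-region and TF-target enrichment -> NB differential
expression -> promoter-beta integration -> immune deconvolution ->
prognostic screen -> neo-epitope resampling FDR.  Every stage writes its
tables under the output directory and the run ends with a manifest
(versions, parameters, derived seeds).  Outputs are pure functions of
(inputs, parameters, seed): reruns with an identical config are
bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    annotation_enrichment,
    data_io,
    diff_expression,
    diff_methylation,
    immune_deconvolution,
    neoepitope_assoc,
    subtype_clustering,
    survival_prognosis,
    synthetic_cohort,
)

log = logging.getLogger("methclass")

# fixed per-stage seed offsets derived from the one global seed
_STAGE_SEED_OFFSET = {
    "simulate": 0,
    "cluster": 101,
    "dm": 202,
    "deconvolve": 303,
    "neoassoc": 404,
}


@dataclass
class PipelineConfig:
    out_dir: str = "methclass_run"
    seed: int = 0
    simulate: dict | None = None  # SimulationConfig fields; None -> load inputs
    inputs: dict = field(default_factory=dict)  # paths keyed like write_cohort
    n_top_probes: int = 30_000
    k_final: int = 3
    n_resamplings: int = 100
    p_item: float = 0.9
    p_feature: float = 0.9
    dm: dict = field(default_factory=dict)  # DiffMethylConfig overrides
    de: dict = field(default_factory=dict)  # DEConfig overrides
    screen: dict = field(default_factory=dict)  # ScreenConfig overrides
    n_fdr_iterations: int = 1000
    continue_on_error: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


def _stage_seed(cfg: PipelineConfig, stage: str) -> int:
    return (cfg.seed + _STAGE_SEED_OFFSET[stage]) % (2**31 - 1)


def _load_inputs(cfg: PipelineConfig) -> synthetic_cohort.SyntheticCohort:
    paths = cfg.inputs
    required = ["beta", "manifest", "gene_models", "counts", "clinical",
                "neo_counts", "tf_sets"]
    missing = [k for k in required if k not in paths]
    if missing:
        raise ValueError(f"missing input paths: {missing}")
    return synthetic_cohort.SyntheticCohort(
        beta=data_io.read_beta_matrix(paths["beta"]),
        annotation=data_io.read_probe_manifest(paths["manifest"]),
        gene_models=data_io.read_gene_models(paths["gene_models"]),
        counts=data_io.read_counts(paths["counts"]),
        clinical=data_io.read_clinical(paths["clinical"]),
        neo_counts=data_io.read_neo_counts(paths["neo_counts"]),
        tf_sets=data_io.read_gmt(paths["tf_sets"]),
    )


def _json_dump(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns a summary dict (also written as JSON)."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed}
    errors: list[str] = []

    def stage(name: str, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - reported per stage
            if cfg.continue_on_error:
                errors.append(f"{name}: {exc}")
                log.error("stage %s failed: %s", name, exc)
                return None
            raise RuntimeError(f"stage {name} failed: {exc}") from exc

    # ---- inputs ----------------------------------------------------------
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        sim.setdefault("seed", _stage_seed(cfg, "simulate"))
        sim_cfg = synthetic_cohort.config_from_dict(sim)
        cohort = stage("simulate", lambda: synthetic_cohort.generate_cohort(sim_cfg))
        synthetic_cohort.write_cohort(cohort, out / "cohort")
    else:
        cohort = stage("load-inputs", lambda: _load_inputs(cfg))
    if cohort is None:
        raise RuntimeError("no inputs available")

    # ---- clustering ------------------------------------------------------
    n_top = min(cfg.n_top_probes, cohort.beta.shape[0])
    top = subtype_clustering.select_top_mad_probes(cohort.beta, n_top)
    clus_cfg = subtype_clustering.ClusteringConfig(
        n_top_probes=n_top, n_resamplings=cfg.n_resamplings,
        p_item=cfg.p_item, p_feature=cfg.p_feature,
        k_range=tuple(sorted({2, cfg.k_final, cfg.k_final + 1})),
        seed=_stage_seed(cfg, "cluster"),
    )
    consensus = stage(
        "cluster",
        lambda: subtype_clustering.consensus_cluster(cohort.beta.loc[top], clus_cfg),
    )
    labels = consensus.labels[cfg.k_final]
    data_io.write_labels(labels, out / "cluster_labels.tsv")
    for k, mat in consensus.consensus.items():
        pd.DataFrame(mat, index=consensus.samples, columns=consensus.samples).to_csv(
            out / f"consensus_k{k}.tsv", sep="\t"
        )
    class_means, meth_p = subtype_clustering.compare_global_methylation(
        cohort.beta, labels
    )
    crosstab = subtype_clustering.crosstab_histology(labels, cohort.clinical)
    crosstab.to_csv(out / "histology_crosstab.tsv", sep="\t")
    summary["cluster"] = {
        "k": cfg.k_final,
        "class_mean_beta": {str(k): float(v) for k, v in class_means.items()},
        "cdf_area": {str(k): v for k, v in consensus.cdf_area.items()},
    }

    # ---- differential methylation + enrichment ---------------------------
    dm_cfg = diff_methylation.DiffMethylConfig(
        **{"seed": _stage_seed(cfg, "dm"), **cfg.dm}
    )
    regions = annotation_enrichment.assign_regions(
        cohort.annotation, cohort.gene_models
    )
    classes = sorted(labels.unique())
    dm_results: dict[tuple, diff_methylation.DiffMethylResult] = {}
    dm_gene_sets: dict[tuple, tuple[set, set]] = {}
    summary["dm"] = {}
    summary["region_enrichment"] = {}
    summary["tf_enrichment"] = {}
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            key = (a, b)
            dm = stage(
                f"dm-{a}v{b}",
                lambda a=a, b=b: diff_methylation.call_dm_probes(
                    cohort.beta, labels, (a, b), dm_cfg
                ),
            )
            if dm is None:
                continue
            dm_results[key] = dm
            dm.table.to_csv(out / f"dm_{a}_vs_{b}.tsv", sep="\t")
            counts = dm.table["call"].value_counts()
            summary["dm"][f"{a}_vs_{b}"] = {
                "high": int(counts.get("high", 0)),
                "low": int(counts.get("low", 0)),
                "s0": dm.s0,
            }
            for direction in ("high", "low"):
                probes = dm.table.index[dm.table["call"] == direction]
                if len(probes) == 0:
                    continue
                recs = annotation_enrichment.region_enrichment(
                    probes, cohort.beta.index, regions
                )
                frame = annotation_enrichment.records_to_frame(recs)
                frame.to_csv(out / f"region_enrich_{a}_vs_{b}_{direction}.tsv",
                             sep="\t")
                best = frame["odds_ratio"].idxmax()
                summary["region_enrichment"][f"{a}_vs_{b}_{direction}"] = best
            high_g, low_g, _both = diff_methylation.map_dm_probes_to_genes(
                dm, cohort.annotation, cohort.gene_models
            )
            dm_gene_sets[key] = (high_g, low_g)
            if low_g:
                recs = annotation_enrichment.geneset_enrichment(
                    sorted(low_g), cohort.tf_sets
                )
                frame = annotation_enrichment.records_to_frame(recs)
                frame.to_csv(out / f"tf_enrich_{a}_vs_{b}_low.tsv", sep="\t")
                sig = frame.index[frame["q"] < 0.05].tolist()
                summary["tf_enrichment"][f"{a}_vs_{b}_low"] = sig

    # ---- differential expression -----------------------------------------
    de_cfg = diff_expression.DEConfig(**cfg.de)
    de_results: dict[tuple, diff_expression.DEResult] = {}
    summary["de"] = {}
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            de = stage(
                f"de-{a}v{b}",
                lambda a=a, b=b: diff_expression.call_de_genes(
                    cohort.counts, labels, (a, b), de_cfg
                ),
            )
            if de is None:
                continue
            de_results[(a, b)] = de
            de.table.to_csv(out / f"de_{a}_vs_{b}.tsv", sep="\t")
            counts = de.table["call"].value_counts()
            summary["de"][f"{a}_vs_{b}"] = {
                "up": int(counts.get("up", 0)),
                "down": int(counts.get("down", 0)),
            }

    # promoter-beta integration + DM/DE overlap on the last CSCC-like pair
    key = (classes[-2], classes[-1]) if len(classes) >= 2 else None
    if key in de_results:
        de = de_results[key]
        up = de.table.index[de.table["call"] == "up"].tolist()
        down = de.table.index[de.table["call"] == "down"].tolist()
        sets = {d: g for d, g in (("up", up), ("down", down)) if g}
        if sets:
            _, tests, _ = diff_expression.promoter_beta_of_gene_sets(
                sets, cohort.beta, cohort.annotation, cohort.gene_models, labels
            )
            tests.to_csv(out / "promoter_beta_tests.tsv", sep="\t", index=False)
        if key in dm_gene_sets:
            high_g, low_g = dm_gene_sets[key]
            overlap, orat, p = diff_expression.dm_de_overlap(high_g, low_g, de)
            overlap.to_csv(out / "dm_de_overlap.tsv", sep="\t")
            summary["dm_de_overlap"] = {
                "odds_ratio": orat if np.isfinite(orat) else None, "p": p
            }

    # ---- immune deconvolution --------------------------------------------
    def _deconvolve():
        if cohort.truth:
            ref = synthetic_cohort.make_cohort_reference(
                cohort, seed=_stage_seed(cfg, "deconvolve")
            )
        elif "reference" in cfg.inputs:
            ref = immune_deconvolution.read_reference(
                cfg.inputs["reference"],
                tuple(cfg.inputs.get("immune_types", ["Tcell", "Bcell"])),
            )
        else:
            return None
        return immune_deconvolution.estimate_fractions(cohort.beta, ref)

    fractions = stage("deconvolve", _deconvolve)
    if fractions is not None:
        fractions.fractions.assign(
            immune_fraction=fractions.immune_fraction
        ).to_csv(out / "cell_fractions.tsv", sep="\t")
        means, frac_p = immune_deconvolution.compare_fractions(fractions, labels)
        summary["immune_fraction_by_class"] = {
            str(k): float(v) for k, v in means.items()
        }

    # ---- prognostic screen -----------------------------------------------
    sf = diff_expression.size_factors(cohort.counts)
    expr = cohort.counts / sf
    screen_genes: list[str] = []
    if key in de_results:
        up = de_results[key].table
        screen_genes = up.index[up["call"] == "up"].tolist()
    summary["screen"] = {}
    screen_table = None
    if screen_genes:
        screen_cfg = survival_prognosis.ScreenConfig(**cfg.screen)
        screen_table, skipped = stage(
            "survival",
            lambda: survival_prognosis.prognostic_screen(
                expr, cohort.clinical, screen_genes, screen_cfg
            ),
        ) or (None, [])
        if screen_table is not None:
            screen_table.to_csv(out / "prognostic_screen.tsv", sep="\t")
            summary["screen"] = {
                "n_tested": int(len(screen_table)),
                "n_favorable": int(screen_table["favorable"].sum()),
            }

    # ---- neo-epitope association -----------------------------------------
    targets = []
    if screen_table is not None and screen_table["favorable"].any():
        targets = screen_table.index[screen_table["favorable"]].tolist()
    elif screen_genes:
        targets = screen_genes
    if targets:
        fdr_res = stage(
            "neoassoc",
            lambda: neoepitope_assoc.resampling_fdr(
                expr, cohort.neo_counts, targets,
                n_iterations=cfg.n_fdr_iterations,
                seed=_stage_seed(cfg, "neoassoc"),
            ),
        )
        if fdr_res is not None:
            fdr_res.iterations.to_csv(out / "neo_fdr_iterations.tsv", sep="\t",
                                      index=False)
            fdr_res.target_table.to_csv(out / "neo_target_correlations.tsv",
                                        sep="\t")
            summary["neo_fdr"] = {
                "fdr": fdr_res.fdr,
                "n_targets": len(targets),
                "n_iterations": cfg.n_fdr_iterations,
            }

    if errors:
        summary["errors"] = errors
    _json_dump(summary, out / "summary.json")
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {s: _stage_seed(cfg, s) for s in _STAGE_SEED_OFFSET},
        "parameters": {
            "n_top_probes": cfg.n_top_probes, "k_final": cfg.k_final,
            "n_resamplings": cfg.n_resamplings, "p_item": cfg.p_item,
            "p_feature": cfg.p_feature, "dm": cfg.dm, "de": cfg.de,
            "screen": cfg.screen, "n_fdr_iterations": cfg.n_fdr_iterations,
            "simulate": cfg.simulate,
        },
    }
    _json_dump(manifest, out / "manifest.json")
    return summary
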