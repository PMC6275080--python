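"""Readers and writers for the tabular formats the pipeline consumes.

All tables are TSV, UTF-8, with the first column holding the row
identifier.  Genomic coordinates are 1-based, fully-closed intervals
(Illumina MAPINFO convention).  Gene sets use the standard GMT dialect
``name<TAB>description<TAB>gene1<TAB>gene2...``.

Containers are plain pandas objects validated on read:

* beta matrix — probe x sample DataFrame of floats in [0, 1], NaN allowed;
* probe manifest — DataFrame indexed by probe id with ``chrom``, ``pos``
  and an optional advisory ``gene`` column;
* gene models — DataFrame indexed by symbol with ``chrom``, ``strand``,
  ``tss``, ``tx_start``, ``tx_end``, exon interval lists and optional UTRs;
* count matrix — gene x sample DataFrame of nonnegative integers;
* clinical table — DataFrame indexed by sample with ``time`` (days),
  ``event`` (0/1) and ``histology``;
* gene-set collection — ``dict[str, list[str]]`` preserving file order;
* neo-epitope counts — Series of nonnegative integers indexed by sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input file violates a container invariant."""


def _check_unique(index: pd.Index, what: str, path) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what} ids in {path}: {dups}")


# ---------------------------------------------------------------------------
# beta matrix

def read_beta_matrix(path) -> pd.DataFrame:
    """Read a probe x sample beta-value TSV; 'NA' cells become NaN."""
    beta = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    beta = beta.astype(float)
    beta.index = beta.index.astype(str)
    _check_unique(beta.index, "probe", path)
    _check_unique(beta.columns, "sample", path)
    bad = (beta < 0) | (beta > 1)
    if bad.any().any():
        probe = beta.index[bad.any(axis=1)][0]
        sample = beta.columns[bad.loc[probe].fillna(False)][0]
        raise ValidationError(
            f"beta value outside [0,1] at probe {probe!r}, sample {sample!r} "
            f"in {path}: {beta.loc[probe, sample]}"
        )
    return beta


def write_beta_matrix(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path, sep="\t", index_label="probe", na_rep="NA")


# ---------------------------------------------------------------------------
# probe manifest

def read_probe_manifest(path) -> pd.DataFrame:
    man = pd.read_csv(path, sep="\t", index_col=0, dtype={"chrom": str})
    man.index = man.index.astype(str)
    _check_unique(man.index, "probe", path)
    if "chrom" not in man.columns or "pos" not in man.columns:
        raise ValidationError(f"manifest {path} needs 'chrom' and 'pos' columns")
    man["pos"] = man["pos"].astype(int)
    if (man["pos"] < 1).any():
        raise ValidationError(f"manifest {path} has positions < 1")
    return man


def write_probe_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index_label="probe")


# ---------------------------------------------------------------------------
# gene models

_GENE_MODEL_COLS = ["chrom", "strand", "tss", "tx_start", "tx_end"]


def _parse_interval_list(text) -> list[tuple[int, int]]:
    """Parse 'a-b,c-d' into [(a, b), (c, d)]; empty/NA gives []."""
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return []
    out = []
    for chunk in str(text).split(","):
        lo, hi = chunk.split("-")
        lo, hi = int(lo), int(hi)
        if lo > hi:
            raise ValidationError(f"malformed interval {chunk!r}")
        out.append((lo, hi))
    return out


def _format_interval_list(intervals) -> str:
    return ",".join(f"{lo}-{hi}" for lo, hi in intervals)


def read_gene_models(path) -> pd.DataFrame:
    """Read a BED-like gene-model TSV into a symbol-indexed DataFrame.

    Columns: chrom, strand, tss, tx_start, tx_end, exons (list of 1-based
    closed intervals), utr5, utr3 (possibly empty lists).
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype={"chrom": str})
    raw.index = raw.index.astype(str)
    _check_unique(raw.index, "gene", path)
    for col in _GENE_MODEL_COLS:
        if col not in raw.columns:
            raise ValidationError(f"gene models {path} missing column {col!r}")
    models = raw[_GENE_MODEL_COLS].copy()
    for col in ("tss", "tx_start", "tx_end"):
        models[col] = models[col].astype(int)
    if (models["tx_start"] > models["tx_end"]).any():
        raise ValidationError(f"gene models {path}: tx_start > tx_end")
    if not models["strand"].isin(["+", "-"]).all():
        raise ValidationError(f"gene models {path}: strand must be '+' or '-'")
    for col in ("exons", "utr5", "utr3"):
        source = raw[col] if col in raw.columns else pd.Series("", index=raw.index)
        models[col] = [_parse_interval_list(v) for v in source]
    return models


def write_gene_models(models: pd.DataFrame, path) -> None:
    out = models[_GENE_MODEL_COLS].copy()
    for col in ("exons", "utr5", "utr3"):
        out[col] = [_format_interval_list(v) for v in models[col]]
    out.to_csv(path, sep="\t", index_label="symbol")


# ---------------------------------------------------------------------------
# counts

def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    _check_unique(counts.index, "gene", path)
    _check_unique(counts.columns, "sample", path)
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError(f"count matrix {path} has non-integer entries")
        counts = counts.round().astype(np.int64)
    if (counts.to_numpy() < 0).any():
        raise ValidationError(f"count matrix {path} has negative entries")
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValidationError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# clinical table

def read_clinical(path) -> pd.DataFrame:
    clin = pd.read_csv(path, sep="\t", index_col=0)
    clin.index = clin.index.astype(str)
    _check_unique(clin.index, "sample", path)
    for col in ("time", "event"):
        if col not in clin.columns:
            raise ValidationError(f"clinical table {path} missing column {col!r}")
    clin["time"] = clin["time"].astype(float)
    if (clin["time"] < 0).any():
        raise ValidationError(f"clinical table {path}: negative survival time")
    if not clin["event"].isin([0, 1]).all():
        bad = clin.loc[~clin["event"].isin([0, 1])].index[0]
        raise ValidationError(
            f"clinical table {path}: event must be 0 or 1 (sample {bad!r})"
        )
    clin["event"] = clin["event"].astype(int)
    return clin


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# neo-epitope counts

def read_neo_counts(path) -> pd.Series:
    neo = pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0]
    neo.index = neo.index.astype(str)
    _check_unique(neo.index, "sample", path)
    if (neo < 0).any() or not np.allclose(neo, np.round(neo)):
        raise ValidationError(f"neo-epitope counts {path} must be nonnegative integers")
    return neo.astype(np.int64).rename("neo_count")


def write_neo_counts(neo: pd.Series, path) -> None:
    neo.rename("neo_count").to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# labels (cluster assignments), shared by several CLI stages

def read_labels(path) -> pd.Series:
    labels = pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0]
    labels.index = labels.index.astype(str)
    _check_unique(labels.index, "sample", path)
    return labels.rename("label")


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("label").to_csv(path, sep="\t", index_label="sample")
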