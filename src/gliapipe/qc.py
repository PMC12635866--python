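"""Per-cell quality control.

Computes library-level metrics (UMI total, detected genes, fraction of
counts in ribosomal and mitochondrial genes) and applies secondary QC
cutoffs: cells are retained when the ribosomal and mitochondrial
fractions are below their caps, and the detected-gene and UMI totals lie
strictly between a floor and a multiple of the per-sample median.

Cluster-level exclusion (doublet/gene-poor/dividing clusters) is handled
by dropping caller-designated cluster labels; no doublet detection is
performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

RIBO_PREFIXES = ("RPS", "RPL")
MITO_PREFIX = "MT-"

#: Columns every CellTable carries after metric computation.
CELLTABLE_COLUMNS = [
    "cell_id",
    "sample_id",
    "genotype",
    "cluster",
    "n_genes",
    "n_umi",
    "pct_ribo",
    "pct_mito",
]


@dataclass(frozen=True)
class QCThresholds:
    """Secondary QC cutoffs.

    All comparisons are strict: a cell sitting exactly on a bound is
    removed (upper bounds) or removed (lower bounds), matching the
    "<"/">" phrasing of the protocol.
    """

    max_pct_ribo: float = 0.25
    max_pct_mito: float = 0.125
    min_genes: int = 500
    max_genes_factor: float = 2.0
    min_umi: int = 500
    max_umi_factor: float = 2.0
    #: "sample" computes gene/UMI medians within each sample (each dataset
    #: is QC'd before merging); "global" pools all cells.
    median_scope: str = "sample"
    #: If True, medians are computed on cells that already passed the
    #: ribo/mito caps; if False, on all cells entering this step.
    medians_after_fraction_filters: bool = True

    def __post_init__(self) -> None:
        if not (self.max_pct_ribo > 0 and self.max_pct_mito > 0):
            raise ValueError("fraction caps must be positive")
        if self.max_genes_factor <= 1 or self.max_umi_factor <= 1:
            raise ValueError("median factors must exceed 1")
        if self.min_genes <= 0 or self.min_umi <= 0:
            raise ValueError("floors must be positive")
        if self.median_scope not in ("sample", "global"):
            raise ValueError(f"unknown median_scope {self.median_scope!r}")


def _as_csc(counts) -> sparse.csc_matrix:
    if sparse.issparse(counts):
        return counts.tocsc()
    return sparse.csc_matrix(np.asarray(counts))


def compute_qc_metrics(counts, gene_names, cells: pd.DataFrame | None = None) -> pd.DataFrame:
    """Compute per-cell QC metrics from a gene x cell count matrix.

    Parameters
    ----------
    counts
        Non-negative gene x cell matrix (dense or scipy sparse).
    gene_names
        Sequence of gene symbols aligned to matrix rows. Ribosomal genes
        are recognised by the RPS/RPL prefixes, mitochondrial genes by
        the MT- prefix.
    cells
        Optional metadata table (cell_id, sample_id, genotype, cluster)
        aligned to matrix columns; metric columns are appended to a copy.

    Returns
    -------
    DataFrame with n_umi, n_genes, pct_ribo, pct_mito per cell. Fractions
    of an all-zero cell are defined as 0.
    """
    X = _as_csc(counts)
    n_genes_total, n_cells = X.shape
    if n_cells == 0 or n_genes_total == 0:
        raise ValueError("count matrix is empty")
    gene_names = np.asarray(gene_names, dtype=object)
    if gene_names.shape[0] != n_genes_total:
        raise ValueError(
            f"{gene_names.shape[0]} gene names for {n_genes_total} matrix rows"
        )

    upper = np.char.upper(gene_names.astype(str))
    ribo_mask = np.char.startswith(upper, RIBO_PREFIXES[0]) | np.char.startswith(
        upper, RIBO_PREFIXES[1]
    )
    mito_mask = np.char.startswith(upper, MITO_PREFIX)

    n_umi = np.asarray(X.sum(axis=0)).ravel()
    n_genes = np.diff(X.indptr) if sparse.issparse(X) else None
    # count strictly-positive entries per column
    n_genes = np.asarray((X > 0).sum(axis=0)).ravel()
    ribo = np.asarray(X[ribo_mask, :].sum(axis=0)).ravel()
    mito = np.asarray(X[mito_mask, :].sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_ribo = np.where(n_umi > 0, ribo / np.maximum(n_umi, 1), 0.0)
        pct_mito = np.where(n_umi > 0, mito / np.maximum(n_umi, 1), 0.0)

    out = cells.copy() if cells is not None else pd.DataFrame(index=range(n_cells))
    if cells is not None and len(cells) != n_cells:
        raise ValueError("cell metadata length does not match matrix columns")
    out = out.reset_index(drop=True)
    out["n_umi"] = n_umi.astype(np.int64)
    out["n_genes"] = n_genes.astype(np.int64)
    out["pct_ribo"] = pct_ribo
    out["pct_mito"] = pct_mito
    return out


def apply_qc(
    cells: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply secondary QC cutoffs; returns (table with passed_qc, report).

    The report counts removals per rule per sample (a cell failing
    several rules is tallied under each, plus once under ``removed``).
    """
    th = thresholds or QCThresholds()
    cells = cells.reset_index(drop=True).copy()
    required = {"n_genes", "n_umi", "pct_ribo", "pct_mito"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"metrics missing from CellTable: {sorted(missing)}")
    if "sample_id" not in cells.columns:
        cells["sample_id"] = "all"

    frac_ok = (cells["pct_ribo"] < th.max_pct_ribo) & (
        cells["pct_mito"] < th.max_pct_mito
    )

    if th.median_scope == "sample":
        groups = cells.groupby("sample_id", sort=False)
    else:
        groups = [("all", cells)]

    med_genes = pd.Series(index=cells.index, dtype=float)
    med_umi = pd.Series(index=cells.index, dtype=float)
    for name, grp in groups if th.median_scope == "sample" else [("all", cells)]:
        if len(grp) < 2:
            warnings.warn(
                f"sample {name!r} has <2 cells; passed through without median rule"
            )
        base = grp[frac_ok.loc[grp.index]] if th.medians_after_fraction_filters else grp
        if len(base) == 0:
            base = grp
        med_genes.loc[grp.index] = float(np.median(base["n_genes"]))
        med_umi.loc[grp.index] = float(np.median(base["n_umi"]))

    fail_ribo = ~(cells["pct_ribo"] < th.max_pct_ribo)
    fail_mito = ~(cells["pct_mito"] < th.max_pct_mito)
    fail_genes_low = ~(cells["n_genes"] > th.min_genes)
    fail_genes_high = ~(cells["n_genes"] < th.max_genes_factor * med_genes)
    fail_umi_low = ~(cells["n_umi"] > th.min_umi)
    fail_umi_high = ~(cells["n_umi"] < th.max_umi_factor * med_umi)

    tiny = cells.groupby("sample_id")["n_umi"].transform("size") < 2
    fails = (
        fail_ribo | fail_mito | fail_genes_low | fail_genes_high | fail_umi_low | fail_umi_high
    ) & ~tiny
    cells["passed_qc"] = ~fails

    rules = {
        "ribo": fail_ribo,
        "mito": fail_mito,
        "genes_low": fail_genes_low,
        "genes_high": fail_genes_high,
        "umi_low": fail_umi_low,
        "umi_high": fail_umi_high,
    }
    rows = []
    for sample, grp in cells.groupby("sample_id", sort=False):
        row = {"sample_id": sample, "n_cells": len(grp)}
        for rule, mask in rules.items():
            row[f"fail_{rule}"] = int(mask.loc[grp.index].sum())
        row["removed"] = int((~grp["passed_qc"]).sum())
        row["retained"] = int(grp["passed_qc"].sum())
        rows.append(row)
    report = pd.DataFrame(rows)
    return cells, report


def drop_clusters(cells: pd.DataFrame, clusters_to_drop) -> pd.DataFrame:
    """Remove caller-designated cluster labels (doublet/gene-poor/dividing)."""
    drop = set(clusters_to_drop)
    return cells[~cells["cluster"].isin(drop)].reset_index(drop=True)
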