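"""Per-cell QC metrics, cell filtering, and the expressed-gene background rule.

Metrics follow the usual droplet-scRNA-seq conventions: n_features is the
number of genes with a non-zero count, n_counts the total UMI count, and
pct_mito the percentage of counts coming from mitochondrially encoded genes
(names starting "MT-", case-insensitive). The default retention rule keeps a
cell iff n_features > 200 and n_counts < 12,000 and pct_mito < 30, all strict.
Ribosomal genes (names matching ^RP[LS], case-insensitive; mitochondrial-
ribosomal MRP* genes are kept) can be dropped from the matrix, after metric
computation, because of their outsized pull on downstream clustering.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "QCThresholds",
    "FilterReport",
    "compute_qc_metrics",
    "filter_cells",
    "remove_ribosomal_genes",
    "expressed_genes",
    "is_mito",
    "is_ribo",
]

_MITO_RE = re.compile(r"^MT-", re.IGNORECASE)
_RIBO_RE = re.compile(r"^RP[LS]", re.IGNORECASE)

QC_COLUMNS = ("n_features", "n_counts", "pct_mito")


def is_mito(gene_names) -> np.ndarray:
    """Boolean mask of mitochondrially encoded genes ("MT-" prefix)."""
    return np.array([bool(_MITO_RE.match(g)) for g in gene_names])


def is_ribo(gene_names) -> np.ndarray:
    """Boolean mask of cytosolic ribosomal protein genes (RPL*/RPS*)."""
    return np.array([bool(_RIBO_RE.match(g)) for g in gene_names])


@dataclass(frozen=True)
class QCThresholds:
    """Cell-retention thresholds; all inequalities are strict.

    A cell is kept iff n_features > min_features AND n_counts < max_counts
    AND pct_mito < max_mito_pct, so a cell sitting exactly on a boundary is
    removed.
    """

    min_features: int = 200
    max_counts: int = 12_000
    max_mito_pct: float = 30.0

    def __post_init__(self):
        if self.min_features < 0:
            raise ValueError("min_features must be >= 0")
        if self.max_counts <= self.min_features:
            raise ValueError("max_counts must exceed min_features")
        if not (0.0 <= self.max_mito_pct <= 100.0):
            raise ValueError("max_mito_pct must lie in [0, 100]")


@dataclass(frozen=True)
class FilterReport:
    """Removal counts per rule, with overlaps for the inclusion-exclusion check."""

    n_input: int
    n_kept: int
    low_features: int
    high_counts: int
    high_mito: int
    low_features_and_high_counts: int
    low_features_and_high_mito: int
    high_counts_and_high_mito: int
    all_three: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, getattr(self, k)) for k in (
            "n_input", "n_kept", "low_features", "high_counts", "high_mito",
            "low_features_and_high_counts", "low_features_and_high_mito",
            "high_counts_and_high_mito", "all_three",
        )]
        rows.append(("n_removed", self.n_removed))
        return pd.DataFrame(rows, columns=["rule", "cells"])


def compute_qc_metrics(matrix) -> pd.DataFrame:
    """Per-cell QC metrics from a gene-by-cell count matrix.

    Returns a table with one row per cell: cell_id, n_counts, n_features,
    pct_mito. Cells with zero total counts get pct_mito = 0 by convention
    (the feature floor removes them regardless).
    """
    counts = matrix.counts
    if counts.shape[0] != len(matrix.gene_names):
        raise ValueError(
            f"matrix has {counts.shape[0]} gene rows but {len(matrix.gene_names)} gene names"
        )
    counts = sp.csc_matrix(counts)
    n_counts = np.asarray(counts.sum(axis=0)).ravel()
    n_features = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito = is_mito(matrix.gene_names)
    mito_counts = (
        np.asarray(counts[mito, :].sum(axis=0)).ravel()
        if mito.any()
        else np.zeros(counts.shape[1])
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(n_counts > 0, 100.0 * mito_counts / np.maximum(n_counts, 1), 0.0)
    return pd.DataFrame(
        {
            "cell_id": np.asarray(matrix.cell_ids),
            "n_counts": n_counts.astype(np.int64),
            "n_features": n_features.astype(np.int64),
            "pct_mito": pct_mito,
        }
    )


def filter_cells(
    table: pd.DataFrame, thr: QCThresholds = QCThresholds()
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the retention rule to a cell table carrying QC metric columns.

    Returns the surviving rows (order preserved) and a removal report whose
    per-rule counts satisfy inclusion-exclusion against n_removed.
    """
    for col in QC_COLUMNS:
        if col not in table.columns:
            raise KeyError(f"cell table lacks QC metric column {col!r}")
    low_f = ~(table["n_features"].to_numpy() > thr.min_features)
    high_c = ~(table["n_counts"].to_numpy() < thr.max_counts)
    high_m = ~(table["pct_mito"].to_numpy() < thr.max_mito_pct)
    fail = low_f | high_c | high_m
    kept = table.loc[~fail]
    report = FilterReport(
        n_input=len(table),
        n_kept=len(kept),
        low_features=int(low_f.sum()),
        high_counts=int(high_c.sum()),
        high_mito=int(high_m.sum()),
        low_features_and_high_counts=int((low_f & high_c).sum()),
        low_features_and_high_mito=int((low_f & high_m).sum()),
        high_counts_and_high_mito=int((high_c & high_m).sum()),
        all_three=int((low_f & high_c & high_m).sum()),
    )
    return kept, report


def remove_ribosomal_genes(matrix):
    """Drop RPL*/RPS* genes; cells and remaining counts are untouched.

    Mitochondrial-ribosomal (MRP*) genes are retained: they do not match the
    cytosolic ribosomal prefix.
    """
    ribo = is_ribo(matrix.gene_names)
    if not ribo.any():
        return matrix
    keep = ~ribo
    return replace(
        matrix,
        counts=sp.csr_matrix(matrix.counts)[keep, :],
        gene_names=np.asarray(matrix.gene_names)[keep],
    )


def expressed_genes(
    matrix, group_labels, min_fraction: float = 0.1, groups=None
) -> dict[object, list[str]]:
    """Per-group expressed-gene sets.

    A gene counts as expressed in a group when it has a non-zero value in at
    least ``min_fraction`` of the group's cells (inclusive threshold, default
    10%). ``groups`` restricts/extends the groups evaluated (default: the
    distinct labels observed). Returns {group: sorted gene-name list}; an
    empty group yields an empty list with a warning.
    """
    labels = np.asarray(group_labels)
    if labels.shape[0] != matrix.counts.shape[1]:
        raise ValueError(
            f"{labels.shape[0]} group labels for {matrix.counts.shape[1]} cells"
        )
    counts = sp.csc_matrix(matrix.counts)
    genes = np.asarray(matrix.gene_names)
    out: dict[object, list[str]] = {}
    for g in pd.unique(labels) if groups is None else groups:
        mask = labels == g
        size = int(mask.sum())
        if size == 0:
            warnings.warn(f"group {g!r} has no cells; expressed set is empty", stacklevel=2)
            out[g] = []
            continue
        nz = np.asarray((counts[:, mask] > 0).sum(axis=1)).ravel()
        out[g] = sorted(genes[nz / size >= min_fraction])
    return out
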