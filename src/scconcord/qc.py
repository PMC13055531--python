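"""Per-cell quality metrics and library-level exclusion rules.

The exclusion rule drops a cell when any of these hold within its library
(one sample x platform):

* UMI count more than ``n_mads`` deviations below the library median,
* detected-gene count more than ``n_mads`` deviations below the median,
* mitochondrial UMI fraction above ``mito_max`` (default 10%),
* the cell is flagged as a doublet.

"Deviation" defaults to the scaled median absolute deviation (constant
1.4826, the scater ``isOutlier`` convention); a literal mean absolute
deviation estimator is available via ``estimator="mean"``.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneAnnotation

logger = logging.getLogger(__name__)

MAD_CONSTANT = 1.4826


def compute_metrics(
    matrix: CountMatrix,
    annotation: GeneAnnotation | None = None,
    doublet_flags: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Per-cell QC metrics: umi_count, genes_detected, mito_fraction, doublet_flag."""
    counts = matrix.counts.tocsc()
    umi = np.asarray(counts.sum(axis=0)).ravel()
    genes_detected = np.diff(counts.indptr)
    if annotation is not None:
        mito = annotation.mito_mask(matrix.gene_ids)
    else:
        mito = np.zeros(matrix.n_genes, dtype=bool)
    mito_umi = np.asarray(counts[mito, :].sum(axis=0)).ravel() if mito.any() else np.zeros_like(umi)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(umi > 0, mito_umi / np.maximum(umi, 1), 0.0)
    if doublet_flags is None:
        doublet_flags = np.zeros(matrix.n_cells, dtype=bool)
    return pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "umi_count": umi.astype(int),
            "genes_detected": genes_detected.astype(int),
            "mito_fraction": mito_fraction,
            "doublet_flag": np.asarray(doublet_flags, dtype=bool),
        }
    )


def _spread(values: np.ndarray, estimator: str, constant: float) -> float:
    if estimator == "median":
        return constant * float(np.median(np.abs(values - np.median(values))))
    if estimator == "mean":
        return float(np.mean(np.abs(values - np.median(values))))
    raise ValueError(f"unknown estimator {estimator!r}")


def mad_filter(
    metrics: pd.DataFrame,
    n_mads: float = 3.0,
    mito_max: float = 0.10,
    estimator: str = "median",
    mad_constant: float = MAD_CONSTANT,
) -> tuple[np.ndarray, list[list[str]]]:
    """Apply the four exclusion rules to one library's metrics.

    Returns (keep mask, per-cell list of triggered exclusion reasons).
    Thresholds are computed once from the full input (frozen), so filtering
    the kept cells again with the same thresholds is idempotent.
    """
    if len(metrics) == 0:
        raise ValueError("empty library")
    umi = metrics["umi_count"].to_numpy(dtype=float)
    genes = metrics["genes_detected"].to_numpy(dtype=float)
    mito = metrics["mito_fraction"].to_numpy(dtype=float)
    doublet = metrics["doublet_flag"].to_numpy(dtype=bool)

    umi_cut = np.median(umi) - n_mads * _spread(umi, estimator, mad_constant)
    gene_cut = np.median(genes) - n_mads * _spread(genes, estimator, mad_constant)

    reasons: list[list[str]] = []
    keep = np.ones(len(metrics), dtype=bool)
    for i in range(len(metrics)):
        r = []
        if umi[i] < umi_cut:
            r.append("low_umi")
        if genes[i] < gene_cut:
            r.append("low_genes")
        if mito[i] > mito_max:
            r.append("high_mito")
        if doublet[i]:
            r.append("doublet")
        if r:
            keep[i] = False
        reasons.append(r)
    logger.info(
        "qc: kept %d/%d cells (umi cut %.1f, gene cut %.1f)",
        keep.sum(), len(keep), umi_cut, gene_cut,
    )
    return keep, reasons


def filter_by_library(
    metrics: pd.DataFrame,
    sample_ids: Sequence,
    platforms: Sequence,
    **kwargs,
) -> tuple[np.ndarray, list[list[str]]]:
    """Run :func:`mad_filter` separately per (sample, platform) library."""
    df = metrics.copy()
    df["_sample"] = np.asarray(sample_ids)
    df["_platform"] = np.asarray(platforms)
    keep = np.ones(len(df), dtype=bool)
    reasons: list[list[str]] = [[] for _ in range(len(df))]
    for _, grp in df.groupby(["_sample", "_platform"], sort=False):
        k, r = mad_filter(grp, **kwargs)
        idx = grp.index.to_numpy()
        keep[idx] = k
        for j, rr in zip(idx, r):
            reasons[j] = rr
    return keep, reasons
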