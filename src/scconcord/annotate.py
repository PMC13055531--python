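"""Correlation-centroid cell-type annotation with a confidence margin,
cross-platform confidence comparison, and the composition test.

The annotator is intentionally simple: per-type centroids of CP10k-log
expression over a variance-selected gene panel, assignment by Spearman
correlation, confidence = normalized margin between the best and
second-best centroid. The confidence scale is internal to this package
and exists to exercise the downstream comparison machinery; it is not a
calibrated probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

from . import stats
from .cna import cp10k_log2
from .io import CellMetadata, CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class ReferenceCentroids:
    panel: np.ndarray  # gene ids
    centroids: pd.DataFrame  # types x panel genes


@dataclass
class AnnotationResult:
    table: pd.DataFrame  # barcode, cell_type, confidence


def build_centroids(
    reference: CountMatrix,
    labels,
    panel=None,
    panel_size: int = 200,
) -> ReferenceCentroids:
    """Mean CP10k-log expression per label over a gene panel.

    With ``panel=None`` the top ``panel_size`` genes by variance in the
    reference are used.
    """
    labels = np.asarray(labels)
    if len(labels) != reference.n_cells:
        raise ValueError("labels do not match reference cells")
    if pd.isna(labels).any():
        raise ValueError("unlabeled reference cells")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("every label needs at least 2 reference cells")
    expr = cp10k_log2(reference)
    if panel is None:
        var = expr.var(axis=0)
        top = np.argsort(var)[::-1][:panel_size]
        top = np.sort(top)
        panel_genes = reference.gene_ids[top]
        cols = top
    else:
        pos = {g: i for i, g in enumerate(reference.gene_ids)}
        missing = [g for g in panel if g not in pos]
        if missing:
            raise ValueError(f"panel genes absent from reference: {missing[:5]}")
        panel_genes = np.asarray(panel, dtype=object)
        cols = np.array([pos[g] for g in panel_genes])
    rows = {}
    for lab in sorted(map(str, set(labels))):
        m = labels.astype(str) == lab
        rows[lab] = expr[np.asarray(m), :][:, cols].mean(axis=0)
    cent = pd.DataFrame(rows).T
    cent.columns = panel_genes
    return ReferenceCentroids(panel_genes, cent)


def transfer_labels(
    query: CountMatrix,
    centroids: ReferenceCentroids,
    min_overlap: float = 0.25,
) -> AnnotationResult:
    """Assign each query cell to the best-correlated centroid.

    Per cell, the Spearman correlation against each centroid is computed
    over panel genes present in the query; the assignment is the argmax
    and the confidence is ``(r_best - r_second) / max(1 - r_second, eps)``
    clipped to [0, 1] (1.0 when there is a single centroid). Ties are
    broken lexicographically on the type name.
    """
    pos = {g: i for i, g in enumerate(query.gene_ids)}
    shared = [g for g in centroids.panel if g in pos]
    frac = len(shared) / len(centroids.panel)
    if frac < min_overlap:
        raise ValueError(
            f"only {len(shared)}/{len(centroids.panel)} panel genes present "
            f"in query ({frac:.0%} < {min_overlap:.0%})"
        )
    expr = cp10k_log2(query)[:, [pos[g] for g in shared]]
    cent = centroids.centroids[shared].to_numpy()
    types = list(centroids.centroids.index)

    # Spearman = Pearson on ranks
    cell_ranks = np.apply_along_axis(rankdata, 1, expr)
    cent_ranks = np.apply_along_axis(rankdata, 1, cent)
    cr = cell_ranks - cell_ranks.mean(axis=1, keepdims=True)
    tr = cent_ranks - cent_ranks.mean(axis=1, keepdims=True)
    cr_norm = np.linalg.norm(cr, axis=1)
    tr_norm = np.linalg.norm(tr, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (cr @ tr.T) / np.outer(np.maximum(cr_norm, 1e-12),
                                   np.maximum(tr_norm, 1e-12))

    if len(types) == 1:
        assigned = np.array(types * query.n_cells, dtype=object)
        conf = np.ones(query.n_cells)
    else:
        best = np.argmax(r, axis=1)  # argmax -> first (lexicographic) on ties
        order = np.sort(r, axis=1)
        r_best = order[:, -1]
        r_second = order[:, -2]
        n_ties = int(np.sum(np.isclose(r_best, r_second)))
        if n_ties:
            logger.info("%d cells with tied top correlations", n_ties)
        conf = np.clip(
            (r_best - r_second) / np.maximum(1.0 - r_second, 1e-12), 0.0, 1.0)
        assigned = np.array([types[i] for i in best], dtype=object)
    return AnnotationResult(pd.DataFrame({
        "barcode": query.barcodes,
        "cell_type": assigned,
        "confidence": conf,
    }))


def _ols(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS fit returning coefficients, their standard errors, and df."""
    n, p = design.shape
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    df = n - np.linalg.matrix_rank(design)
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.maximum(np.diag(cov), 0))
    return beta, se, df


def compare_confidence(
    annotation: AnnotationResult,
    metadata: CellMetadata,
) -> pd.DataFrame:
    """Per-cell-type fixed-effect comparison of confidence across platforms.

    Fits confidence ~ platform + sample (ordinary least squares with
    sample indicator covariates) within each cell type present on both
    platforms, reporting the FFPE-vs-FROZEN effect, its two-sided t-test
    p-value, and BH-adjusted q across cell types.
    """
    meta = metadata.aligned(annotation.table["barcode"])
    df = annotation.table.assign(
        platform=meta["platform"].to_numpy(),
        sample_id=meta["sample_id"].to_numpy(),
    )
    rows = []
    for ct, grp in df.groupby("cell_type", sort=True):
        platforms = set(grp["platform"])
        if len(platforms) < 2:
            logger.info("cell type %r present on one platform only; skipped", ct)
            continue
        y = grp["confidence"].to_numpy(dtype=float)
        plat = (grp["platform"] == "FFPE").to_numpy(dtype=float)
        samples = pd.get_dummies(grp["sample_id"], drop_first=True).to_numpy(dtype=float)
        design = np.column_stack([np.ones(len(y)), plat, samples])
        try:
            beta, se, dof = _ols(design, y)
        except ValueError:
            logger.info("cell type %r: degenerate design; skipped", ct)
            continue
        if se[1] == 0:
            p = 1.0 if beta[1] == 0 else 0.0
        else:
            tstat = beta[1] / se[1]
            p = 2.0 * float(t_dist.sf(abs(tstat), dof))
        rows.append({"cell_type": ct, "effect": float(beta[1]), "pvalue": min(1.0, p)})
    out = pd.DataFrame(rows, columns=["cell_type", "effect", "pvalue"])
    if len(out):
        out["qvalue"] = stats.bh_fdr(out["pvalue"].to_numpy())
    else:
        out["qvalue"] = []
    return out


def composition_test(metadata: CellMetadata) -> stats.CMHResult:
    """Cochran-Mantel-Haenszel test of platform x cell-type association,
    stratified by matched sample.

    Samples present on only one platform are dropped (logged and counted
    in the result).
    """
    t = metadata.table
    if "cell_type" not in t.columns or t["cell_type"].isna().any():
        raise ValueError("every cell needs a cell_type for the composition test")
    cell_types = sorted(t["cell_type"].unique())
    tables = []
    dropped = 0
    for sample, grp in t.groupby("sample_id", sort=True):
        if len(set(grp["platform"])) < 2:
            logger.info("sample %r on one platform only; stratum dropped", sample)
            dropped += 1
            continue
        tab = np.zeros((2, len(cell_types)))
        for i, plat in enumerate(("FROZEN", "FFPE")):
            sub = grp[grp["platform"] == plat]
            vc = sub["cell_type"].value_counts()
            for j, ct in enumerate(cell_types):
                tab[i, j] = vc.get(ct, 0)
        tables.append(tab)
    if not tables:
        raise ValueError("no sample present on both platforms")
    res = stats.cmh_test(tables)
    return stats.CMHResult(res.statistic, res.df, res.pvalue,
                           res.n_strata_used, res.n_strata_dropped + dropped)
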