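"""Marker-set scoring, margin-based subtype assignment, and cross-platform
per-sample marker correlation.

Marker scores are means of CP10k-log expression over the set's genes, so
they are invariant to per-cell depth. Subtype assignment z-scores each
set's score vector across cells and assigns the top set when its margin
over the runner-up reaches ``min_margin``; otherwise the cell is left
"unassigned".
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .cna import cp10k_log2
from .io import CellMetadata, CountMatrix

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

#: T-cell exhaustion marker panel used by the cross-platform comparison
EXHAUSTION_MARKERS = ("PDCD1", "CTLA4", "HAVCR2", "LAG3", "TIGIT", "TOX")

#: generic default subtype sets; placeholders meant to be replaced by a
#: user-supplied marker config for any real analysis
DEFAULT_MARKER_SETS = {
    "CD4_T": ["CD4", "IL7R", "CCR7", "TCF7"],
    "CD8_T": ["CD8A", "CD8B", "GZMK", "NKG7"],
    "Treg": ["FOXP3", "IL2RA", "CTLA4", "IKZF2"],
    "NK": ["NCAM1", "KLRD1", "GNLY", "NKG7"],
    "exhausted_T": list(EXHAUSTION_MARKERS),
}


@dataclass
class MarkerSet:
    name: str
    genes: list

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"marker set {self.name!r} has no genes")


def load_marker_sets(path) -> list[MarkerSet]:
    """Load marker sets from a JSON object or a 2-column TSV (set, gene)."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            data = json.load(fh)
        return [MarkerSet(k, list(v)) for k, v in data.items()]
    df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"])
    return [MarkerSet(k, g["gene"].tolist()) for k, g in df.groupby("set", sort=True)]


def _resolve_genes(matrix: CountMatrix, genes) -> np.ndarray:
    """Column indices for gene symbols or ids; missing genes dropped."""
    by_symbol = {}
    for i, s in enumerate(matrix.gene_symbols):
        by_symbol.setdefault(s, i)
    by_id = {g: i for i, g in enumerate(matrix.gene_ids)}
    idx = []
    for g in genes:
        if g in by_id:
            idx.append(by_id[g])
        elif g in by_symbol:
            idx.append(by_symbol[g])
    return np.array(sorted(set(idx)), dtype=int)


def score_marker_set(matrix: CountMatrix, marker_set: MarkerSet) -> np.ndarray:
    """Per-cell mean CP10k-log expression over the set's present genes."""
    idx = _resolve_genes(matrix, marker_set.genes)
    if len(idx) == 0:
        raise ValueError(f"no genes of set {marker_set.name!r} present in matrix")
    if len(idx) < len(marker_set.genes):
        logger.info("set %r: %d/%d genes present", marker_set.name,
                    len(idx), len(marker_set.genes))
    expr = cp10k_log2(matrix)
    return expr[:, idx].mean(axis=1)


def subtype_cells(
    matrix: CountMatrix,
    sets: list[MarkerSet],
    min_margin: float = 0.25,
) -> np.ndarray:
    """Assign each cell the best z-scored marker set or "unassigned"."""
    if len(sets) < 2:
        raise ValueError("need at least 2 marker sets")
    cols, names = [], []
    for s in sets:
        sc = score_marker_set(matrix, s)
        sd = sc.std()
        if sd == 0:
            logger.info("set %r has constant scores; excluded", s.name)
            continue
        cols.append((sc - sc.mean()) / sd)
        names.append(s.name)
    if len(cols) < 2:
        raise ValueError("fewer than 2 non-degenerate marker sets")
    Z = np.column_stack(cols)
    # stable across set ordering: rank by (z, name) so ties break by name
    order = np.argsort(names, kind="stable")
    Z = Z[:, order]
    names = [names[i] for i in order]
    top = np.argmax(Z, axis=1)
    zs = np.sort(Z, axis=1)
    margin = zs[:, -1] - zs[:, -2]
    labels = np.array([names[i] for i in top], dtype=object)
    labels[margin < min_margin] = UNASSIGNED
    return labels


def cross_platform_marker_cor(
    matrices: dict,
    metadata: CellMetadata,
    gene: str,
    cell_type: str | None = None,
    subtype_labels: pd.Series | None = None,
):
    """Per-sample paired platform means of one gene, and their correlation.

    For every sample and platform the mean CP10k-log expression of
    ``gene`` over the selected cells (optionally restricted to a cell type
    from metadata or to externally supplied subtype labels) is computed;
    Pearson correlation is taken across samples between the two platform
    columns. Returns ``(table, r, p)``.
    """
    rows = {}
    for (sample, platform), matrix in sorted(matrices.items()):
        idx = _resolve_genes(matrix, [gene])
        if len(idx) == 0:
            raise ValueError(f"gene {gene!r} absent from platform {platform}")
        keep = np.ones(matrix.n_cells, dtype=bool)
        if cell_type is not None:
            meta = metadata.aligned(matrix.barcodes)
            keep &= (meta["cell_type"] == cell_type).to_numpy()
        if subtype_labels is not None:
            lab = subtype_labels.reindex(matrix.barcodes)
            keep &= (lab.notna() & (lab != UNASSIGNED)).to_numpy()
        if keep.sum() == 0:
            continue
        expr = cp10k_log2(matrix.subset_cells(keep))[:, idx[0]]
        rows.setdefault(sample, {})[platform] = float(expr.mean())
    table = pd.DataFrame(rows).T.sort_index()
    table.index.name = "sample_id"
    paired = table.dropna()
    if len(paired) < 3 or {"FROZEN", "FFPE"} - set(paired.columns):
        raise ValueError("need >= 3 samples with the subset on both platforms")
    r, p = stats.pearson_cor(paired["FROZEN"], paired["FFPE"])
    return table, r, p
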