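"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention) throughout
the package. Gene order inside a :class:`CountMatrix` is authoritative;
:class:`GeneAnnotation` is joined by ``gene_id`` and genes lacking
coordinates are kept for expression analyses but dropped from genomic
windowing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

PLATFORMS = ("FROZEN", "FFPE")


class FormatError(ValueError):
    """A file does not parse as the expected format."""


class IntegrityError(ValueError):
    """Parsed components are mutually inconsistent."""


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sparse genes x cells integer count matrix with axis annotations.

    Parameters
    ----------
    counts
        Sparse non-negative integer matrix, genes on rows, cells on columns.
    gene_ids
        Unique gene identifiers, one per row.
    gene_symbols
        Human-readable symbols, parallel to ``gene_ids``.
    barcodes
        Unique cell identifiers, one per column.
    """

    counts: sp.csc_matrix
    gene_ids: np.ndarray
    gene_symbols: np.ndarray
    barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.gene_symbols) != n_genes:
            raise IntegrityError(
                f"gene annotations ({len(self.gene_ids)}) do not match "
                f"matrix rows ({n_genes})"
            )
        if len(self.barcodes) != n_cells:
            raise IntegrityError(
                f"barcodes ({len(self.barcodes)}) do not match matrix "
                f"columns ({n_cells})"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise IntegrityError("duplicate gene_ids")
        if len(set(self.barcodes)) != n_cells:
            raise IntegrityError("duplicate barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise IntegrityError("negative counts")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask_or_barcodes) -> "CountMatrix":
        """Return a new matrix restricted to the given cells (order kept)."""
        arr = np.asarray(mask_or_barcodes)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            pos = {b: i for i, b in enumerate(self.barcodes)}
            idx = np.array([pos[b] for b in arr], dtype=int)
        return CountMatrix(
            self.counts[:, idx],
            self.gene_ids,
            self.gene_symbols,
            self.barcodes[idx],
        )

    def subset_genes(self, mask_or_ids) -> "CountMatrix":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in arr], dtype=int)
        return CountMatrix(
            self.counts[idx, :],
            self.gene_ids[idx],
            self.gene_symbols[idx],
            self.barcodes,
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
            and np.array_equal(self.gene_ids, other.gene_ids)
            and np.array_equal(self.gene_symbols, other.gene_symbols)
            and np.array_equal(self.barcodes, other.barcodes)
        )


def read_10x_triplet(directory_path) -> CountMatrix:
    """Read a 10x-convention triplet (matrix.mtx, features.tsv, barcodes.tsv).

    The MatrixMarket header dimensions are checked against the TSV lengths;
    a mismatch raises :class:`IntegrityError`.
    """
    d = Path(directory_path)
    mtx = _find_file(d, "matrix.mtx")
    feat = _find_file(d, "features.tsv", "genes.tsv")
    bc = _find_file(d, "barcodes.tsv")
    try:
        counts = sp.csc_matrix(scipy.io.mmread(mtx))
    except Exception as exc:  # pragma: no cover - delegated parse errors
        raise FormatError(f"cannot parse {mtx}: {exc}") from exc
    try:
        features = pd.read_csv(feat, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        features = pd.DataFrame(columns=[0, 1])
    try:
        barcodes = pd.read_csv(bc, sep="\t", header=None, dtype=str)[0].to_numpy()
    except pd.errors.EmptyDataError:
        barcodes = np.array([], dtype=object)
    if features.shape[0] != counts.shape[0]:
        raise IntegrityError(
            f"features.tsv has {features.shape[0]} rows but matrix header "
            f"declares {counts.shape[0]} genes"
        )
    if len(barcodes) != counts.shape[1]:
        raise IntegrityError(
            f"barcodes.tsv has {len(barcodes)} rows but matrix header "
            f"declares {counts.shape[1]} cells"
        )
    gene_ids = features[0].to_numpy()
    gene_symbols = (features[1] if features.shape[1] > 1 else features[0]).to_numpy()
    return CountMatrix(counts.astype(np.int64), gene_ids, gene_symbols, barcodes)


def write_10x_triplet(matrix: CountMatrix, directory_path) -> None:
    """Write a :class:`CountMatrix` as an uncompressed 10x triplet."""
    d = Path(directory_path)
    d.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(matrix.counts)
    scipy.io.mmwrite(d / "matrix.mtx", coo, field="integer")
    feat = pd.DataFrame(
        {
            0: matrix.gene_ids,
            1: matrix.gene_symbols,
            2: "Gene Expression",
        }
    )
    feat.to_csv(d / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(matrix.barcodes).to_csv(
        d / "barcodes.tsv", sep="\t", header=False, index=False
    )


def _find_file(directory: Path, *names: str) -> Path:
    for name in names:
        for cand in (directory / name, directory / (name + ".gz")):
            if cand.exists():
                return cand
    raise FormatError(f"no {' or '.join(names)} in {directory}")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Per-gene genomic coordinates (0-based half-open) and mito flags.

    ``table`` columns: gene_id, chromosome, start, end, is_mitochondrial.
    """

    table: pd.DataFrame

    REQUIRED = ("gene_id", "chromosome", "start", "end", "is_mitochondrial")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise FormatError(f"gene annotation missing columns: {sorted(missing)}")
        t = self.table
        if t["gene_id"].duplicated().any():
            raise IntegrityError("duplicate gene_id in annotation")
        if (t["start"] < 0).any():
            raise FormatError("negative start coordinate")
        if (t["start"] >= t["end"]).any():
            raise FormatError("start >= end in gene annotation")
        self.table = t.reset_index(drop=True)

    def mito_mask(self, gene_ids) -> np.ndarray:
        """Boolean mitochondrial mask aligned to ``gene_ids``.

        Genes absent from the annotation default to non-mitochondrial.
        """
        flags = dict(zip(self.table["gene_id"], self.table["is_mitochondrial"]))
        n_missing = sum(g not in flags for g in gene_ids)
        if n_missing:
            logger.info("%d genes missing from annotation; treated non-mito", n_missing)
        return np.array([bool(flags.get(g, False)) for g in gene_ids])

    def positioned(self, gene_ids) -> pd.DataFrame:
        """Annotation rows for ``gene_ids`` that have coordinates, matrix order."""
        t = self.table.set_index("gene_id")
        present = [g for g in gene_ids if g in t.index]
        dropped = len(gene_ids) - len(present)
        if dropped:
            logger.info("%d genes lack coordinates; excluded from windowing", dropped)
        out = t.loc[present].reset_index()
        return out

    @classmethod
    def read_tsv(cls, path) -> "GeneAnnotation":
        t = pd.read_csv(path, sep="\t", comment="#", header=None,
                        names=list(cls.REQUIRED))
        t["is_mitochondrial"] = t["is_mitochondrial"].astype(str).isin(
            {"1", "True", "true", "TRUE"}
        )
        return cls(t)

    def to_tsv(self, path) -> None:
        t = self.table.copy()
        t["is_mitochondrial"] = t["is_mitochondrial"].astype(int)
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(self.REQUIRED) + "\n")
            t.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Cell metadata
# ---------------------------------------------------------------------------

@dataclass
class CellMetadata:
    """Per-cell sample/platform assignment plus optional labels.

    ``table`` columns: barcode, sample_id, platform plus optional
    doublet_flag, cell_type, cluster.
    """

    table: pd.DataFrame

    REQUIRED = ("barcode", "sample_id", "platform")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise FormatError(f"cell metadata missing columns: {sorted(missing)}")
        t = self.table
        if t["barcode"].duplicated().any():
            raise IntegrityError("duplicate barcodes in metadata")
        bad = set(t["platform"].unique()) - set(PLATFORMS)
        if bad:
            raise IntegrityError(f"unknown platform values: {sorted(bad)}")
        self.table = t.reset_index(drop=True)

    def aligned(self, barcodes) -> pd.DataFrame:
        """Rows reordered to match ``barcodes``; missing barcodes error."""
        t = self.table.set_index("barcode")
        try:
            out = t.loc[list(barcodes)].reset_index()
        except KeyError as exc:
            raise IntegrityError(f"metadata missing barcodes: {exc}") from exc
        return out

    @classmethod
    def read_tsv(cls, path) -> "CellMetadata":
        t = pd.read_csv(path, sep="\t")
        if "doublet_flag" in t.columns:
            t["doublet_flag"] = t["doublet_flag"].astype(bool)
        return cls(t)

    def to_tsv(self, path) -> None:
        t = self.table.copy()
        if "doublet_flag" in t.columns:
            t["doublet_flag"] = t["doublet_flag"].astype(int)
        t.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CNA segment tables
# ---------------------------------------------------------------------------

@dataclass
class SegmentTable:
    """BED-like copy-ratio segments; ``copy_ratio`` 1.0 is neutral.

    ``table`` columns: chromosome, start, end, copy_ratio and optional
    clone_id. Within one clone, segments on a chromosome must not overlap.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"chromosome", "start", "end", "copy_ratio"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"segment table missing columns: {sorted(missing)}")
        if "clone_id" not in t.columns:
            t = t.assign(clone_id=None)
        if (t["start"] >= t["end"]).any():
            raise FormatError("segment with start >= end")
        if (t["copy_ratio"] <= 0).any():
            raise FormatError("non-positive copy_ratio")
        for (_, _), grp in t.groupby(["clone_id", "chromosome"], dropna=False):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise IntegrityError("overlapping segments within one clone")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


def read_segments(path) -> SegmentTable:
    """Read a BED-like TSV: chrom, start, end, copy_ratio[, clone_id]."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"segment line has {len(parts)} fields: {line!r}")
            try:
                rec = {
                    "chromosome": parts[0],
                    "start": int(parts[1]),
                    "end": int(parts[2]),
                    "copy_ratio": float(parts[3]),
                }
            except ValueError as exc:
                raise FormatError(f"unparsable segment line {line!r}") from exc
            rec["clone_id"] = parts[4] if len(parts) > 4 else None
            rows.append(rec)
    return SegmentTable(pd.DataFrame(rows, columns=[
        "chromosome", "start", "end", "copy_ratio", "clone_id"]))


def write_segments(segments: SegmentTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chromosome\tstart\tend\tcopy_ratio\tclone_id\n")
        for row in segments.table.itertuples(index=False):
            clone = "" if row.clone_id is None else str(row.clone_id)
            fh.write(
                f"{row.chromosome}\t{row.start}\t{row.end}\t{row.copy_ratio:g}"
                + (f"\t{clone}" if clone else "")
                + "\n"
            )
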