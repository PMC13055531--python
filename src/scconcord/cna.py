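"""Expression-derived copy-number scoring, genomic windowing, and the
malignancy / subpopulation decision rules.

The score operator is a deliberately simple reference-normalized smoother:
counts-per-10k -> log2(x+1) -> subtract per-gene reference-cell mean ->
clip to +/-3 -> per-chromosome centered moving average over genes ->
per-cell median re-centering. It is not a re-implementation of any
published CNV caller; it produces centered log2 dosage estimates (neutral
= 0) suitable for window averaging.

Windows tile each chromosome from coordinate 0 at a fixed width (default
10 Mb, last window per chromosome may be short); genes are assigned to the
window containing their midpoint. Profiles carry an explicit scale tag:
``centered`` (log2, neutral 0) or ``ratio`` (neutral 1, ratio = 2**centered).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .io import CountMatrix, GeneAnnotation, SegmentTable

logger = logging.getLogger(__name__)

CALL_GAIN = "gain"
CALL_NEUTRAL = "neutral"
CALL_LOSS = "loss"


# ---------------------------------------------------------------------------
# Gene-level scores
# ---------------------------------------------------------------------------

@dataclass
class CNAGeneScores:
    """Cells x genomically-ordered-genes matrix of centered log2 ratios."""

    values: np.ndarray  # cells x genes, finite
    barcodes: np.ndarray
    genes: pd.DataFrame  # gene_id, chromosome, start, end, midpoint (genomic order)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.barcodes), len(self.genes)):
            raise ValueError("score matrix shape mismatch")


def _chromosome_order(chroms: pd.Series) -> list[str]:
    """Stable natural ordering: numeric chromosome suffixes sort numerically."""

    def key(c: str):
        s = c[3:] if c.lower().startswith("chr") else c
        return (0, int(s)) if s.isdigit() else (1, s)

    return sorted(chroms.unique(), key=key)


def _moving_average(block: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1, truncated at the ends."""
    n = block.shape[1]
    half = window // 2
    csum = np.cumsum(block, axis=1)
    csum = np.concatenate([np.zeros((block.shape[0], 1)), csum], axis=1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[:, hi] - csum[:, lo]) / (hi - lo)


def cp10k_log2(matrix: CountMatrix) -> np.ndarray:
    """Dense cells x genes log2(1 + counts-per-10k) expression."""
    counts = matrix.counts.tocsc().astype(float)
    libsize = np.asarray(counts.sum(axis=0)).ravel()
    scale = np.where(libsize > 0, 1e4 / np.maximum(libsize, 1), 0.0)
    dense = counts.toarray().T * scale[:, None]
    return np.log2(dense + 1.0)


def infer_cna_scores(
    matrix: CountMatrix,
    annotation: GeneAnnotation,
    reference_cells,
    smoothing_genes: int = 101,
    clip: float = 3.0,
) -> CNAGeneScores:
    """Reference-normalized smoothed dosage scores for every cell.

    ``reference_cells`` are the barcodes of the presumed copy-neutral
    population (all cells, including the reference, receive scores).
    Chromosomes with fewer than 3 positioned genes are excluded.
    """
    ref = set(reference_cells)
    if not ref:
        raise ValueError("empty reference cell set")
    if smoothing_genes < 1 or smoothing_genes % 2 == 0:
        raise ValueError("smoothing_genes must be a positive odd integer")

    pos = annotation.positioned(matrix.gene_ids)
    counts_per_chrom = pos["chromosome"].value_counts()
    small = counts_per_chrom[counts_per_chrom < 3].index
    if len(small):
        logger.info("excluding %d chromosomes with <3 positioned genes", len(small))
        pos = pos[~pos["chromosome"].isin(small)]
    if len(pos) < smoothing_genes:
        raise ValueError(
            f"only {len(pos)} positioned genes; need >= smoothing_genes "
            f"({smoothing_genes})"
        )
    pos = pos.assign(midpoint=(pos["start"] + pos["end"]) // 2)
    order = _chromosome_order(pos["chromosome"])
    pos["__chrom_rank"] = pos["chromosome"].map({c: i for i, c in enumerate(order)})
    pos = pos.sort_values(["__chrom_rank", "midpoint", "gene_id"], kind="stable")
    pos = pos.drop(columns="__chrom_rank").reset_index(drop=True)

    expr = cp10k_log2(matrix)  # cells x all genes; library size uses all genes
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    cols = np.array([gene_pos[g] for g in pos["gene_id"]])
    expr = expr[:, cols]

    ref_mask = np.array([b in ref for b in matrix.barcodes])
    if not ref_mask.any():
        raise ValueError("no reference barcodes found in matrix")
    resid = expr - expr[ref_mask].mean(axis=0)
    np.clip(resid, -clip, clip, out=resid)

    smoothed = np.empty_like(resid)
    for chrom in order:
        idx = np.flatnonzero((pos["chromosome"] == chrom).to_numpy())
        if len(idx) == 0:
            continue
        smoothed[:, idx] = _moving_average(resid[:, idx], smoothing_genes)
    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    return CNAGeneScores(smoothed, matrix.barcodes, pos[
        ["gene_id", "chromosome", "start", "end", "midpoint"]].copy())


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

@dataclass
class WindowProfiles:
    """Per-entity values over a fixed-width genomic window tiling.

    ``values`` is entities x windows with NaN marking windows that have no
    assigned genes (missing, not zero). ``scale`` is ``centered`` (log2,
    neutral 0) or ``ratio`` (neutral 1).
    """

    entity_ids: np.ndarray
    windows: pd.DataFrame  # chromosome, start, end
    values: np.ndarray
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in ("centered", "ratio"):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if self.values.shape != (len(self.entity_ids), len(self.windows)):
            raise ValueError("profile shape mismatch")

    def to_scale(self, scale: str) -> "WindowProfiles":
        if scale == self.scale:
            return self
        if scale == "ratio":
            vals = np.power(2.0, self.values)
        elif scale == "centered":
            vals = np.log2(self.values)
        else:
            raise ValueError(f"unknown scale tag {scale!r}")
        return WindowProfiles(self.entity_ids, self.windows, vals, scale)

    def select(self, entity_ids) -> "WindowProfiles":
        pos = {e: i for i, e in enumerate(self.entity_ids)}
        idx = np.array([pos[e] for e in entity_ids], dtype=int)
        return WindowProfiles(
            self.entity_ids[idx], self.windows, self.values[idx], self.scale
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"{r.chromosome}:{r.start}-{r.end}"
            for r in self.windows.itertuples(index=False)
        ]
        return pd.DataFrame(self.values, index=self.entity_ids, columns=cols)


def tile_windows(genome: list[tuple[str, int]], width: int) -> pd.DataFrame:
    """Fixed-width windows from coordinate 0; last window may be short."""
    if width <= 0:
        raise ValueError("window width must be positive")
    rows = []
    for chrom, length in genome:
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + width, length)))
            start += width
    return pd.DataFrame(rows, columns=["chromosome", "start", "end"])


def window_profile(
    scores: CNAGeneScores,
    width: int = 10_000_000,
    out_scale: str = "centered",
    genome: list[tuple[str, int]] | None = None,
) -> WindowProfiles:
    """Average gene scores in fixed windows (gene -> window by midpoint)."""
    if width <= 0:
        raise ValueError("window width must be positive")
    if genome is None:
        extents = scores.genes.groupby("chromosome", sort=False)["end"].max()
        genome = [(c, int(extents[c])) for c in _chromosome_order(scores.genes["chromosome"])]
    windows = tile_windows(genome, width)
    wkey = {
        (r.chromosome, r.start // width): i
        for i, r in enumerate(windows.itertuples(index=False))
    }
    gene_win = np.array([
        wkey.get((c, m // width), -1)
        for c, m in zip(scores.genes["chromosome"], scores.genes["midpoint"])
    ])
    n_dropped = int((gene_win < 0).sum())
    if n_dropped:
        logger.info("%d genes fall outside the window tiling; dropped", n_dropped)
    n_win = len(windows)
    sums = np.zeros((scores.values.shape[0], n_win))
    counts = np.bincount(gene_win[gene_win >= 0], minlength=n_win).astype(float)
    for w in range(n_win):
        cols = gene_win == w
        if cols.any():
            sums[:, w] = scores.values[:, cols].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    prof = WindowProfiles(scores.barcodes.copy(), windows, vals, "centered")
    return prof.to_scale(out_scale)


def segment_profile(
    segments: SegmentTable,
    genome: list[tuple[str, int]],
    width: int = 10_000_000,
    clone_fractions: dict | None = None,
    entity_id: str = "bulk",
) -> WindowProfiles:
    """Base-weighted mean copy ratio of a segment table over a window tiling.

    With ``clone_fractions`` the value is the clone-fraction-weighted
    mixture ``sum_c f_c * r_c + (1 - sum f_c) * 1`` averaged over the
    window's bases; without, every segment gets weight 1 (a plain bulk
    profile). Bases not covered by any segment are neutral (ratio 1).
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    windows = tile_windows(genome, width)
    vals = np.ones(len(windows))
    for i, w in enumerate(windows.itertuples(index=False)):
        wlen = w.end - w.start
        bump = 0.0
        for seg in segments.table.itertuples(index=False):
            if seg.chromosome != w.chromosome:
                continue
            ov = min(seg.end, w.end) - max(seg.start, w.start)
            if ov <= 0:
                continue
            f = 1.0
            if clone_fractions is not None and seg.clone_id is not None:
                f = float(clone_fractions[seg.clone_id])
            bump += f * (seg.copy_ratio - 1.0) * ov / wlen
        vals[i] = 1.0 + bump
    return WindowProfiles(
        np.array([entity_id], dtype=object), windows, vals[None, :], "ratio"
    )


# ---------------------------------------------------------------------------
# Calls and decision rules
# ---------------------------------------------------------------------------

def trichotomize(profile: WindowProfiles, epsilon: float = 0.05) -> np.ndarray:
    """gain/neutral/loss calls per window on the ratio scale.

    ``epsilon`` widens the neutral band around ratio 1; epsilon 0 is the
    literal rule (gain iff > 1, loss iff < 1). Missing windows stay None.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    vals = profile.to_scale("ratio").values
    calls = np.full(vals.shape, None, dtype=object)
    calls[vals > 1.0 + epsilon] = CALL_GAIN
    calls[vals < 1.0 - epsilon] = CALL_LOSS
    calls[(vals >= 1.0 - epsilon) & (vals <= 1.0 + epsilon)] = CALL_NEUTRAL
    return calls


def cell_bulk_kappa(cell_track: np.ndarray, bulk_track: np.ndarray) -> float:
    """Cohen's kappa between two call tracks, pairwise-excluding missing.

    Returns NaN when fewer than 2 windows are shared.
    """
    cell_track = np.asarray(cell_track, dtype=object).ravel()
    bulk_track = np.asarray(bulk_track, dtype=object).ravel()
    if len(cell_track) != len(bulk_track):
        raise ValueError("tracks cover different window sets")
    mask = np.array([
        c is not None and b is not None for c, b in zip(cell_track, bulk_track)
    ])
    if mask.sum() < 2:
        return float("nan")
    return stats.cohens_kappa(cell_track[mask], bulk_track[mask])


def cell_burden(profiles: WindowProfiles) -> np.ndarray:
    """Per-cell alteration burden: mean absolute centered window value."""
    vals = profiles.to_scale("centered").values
    return np.nanmean(np.abs(vals), axis=1)


def reference_threshold(
    profiles: WindowProfiles,
    reference_cells,
    level: float = 0.50,
    pool: str = "cells",
) -> float:
    """Data-driven noise floor from the reference (copy-neutral) population.

    ``pool="cells"``: the ``level`` quantile of per-cell burdens;
    ``pool="windows"``: the ``level`` quantile of all absolute window
    values. Pair the mode with the same mode in
    :func:`classify_malignant_clusters`.
    """
    sub = profiles.to_scale("centered").select(list(reference_cells))
    if pool == "cells":
        vals = cell_burden(sub)
    elif pool == "windows":
        vals = np.abs(sub.values).ravel()
    else:
        raise ValueError(f"unknown pool mode {pool!r}")
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("reference cells have no defined window values")
    return float(np.quantile(vals, level))


def classify_malignant_clusters(
    profiles: WindowProfiles,
    clusters,
    percentile: float = 10.0,
    threshold: float = 0.0,
    pool: str = "cells",
) -> dict:
    """Flag clusters whose low-percentile CNA signal exceeds a threshold.

    With the default ``pool="cells"`` each member cell is summarized by
    its burden (mean |centered window value|) and the cluster is called
    malignant iff the ``percentile``-th percentile of member burdens is
    strictly greater than ``threshold`` — i.e. at least
    ``100 - percentile`` percent of its cells show signal above the noise
    floor. ``pool="windows"`` instead pools all window values of all
    member cells and takes the percentile of their absolute values (the
    literal published wording); on continuous scores that variant barely
    moves for focal alterations, so the per-cell mode is the default.
    ``threshold=0`` is the literal rule; in practice use
    :func:`reference_threshold`. Percentiles interpolate linearly between
    order statistics.
    """
    clusters = np.asarray(clusters)
    if len(clusters) != len(profiles.entity_ids):
        raise ValueError("cluster labels do not match profile entities")
    if pool not in ("cells", "windows"):
        raise ValueError(f"unknown pool mode {pool!r}")
    vals = profiles.to_scale("centered").values
    burdens = cell_burden(profiles) if pool == "cells" else None
    out = {}
    for c in pd.unique(clusters):
        m = clusters == c
        if pool == "cells":
            sample = burdens[m]
        else:
            sample = np.abs(vals[m]).ravel()
        sample = sample[np.isfinite(sample)]
        if sample.size == 0:
            logger.info("cluster %r has no window values; skipped", c)
            continue
        q = float(np.percentile(sample, percentile))
        out[c] = q > threshold
    return out


def subpop_cna_test(
    profiles: WindowProfiles,
    cells,
    window_index: int,
    direction: str,
    min_cells: int = 5,
) -> float:
    """Directional one-sample sign test of a cell population's window ratios.

    Tests whether the population's copy-ratio values in one window lie
    above (``gain``) or below (``loss``) the neutral value 1. Returns NaN
    when fewer than ``min_cells`` cells have a defined value.
    """
    if direction not in (CALL_GAIN, CALL_LOSS):
        raise ValueError("direction must be 'gain' or 'loss'")
    vals = profiles.to_scale("ratio").select(list(cells)).values[:, window_index]
    vals = vals[np.isfinite(vals)]
    if len(vals) < min_cells:
        return float("nan")
    alternative = "greater" if direction == CALL_GAIN else "less"
    return stats.sign_test(vals, 1.0, alternative)


def find_window(profiles: WindowProfiles, chromosome: str, position: int) -> int:
    """Index of the window containing ``position`` on ``chromosome``."""
    w = profiles.windows
    hit = (w["chromosome"] == chromosome) & (w["start"] <= position) & (w["end"] > position)
    idx = np.flatnonzero(hit.to_numpy())
    if len(idx) != 1:
        raise ValueError(f"no unique window for {chromosome}:{position}")
    return int(idx[0])
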