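"""Matched two-platform synthetic cohort generator.

Produces paired FROZEN / FFPE libraries that share cell-type programs and
clonal copy-number structure but differ by platform: the FFPE platform
measures only a seeded random probe panel of genes and has a lower mean
depth. Counts are negative-binomial (Gamma-Poisson) around cell-type
program means scaled by a per-cell depth factor; genes inside a clone's
CNA segment have their means multiplied by the segment copy ratio for
cells of that clone. Doublets are sums of two cells' expected profiles
renormalized to the host cell's depth. Ground truth (cell types, clone
assignments, panel membership, doublet flags, clone segments) is returned
alongside the matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .cna import WindowProfiles, segment_profile
from .io import CellMetadata, CountMatrix, GeneAnnotation, SegmentTable


class ConfigError(ValueError):
    pass


@dataclass
class CellTypeSpec:
    name: str
    proportion: float
    is_malignant: bool = False


@dataclass
class CloneSpec:
    clone_id: str
    fraction: float  # fraction of the malignant population carrying the clone
    segments: list = field(default_factory=list)  # (chrom, start, end, copy_ratio)


@dataclass
class SynthConfig:
    """All knobs of the generator; defaults give a small 4-type cohort."""

    n_samples: int = 2
    cell_types: list = field(default_factory=lambda: [
        CellTypeSpec("immune", 0.4),
        CellTypeSpec("fibroblast", 0.2),
        CellTypeSpec("epithelial", 0.2),
        CellTypeSpec("malignant", 0.2, is_malignant=True),
    ])
    n_cells: dict = field(default_factory=lambda: {"FROZEN": 400, "FFPE": 400})
    genome: list = field(default_factory=lambda: [
        ("chr1", 100_000_000),
        ("chr2", 100_000_000),
        ("chr3", 100_000_000),
        ("chr4", 100_000_000),
        ("chr5", 100_000_000),
    ])
    n_genes: int = 1500
    gene_length: int = 2000
    n_mito_genes: int = 10
    clones: list = field(default_factory=list)
    ffpe_panel_fraction: float = 0.5
    depth_scale: dict = field(default_factory=lambda: {"FROZEN": 6000.0, "FFPE": 2000.0})
    depth_cv: float = 0.25  # lognormal sigma of the per-cell depth factor
    mito_beta: tuple = (2.0, 38.0)  # Beta(a, b); mean a/(a+b) = 5%
    doublet_rate: float = 0.05
    dispersion: float = 2.0  # NB size parameter
    n_marker_genes: int = 40
    marker_strength: float = 6.0
    platform_gene_scale_sd: float = 0.0  # optional FFPE gene-wise lognormal effect
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_types = [
            CellTypeSpec(**ct) if isinstance(ct, dict) else ct for ct in self.cell_types
        ]
        self.clones = [
            CloneSpec(**cl) if isinstance(cl, dict) else cl for cl in self.clones
        ]
        self.genome = [tuple(g) for g in self.genome]
        self.mito_beta = tuple(self.mito_beta)
        for cl in self.clones:
            cl.segments = [tuple(s) for s in cl.segments]
        props = sum(ct.proportion for ct in self.cell_types)
        if abs(props - 1.0) > 1e-9:
            raise ConfigError(f"cell-type proportions sum to {props}, not 1")
        cf = sum(cl.fraction for cl in self.clones)
        if cf > 1.0 + 1e-9:
            raise ConfigError(f"clone fractions sum to {cf} > 1")
        if not (0.0 < self.ffpe_panel_fraction <= 1.0):
            raise ConfigError("ffpe_panel_fraction must be in (0, 1]")
        if self.clones and not any(ct.is_malignant for ct in self.cell_types):
            raise ConfigError("clones configured but no cell type is malignant")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SyntheticTruth:
    """Ground truth emitted next to the synthetic matrices."""

    cells: pd.DataFrame  # barcode, sample_id, platform, cell_type, clone_id, doublet_flag
    genes: pd.DataFrame  # gene_id, in_ffpe_panel
    clone_segments: SegmentTable
    clone_fractions: dict
    config: SynthConfig


def _gene_annotation(config: SynthConfig, rng: np.random.Generator) -> GeneAnnotation:
    lengths = np.array([l for _, l in config.genome], dtype=float)
    chrom_p = lengths / lengths.sum()
    chrom_idx = rng.choice(len(config.genome), size=config.n_genes, p=chrom_p)
    starts = np.array([
        int(rng.integers(0, config.genome[c][1] - config.gene_length))
        for c in chrom_idx
    ])
    rows = []
    for i, (c, s) in enumerate(zip(chrom_idx, starts)):
        rows.append((f"G{i:05d}", config.genome[c][0], int(s),
                     int(s) + config.gene_length, False))
    for j in range(config.n_mito_genes):
        rows.append((f"MT{j:03d}", "chrM", j * 1000, j * 1000 + 900, True))
    t = pd.DataFrame(rows, columns=list(GeneAnnotation.REQUIRED))
    return GeneAnnotation(t)


def _clone_multipliers(config: SynthConfig, annotation: GeneAnnotation) -> dict:
    """Per-clone vector of copy-ratio multipliers over all genes."""
    t = annotation.table
    mid = ((t["start"] + t["end"]) // 2).to_numpy()
    chrom = t["chromosome"].to_numpy()
    out = {}
    for clone in config.clones:
        mult = np.ones(len(t))
        for seg_chrom, seg_start, seg_end, ratio in clone.segments:
            inside = (chrom == seg_chrom) & (mid >= seg_start) & (mid < seg_end)
            mult[inside] = ratio
        out[clone.clone_id] = mult
    return out


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, size_param: float) -> np.ndarray:
    """Gamma-Poisson draw with mean mu and NB size parameter."""
    lam = np.zeros_like(mu)
    pos = mu > 0
    lam[pos] = rng.gamma(shape=size_param, scale=mu[pos] / size_param)
    return rng.poisson(lam)


def generate_cohort(config: SynthConfig):
    """Generate the full matched cohort.

    Returns ``(matrices, metadata, annotation, truth)`` where ``matrices``
    maps ``(sample_id, platform)`` to a :class:`CountMatrix`.
    """
    rng = np.random.default_rng(config.seed)
    annotation = _gene_annotation(config, rng)
    t = annotation.table
    mito = t["is_mitochondrial"].to_numpy()
    n_genes = len(t)
    gene_ids = t["gene_id"].to_numpy()

    # baseline relative expression and cell-type programs
    base = rng.gamma(shape=0.5, scale=1.0, size=n_genes) + 1e-4
    type_names = [ct.name for ct in config.cell_types]
    nonmito_idx = np.flatnonzero(~mito)
    marker_pool = rng.permutation(nonmito_idx)
    if len(config.cell_types) * config.n_marker_genes > len(marker_pool):
        raise ConfigError("not enough genes for disjoint marker blocks")
    programs = {}
    marker_of = np.full(n_genes, None, dtype=object)
    off = 0
    for ct in config.cell_types:
        w = base.copy()
        markers = marker_pool[off: off + config.n_marker_genes]
        off += config.n_marker_genes
        w[markers] *= config.marker_strength
        marker_of[markers] = ct.name
        programs[ct.name] = w

    # FFPE probe panel: seeded subset of non-mito genes; mito always kept
    n_panel = int(round(config.ffpe_panel_fraction * len(nonmito_idx)))
    panel = np.zeros(n_genes, dtype=bool)
    panel[rng.choice(nonmito_idx, size=n_panel, replace=False)] = True
    panel[mito] = True

    ffpe_gene_scale = np.ones(n_genes)
    if config.platform_gene_scale_sd > 0:
        ffpe_gene_scale = np.exp(rng.normal(
            -config.platform_gene_scale_sd**2 / 2,
            config.platform_gene_scale_sd, size=n_genes))

    clone_mult = _clone_multipliers(config, annotation)
    clone_ids = [cl.clone_id for cl in config.clones]
    clone_fracs = np.array([cl.fraction for cl in config.clones])
    type_props = np.array([ct.proportion for ct in config.cell_types])
    malignant_types = {ct.name for ct in config.cell_types if ct.is_malignant}

    matrices = {}
    cell_rows = []
    a, b = config.mito_beta
    for s in range(config.n_samples):
        sample_id = f"S{s + 1}"
        for platform in ("FROZEN", "FFPE"):
            n = int(config.n_cells[platform])
            types = rng.choice(type_names, size=n, p=type_props)
            clones = np.full(n, None, dtype=object)
            if clone_ids:
                malignant = np.array([ty in malignant_types for ty in types])
                probs = np.append(clone_fracs, max(0.0, 1.0 - clone_fracs.sum()))
                draw = rng.choice(len(probs), size=int(malignant.sum()), p=probs)
                assigned = np.array(
                    [clone_ids[d] if d < len(clone_ids) else None for d in draw],
                    dtype=object)
                clones[malignant] = assigned
            depth = config.depth_scale[platform] * np.exp(rng.normal(
                -config.depth_cv**2 / 2, config.depth_cv, size=n))
            mito_frac = rng.beta(a, b, size=n)

            # expected profiles; the normalizer is the clone-FREE program
            # mass, so a ratio-r segment multiplies gene means by exactly r
            mu = np.empty((n, n_genes))
            w_mito = base[mito] / base[mito].sum() if mito.any() else None
            for i in range(n):
                w = programs[types[i]]
                if platform == "FFPE":
                    w = w * ffpe_gene_scale
                norm = w[~mito].sum()
                if clones[i] is not None:
                    w = w * clone_mult[clones[i]]
                row = np.zeros(n_genes)
                row[~mito] = (1.0 - mito_frac[i]) * w[~mito] / norm
                if mito.any():
                    row[mito] = mito_frac[i] * w_mito
                mu[i] = depth[i] * row

            # doublets: expected-profile sums renormalized to host depth
            n_doub = int(round(config.doublet_rate * n))
            doublet = np.zeros(n, dtype=bool)
            if n_doub:
                hosts = rng.choice(n, size=n_doub, replace=False)
                partners = rng.integers(0, n, size=n_doub)
                for h, p in zip(hosts, partners):
                    combo = mu[h] + mu[p]
                    mu[h] = combo * (depth[h] / combo.sum())
                doublet[hosts] = True

            if platform == "FFPE":
                mu[:, ~panel] = 0.0

            counts = _nb_draw(rng, mu, config.dispersion)
            barcodes = np.array(
                [f"{sample_id}-{platform}-{i:05d}" for i in range(n)], dtype=object)
            matrices[(sample_id, platform)] = CountMatrix(
                sp.csc_matrix(counts.T.astype(np.int64)),
                gene_ids, gene_ids.copy(), barcodes)
            for i in range(n):
                cell_rows.append((barcodes[i], sample_id, platform, types[i],
                                  clones[i], bool(doublet[i])))

    cells = pd.DataFrame(cell_rows, columns=[
        "barcode", "sample_id", "platform", "cell_type", "clone_id",
        "doublet_flag"])
    metadata = CellMetadata(cells[[
        "barcode", "sample_id", "platform", "doublet_flag"]].assign(
            cell_type=cells["cell_type"]))
    genes_truth = pd.DataFrame({
        "gene_id": gene_ids,
        "in_ffpe_panel": panel,
        "marker_of": marker_of,
    })
    seg_rows = [
        {"chromosome": c, "start": s, "end": e, "copy_ratio": r,
         "clone_id": cl.clone_id}
        for cl in config.clones for (c, s, e, r) in cl.segments
    ]
    clone_segments = SegmentTable(pd.DataFrame(
        seg_rows, columns=["chromosome", "start", "end", "copy_ratio", "clone_id"]))
    truth = SyntheticTruth(
        cells=cells,
        genes=genes_truth,
        clone_segments=clone_segments,
        clone_fractions={cl.clone_id: cl.fraction for cl in config.clones},
        config=config,
    )
    return matrices, metadata, annotation, truth


def derive_bulk_cna(truth: SyntheticTruth, window_width: int = 10_000_000) -> WindowProfiles:
    """Clone-fraction-weighted mean copy ratio per genomic window.

    Window value = sum_c f_c * r_c + (1 - sum f_c) * 1, base-weighted over
    the window; windows untouched by any clone segment are exactly 1.0.
    """
    if window_width <= 0:
        raise ValueError("window width must be positive")
    return segment_profile(
        truth.clone_segments,
        genome=truth.config.genome,
        width=window_width,
        clone_fractions=truth.clone_fractions,
    )


def concat_matrices(matrices: list[CountMatrix]) -> CountMatrix:
    """Column-concatenate matrices sharing an identical gene axis."""
    first = matrices[0]
    for m in matrices[1:]:
        if not np.array_equal(m.gene_ids, first.gene_ids):
            raise ValueError("matrices have different gene axes")
    return CountMatrix(
        sp.hstack([m.counts for m in matrices], format="csc"),
        first.gene_ids,
        first.gene_symbols,
        np.concatenate([m.barcodes for m in matrices]),
    )
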