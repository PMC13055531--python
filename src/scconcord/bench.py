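"""Controlled-overlap integration benchmark.

Cohort cells are repeatedly partitioned into a FROZEN selection and an
FFPE selection of samples x cell types with controlled cell-type overlap
(complete / partial / none; default 25 / 100 / 25 scenarios). Each
scenario is embedded with a correction method (a built-in per-platform
standardization + joint PCA baseline, an uncorrected joint PCA, or any
user-registered callable), clustered over a resolution sweep with
NMI-based selection, and scored with four metrics: NMI and ARI of
clusters vs cell types, batch ASW (undefined when no cell type contains
both platforms), and PC regression of the platform covariate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Callable

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from . import stats
from .cna import cp10k_log2
from .io import CellMetadata, CountMatrix

logger = logging.getLogger(__name__)

DEFAULT_RESOLUTIONS = tuple(round(0.05 * i, 2) for i in range(1, 7))  # 0.05..0.30


@dataclass
class Scenario:
    id: str
    category: str  # complete | partial | none
    samples_a: list  # FROZEN selection
    types_a: list
    samples_b: list  # FFPE selection
    types_b: list
    shared_fraction: float

    def __post_init__(self) -> None:
        shared = set(self.types_a) & set(self.types_b)
        if self.category == "complete" and self.shared_fraction != 1.0:
            raise ValueError("complete scenario must have shared_fraction 1")
        if self.category == "none" and shared:
            raise ValueError("none scenario has shared cell types")
        if self.category == "partial" and not 0.0 < self.shared_fraction < 1.0:
            raise ValueError("partial scenario must have 0 < shared_fraction < 1")


@dataclass
class ScenarioSet:
    scenarios: list

    def __len__(self) -> int:
        return len(self.scenarios)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(s) for s in self.scenarios], fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScenarioSet":
        with open(path) as fh:
            return cls([Scenario(**d) for d in json.load(fh)])


def _shared_fraction(types_a, types_b) -> float:
    """Jaccard overlap of the two cell-type selections."""
    a, b = set(types_a), set(types_b)
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def generate_scenarios(
    metadata: CellMetadata,
    n_complete: int = 25,
    n_none: int = 25,
    n_partial: int = 100,
    seed: int = 0,
    max_retries: int = 100,
) -> ScenarioSet:
    """Random sample/cell-type partitions with controlled overlap.

    For every scenario a random non-empty subset of samples and of cell
    types defines the FROZEN selection. The FFPE selection is the same
    sets (complete), an independent re-draw resampled until the overlap is
    strictly partial (partial), or the complementary samples and cell
    types (none). Requires >= 2 cell types and >= 2 samples present on
    both platforms.
    """
    t = metadata.table
    if "cell_type" not in t.columns:
        raise ValueError("metadata needs a cell_type column")
    both = None
    for plat in ("FROZEN", "FFPE"):
        sub = t[t["platform"] == plat]
        pairs = set(zip(sub["sample_id"], sub["cell_type"]))
        both = pairs if both is None else both & pairs
    samples = sorted({s for s, _ in both})
    types = sorted({c for _, c in both})
    if len(samples) < 2 or len(types) < 2:
        raise ValueError(
            f"need >= 2 samples and >= 2 cell types on both platforms; "
            f"have {len(samples)} samples, {len(types)} types"
        )
    rng = np.random.default_rng(seed)

    def pick(pool):
        k = int(rng.integers(1, len(pool) + 1))
        return sorted(rng.choice(pool, size=k, replace=False).tolist())

    scenarios = []
    plan = (["complete"] * n_complete + ["none"] * n_none
            + ["partial"] * n_partial)
    for i, category in enumerate(plan):
        for attempt in range(max_retries):
            samples_a, types_a = pick(samples), pick(types)
            if category == "complete":
                samples_b, types_b = samples_a, types_a
            elif category == "none":
                samples_b = sorted(set(samples) - set(samples_a))
                types_b = sorted(set(types) - set(types_a))
                if not samples_b or not types_b:
                    continue
            else:
                samples_b, types_b = pick(samples), pick(types)
                if not 0.0 < _shared_fraction(types_a, types_b) < 1.0:
                    continue
            scenarios.append(Scenario(
                id=f"sc{i:03d}",
                category=category,
                samples_a=samples_a, types_a=types_a,
                samples_b=samples_b, types_b=types_b,
                shared_fraction=_shared_fraction(types_a, types_b),
            ))
            break
        else:
            raise RuntimeError(
                f"could not realize a {category} scenario in {max_retries} tries"
            )
    return ScenarioSet(scenarios)


# ---------------------------------------------------------------------------
# Correction methods
# ---------------------------------------------------------------------------

def _joint_pca(expr: np.ndarray, n_pcs: int) -> np.ndarray:
    Xc = expr - expr.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_pcs, len(S))
    return U[:, :k] * S[:k]


def _shared_gene_expr(matrices: dict, min_shared: int = 50):
    """CP10k-log blocks over the gene intersection, FROZEN block first."""
    platforms = [p for p in ("FROZEN", "FFPE") if p in matrices]
    shared = None
    for p in platforms:
        ids = set(matrices[p].gene_ids)
        shared = ids if shared is None else shared & ids
    first = matrices[platforms[0]]
    shared_ids = [g for g in first.gene_ids if g in shared]
    if len(shared_ids) < min_shared:
        raise ValueError(f"only {len(shared_ids)} shared genes (< {min_shared})")
    blocks, barcodes, labels = [], [], []
    for p in platforms:
        m = matrices[p].subset_genes(np.array(shared_ids, dtype=object))
        blocks.append(cp10k_log2(m))
        barcodes.append(m.barcodes)
        labels.extend([p] * m.n_cells)
    return blocks, np.concatenate(barcodes), np.array(labels, dtype=object)


def baseline_correct(matrices: dict, n_pcs: int = 30):
    """Per-platform gene standardization then joint PCA.

    Restricts to shared genes, CP10k-log transforms, centers and
    unit-scales every gene within each platform, concatenates cells and
    projects to ``n_pcs`` principal components. Returns
    ``(embedding, barcodes)``.
    """
    blocks, barcodes, _ = _shared_gene_expr(matrices)
    scaled = []
    for b in blocks:
        mu = b.mean(axis=0)
        sd = b.std(axis=0)
        sd[sd == 0] = 1.0
        scaled.append((b - mu) / sd)
    emb = _joint_pca(np.vstack(scaled), n_pcs)
    return emb, barcodes


def uncorrected(matrices: dict, n_pcs: int = 30):
    """Joint PCA on shared-gene CP10k-log expression, no per-platform scaling."""
    blocks, barcodes, _ = _shared_gene_expr(matrices)
    emb = _joint_pca(np.vstack(blocks), n_pcs)
    return emb, barcodes


#: registry of correction methods; external methods may be added under a
#: name and then referenced from the CLI / benchmark runner
CORRECTION_METHODS: dict[str, Callable] = {
    "baseline": baseline_correct,
    "uncorrected": uncorrected,
}


# ---------------------------------------------------------------------------
# Clustering and evaluation
# ---------------------------------------------------------------------------

def knn_graph(embedding: np.ndarray, neighbors: int = 20) -> igraph.Graph:
    """Undirected union-of-neighborhoods kNN graph (Euclidean)."""
    n = len(embedding)
    k = min(neighbors, n - 1)
    if k < 1:
        raise ValueError("need at least 2 cells")
    if k < neighbors:
        logger.info("reducing neighbors from %d to %d (n=%d)", neighbors, k, n)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def cluster_sweep(
    embedding: np.ndarray,
    cell_types,
    resolutions=DEFAULT_RESOLUTIONS,
    neighbors: int = 20,
    seed: int = 0,
):
    """Leiden modularity clustering over a resolution sweep; the partition
    maximizing NMI against ``cell_types`` wins (ties -> lowest resolution).

    Returns ``(labels, chosen_resolution)``.
    """
    cell_types = np.asarray(cell_types)
    g = knn_graph(embedding, neighbors)
    best = None
    for res in resolutions:
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=float(res),
            seed=int(seed) % (2**31 - 1),
            n_iterations=2,
        )
        labels = np.array(part.membership)
        score = stats.nmi(labels, cell_types)
        if best is None or score > best[0] + 1e-12:
            best = (score, float(res), labels)
    return best[2], best[1]


def evaluate_scenario(
    embedding: np.ndarray,
    clusters,
    cell_types,
    platform,
) -> dict:
    """The four integration metrics for one embedded scenario."""
    asw = stats.batch_asw(embedding, platform, cell_types)
    return {
        "nmi": stats.nmi(clusters, cell_types),
        "ari": stats.ari(clusters, cell_types),
        "asw_badness": asw.badness,
        "pcr": stats.pc_regression(embedding, platform),
    }


def _scenario_cells(scenario: Scenario, meta: pd.DataFrame) -> pd.DataFrame:
    a = meta[
        (meta["platform"] == "FROZEN")
        & meta["sample_id"].isin(scenario.samples_a)
        & meta["cell_type"].isin(scenario.types_a)
    ]
    b = meta[
        (meta["platform"] == "FFPE")
        & meta["sample_id"].isin(scenario.samples_b)
        & meta["cell_type"].isin(scenario.types_b)
    ]
    return pd.concat([a, b], ignore_index=True)


def run_benchmark(
    matrix: CountMatrix,
    metadata: CellMetadata,
    scenarios: ScenarioSet,
    methods=("baseline",),
    n_pcs: int = 30,
    resolutions=DEFAULT_RESOLUTIONS,
    neighbors: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full scenario x method grid and return the result table.

    One row per scenario x method with the four metrics, the scenario's
    shared cell-type fraction, and the NMI-chosen clustering resolution.
    """
    meta = metadata.aligned(matrix.barcodes)
    rows = []
    for scenario in scenarios.scenarios:
        cells = _scenario_cells(scenario, meta)
        if len(cells) < neighbors + 2:
            logger.info("scenario %s too small (%d cells); skipped",
                        scenario.id, len(cells))
            continue
        by_platform = {
            p: matrix.subset_cells(cells[cells["platform"] == p]["barcode"].to_numpy())
            for p in ("FROZEN", "FFPE")
            if (cells["platform"] == p).any()
        }
        order = {b: i for i, b in enumerate(cells["barcode"])}
        for name in methods:
            fn = CORRECTION_METHODS[name] if isinstance(name, str) else name
            emb, barcodes = fn(by_platform, n_pcs=n_pcs)
            idx = np.argsort([order[b] for b in barcodes])
            emb = emb[idx]
            cell_types = cells["cell_type"].to_numpy()
            platform = cells["platform"].to_numpy()
            clusters, res = cluster_sweep(
                emb, cell_types, resolutions=resolutions,
                neighbors=neighbors, seed=seed)
            metrics = evaluate_scenario(emb, clusters, cell_types, platform)
            rows.append({
                "scenario": scenario.id,
                "category": scenario.category,
                "method": name if isinstance(name, str) else fn.__name__,
                **metrics,
                "shared_fraction": scenario.shared_fraction,
                "chosen_resolution": res,
            })
    return pd.DataFrame(rows)


def overlap_correlation(results: pd.DataFrame, metric: str) -> tuple[float, float]:
    """Pearson correlation of a metric with the shared cell-type fraction."""
    if metric not in results.columns:
        raise ValueError(f"unknown metric {metric!r}")
    sub = results[np.isfinite(results[metric])]
    if len(sub) < 3:
        raise ValueError(f"metric {metric!r} defined in fewer than 3 scenarios")
    return stats.pearson_cor(sub["shared_fraction"], sub[metric])
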