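"""End-to-end orchestration of the synthetic study.

``run_pipeline`` wires simulate -> qc -> annotate -> cna -> bench ->
markers on a generated matched cohort, writes per-stage TSV outputs plus
a JSON summary of headline statistics, and is fully determined by the
root seed: per-stage seeds are derived by hashing the stage name with the
root seed, so stages are individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, bench, cna, markers, qc, stats
from .io import CellMetadata, write_segments
from .synth import SynthConfig, concat_matrices, derive_bulk_cna, generate_cohort

logger = logging.getLogger(__name__)

_DEFAULTS = {
    "qc": {"n_mads": 3.0, "mito_max": 0.10, "estimator": "median",
           "mad_constant": 1.4826},
    "cna": {"smoothing_genes": 101, "window_width": 10_000_000,
            "epsilon": 0.05, "percentile": 10.0,
            "threshold_mode": "reference", "threshold_level": 0.50,
            "reference_type": "immune"},
    "bench": {"n_complete": 5, "n_none": 5, "n_partial": 20, "n_pcs": 30,
              "neighbors": 15, "methods": ["baseline", "uncorrected"]},
    "markers": {"min_margin": 0.25},
}


class ConfigError(ValueError):
    pass


def stage_seed(root_seed: int, stage: str) -> int:
    """Stage-name-salted 32-bit seed derived from the root seed."""
    h = hashlib.blake2b(f"{root_seed}:{stage}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big")


@dataclass
class RunConfig:
    seed: int = 0
    synth: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    cna: dict = field(default_factory=dict)
    bench: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for section, defaults in _DEFAULTS.items():
            given = getattr(self, section)
            unknown = set(given) - set(defaults)
            if unknown:
                raise ConfigError(
                    f"unknown keys in [{section}]: {sorted(unknown)}")
            setattr(self, section, {**defaults, **given})

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else round(v, 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if obj is None or isinstance(obj, str):
        return obj
    return str(obj)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}

    # ----- simulate -------------------------------------------------------
    synth_cfg = SynthConfig(**{**config.synth,
                               "seed": stage_seed(config.seed, "synth")})
    matrices, metadata, annotation, truth = generate_cohort(synth_cfg)
    matrix = concat_matrices([matrices[k] for k in sorted(matrices)])
    meta = metadata.aligned(matrix.barcodes)
    truth_cells = truth.cells.set_index("barcode").loc[matrix.barcodes].reset_index()
    annotation.to_tsv(out / "genes.tsv")
    CellMetadata(meta).to_tsv(out / "cells.tsv")
    truth.cells.to_csv(out / "truth_cells.tsv", sep="\t", index=False)
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    write_segments(truth.clone_segments, out / "clone_segments.bed")
    summary["stages"]["simulate"] = {
        "n_cells": matrix.n_cells, "n_genes": matrix.n_genes,
        "n_samples": synth_cfg.n_samples, "n_clones": len(synth_cfg.clones),
    }

    # ----- qc -------------------------------------------------------------
    metrics = qc.compute_metrics(matrix, annotation,
                                 truth_cells["doublet_flag"].to_numpy())
    keep, reasons = qc.filter_by_library(
        metrics, meta["sample_id"], meta["platform"], **config.qc)
    qc_out = metrics.assign(keep=keep, reasons=[";".join(r) for r in reasons])
    qc_out.to_csv(out / "qc.tsv", sep="\t", index=False)
    matrix_k = matrix.subset_cells(keep)
    meta_k = meta[keep].reset_index(drop=True)
    truth_k = truth_cells[keep].reset_index(drop=True)
    summary["stages"]["qc"] = {
        "n_in": int(len(keep)), "n_kept": int(keep.sum()),
        "n_excluded": int((~keep).sum()),
    }

    # ----- annotate -------------------------------------------------------
    frozen_mask = (meta_k["platform"] == "FROZEN").to_numpy()
    reference = matrix_k.subset_cells(frozen_mask)
    centroids = annotate.build_centroids(
        reference, truth_k.loc[frozen_mask, "cell_type"].to_numpy())
    result = annotate.transfer_labels(matrix_k, centroids)
    result.table.to_csv(out / "annotation.tsv", sep="\t", index=False)
    meta_annot = CellMetadata(meta_k.drop(columns=["cell_type"], errors="ignore")
                              .assign(cell_type=result.table["cell_type"].to_numpy()))
    conf_cmp = annotate.compare_confidence(result, meta_annot)
    comp = annotate.composition_test(meta_annot)
    accuracy = float(np.mean(
        result.table["cell_type"].to_numpy() == truth_k["cell_type"].to_numpy()))
    summary["stages"]["annotate"] = {
        "accuracy_vs_truth": accuracy,
        "confidence_comparison": conf_cmp.to_dict(orient="records"),
        "composition_cmh": {"statistic": comp.statistic, "df": comp.df,
                            "pvalue": comp.pvalue},
    }

    # ----- cna ------------------------------------------------------------
    c = config.cna
    ref_barcodes = truth_k.loc[
        truth_k["cell_type"] == c["reference_type"], "barcode"].to_numpy()
    scores = cna.infer_cna_scores(matrix_k, annotation, set(ref_barcodes),
                                  smoothing_genes=c["smoothing_genes"])
    profiles = cna.window_profile(scores, width=c["window_width"],
                                  genome=synth_cfg.genome)
    bulk = derive_bulk_cna(truth, window_width=c["window_width"])
    bulk_track = cna.trichotomize(bulk, epsilon=c["epsilon"])[0]
    tracks = cna.trichotomize(profiles, epsilon=c["epsilon"])
    kappas = np.array([
        cna.cell_bulk_kappa(tracks[i], bulk_track)
        for i in range(len(profiles.entity_ids))
    ])
    threshold = 0.0
    if c["threshold_mode"] == "reference":
        threshold = cna.reference_threshold(profiles, ref_barcodes,
                                            level=c["threshold_level"])
    clusters = result.table["cell_type"].to_numpy()
    flags = cna.classify_malignant_clusters(
        profiles, clusters, percentile=c["percentile"], threshold=threshold)
    is_malig_cluster = np.array([bool(flags.get(ct, False)) for ct in clusters])
    profiles.to_frame().assign(kappa=kappas).to_csv(
        out / "cna_windows.tsv", sep="\t")
    subpop = {}
    for clone_id, grp in truth.clone_segments.table.groupby("clone_id"):
        seg = grp.iloc[0]
        widx = cna.find_window(profiles, seg["chromosome"],
                               int((seg["start"] + seg["end"]) // 2))
        direction = cna.CALL_GAIN if seg["copy_ratio"] > 1 else cna.CALL_LOSS
        cells_in = profiles.entity_ids[is_malig_cluster]
        if len(cells_in) >= 5:
            subpop[str(clone_id)] = cna.subpop_cna_test(
                profiles, cells_in, widx, direction)
    summary["stages"]["cna"] = {
        "threshold": threshold,
        "malignant_clusters": {str(k): bool(v) for k, v in flags.items()},
        "n_malignant_clusters": int(sum(flags.values())),
        "median_kappa_malignant": float(np.nanmedian(kappas[is_malig_cluster]))
        if is_malig_cluster.any() else None,
        "median_kappa_normal": float(np.nanmedian(kappas[~is_malig_cluster]))
        if (~is_malig_cluster).any() else None,
        "subpop_tests": subpop,
    }

    # ----- bench ----------------------------------------------------------
    b = config.bench
    bench_summary: dict = {}
    try:
        scenarios = bench.generate_scenarios(
            meta_annot, n_complete=b["n_complete"], n_none=b["n_none"],
            n_partial=b["n_partial"], seed=stage_seed(config.seed, "bench"))
        results = bench.run_benchmark(
            matrix_k, meta_annot, scenarios, methods=b["methods"],
            n_pcs=b["n_pcs"], neighbors=b["neighbors"],
            seed=stage_seed(config.seed, "bench-cluster"))
        results.to_csv(out / "bench.tsv", sep="\t", index=False)
        bench_summary["n_scenarios"] = len(scenarios)
        bench_summary["metric_means"] = {
            name: grp[["nmi", "ari", "asw_badness", "pcr"]].mean().to_dict()
            for name, grp in results.groupby("method")
        }
        try:
            r, p = bench.overlap_correlation(
                results[results["method"] == b["methods"][0]], "pcr")
            bench_summary["pcr_overlap_correlation"] = {"r": r, "p": p}
        except ValueError as exc:
            bench_summary["pcr_overlap_correlation"] = str(exc)
    except (ValueError, RuntimeError) as exc:
        bench_summary["skipped"] = str(exc)
    summary["stages"]["bench"] = bench_summary

    # ----- markers --------------------------------------------------------
    m = config.markers
    marker_sets = [
        markers.MarkerSet(str(name), grp["gene_id"].tolist())
        for name, grp in truth.genes.dropna(subset=["marker_of"])
        .groupby("marker_of")
    ]
    marker_summary: dict = {}
    if len(marker_sets) >= 2:
        labels = markers.subtype_cells(matrix_k, marker_sets,
                                       min_margin=m["min_margin"])
        agree = float(np.mean(labels[labels != markers.UNASSIGNED]
                              == truth_k["cell_type"].to_numpy()[
                                  labels != markers.UNASSIGNED]))
        marker_summary["subtype_agreement"] = agree
        marker_summary["fraction_unassigned"] = float(
            np.mean(labels == markers.UNASSIGNED))
        gene = marker_sets[0].genes[0]
        kept_by_lib = {
            key: mat.subset_cells(np.isin(mat.barcodes, matrix_k.barcodes))
            for key, mat in matrices.items()
        }
        try:
            _, r, p = markers.cross_platform_marker_cor(
                kept_by_lib, meta_annot, gene,
                cell_type=marker_sets[0].name)
            marker_summary["xplatform"] = {"gene": gene, "r": r, "p": p}
        except ValueError as exc:
            marker_summary["xplatform"] = str(exc)
    summary["stages"]["markers"] = marker_summary

    summary = _jsonable(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
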