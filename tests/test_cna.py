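import math

import numpy as np
import pandas as pd
import pytest

from scconcord import cna
from scconcord.io import GeneAnnotation, SegmentTable
from scconcord.synth import (CellTypeSpec, CloneSpec, SynthConfig,
                             concat_matrices, derive_bulk_cna, generate_cohort)

from conftest import STANDARD_CLONE, small_cohort_config, tiny_matrix


def make_scores(values, chroms, midpoints, barcodes=None):
    values = np.asarray(values, dtype=float)
    genes = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(values.shape[1])],
        "chromosome": chroms,
        "start": [m - 500 for m in midpoints],
        "end": [m + 500 for m in midpoints],
        "midpoint": midpoints,
    })
    if barcodes is None:
        barcodes = [f"c{i}" for i in range(values.shape[0])]
    return cna.CNAGeneScores(values, np.array(barcodes, dtype=object), genes)


@pytest.fixture(scope="module")
def clone_pipeline(small_cohort):
    """Scores + window profiles for the shared clone-bearing cohort."""
    matrix = small_cohort["matrix"]
    truth = small_cohort["truth"]
    tc = truth.cells.set_index("barcode").loc[matrix.barcodes].reset_index()
    ref = tc.loc[tc["cell_type"] == "immune", "barcode"].to_numpy()
    scores = cna.infer_cna_scores(matrix, small_cohort["annotation"], set(ref))
    profiles = cna.window_profile(scores, genome=small_cohort["config"].genome)
    return {"tc": tc, "ref": ref, "scores": scores, "profiles": profiles,
            "truth": truth}


class TestInferScores:
    def test_null_scores_near_zero(self):
        # all cells identically distributed (single type, no CNA)
        cfg = SynthConfig(
            n_samples=1, cell_types=[CellTypeSpec("only", 1.0)],
            n_cells={"FROZEN": 1000, "FFPE": 2},
            genome=[("chr1", 100_000_000), ("chr2", 100_000_000)],
            n_genes=600, n_mito_genes=2, doublet_rate=0.0, seed=22,
        )
        matrices, _, ann, truth = generate_cohort(cfg)
        m = matrices[("S1", "FROZEN")]
        ref = set(m.barcodes[:300])
        scores = cna.infer_cna_scores(m, ann, ref)
        per_gene = scores.values.mean(axis=0)
        assert np.abs(per_gene).max() < 0.05

    def test_reference_mean_zero_before_recentering(self):
        # hand-built: 4 genes on one chromosome, smoothing window 1 ->
        # ref-subtraction alone determines the scores up to re-centering
        rng = np.random.default_rng(0)
        dense = rng.integers(5, 20, size=(12, 30))  # bounded range: no clipping
        m = tiny_matrix(dense)
        ann = GeneAnnotation(pd.DataFrame({
            "gene_id": m.gene_ids, "chromosome": "chr1",
            "start": np.arange(12) * 1000, "end": np.arange(12) * 1000 + 900,
            "is_mitochondrial": False}))
        ref = set(m.barcodes[:15])
        scores = cna.infer_cna_scores(m, ann, ref, smoothing_genes=1)
        # undo per-cell re-centering and check ref-mean ~ 0 per gene
        expr = cna.cp10k_log2(m)
        order = [list(m.gene_ids).index(g) for g in scores.genes["gene_id"]]
        resid = np.clip(expr[:, order]
                        - expr[np.array([b in ref for b in m.barcodes])]
                        [:, order].mean(axis=0), -3, 3)
        ref_rows = np.array([b in ref for b in scores.barcodes])
        np.testing.assert_allclose(resid[ref_rows].mean(axis=0), 0, atol=1e-10)

    def test_clone_dosage_on_log_scale(self):
        # low-noise regime (deep, mildly dispersed counts) so the log1p
        # transform does not attenuate the response: ratio 2 -> ~ +1 log2
        clone = CloneSpec("c", 1.0, [("chr1", 0, 100_000_000, 2.0)])
        cfg = SynthConfig(
            n_samples=1,
            cell_types=[CellTypeSpec("immune", 0.5),
                        CellTypeSpec("malignant", 0.5, is_malignant=True)],
            n_cells={"FROZEN": 200, "FFPE": 2},
            genome=[("chr1", 100_000_000), ("chr2", 300_000_000)],
            n_genes=400, n_mito_genes=2, n_marker_genes=10,
            depth_scale={"FROZEN": 60000.0, "FFPE": 60000.0},
            dispersion=50.0, clones=[clone], doublet_rate=0.0, seed=21,
        )
        matrices, _, ann, truth = generate_cohort(cfg)
        m = matrices[("S1", "FROZEN")]
        tc = truth.cells[truth.cells["platform"] == "FROZEN"]
        ref = set(tc.loc[tc["cell_type"] == "immune", "barcode"])
        scores = cna.infer_cna_scores(m, ann, ref)
        chr1 = (scores.genes["chromosome"] == "chr1").to_numpy()
        clone_rows = np.isin(scores.barcodes,
                             tc.loc[tc["clone_id"] == "c", "barcode"])
        mean_gain = scores.values[clone_rows][:, chr1].mean()
        assert mean_gain == pytest.approx(1.0, abs=0.3)

    def test_empty_reference_errors(self, small_cohort):
        with pytest.raises(ValueError):
            cna.infer_cna_scores(small_cohort["matrix"],
                                 small_cohort["annotation"], set())

    def test_even_smoothing_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            cna.infer_cna_scores(small_cohort["matrix"],
                                 small_cohort["annotation"], {"x"},
                                 smoothing_genes=100)

    def test_genomic_gene_order(self, clone_pipeline):
        g = clone_pipeline["scores"].genes
        for _, grp in g.groupby("chromosome"):
            assert grp["midpoint"].is_monotonic_increasing


class TestWindowProfile:
    def test_singleton_window_mean(self):
        s = make_scores([[0.8]], ["chr1"], [5_000_000])
        prof = cna.window_profile(s, width=10_000_000,
                                  genome=[("chr1", 10_000_000)])
        assert prof.values[0, 0] == pytest.approx(0.8)

    def test_empty_window_missing_not_zero(self):
        s = make_scores([[0.5]], ["chr1"], [15_000_000])
        prof = cna.window_profile(s, width=10_000_000,
                                  genome=[("chr1", 20_000_000)])
        assert math.isnan(prof.values[0, 0])
        assert prof.values[0, 1] == pytest.approx(0.5)

    def test_opposite_scores_cancel(self):
        s = make_scores([[1.0, -1.0]], ["chr1", "chr1"],
                        [1_000_000, 2_000_000])
        prof = cna.window_profile(s, width=10_000_000,
                                  genome=[("chr1", 10_000_000)])
        assert prof.values[0, 0] == pytest.approx(0.0)
        assert prof.to_scale("ratio").values[0, 0] == pytest.approx(1.0)

    def test_mass_conservation(self, clone_pipeline):
        # gene-count-weighted mean of window values == mean of gene scores
        prof = clone_pipeline["profiles"]
        scores = clone_pipeline["scores"]
        counts = scores.genes.groupby(
            [scores.genes["chromosome"],
             scores.genes["midpoint"] // 10_000_000]).size()
        wkey = [(r.chromosome, r.start // 10_000_000)
                for r in prof.windows.itertuples(index=False)]
        weights = np.array([counts.get(k, 0) for k in wkey], dtype=float)
        defined = weights > 0
        lhs = (np.nan_to_num(prof.values[:, defined])
               @ weights[defined]) / weights.sum()
        # only genes inside the tiling participate (chrM is excluded)
        tiled = scores.genes["chromosome"].isin(
            prof.windows["chromosome"]).to_numpy()
        rhs = scores.values[:, tiled].mean(axis=1)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_bad_width(self, clone_pipeline):
        with pytest.raises(ValueError):
            cna.window_profile(clone_pipeline["scores"], width=0)


class TestTrichotomize:
    def test_exact_one_is_neutral(self):
        prof = cna.WindowProfiles(
            np.array(["b"], dtype=object),
            pd.DataFrame({"chromosome": ["chr1"], "start": [0], "end": [10]}),
            np.array([[1.0]]), "ratio")
        assert cna.trichotomize(prof, epsilon=0.0)[0, 0] == cna.CALL_NEUTRAL

    def test_threshold_calls(self):
        prof = cna.WindowProfiles(
            np.array(["b"], dtype=object),
            pd.DataFrame({"chromosome": ["chr1"] * 3, "start": [0, 10, 20],
                          "end": [10, 20, 30]}),
            np.array([[1.5, 0.5, 1.03]]), "ratio")
        calls = cna.trichotomize(prof, epsilon=0.05)
        assert calls.tolist()[0] == [cna.CALL_GAIN, cna.CALL_LOSS,
                                     cna.CALL_NEUTRAL]

    def test_literal_epsilon_zero_rarely_neutral(self, clone_pipeline):
        calls = cna.trichotomize(clone_pipeline["profiles"], epsilon=0.0)
        frac_neutral = np.mean(calls == cna.CALL_NEUTRAL)
        assert frac_neutral < 0.01

    def test_negative_epsilon_rejected(self, clone_pipeline):
        with pytest.raises(ValueError):
            cna.trichotomize(clone_pipeline["profiles"], epsilon=-0.1)

    def test_missing_stays_missing(self):
        prof = cna.WindowProfiles(
            np.array(["b"], dtype=object),
            pd.DataFrame({"chromosome": ["chr1"], "start": [0], "end": [10]}),
            np.array([[np.nan]]), "ratio")
        assert cna.trichotomize(prof)[0, 0] is None


class TestKappaTrack:
    def test_identical_tracks(self):
        t = np.array(["gain", "neutral", "loss", "gain"], dtype=object)
        assert cna.cell_bulk_kappa(t, t.copy()) == 1.0

    def test_all_neutral_convention(self):
        t = np.array(["neutral"] * 5, dtype=object)
        assert cna.cell_bulk_kappa(t, t.copy()) == 1.0

    def test_missing_windows_excluded_pairwise(self):
        a = np.array(["gain", None, "loss", "gain"], dtype=object)
        b = np.array(["gain", "loss", None, "gain"], dtype=object)
        assert cna.cell_bulk_kappa(a, b) == 1.0  # only windows 0 and 3 shared

    def test_too_few_shared_is_nan(self):
        a = np.array([None, "gain"], dtype=object)
        b = np.array(["gain", None], dtype=object)
        assert math.isnan(cna.cell_bulk_kappa(a, b))

    def test_clone_cells_beat_normal_cells(self, clone_pipeline):
        # simulation-level restatement of the malignant-vs-normal split
        prof = clone_pipeline["profiles"]
        truth = clone_pipeline["truth"]
        tc = clone_pipeline["tc"]
        bulk = derive_bulk_cna(truth)
        bulk_track = cna.trichotomize(bulk)[0]
        tracks = cna.trichotomize(prof)
        kappas = np.array([cna.cell_bulk_kappa(tracks[i], bulk_track)
                           for i in range(len(prof.entity_ids))])
        clone_cells = (tc["clone_id"] == "c1").to_numpy()
        normal_cells = tc["cell_type"].ne("malignant").to_numpy()
        assert (np.nanmedian(kappas[clone_cells])
                > np.nanmedian(kappas[normal_cells]))


class TestMalignancyRule:
    def _profiles(self, values, barcodes=None):
        n_cells, n_win = values.shape
        windows = pd.DataFrame({
            "chromosome": ["chr1"] * n_win,
            "start": np.arange(n_win) * 10, "end": np.arange(n_win) * 10 + 10})
        if barcodes is None:
            barcodes = [f"c{i}" for i in range(n_cells)]
        return cna.WindowProfiles(np.array(barcodes, dtype=object), windows,
                                  np.asarray(values, dtype=float), "centered")

    def test_all_zero_cluster_not_malignant_literal(self):
        prof = self._profiles(np.zeros((4, 6)))
        flags = cna.classify_malignant_clusters(prof, ["a"] * 4, threshold=0.0)
        assert flags == {"a": False}  # 0 is not > 0

    def test_order_statistic_bound(self):
        # >=95% of values with |v| >= 0.5 -> malignant for any threshold < 0.5
        vals = np.full((20, 10), 0.7)
        vals[0, 0] = 0.0
        prof = self._profiles(vals)
        flags = cna.classify_malignant_clusters(prof, ["a"] * 20,
                                                threshold=0.4, pool="windows")
        assert flags["a"]
        flags_cells = cna.classify_malignant_clusters(prof, ["a"] * 20,
                                                      threshold=0.4)
        assert flags_cells["a"]

    def test_truth_recovery_on_synthetic(self, clone_pipeline, null_cohort):
        prof = clone_pipeline["profiles"]
        tc = clone_pipeline["tc"]
        thr = cna.reference_threshold(prof, clone_pipeline["ref"])
        flags = cna.classify_malignant_clusters(
            prof, tc["cell_type"].to_numpy(), threshold=thr)
        assert flags["malignant"]
        assert not any(flags[c] for c in ("immune", "fibroblast", "epithelial"))

    def test_windows_pool_mode_runs(self, clone_pipeline):
        prof = clone_pipeline["profiles"]
        tc = clone_pipeline["tc"]
        thr = cna.reference_threshold(prof, clone_pipeline["ref"],
                                      pool="windows", level=0.5)
        flags = cna.classify_malignant_clusters(
            prof, tc["cell_type"].to_numpy(), threshold=thr, pool="windows")
        assert set(flags) == set(tc["cell_type"].unique())

    def test_label_length_mismatch(self, clone_pipeline):
        with pytest.raises(ValueError):
            cna.classify_malignant_clusters(clone_pipeline["profiles"], ["a"])


class TestSubpopTest:
    def _ratio_profiles(self, col):
        col = np.asarray(col, dtype=float)
        windows = pd.DataFrame({"chromosome": ["chr1"], "start": [0],
                                "end": [10]})
        return cna.WindowProfiles(
            np.array([f"c{i}" for i in range(len(col))], dtype=object),
            windows, col[:, None], "ratio")

    def test_all_above_closed_form(self):
        prof = self._ratio_profiles([1.5] * 200)
        p = cna.subpop_cna_test(prof, prof.entity_ids, 0, "gain")
        assert p == pytest.approx(0.5**200, rel=1e-9)
        assert p < 1e-60

    def test_all_below_gain_is_one(self):
        prof = self._ratio_profiles([0.5] * 50)
        assert cna.subpop_cna_test(prof, prof.entity_ids, 0, "gain") == 1.0

    def test_symmetric_null_not_significant(self):
        rng = np.random.default_rng(3)
        prof = self._ratio_profiles(np.exp(rng.normal(0, 0.1, size=400)))
        p = cna.subpop_cna_test(prof, prof.entity_ids, 0, "gain")
        assert p > 0.01

    def test_too_few_cells_nan(self):
        prof = self._ratio_profiles([1.5] * 3)
        assert math.isnan(cna.subpop_cna_test(prof, prof.entity_ids, 0, "gain"))

    def test_bad_direction(self):
        prof = self._ratio_profiles([1.5] * 10)
        with pytest.raises(ValueError):
            cna.subpop_cna_test(prof, prof.entity_ids, 0, "up")


class TestSegmentProfile:
    def test_plain_bulk_profile(self):
        seg = SegmentTable(pd.DataFrame({
            "chromosome": ["chr1"], "start": [0], "end": [5_000_000],
            "copy_ratio": [3.0]}))
        prof = cna.segment_profile(seg, [("chr1", 10_000_000)], 10_000_000)
        assert prof.values[0, 0] == pytest.approx(2.0)

    def test_find_window(self):
        seg = SegmentTable(pd.DataFrame({
            "chromosome": ["chr1"], "start": [0], "end": [1],
            "copy_ratio": [2.0]}))
        prof = cna.segment_profile(seg, [("chr1", 30_000_000)], 10_000_000)
        assert cna.find_window(prof, "chr1", 15_000_000) == 1
        with pytest.raises(ValueError):
            cna.find_window(prof, "chr2", 0)
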