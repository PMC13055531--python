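# scconcord

Concordance analysis toolkit for matched-platform single-cell RNA-seq
cohorts: paired libraries of the same biopsies profiled on two platforms
(`FROZEN`, e.g. 3' snRNA-seq on frozen tissue, and `FFPE`, e.g. a
probe-panel assay on fixed tissue). The package covers the full desk-scale
workflow:

- **io** — 10x-style MatrixMarket triplets, BED-like copy-ratio segment
  tables, per-gene coordinate/mito annotation, per-cell metadata.
- **synth** — a seeded generator of matched two-platform cohorts with known
  cell-type programs, clonal copy-number segments, probe-panel restriction,
  per-platform depth, doublets and mitochondrial fractions, plus the
  derived bulk copy-number truth. All downstream stages are tested against
  this ground truth.
- **stats** — from-scratch implementations of every statistic used:
  Cohen's kappa, exact one-sample sign test, Benjamini–Hochberg FDR,
  generalized Cochran–Mantel–Haenszel (2×J×K), Pearson correlation, NMI
  (arithmetic-mean normalization), ARI, batch silhouette width (scIB
  style), and principal-component regression.
- **qc** — per-cell UMI / gene / mitochondrial metrics and per-library
  exclusion rules (3-MAD low-depth filters, 10% mito cap, doublet flags).
- **cna** — reference-normalized smoothed dosage scores from expression
  (CP10k → log2 → reference-mean subtraction → ±3 clip → moving average →
  per-cell median re-centering), fixed-width genomic windowing (default
  10 Mb), gain/neutral/loss calls, per-cell Cohen's kappa against a bulk
  segment track, cluster-level malignancy classification, and directional
  sign tests for subclonal gains/losses.
- **annotate** — correlation-centroid label transfer with a
  margin-based confidence score, cross-platform confidence comparison
  (fixed-effect OLS per cell type, BH-corrected), and the stratified
  composition test.
- **bench** — the controlled-overlap integration benchmark: 150 random
  partition scenarios (25 complete / 100 partial / 25 no overlap),
  pluggable correction methods (built-in per-platform-standardization
  baseline and an uncorrected joint PCA), Leiden clustering over a
  0.05–0.30 resolution sweep with NMI-based selection, and the four
  metrics (NMI, ARI, batch-ASW "badness", PC regression).
- **markers** — marker-set scoring, margin-rule subtyping, and per-sample
  cross-platform marker correlation.

## Conventions

- All genomic coordinates are **0-based half-open** (BED convention).
- Window profiles carry an explicit scale tag: `centered` (log2, neutral
  = 0) or `ratio` (neutral = 1; `ratio = 2**centered`).
- Genes are ordered and assigned to windows by their midpoint; windows
  tile each chromosome from coordinate 0.
- The cluster malignancy rule defaults to per-cell pooling: a cluster is
  malignant when the 10th percentile of member-cell burdens (mean absolute
  centered window value) exceeds a noise floor estimated from the
  reference cells (their median burden by default). The literal
  pooled-window variant and a zero threshold are available via
  `pool="windows"` / `threshold=0.0`.

## CLI

Everything is reachable through one entry point:

```bash
scconcord simulate --config cohort.yaml --out data/ --seed 7
scconcord qc --matrix data/S1_FROZEN --genes data/genes.tsv \
             --meta data/cells.tsv --out qc.tsv
scconcord annotate --query data/S1_FFPE --reference data/S1_FROZEN \
                   --ref-labels labels.tsv --out annot.tsv
scconcord cna --matrix data/S1_FROZEN --genes data/genes.tsv \
              --reference-barcodes ref.txt --bulk segments.bed --out cna.tsv
scconcord bench scenarios --meta data/cells.tsv --seed 7 --out scenarios.json
scconcord bench run --matrix data/all --meta data/cells.tsv \
                    --scenarios scenarios.json --method baseline --out bench.tsv
scconcord markers --matrix data/S1_FROZEN --sets markers.json --out mk.tsv
scconcord reproduce --seed 7 --out run/    # full synthetic study, one command
```

`reproduce` runs simulate → qc → annotate → cna → bench → markers and
writes per-stage TSVs plus `summary.json`; identical seeds give
byte-identical summaries. Exit codes: 0 success, 2 validation error,
1 runtime failure.

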