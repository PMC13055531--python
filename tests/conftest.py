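import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

settings.register_profile("ci", deadline=None)
settings.load_profile("ci")

from scconcord.io import CountMatrix
from scconcord.synth import (CloneSpec, SynthConfig, concat_matrices,
                             generate_cohort)


def tiny_matrix(dense, gene_ids=None, barcodes=None) -> CountMatrix:
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if barcodes is None:
        barcodes = [f"c{j}" for j in range(n_cells)]
    return CountMatrix(sp.csc_matrix(dense), np.array(gene_ids, dtype=object),
                       np.array(gene_ids, dtype=object),
                       np.array(barcodes, dtype=object))


def small_cohort_config(seed=0, clones=(), **overrides) -> SynthConfig:
    """A fast cohort: 1 sample, ~500 cells, 900 genes on a 300 Mb genome."""
    kwargs = dict(
        n_samples=1,
        n_cells={"FROZEN": 260, "FFPE": 260},
        genome=[("chr1", 100_000_000), ("chr2", 100_000_000),
                ("chr3", 100_000_000)],
        n_genes=900,
        clones=list(clones),
        seed=seed,
    )
    kwargs.update(overrides)
    return SynthConfig(**kwargs)


STANDARD_CLONE = CloneSpec(
    "c1", 1.0,
    [("chr1", 0, 60_000_000, 2.0), ("chr2", 0, 30_000_000, 2.0)],
)  # 90 Mb of a 300 Mb genome = 30%


@pytest.fixture(scope="session")
def small_cohort():
    """Clone-bearing cohort shared by cna/annotate/markers tests."""
    cfg = small_cohort_config(seed=11, clones=[STANDARD_CLONE])
    matrices, metadata, annotation, truth = generate_cohort(cfg)
    matrix = concat_matrices([matrices[k] for k in sorted(matrices)])
    return {"config": cfg, "matrices": matrices, "matrix": matrix,
            "metadata": metadata, "annotation": annotation, "truth": truth}


@pytest.fixture(scope="session")
def null_cohort():
    """Clone-free cohort (no CNA signal anywhere)."""
    cfg = small_cohort_config(seed=12)
    matrices, metadata, annotation, truth = generate_cohort(cfg)
    matrix = concat_matrices([matrices[k] for k in sorted(matrices)])
    return {"config": cfg, "matrices": matrices, "matrix": matrix,
            "metadata": metadata, "annotation": annotation, "truth": truth}
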