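"""From-scratch implementations of the statistics used across the pipeline.

Every statistic here is computed from its defining formula rather than
delegated to a library, so the rest of the package can be validated against
independent implementations. Conventions that the formulas leave open:

* NMI uses arithmetic-mean entropy normalization and is defined as 0 when
  either partition has zero entropy.
* Cohen's kappa with both raters constant: 1 if they agree, 0 otherwise.
* ``batch_asw`` follows the scIB batch-silhouette recipe and additionally
  reports a "mixing badness" orientation (0 = perfectly mixed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

#: sentinel for metrics that are undefined on the given input (e.g. batch
#: ASW when no group contains both batches)
UNDEFINED = float("nan")


def _as_labels(x) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValueError("labels must be one-dimensional")
    return arr


# ---------------------------------------------------------------------------
# Agreement between categorical sequences
# ---------------------------------------------------------------------------

def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Degenerate conventions: if both sequences are constant, kappa is 1.0
    when they agree everywhere and 0.0 otherwise (avoids 0/0).
    """
    a = _as_labels(labels_a)
    b = _as_labels(labels_b)
    if len(a) == 0:
        raise ValueError("empty label sequences")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    n = len(a)
    cats = sorted(set(a) | set(b), key=str)
    index = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    p_o = np.trace(table) / n
    p_e = float(np.sum(table.sum(axis=1) * table.sum(axis=0))) / n**2
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def nmi(a: Sequence, b: Sequence) -> float:
    """Normalized mutual information with arithmetic-mean normalization.

    Returns 0.0 when either partition has a single cluster (zero entropy).
    """
    a = _as_labels(a)
    b = _as_labels(b)
    if len(a) != len(b):
        raise ValueError("length mismatch")
    if len(a) == 0:
        raise ValueError("empty partitions")
    n = len(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    h_a = -np.sum(pa[pa > 0] * np.log(pa[pa > 0]))
    h_b = -np.sum(pb[pb > 0] * np.log(pb[pb > 0]))
    if h_a <= 0 or h_b <= 0:
        return 0.0
    nz = joint > 0
    mi = np.sum(joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz]))
    return float(min(1.0, max(0.0, mi / ((h_a + h_b) / 2.0))))


def ari(a: Sequence, b: Sequence) -> float:
    """Adjusted Rand index via the pair-counting contingency formula."""
    a = _as_labels(a)
    b = _as_labels(b)
    if len(a) != len(b):
        raise ValueError("length mismatch")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(joint).sum()
    sum_a = comb2(joint.sum(axis=1)).sum()
    sum_b = comb2(joint.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        # both partitions trivial (all singletons or single cluster)
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# Exact and classical tests
# ---------------------------------------------------------------------------

def sign_test(values: Sequence[float], null_center: float,
              alternative: str) -> float:
    """One-sided exact binomial sign test against ``null_center``.

    Ties at the center are removed; with n non-ties and k in the stated
    direction the p-value is the exact Binomial(n, 1/2) upper tail at k.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    nonties = v[v != null_center]
    n = len(nonties)
    if n == 0:
        raise ValueError("all values tied at the null center")
    if alternative == "greater":
        k = int(np.sum(nonties > null_center))
    else:
        k = int(np.sum(nonties < null_center))
    # exact upper tail P(X >= k), X ~ Binomial(n, 1/2)
    tail = sum(math.comb(n, i) for i in range(k, n + 1))
    return float(tail * 0.5**n)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass
class CMHResult:
    statistic: float
    df: int
    pvalue: float
    n_strata_used: int
    n_strata_dropped: int


def cmh_test(tables: Sequence[np.ndarray]) -> CMHResult:
    """Generalized Cochran-Mantel-Haenszel test for 2 x J x K tables.

    Tests general association of the row factor (2 levels) with the column
    factor (J levels) across K strata; chi-square reference with J - 1
    degrees of freedom. No continuity correction. Strata with a zero row or
    overall margin are dropped (counted in the result).
    """
    arrs = [np.asarray(t, dtype=float) for t in tables]
    if not arrs:
        raise ValueError("no strata")
    J = arrs[0].shape[1]
    for t in arrs:
        if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] != J:
            raise ValueError("every stratum must be a 2 x J table")
        if (t < 0).any():
            raise ValueError("negative cell count")
    d = np.zeros(J - 1)
    V = np.zeros((J - 1, J - 1))
    used = dropped = 0
    for t in arrs:
        N = t.sum()
        n1, n2 = t.sum(axis=1)
        if N < 2 or n1 == 0 or n2 == 0:
            dropped += 1
            continue
        c = t.sum(axis=0)  # column margins
        x = t[0, : J - 1]
        e = n1 * c[: J - 1] / N
        p = c[: J - 1] / N
        # hypergeometric covariance of row-1 counts
        cov = (n1 * n2 / (N - 1)) * (np.diag(p) - np.outer(p, p))
        d += x - e
        V += cov
        used += 1
    if used == 0:
        raise ValueError("all strata degenerate")
    Vinv = np.linalg.pinv(V)
    stat = float(d @ Vinv @ d)
    df = J - 1
    pvalue = float(sps.chi2.sf(stat, df))
    return CMHResult(stat, df, pvalue, used, dropped)


def pearson_cor(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc**2)))
    sy = float(np.sqrt(np.sum(yc**2)))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance")
    r = float(np.sum(xc * yc) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return r, min(1.0, p)


# ---------------------------------------------------------------------------
# Embedding-level mixing metrics
# ---------------------------------------------------------------------------

def _silhouette_samples(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Plain silhouette values, computed from the defining formula."""
    n = len(labels)
    cats, inv = np.unique(labels, return_inverse=True)
    # pairwise Euclidean distances
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    D = np.sqrt(d2)
    sil = np.zeros(n)
    sums = np.zeros((n, len(cats)))
    counts = np.bincount(inv, minlength=len(cats))
    for k in range(len(cats)):
        sums[:, k] = D[:, inv == k].sum(axis=1)
    for i in range(n):
        k = inv[i]
        if counts[k] <= 1:
            sil[i] = 0.0
            continue
        a = sums[i, k] / (counts[k] - 1)
        other = [sums[i, j] / counts[j] for j in range(len(cats)) if j != k]
        b = min(other)
        denom = max(a, b)
        sil[i] = 0.0 if denom == 0 else (b - a) / denom
    return sil


@dataclass
class BatchASWResult:
    #: scIB orientation: 1 = perfectly mixed, 0 = unmixed
    score: float
    #: 1 - score: 0 = perfectly mixed ("lower is better mixing")
    badness: float
    groups_used: int
    groups_skipped: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.score)


def batch_asw(embedding: np.ndarray, batch: Sequence, group: Sequence) -> BatchASWResult:
    """Batch silhouette width per group (cell type), scIB style.

    Within each group the silhouette of the batch labels is computed on the
    embedding, transformed per item as ``1 - |s|``, and averaged; group
    means are then averaged. Groups lacking >= 2 batches with >= 2 items
    each are skipped. If every group is skipped the result is undefined
    (NaN score) rather than a number.
    """
    X = np.asarray(embedding, dtype=float)
    batch = _as_labels(batch)
    group = _as_labels(group)
    if len(X) < 2:
        raise ValueError("need at least 2 items")
    if not (len(X) == len(batch) == len(group)):
        raise ValueError("length mismatch")
    means = []
    skipped = 0
    for g in np.unique(group):
        m = group == g
        b = batch[m]
        cats, cnt = np.unique(b, return_counts=True)
        if len(cats) < 2 or cnt.min() < 2:
            skipped += 1
            continue
        s = _silhouette_samples(X[m], b)
        means.append(float(np.mean(1.0 - np.abs(s))))
    if not means:
        return BatchASWResult(UNDEFINED, UNDEFINED, 0, skipped)
    score = float(np.mean(means))
    return BatchASWResult(score, 1.0 - score, len(means), skipped)


def pc_regression(data: np.ndarray, covariate, n_pcs: int | None = None) -> float:
    """Variance-weighted fraction of top-PC variance explained by a covariate.

    PCA is computed on the (centered) data; each of the top ``n_pcs``
    component score vectors is regressed on the covariate (one-hot encoded
    if categorical) and the R-squared values are combined weighted by the
    component variances. A constant covariate yields 0 by convention.
    """
    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    cov = np.asarray(covariate)
    if len(cov) != n:
        raise ValueError("covariate length mismatch")
    if n_pcs is None:
        n_pcs = min(50, n - 2, X.shape[1])
    if n < n_pcs + 2:
        raise ValueError("too few items for the requested number of PCs")
    if len(np.unique(cov)) < 2:
        return 0.0
    if cov.dtype.kind in "fiu" and len(np.unique(cov)) > 2:
        design = cov.astype(float)[:, None]
    else:
        _, inv = np.unique(cov, return_inverse=True)
        design = np.eye(inv.max() + 1)[inv]
    design = np.column_stack([np.ones(n), design])

    Xc = X - X.mean(axis=0)
    # PCA via SVD; scores = U * S
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_pcs, len(S))
    scores = U[:, :k] * S[:k]
    variances = (S[:k] ** 2) / (n - 1)
    r2 = np.zeros(k)
    for i in range(k):
        y = scores[:, i]
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss == 0:
            continue
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((y - design @ beta) ** 2))
        r2[i] = 1.0 - rss / tss
    total = variances.sum()
    if total == 0:
        return 0.0
    return float(np.clip(np.sum(r2 * variances) / total, 0.0, 1.0))
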