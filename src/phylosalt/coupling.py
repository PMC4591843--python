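"""Composition-function coupling: weighted UniFrac, Gower distance, Mantel test.

Weighted UniFrac sums, over every branch, the branch length times the
absolute difference in the fraction of each sample's reads descending
through that branch; the normalized variant divides by the abundance-
weighted root-distance sum, bounding it in [0, 1]. The raw variant is the
default. Gower distance is the range-normalized mean absolute difference
across functional variables with pairwise-complete handling of missing
values. The Mantel test correlates the lower triangles of two distance
matrices with a joint row/column permutation null.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from ._util import derive_rng, log_stage, logger
from .io import TaxonCountTable
from .phylo import TreeIndex


def weighted_unifrac(
    table: TaxonCountTable,
    tree: TreeNode | TreeIndex,
    normalized: bool = False,
) -> DistanceMatrix:
    """Weighted UniFrac distances between all sample pairs.

    The table's taxa must all be tips of the tree (apply
    :func:`phylosalt.io.align_inputs` first); samples with zero totals are
    an error.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    missing = [t for t in table.taxon_ids if t not in index.tip_pos]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing[:10]}")
    rel = table.relative_abundance()  # taxa x samples, columns sum to 1
    # branch-flow matrix: fraction of each sample's reads through each edge
    order = index.tip_indices(table.taxon_ids)
    p = np.zeros((index.n_tips, rel.shape[1]))
    p[order] = rel.to_numpy()
    flow = index.incidence.astype(float) @ p  # (n_edges, n_samples)
    lengths = index.edge_lengths
    a = flow.T  # (n_samples, n_edges)
    diff = np.abs(a[:, None, :] - a[None, :, :])
    raw = diff @ lengths
    if normalized:
        denom = (a[:, None, :] + a[None, :, :]) @ lengths
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(denom > 0, raw / np.where(denom > 0, denom, 1.0), 0.0)
    else:
        out = raw
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 0.0)
    log_stage("weighted_unifrac", samples=rel.shape[1], normalized=normalized)
    return DistanceMatrix(out, ids=table.sample_ids)


def gower_distance(functions: pd.DataFrame) -> DistanceMatrix:
    """Gower distance between samples over numeric functional variables.

    Each variable is scaled by its observed range; per-pair distance is the
    mean over variables where both samples are observed. Zero-range
    variables are dropped with a warning (all zero-range is an error).
    """
    num = functions.apply(pd.to_numeric, errors="coerce")
    if num.shape[1] < 1:
        raise ValueError("function table needs at least one variable")
    rng_ = num.max() - num.min()
    zero = rng_.index[(rng_ == 0) | rng_.isna()].tolist()
    if zero:
        if len(zero) == num.shape[1]:
            raise ValueError("all functional variables have zero range")
        logger.warning("gower_distance: dropping zero-range variable(s) %s", zero)
        num = num.drop(columns=zero)
        rng_ = rng_.drop(zero)
    x = num.to_numpy(dtype=float)
    scaled = x / rng_.to_numpy()
    mask = np.isfinite(scaled)
    s = np.where(mask, scaled, 0.0)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        both = mask[i] & mask
        diffs = np.abs(s[i] - s) * both
        counts = both.sum(axis=1)
        if np.any(counts == 0):
            raise ValueError("a sample pair shares no observed variables")
        d[i] = diffs.sum(axis=1) / counts
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[str(i) for i in num.index])


@dataclasses.dataclass
class MantelResult:
    """Mantel correlation between two distance matrices."""

    r: float
    p_value: float
    permutations: int
    n: int
    method: str = "pearson"
    seed: int | None = None


def _condensed(mat: np.ndarray) -> np.ndarray:
    return mat[np.tril_indices_from(mat, k=-1)]


def mantel_test(
    d1: DistanceMatrix | np.ndarray,
    d2: DistanceMatrix | np.ndarray,
    permutations: int = 999,
    seed: int | None = None,
    method: str = "pearson",
) -> MantelResult:
    """Permutation Mantel test of association between two distance matrices.

    The statistic is the Pearson (or Spearman) correlation of the strictly
    lower triangles; the null jointly permutes rows and columns of the
    second matrix. One-sided (upper-tail) rank p with the +1 convention.
    """
    if permutations < 99:
        raise ValueError("permutations must be >= 99")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if isinstance(d1, DistanceMatrix) and isinstance(d2, DistanceMatrix):
        if list(d1.ids) != list(d2.ids):
            raise ValueError("distance matrices have mismatched ids")
    x = d1.data if isinstance(d1, DistanceMatrix) else np.asarray(d1, dtype=float)
    y = d2.data if isinstance(d2, DistanceMatrix) else np.asarray(d2, dtype=float)
    if x.shape != y.shape or x.shape[0] != x.shape[1]:
        raise ValueError("distance matrices must be square and equal-sized")
    n = x.shape[0]
    rng = derive_rng(seed, "mantel")

    if method == "spearman":
        from scipy.stats import rankdata

        def stat(u, v):
            return float(np.corrcoef(rankdata(u), rankdata(v))[0, 1])
    else:
        def stat(u, v):
            return float(np.corrcoef(u, v)[0, 1])

    xv = _condensed(x)
    r_obs = stat(xv, _condensed(y))

    perms = np.array([rng.permutation(n) for _ in range(permutations)])
    permuted = y[perms[:, :, None], perms[:, None, :]]  # (P, n, n)
    tril = np.tril_indices(n, k=-1)
    yv = permuted[:, tril[0], tril[1]]  # (P, n*(n-1)/2)
    if method == "spearman":
        null = np.array([stat(xv, row) for row in yv])
    else:
        xc = xv - xv.mean()
        xn = xc / np.linalg.norm(xc)
        yc = yv - yv.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(yc, axis=1)
        null = (yc @ xn) / np.where(norms > 0, norms, np.inf)
    p = (int((null >= r_obs).sum()) + 1) / (permutations + 1)
    log_stage("mantel_test", n=n, permutations=permutations, r=round(r_obs, 4))
    return MantelResult(r=r_obs, p_value=p, permutations=permutations,
                        n=n, method=method, seed=seed)
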